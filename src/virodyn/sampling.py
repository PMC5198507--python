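"""Seeded random admissible models for property-based verification.

The threshold theory makes sharp claims over *families* of models (sign
lemmas, R1 < R0, regime-wise global stability).  This module draws random
models that satisfy H1–H4 by construction, either unconstrained or steered
into a prescribed threshold regime.

Regime steering uses the closed forms available for the bilinear/linear/
identity family (f = βxv, s = λ − dx, g_i = ξ):

    R0 = kβx̄e/(au),  R1 = R0·d/(d + βv2),  R2 = R0·d/(d + βv3),
    R4 = v3/v2,       R3 = R1/R4,

with v2 = h/r and v3 = bk·e^{−m2τ2}/(cu); so v2 and v3 (hence h, b) can be
solved from any target (R1, R2, R3, R4) pattern.  All draws flow through a
single seeded NumPy generator, so suites are reproducible.
"""

from __future__ import annotations

import math

import numpy as np

from .equilibria import compute_thresholds
from .model import ModelSpec, RateParameters

__all__ = ["random_model", "random_model_in_regime", "random_history"]


def _base_rates(rng: np.random.Generator) -> dict:
    return {
        "a": rng.uniform(0.3, 1.0),
        "k": rng.uniform(0.5, 3.0),
        "u": rng.uniform(1.0, 4.0),
        "p": rng.uniform(0.5, 2.0),
        "q": rng.uniform(0.5, 2.0),
        "c": rng.uniform(0.1, 0.5),
        "r": rng.uniform(0.5, 2.0),
        "m1": rng.uniform(0.01, 0.1),
        "m2": rng.uniform(0.01, 0.1),
        "tau1": rng.uniform(0.0, 2.0),
        "tau2": rng.uniform(0.0, 2.0),
        "tau3": rng.uniform(0.0, 2.0),
    }


def random_model(rng: np.random.Generator, incidence: str | None = None) -> ModelSpec:
    """A random model satisfying H1–H4 (unconstrained thresholds)."""
    lam = rng.uniform(5.0, 20.0)
    d = rng.uniform(0.05, 0.2)
    base = _base_rates(rng)
    base["b"] = rng.uniform(0.05, 0.5)
    base["h"] = rng.uniform(0.05, 1.0)
    xbar = lam / d
    if incidence is None:
        incidence = rng.choice(["bilinear", "saturated", "holling2", "crowley_martin"])
    if incidence == "bilinear":
        inc = ("bilinear", {"beta": rng.uniform(0.1, 5.0) / xbar})
    elif incidence == "saturated":
        inc = ("saturated", {"beta": rng.uniform(0.1, 5.0) / xbar, "b": rng.uniform(0.01, 0.5)})
    elif incidence == "holling2":
        inc = ("holling2", {"beta": rng.uniform(0.1, 5.0) / xbar, "a": rng.uniform(0.001, 0.05)})
    else:
        inc = ("crowley_martin", {"beta": rng.uniform(0.1, 5.0) / xbar,
                                  "a": rng.uniform(0.001, 0.05), "b": rng.uniform(0.01, 0.5)})
    rates = RateParameters(**base)
    return ModelSpec.build("linear", {"lam": lam, "d": d}, inc[0], inc[1],
                           ["identity"] * 4, rates)


def random_model_in_regime(rng: np.random.Generator, regime: str,
                           tau3_zero: bool | None = None,
                           max_tries: int = 50) -> ModelSpec:
    """Random bilinear/linear/identity model steered into a regime.

    ``regime`` is one of E0..E4 (the equilibrium the theory predicts to be
    globally stable there).  For E3/E4 the delay τ3 is set to 0 unless
    ``tau3_zero=False`` is forced.
    """
    if regime not in ("E0", "E1", "E2", "E3", "E4"):
        raise ValueError(f"unknown regime {regime!r}")
    if tau3_zero is None:
        tau3_zero = regime in ("E3", "E4")
    for _ in range(max_tries):
        model = _steered(rng, regime, tau3_zero)
        if model is None:
            continue
        t = compute_thresholds(model)
        if _matches(t, regime):
            return model
    raise RuntimeError(f"could not steer a model into regime {regime}")


def _matches(t, regime: str) -> bool:
    if regime == "E0":
        return t.R0 <= 1.0
    if regime == "E1":
        return t.R0 > 1.0 and t.R1 is not None and t.R1 <= 1.0 \
            and t.R2 is not None and t.R2 <= 1.0
    if regime == "E2":
        return t.R1 is not None and t.R1 > 1.0 and t.R3 is not None and t.R3 <= 1.0
    if regime == "E3":
        return t.R2 is not None and t.R2 > 1.0 and t.R4 is not None and t.R4 <= 1.0
    return t.R3 is not None and t.R3 > 1.0 and t.R4 is not None and t.R4 > 1.0


def _steered(rng: np.random.Generator, regime: str, tau3_zero: bool) -> ModelSpec | None:
    lam = rng.uniform(5.0, 20.0)
    d = rng.uniform(0.05, 0.2)
    xbar = lam / d
    base = _base_rates(rng)
    if tau3_zero:
        base["tau3"] = 0.0
    a, k, u, c = base["a"], base["k"], base["u"], base["c"]
    e12 = math.exp(-base["m1"] * base["tau1"] - base["m2"] * base["tau2"])
    e2 = math.exp(-base["m2"] * base["tau2"])

    if regime == "E0":
        R0 = rng.uniform(0.2, 0.9)
    else:
        R0 = rng.uniform(2.0, 6.0)
    beta = R0 * a * u / (k * e12 * xbar)

    def v_for(R_target: float) -> float:
        # R_target = R0·d/(d + β·v)  ⇒  v = d(R0/R_target − 1)/β
        return d * (R0 / R_target - 1.0) / beta

    if regime == "E0":
        base["b"], base["h"] = rng.uniform(0.05, 0.5), rng.uniform(0.05, 1.0)
    elif regime == "E1":
        v2 = v_for(rng.uniform(0.3, 0.8))
        v3 = v_for(rng.uniform(0.3, 0.8))
        base["h"] = base["r"] * v2
        base["b"] = v3 * c * u / (k * e2)
    elif regime == "E2":
        v2 = v_for(rng.uniform(1.5, 3.0))      # R1 > 1
        base["h"] = base["r"] * v2
        # R3 = R1/R4 = R1·v2/v3 ≤ target < 1 ⇒ v3 = v2·R1/target
        R1 = R0 * d / (d + beta * v2)
        v3 = v2 * R1 / rng.uniform(0.3, 0.8)
        base["b"] = v3 * c * u / (k * e2)
    elif regime == "E3":
        v3 = v_for(rng.uniform(1.5, 4.0))      # R2 > 1
        base["b"] = v3 * c * u / (k * e2)
        v2 = v3 / rng.uniform(0.3, 0.9)        # R4 = v3/v2 ≤ 1
        base["h"] = base["r"] * v2
    else:  # E4: need R1 > R4 > 1 with R3 = R1/R4
        R4t = rng.uniform(1.2, 2.0)
        R1t = R4t * rng.uniform(1.3, 2.5)      # R3 = R1/R4 > 1
        if R1t >= R0:
            return None
        v2 = v_for(R1t)
        v3 = R4t * v2
        base["h"] = base["r"] * v2
        base["b"] = v3 * c * u / (k * e2)
    if base["b"] <= 0 or base["h"] <= 0:
        return None
    rates = RateParameters(**base)
    return ModelSpec.build("linear", {"lam": lam, "d": d},
                           "bilinear", {"beta": beta}, ["identity"] * 4, rates)


def random_history(rng: np.random.Generator, eq_point: np.ndarray,
                   spread: float = 0.5, floor: float = 0.05) -> np.ndarray:
    """Random positive constant history around an equilibrium point."""
    factors = rng.uniform(1.0 - spread, 1.0 + spread, size=len(eq_point))
    out = eq_point * factors
    out[out <= 0.0] = floor * rng.uniform(0.5, 2.0)
    return out
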