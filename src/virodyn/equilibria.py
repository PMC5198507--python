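"""Steady states E0–E4 and the five reproduction numbers R0–R4.

The model has up to five equilibria, ordered by which defences are active:

* ``E0 = (x̄, 0, 0, 0, 0)`` — infection-free;
* ``E1 = (x1, y1, v1, 0, 0)`` — infection established, no immune response;
* ``E2 = (x2, y2, v2, 0, w2)`` — antibody response only;
* ``E3 = (x3, y3, v3, z3, 0)`` — CTL response only;
* ``E4 = (x4, y4, v4, z4, w4)`` — both responses active.

Existence is gated by five dimensionless thresholds: the basic reproduction
number ``R0`` (infection), ``R1`` (antibody establishment), ``R2`` (CTL
establishment), ``R3`` (CTL competition) and ``R4`` (antibody competition).
Each construction reduces to a single bracketed scalar root on ``(0, x̄)``,
which is provably unique under H1–H4, plus closed-form inversions of the
removal laws.

Note on ``R1``: the consistent form is
``R1 = k·e^{−m1τ1−m2τ2}·f(x2, v2) / (a·u·g2(v2))``
(the infected-cell death rate ``a`` belongs in the denominator: it is what
makes ``w2 = g3^{-1}(u(R1−1)/q)`` an identity and keeps ``R1 < R0``).
Similarly ``R4 = k·e^{−m2τ2}·g1(y4) / (u·g2(v4))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model import ModelSpec, find_growth_root, rhs

__all__ = [
    "Equilibrium",
    "ThresholdSet",
    "find_xbar",
    "compute_R0",
    "solve_E0",
    "solve_E1",
    "solve_E2",
    "solve_E3",
    "solve_E4",
    "compute_thresholds",
    "solve_all",
    "classify_regime",
    "REGIMES",
]

_BRENT_RTOL = 1e-12


@dataclass(frozen=True)
class Equilibrium:
    """A labelled steady state with existence flag and residual.

    ``residual`` is the max-norm of the steady-state system evaluated at
    the point (meaningful when ``exists``).
    """

    label: str
    x: float
    y: float
    v: float
    z: float
    w: float
    exists: bool
    residual: float = float("nan")

    @property
    def point(self) -> np.ndarray:
        return np.array([self.x, self.y, self.v, self.z, self.w])


@dataclass(frozen=True)
class ThresholdSet:
    """R0..R4 with per-value defined flags.

    ``R1``/``R2``/``R3`` need the auxiliary components ``(x2, v2)`` /
    ``(x3, v3)`` / ``(x4, v4)``, which exist whenever the corresponding
    bracketed root problem is solvable; the flags record that.
    """

    R0: float
    R1: float | None
    R2: float | None
    R3: float | None
    R4: float | None

    def defined(self, name: str) -> bool:
        return getattr(self, name) is not None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("R0", "R1", "R2", "R3", "R4")}


def _residual(model: ModelSpec, point: np.ndarray) -> float:
    d = rhs(model, point, (point, point, point))
    return float(np.max(np.abs(d)))


def find_xbar(model: ModelSpec) -> float:
    """Uninfected steady state x̄: the positive zero of the growth law."""
    return find_growth_root(model.growth)


def compute_R0(model: ModelSpec, xbar: float | None = None) -> float:
    """Basic reproduction number for viral infection.

    ``R0 = k e^{−m1τ1−m2τ2} ∂f(x̄,0)/∂v / (a·u)``: secondary infections
    produced by one infected cell in the fully susceptible state, after
    discounting eclipse and maturation mortality.
    """
    if xbar is None:
        xbar = find_xbar(model)
    r = model.rates
    return r.k * r.survival1 * r.survival2 * model.fv(xbar, 0.0) / (r.a * r.u)


def solve_E0(model: ModelSpec) -> Equilibrium:
    xbar = find_xbar(model)
    pt = np.array([xbar, 0.0, 0.0, 0.0, 0.0])
    return Equilibrium("E0", xbar, 0.0, 0.0, 0.0, 0.0, True, _residual(model, pt))


def _bracketed_root(fun, xbar: float, want_positive_left: bool = False) -> float:
    """Unique root of ``fun`` on (0, x̄), with adaptive bracket shrinking.

    ``fun`` is negative at 0+ and (for the E1 construction) returns to 0
    at x̄ itself, so the right end of the bracket must stay strictly
    inside; δ is shrunk until the sign straddles.
    """
    eps = 1e-9 * xbar
    lo = eps
    flo = fun(lo)
    delta = 1e-6 * xbar
    for _ in range(40):
        hi = xbar - delta
        if hi <= lo:
            break
        fhi = fun(hi)
        if flo * fhi < 0.0:
            return brentq(fun, lo, hi, rtol=_BRENT_RTOL, maxiter=300)
        delta *= 0.5
    raise ArithmeticError(
        f"bracketing failed on (0, x̄={xbar:.6g}): f(lo)={flo:.3g}")


def solve_E1(model: ModelSpec) -> Equilibrium:
    """Immune-free equilibrium; exists iff R0 > 1.

    Construction: ``v = φ(x) = g2^{-1}(k·s(x)·e^{−m1τ1−m2τ2}/(a·u))`` from
    the x/y/v balance, then the unique zero of
    ``G(x) = f(x, φ(x)) − (a·u·e^{m1τ1+m2τ2}/k)·g2(φ(x))`` on (0, x̄).
    """
    r = model.rates
    xbar = find_xbar(model)
    R0 = compute_R0(model, xbar)
    if R0 <= 1.0:
        return Equilibrium("E1", math.nan, math.nan, math.nan, 0.0, 0.0, False)
    au_scaled = r.a * r.u / (r.k * r.survival1 * r.survival2)

    def phi(x: float) -> float:
        return model.ginv(2, max(model.s(x), 0.0) / au_scaled)

    def G(x: float) -> float:
        v = phi(x)
        return model.f(x, v) - au_scaled * model.g(2, v)

    x1 = _bracketed_root(G, xbar)
    v1 = phi(x1)
    y1 = model.ginv(1, r.u * model.g(2, v1) / (r.k * r.survival2))
    pt = np.array([x1, y1, v1, 0.0, 0.0])
    return Equilibrium("E1", x1, y1, v1, 0.0, 0.0, True, _residual(model, pt))


def _solve_x_for_v(model: ModelSpec, v: float, xbar: float) -> float:
    """Unique root of F(x) = s(x) − f(x, v) on (0, x̄) (F is decreasing)."""
    def F(x: float) -> float:
        return model.s(x) - model.f(x, v)

    if F(xbar) >= 0.0:  # pragma: no cover - impossible for v > 0 under H2
        raise ArithmeticError("F(x̄) ≥ 0: no interior root")
    return brentq(F, 1e-12 * xbar, xbar, rtol=_BRENT_RTOL, maxiter=300)


def compute_R1(model: ModelSpec) -> float:
    """Antibody response reproductive number (needs x2, v2)."""
    r = model.rates
    xbar = find_xbar(model)
    v2 = model.ginv(2, r.h / r.r)
    x2 = _solve_x_for_v(model, v2, xbar)
    return r.k * r.survival1 * r.survival2 * model.f(x2, v2) / (r.a * r.u * model.g(2, v2))


def solve_E2(model: ModelSpec) -> tuple[Equilibrium, float]:
    """Antibody-only equilibrium and R1; E2 exists iff R1 > 1."""
    r = model.rates
    xbar = find_xbar(model)
    v2 = model.ginv(2, r.h / r.r)
    x2 = _solve_x_for_v(model, v2, xbar)
    y2 = model.ginv(1, r.survival1 * model.f(x2, v2) / r.a)
    R1 = r.k * r.survival1 * r.survival2 * model.f(x2, v2) / (r.a * r.u * model.g(2, v2))
    if R1 <= 1.0:
        return Equilibrium("E2", x2, y2, v2, 0.0, math.nan, False), R1
    w2 = model.ginv(3, r.u * (R1 - 1.0) / r.q)
    pt = np.array([x2, y2, v2, 0.0, w2])
    return Equilibrium("E2", x2, y2, v2, 0.0, w2, True, _residual(model, pt)), R1


def compute_R2(model: ModelSpec) -> float:
    """CTL immune response reproductive number (needs x3, v3)."""
    r = model.rates
    xbar = find_xbar(model)
    v3 = model.ginv(2, r.b * r.k * r.survival2 / (r.c * r.u))
    x3 = _solve_x_for_v(model, v3, xbar)
    return r.k * r.survival1 * r.survival2 * model.f(x3, v3) / (r.a * r.u * model.g(2, v3))


def solve_E3(model: ModelSpec) -> tuple[Equilibrium, float]:
    """CTL-only equilibrium and R2; E3 exists iff R2 > 1."""
    r = model.rates
    xbar = find_xbar(model)
    y3 = model.ginv(1, r.b / r.c)
    v3 = model.ginv(2, r.b * r.k * r.survival2 / (r.c * r.u))
    x3 = _solve_x_for_v(model, v3, xbar)
    R2 = r.k * r.survival1 * r.survival2 * model.f(x3, v3) / (r.a * r.u * model.g(2, v3))
    if R2 <= 1.0:
        return Equilibrium("E3", x3, y3, v3, math.nan, 0.0, False), R2
    z3 = model.ginv(4, r.a * (R2 - 1.0) / r.p)
    pt = np.array([x3, y3, v3, z3, 0.0])
    return Equilibrium("E3", x3, y3, v3, z3, 0.0, True, _residual(model, pt)), R2


def solve_E4(model: ModelSpec) -> tuple[Equilibrium, float, float]:
    """Coexistence equilibrium with R3 and R4; exists iff both exceed 1.

    ``R3 = c·e^{−m1τ1}·f(x4, v4)/(a·b)`` (CTL competition) and
    ``R4 = k·e^{−m2τ2}·g1(y4)/(u·g2(v4))`` (antibody competition; equals
    ``k·b·r·e^{−m2τ2}/(u·c·h)`` for identity removals).
    """
    r = model.rates
    xbar = find_xbar(model)
    y4 = model.ginv(1, r.b / r.c)
    v4 = model.ginv(2, r.h / r.r)
    x4 = _solve_x_for_v(model, v4, xbar)
    R3 = r.c * r.survival1 * model.f(x4, v4) / (r.a * r.b)
    R4 = r.k * r.survival2 * model.g(1, y4) / (r.u * model.g(2, v4))
    if R3 <= 1.0 or R4 <= 1.0:
        return Equilibrium("E4", x4, y4, v4, math.nan, math.nan, False), R3, R4
    z4 = model.ginv(4, r.a * (R3 - 1.0) / r.p)
    w4 = model.ginv(3, r.u * (R4 - 1.0) / r.q)
    pt = np.array([x4, y4, v4, z4, w4])
    return Equilibrium("E4", x4, y4, v4, z4, w4, True, _residual(model, pt)), R3, R4


def compute_thresholds(model: ModelSpec) -> ThresholdSet:
    """All five reproduction numbers (None where a construction fails)."""
    R0 = compute_R0(model)

    def _try(fun):
        try:
            return fun()
        except (ArithmeticError, ValueError):
            return None

    R1 = _try(lambda: compute_R1(model))
    R2 = _try(lambda: compute_R2(model))

    def _r34():
        _, R3, R4 = solve_E4(model)
        return R3, R4

    r34 = _try(_r34)
    R3, R4 = r34 if r34 is not None else (None, None)
    return ThresholdSet(R0, R1, R2, R3, R4)


def solve_all(model: ModelSpec) -> dict[str, Equilibrium]:
    """Solve E0–E4 (nonexistent ones carry ``exists=False``)."""
    e2, _ = solve_E2(model)
    e3, _ = solve_E3(model)
    e4, _, _ = solve_E4(model)
    return {
        "E0": solve_E0(model),
        "E1": solve_E1(model),
        "E2": e2,
        "E3": e3,
        "E4": e4,
    }


REGIMES = ("E0-stable", "E1-stable", "E2-stable", "E3-stable", "E4-stable", "indeterminate")


def classify_regime(model: ModelSpec, tau3_zero: bool | None = None,
                    thresholds: ThresholdSet | None = None) -> str:
    """Globally stable regime predicted by the threshold pattern.

    * R0 ≤ 1                        → E0-stable (any delays)
    * R0 > 1, R1 ≤ 1, R2 ≤ 1        → E1-stable (any delays)
    * R1 > 1, R3 ≤ 1                → E2-stable (any delays)
    * R2 > 1, R4 ≤ 1, τ3 = 0        → E3-stable
    * R3 > 1, R4 > 1, τ3 = 0        → E4-stable

    Boundary equalities count as "≤ 1" (the interior component does not
    exist there).  Parameter corners covered by none of the clauses — or
    by an E3/E4 clause when τ3 > 0, where only numerical evidence exists —
    return ``indeterminate`` listing the satisfied conditions.
    """
    t = thresholds if thresholds is not None else compute_thresholds(model)
    if tau3_zero is None:
        tau3_zero = model.rates.tau3 == 0.0
    R0, R1, R2, R3, R4 = t.R0, t.R1, t.R2, t.R3, t.R4
    if R0 <= 1.0:
        return "E0-stable"
    le = lambda val: val is not None and val <= 1.0
    gt = lambda val: val is not None and val > 1.0
    if le(R1) and le(R2):
        return "E1-stable"
    if gt(R1) and le(R3):
        return "E2-stable"
    if gt(R2) and le(R4) and tau3_zero:
        return "E3-stable"
    if gt(R3) and gt(R4) and tau3_zero:
        return "E4-stable"
    conds = [f"R0={R0:.4g}>1"]
    for name, val in (("R1", R1), ("R2", R2), ("R3", R3), ("R4", R4)):
        if val is not None:
            conds.append(f"{name}={val:.4g}{'>' if val > 1 else '≤'}1")
    return "indeterminate (" + ", ".join(conds) + f", tau3_zero={tau3_zero})"
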