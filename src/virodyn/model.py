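"""Model specification: five compartments, three delays, structural checks.

The state is ``(x, y, v, z, w)``: uninfected target cells, infected cells,
free virus, CTLs and antibodies.  The dynamics are

.. code-block:: text

    x' = s(x) − f(x, v)
    y' = e^{−m1·τ1} f(x(t−τ1), v(t−τ1)) − a·g1(y) − p·g1(y)·g4(z)
    v' = k·e^{−m2·τ2} g1(y(t−τ2)) − u·g2(v) − q·g2(v)·g3(w)
    z' = c·g1(y(t−τ3))·g4(z(t−τ3)) − b·g4(z)
    w' = r·g2(v)·g3(w) − h·g3(w)

τ1 is the eclipse (cell-infection) delay, τ2 the virion maturation delay
and τ3 the immune (CTL) activation delay; e^{−m1·τ1}, e^{−m2·τ2} are the
corresponding survival probabilities.  Time and concentration units are
abstract (the model fixes none).

The structural assumptions under which the whole analysis operates are:

H1  s has a unique positive zero x̄ with s'(x̄) < 0 (carrying state);
H2  f ≥ 0 vanishes exactly on the axes, is nondecreasing in both
    arguments, and ∂f(x,0)/∂v is nondecreasing in x;
H3  each g_i is strictly increasing, g_i(0) = 0, g_i'(0) = 1 and
    g_i(ξ) ≥ k_i·ξ for some k_i > 0;
H4  f(x, v)/g2(v) is nonincreasing in v.

These are semialgebraic/transcendental statements; they are certified on a
dense grid over the biologically relevant box, not symbolically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .forms import (
    GrowthFunction,
    IncidenceFunction,
    RemovalFunction,
    make_growth,
    make_incidence,
    make_removal,
)

__all__ = [
    "RateParameters",
    "ModelSpec",
    "GridSpec",
    "AssumptionCheck",
    "AssumptionReport",
    "validate_assumptions",
    "rhs",
    "partial_f_v",
    "find_growth_root",
]

_RATE_NAMES = ("a", "b", "c", "k", "u", "p", "q", "r", "h")


@dataclass(frozen=True)
class RateParameters:
    """Rate constants, survival exponents and delays.

    a: infected-cell death; b: CTL death; c: CTL activation; k: virus
    production; u: virus clearance; p: CTL killing; q: antibody
    neutralization; r: antibody activation; h: antibody death.
    m1, m2 are the decay exponents of the delay-survival factors; tau1,
    tau2, tau3 the delays (time units).
    """

    a: float
    b: float
    c: float
    k: float
    u: float
    p: float
    q: float
    r: float
    h: float
    m1: float
    m2: float
    tau1: float
    tau2: float
    tau3: float

    def __post_init__(self):
        for name in _RATE_NAMES:
            if getattr(self, name) <= 0.0:
                raise ValueError(f"rate {name!r} must be strictly positive")
        for name in ("m1", "m2"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"decay exponent {name!r} must be nonnegative")
        for name in ("tau1", "tau2", "tau3"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"delay {name!r} must be nonnegative")

    @property
    def survival1(self) -> float:
        """e^{−m1·τ1}: probability an infected cell survives the eclipse."""
        return math.exp(-self.m1 * self.tau1)

    @property
    def survival2(self) -> float:
        """e^{−m2·τ2}: probability a virion survives maturation."""
        return math.exp(-self.m2 * self.tau2)

    @property
    def tau_max(self) -> float:
        return max(self.tau1, self.tau2, self.tau3)


@dataclass(frozen=True)
class ModelSpec:
    """Full model: growth, incidence, four removals, rates and delays."""

    growth: GrowthFunction
    incidence: IncidenceFunction
    removals: tuple[RemovalFunction, RemovalFunction, RemovalFunction, RemovalFunction]
    rates: RateParameters

    def __post_init__(self):
        if len(self.removals) != 4:
            raise ValueError("exactly four removal functions g1..g4 are required")

    # convenience accessors -------------------------------------------------
    def s(self, x: float) -> float:
        return self.growth(x)

    def sp(self, x: float) -> float:
        return self.growth.deriv(x)

    def f(self, x: float, v: float) -> float:
        return self.incidence(x, v)

    def fx(self, x: float, v: float) -> float:
        return self.incidence.partial_x(x, v)

    def fv(self, x: float, v: float) -> float:
        return self.incidence.partial_v(x, v)

    def g(self, i: int, xi: float) -> float:
        return self.removals[i - 1](xi)

    def gp(self, i: int, xi: float) -> float:
        return self.removals[i - 1].deriv(xi)

    def ginv(self, i: int, eta: float) -> float:
        return self.removals[i - 1].inverse(eta)

    def with_rates(self, **changes) -> "ModelSpec":
        """Copy of the model with some rate/delay values replaced."""
        return replace(self, rates=replace(self.rates, **changes))

    @staticmethod
    def build(growth_form: str, growth_params: dict,
              incidence_form: str, incidence_params: dict,
              removal_forms: Sequence[str | tuple[str, dict]],
              rates: RateParameters) -> "ModelSpec":
        removals = []
        for spec in removal_forms:
            if isinstance(spec, str):
                removals.append(make_removal(spec))
            else:
                removals.append(make_removal(spec[0], spec[1]))
        return ModelSpec(
            make_growth(growth_form, growth_params),
            make_incidence(incidence_form, incidence_params),
            tuple(removals),
            rates,
        )


def find_growth_root(growth: GrowthFunction, rtol: float = 1e-12) -> float:
    """Positive zero x̄ of the growth law, with s'(x̄) < 0 (assumption H1)."""
    hi = 1.0
    for _ in range(200):
        if growth(hi) < 0.0:
            break
        hi *= 2.0
    else:
        raise ValueError("growth law has no sign change on (0, 2^200]")
    xbar = brentq(growth, 0.0, hi, rtol=rtol, maxiter=300)
    if growth.deriv(xbar) >= 0.0:
        raise ValueError(f"growth derivative at root x̄={xbar} is not negative")
    return xbar


# --------------------------------------------------------------------------
# right-hand side
# --------------------------------------------------------------------------

def rhs(model: ModelSpec,
        state: Sequence[float],
        delayed: Sequence[Sequence[float]]) -> np.ndarray:
    """Time derivatives at ``state`` given the three delayed states.

    ``delayed`` holds the full 5-vectors at lags τ1, τ2, τ3 (in that
    order).  All entries must be nonnegative.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (5,):
        raise ValueError("state must be a 5-vector")
    if len(delayed) != 3:
        raise ValueError("three delayed states (lags τ1, τ2, τ3) are required")
    dl = [np.asarray(d, dtype=float) for d in delayed]
    if state.min() < 0.0 or any(d.min() < 0.0 for d in dl):
        raise ValueError("negative state entry: model is defined on the positive orthant")
    x, y, v, z, w = state
    r = model.rates
    g1y = model.g(1, y)
    g2v = model.g(2, v)
    g3w = model.g(3, w)
    g4z = model.g(4, z)
    return np.array([
        model.s(x) - model.f(x, v),
        r.survival1 * model.f(dl[0][0], dl[0][2]) - r.a * g1y - r.p * g1y * g4z,
        r.k * r.survival2 * model.g(1, dl[1][1]) - r.u * g2v - r.q * g2v * g3w,
        r.c * model.g(1, dl[2][1]) * model.g(4, dl[2][3]) - r.b * g4z,
        r.r * g2v * g3w - r.h * g3w,
    ])


def partial_f_v(model: ModelSpec, x: float, v: float) -> float:
    """Incidence slope ∂f/∂v at ``(x, v)`` (analytic where available)."""
    if x < 0.0 or v < 0.0:
        raise ValueError("partial_f_v is defined for x ≥ 0, v ≥ 0")
    return model.fv(x, v)


# --------------------------------------------------------------------------
# assumption validation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Positive-orthant sample grid for the structural checks.

    The x-axis covers (0, 2x̄] and the v-axis (0, v_max] with at least
    ``nx``/``nv`` points; ``v_max`` should cover the virus levels the
    trajectories of interest can reach.
    """

    nx: int = 120
    nv: int = 120
    v_max: float = 10.0
    xi_max: float = 50.0  # range for the scalar removal-law checks


@dataclass(frozen=True)
class AssumptionCheck:
    name: str
    passed: bool
    detail: str = ""
    point: tuple | None = None


@dataclass(frozen=True)
class AssumptionReport:
    checks: tuple[AssumptionCheck, ...]
    xbar: float | None

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def __getitem__(self, name: str) -> AssumptionCheck:
        for c in self.checks:
            if c.name == name:
                return c
        raise KeyError(name)


def _finite_or_raise(name: str, value: float, point) -> None:
    if not math.isfinite(value):
        raise ArithmeticError(f"{name} evaluates to {value} at {point}")


def validate_assumptions(model: ModelSpec, grid: GridSpec = GridSpec()) -> AssumptionReport:
    """Check H1–H4 on a dense grid; failures carry the violating point.

    Non-finite function values raise :class:`ArithmeticError` naming the
    offending function and point.
    """
    if grid.nx < 100 or grid.nv < 100:
        raise ValueError("grid needs at least 100 points per axis")
    checks: list[AssumptionCheck] = []

    # H1: unique positive zero of s with negative slope, sign pattern around it
    xbar = None
    try:
        xbar = find_growth_root(model.growth)
    except ValueError as exc:
        checks.append(AssumptionCheck("H1", False, str(exc)))
    if xbar is not None:
        xs = np.linspace(2.0 * xbar / grid.nx, 2.0 * xbar, grid.nx)
        h1 = AssumptionCheck("H1", True, f"xbar={xbar:.6g}")
        for x in xs:
            sx = model.s(x)
            _finite_or_raise("s", sx, (x,))
            margin = 1e-9 * (1.0 + abs(x - xbar))
            if x < xbar - margin and sx <= 0.0:
                h1 = AssumptionCheck("H1", False, f"s({x:.6g}) = {sx:.3g} ≤ 0 below x̄", (x,))
                break
            if x > xbar + margin and sx >= 0.0:
                h1 = AssumptionCheck("H1", False, f"s({x:.6g}) = {sx:.3g} ≥ 0 above x̄", (x,))
                break
        checks.append(h1)
        xs_grid = xs
    else:
        xs_grid = np.linspace(1.0 / grid.nx, 2.0, grid.nx)

    vs = np.linspace(grid.v_max / grid.nv, grid.v_max, grid.nv)

    # H2: sign, axis behaviour and monotonicity of the incidence rate
    h2 = AssumptionCheck("H2", True)
    for x in xs_grid:
        if model.f(x, 0.0) != 0.0:
            h2 = AssumptionCheck("H2", False, f"f({x:.6g}, 0) ≠ 0", (x, 0.0))
            break
    if h2.passed:
        for v in vs:
            if model.f(0.0, v) != 0.0:
                h2 = AssumptionCheck("H2", False, f"f(0, {v:.6g}) ≠ 0", (0.0, v))
                break
    if h2.passed:
        for x in xs_grid:
            for v in vs:
                fxv = model.f(x, v)
                _finite_or_raise("f", fxv, (x, v))
                if fxv <= 0.0:
                    h2 = AssumptionCheck("H2", False, f"f ≤ 0 at ({x:.6g}, {v:.6g})", (x, v))
                    break
                if model.fx(x, v) < -1e-12 * (1.0 + abs(fxv)):
                    h2 = AssumptionCheck("H2", False, f"∂f/∂x < 0 at ({x:.6g}, {v:.6g})", (x, v))
                    break
                if model.fv(x, v) < -1e-12 * (1.0 + abs(fxv)):
                    h2 = AssumptionCheck("H2", False, f"∂f/∂v < 0 at ({x:.6g}, {v:.6g})", (x, v))
                    break
            if not h2.passed:
                break
    if h2.passed:
        slopes = [model.fv(x, 0.0) for x in xs_grid]
        for i in range(1, len(slopes)):
            if slopes[i] < slopes[i - 1] - 1e-10 * (1.0 + abs(slopes[i])):
                h2 = AssumptionCheck(
                    "H2", False, "∂f(x,0)/∂v decreasing in x", (xs_grid[i],))
                break
    checks.append(h2)

    # H3: each removal law increasing from 0 with unit slope and linear bound
    h3 = AssumptionCheck("H3", True)
    xis = np.linspace(grid.xi_max / max(grid.nx, grid.nv), grid.xi_max, max(grid.nx, grid.nv))
    for i, g in enumerate(model.removals, start=1):
        if g(0.0) != 0.0:
            h3 = AssumptionCheck("H3", False, f"g{i}(0) ≠ 0", (0.0,))
            break
        if abs(g.deriv(0.0) - 1.0) > 1e-12:
            h3 = AssumptionCheck("H3", False, f"g{i}'(0) = {g.deriv(0.0)!r} ≠ 1", (0.0,))
            break
        prev = 0.0
        ok = True
        for xi in xis:
            val = g(xi)
            _finite_or_raise(f"g{i}", val, (xi,))
            if val <= prev:
                h3 = AssumptionCheck(
                    "H3", False, f"g{i} not strictly increasing at ξ={xi:.6g}", (xi,))
                ok = False
                break
            if val < g.k_lower * xi * (1.0 - 1e-12):
                h3 = AssumptionCheck(
                    "H3", False, f"g{i}(ξ) < k·ξ at ξ={xi:.6g}", (xi,))
                ok = False
                break
            prev = val
        if not ok:
            break
        # inverse consistency on a few targets
        for eta in (g(xis[0]), g(xis[-1] / 2.0), g(xis[-1])):
            back = g(g.inverse(eta))
            if abs(back - eta) > 1e-9 * (1.0 + abs(eta)):
                h3 = AssumptionCheck("H3", False, f"g{i} inverse mismatch at η={eta:.6g}")
                ok = False
                break
        if not ok:
            break
    checks.append(h3)

    # H4: f(x, v)/g2(v) nonincreasing in v (jointly with g2)
    h4 = AssumptionCheck("H4", True)
    g2 = model.removals[1]
    for x in xs_grid:
        prev = None
        for v in vs:
            ratio = model.f(x, v) / g2(v)
            _finite_or_raise("f/g2", ratio, (x, v))
            if prev is not None and ratio > prev * (1.0 + 1e-10) + 1e-14:
                h4 = AssumptionCheck(
                    "H4", False, f"f/g2 increasing in v at ({x:.6g}, {v:.6g})", (x, v))
                break
            prev = ratio
        if not h4.passed:
            break
    checks.append(h4)

    return AssumptionReport(tuple(checks), xbar)
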