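"""Local linear stability via transcendental characteristic equations.

Linearising the delayed system at an equilibrium gives a characteristic
matrix

    M(λ) = λ·I − J0 − J1·e^{−λτ1} − J2·e^{−λτ2} − J3·e^{−λτ3},

where J0 collects the partials with respect to the current state and J1–J3
those with respect to the states lagged by τ1 (incidence), τ2 (virus
production) and τ3 (CTL activation).  Δ(λ) = det M(λ) is entire; the
equilibrium is linearly asymptotically stable iff all its zeros satisfy
Re λ < 0.

At E0–E3 the determinant factors into the scalar factors and reduced
determinants the theory derives (used here as a cross-check of the generic
matrix); at the coexistence equilibrium E4 only the generic matrix is
available.

Root location is numerical: Newton iterations (with a finite-difference
derivative, valid because Δ is holomorphic) started from a coarse grid,
plus an argument-principle winding count over the right-half search
rectangle to certify absence of unstable roots.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .equilibria import Equilibrium, ThresholdSet, compute_thresholds, solve_all
from .model import ModelSpec

__all__ = [
    "CharacteristicProblem",
    "StabilityReport",
    "delay_jacobians",
    "characteristic_problem",
    "characteristic_at",
    "factored_characteristic",
    "analytic_unstable_roots",
    "rightmost_root",
    "default_rectangle",
]

_AXIS_TOL = 1e-7


@dataclass
class CharacteristicProblem:
    """Δ(λ) for one equilibrium: matrix map, delays, optional factored form."""

    label: str
    delays: tuple[float, float, float]
    matrix: Callable[[complex], np.ndarray]
    factored: Callable[[complex], complex] | None = None

    def delta(self, lam: complex) -> complex:
        return complex(np.linalg.det(self.matrix(lam)))

    def __call__(self, lam: complex) -> complex:
        return self.delta(lam)


@dataclass(frozen=True)
class StabilityReport:
    label: str
    rightmost: complex | None
    unstable_count: int
    verdict: str  # stable | unstable | marginal | inconclusive
    notes: str = ""
    roots: tuple = field(default_factory=tuple)


def delay_jacobians(model: ModelSpec, eq: Equilibrium):
    """(J0, J1, J2, J3) of the right-hand side at an equilibrium."""
    r = model.rates
    x, y, v, z, w = eq.x, eq.y, eq.v, eq.z, eq.w
    fx, fv = model.fx(x, v), model.fv(x, v)
    g1, g2, g3, g4 = model.g(1, y), model.g(2, v), model.g(3, w), model.g(4, z)
    g1p, g2p, g3p, g4p = model.gp(1, y), model.gp(2, v), model.gp(3, w), model.gp(4, z)

    J0 = np.zeros((5, 5))
    J0[0, 0] = model.sp(x) - fx
    J0[0, 2] = -fv
    J0[1, 1] = -(r.a + r.p * g4) * g1p
    J0[1, 3] = -r.p * g1 * g4p
    J0[2, 2] = -(r.u + r.q * g3) * g2p
    J0[2, 4] = -r.q * g2 * g3p
    J0[3, 3] = -r.b * g4p
    J0[4, 2] = r.r * g2p * g3
    J0[4, 4] = (r.r * g2 - r.h) * g3p

    J1 = np.zeros((5, 5))
    J1[1, 0] = r.survival1 * fx
    J1[1, 2] = r.survival1 * fv

    J2 = np.zeros((5, 5))
    J2[2, 1] = r.k * r.survival2 * g1p

    J3 = np.zeros((5, 5))
    J3[3, 1] = r.c * g1p * g4
    J3[3, 3] = r.c * g1 * g4p
    return J0, J1, J2, J3


def characteristic_problem(model: ModelSpec, eq: Equilibrium) -> CharacteristicProblem:
    if not eq.exists:
        raise ValueError(f"equilibrium {eq.label} does not exist for this model")
    r = model.rates
    J0, J1, J2, J3 = delay_jacobians(model, eq)
    taus = (r.tau1, r.tau2, r.tau3)
    eye = np.eye(5)

    def matrix(lam: complex) -> np.ndarray:
        return (lam * eye - J0
                - J1 * cmath.exp(-lam * taus[0])
                - J2 * cmath.exp(-lam * taus[1])
                - J3 * cmath.exp(-lam * taus[2]))

    factored = _make_factored(model, eq)
    return CharacteristicProblem(eq.label, taus, matrix, factored)


def characteristic_at(model: ModelSpec, eq: Equilibrium, lam: complex) -> complex:
    """Δ(λ) from the generic delayed-Jacobian determinant."""
    return characteristic_problem(model, eq).delta(lam)


def _make_factored(model: ModelSpec, eq: Equilibrium):
    """Closed factored Δ(λ) at E0–E3 (None at E4)."""
    r = model.rates
    x, y, v, z, w = eq.x, eq.y, eq.v, eq.z, eq.w
    fx, fv = model.fx(x, v), model.fv(x, v)
    sp = model.sp(x)

    if eq.label == "E0":
        fv0 = model.fv(x, 0.0)
        g3p0, g4p0 = model.gp(3, 0.0), model.gp(4, 0.0)

        def factored(lam: complex) -> complex:
            quad = (lam ** 2 + (r.a + r.u) * lam + r.a * r.u
                    - r.k * fv0 * cmath.exp(-(r.m1 + lam) * r.tau1)
                    * cmath.exp(-(r.m2 + lam) * r.tau2))
            return (lam + r.h * g3p0) * (lam + r.b * g4p0) * (lam - sp) * quad

        return factored

    g1y, g2v = model.g(1, y), model.g(2, v)
    g1p, g2p = model.gp(1, y), model.gp(2, v)

    if eq.label == "E1":
        def factored(lam: complex) -> complex:
            f1 = lam + r.b - r.c * g1y * cmath.exp(-lam * r.tau3)
            e1 = cmath.exp(-(r.m1 + lam) * r.tau1)
            m3 = np.array([
                [lam - sp + fx, 0.0, fv],
                [-e1 * fx, lam + r.a * g1p, -e1 * fv],
                [0.0, -r.k * cmath.exp(-(r.m2 + lam) * r.tau2) * g1p, lam + r.u * g2p],
            ], dtype=complex)
            return (lam + r.h - r.r * g2v) * f1 * complex(np.linalg.det(m3))

        return factored

    if eq.label == "E2":
        g3w, g3p = model.g(3, w), model.gp(3, w)

        def factored(lam: complex) -> complex:
            f1 = lam + r.b - r.c * g1y * cmath.exp(-lam * r.tau3)
            e1 = cmath.exp(-(r.m1 + lam) * r.tau1)
            m4 = np.array([
                [lam - sp + fx, 0.0, fv, 0.0],
                [-e1 * fx, lam + r.a * g1p, -e1 * fv, 0.0],
                [0.0, -r.k * cmath.exp(-(r.m2 + lam) * r.tau2) * g1p,
                 lam + (r.u + r.q * g3w) * g2p, r.q * g2v * g3p],
                [0.0, 0.0, -r.r * g2p * g3w, lam + (r.h - r.r * g2v) * g3p],
            ], dtype=complex)
            return f1 * complex(np.linalg.det(m4))

        return factored

    if eq.label == "E3":
        g4z, g4p = model.g(4, z), model.gp(4, z)

        def factored(lam: complex) -> complex:
            e1 = cmath.exp(-(r.m1 + lam) * r.tau1)
            e3 = cmath.exp(-lam * r.tau3)
            m4 = np.array([
                [lam - sp + fx, 0.0, fv, 0.0],
                [-e1 * fx, lam + (r.a + r.p * g4z) * g1p, -e1 * fv, r.p * g1y * g4p],
                [0.0, -r.k * cmath.exp(-(r.m2 + lam) * r.tau2) * g1p,
                 lam + r.u * g2p, 0.0],
                [0.0, -r.c * e3 * g4z * g1p, 0.0, lam + (r.b - r.c * g1y * e3) * g4p],
            ], dtype=complex)
            return (lam + r.h - r.r * g2v) * complex(np.linalg.det(m4))

        return factored

    return None


# --------------------------------------------------------------------------
# analytic unstable roots (the theory's instability shortcuts)
# --------------------------------------------------------------------------

def _positive_root_scalar(fun, hi0: float = 1.0) -> float:
    """Positive root of a scalar function with fun(0) < 0, fun(∞) = +∞."""
    hi = hi0
    for _ in range(200):
        if fun(hi) > 0.0:
            break
        hi *= 2.0
    return brentq(fun, 0.0, hi, rtol=1e-12, maxiter=300)


def analytic_unstable_roots(model: ModelSpec, eq: Equilibrium,
                            thresholds: ThresholdSet | None = None) -> list[float]:
    """Proven positive real characteristic roots at E0–E3.

    * E0, R0 > 1: the quadratic-with-delay factor has f(0) = a·u(1−R0) < 0.
    * E1, R1 > 1: the antibody factor root λ* = r·g2(v1) − h.
    * E1, R2 > 1 and E2, R3 > 1: the CTL factor λ + b − c·g1(y)e^{−λτ3}
      has a negative value at 0, hence a positive root.
    * E3, R4 > 1: λ* = r·g2(v3) − h.
    """
    if not eq.exists:
        return []
    t = thresholds if thresholds is not None else compute_thresholds(model)
    r = model.rates
    roots: list[float] = []
    if eq.label == "E0" and t.R0 > 1.0:
        xbar = eq.x
        fv0 = model.fv(xbar, 0.0)

        def f0(lam: float) -> float:
            return (lam * lam + (r.a + r.u) * lam + r.a * r.u
                    - r.k * fv0 * math.exp(-(r.m1 + lam) * r.tau1
                                           - (r.m2 + lam) * r.tau2))

        roots.append(_positive_root_scalar(f0))
    elif eq.label == "E1":
        if t.R1 is not None and t.R1 > 1.0:
            roots.append(r.r * model.g(2, eq.v) - r.h)
        if t.R2 is not None and t.R2 > 1.0:
            g1y = model.g(1, eq.y)
            roots.append(_positive_root_scalar(
                lambda lam: lam + r.b - r.c * g1y * math.exp(-lam * r.tau3)))
    elif eq.label == "E2":
        if t.R3 is not None and t.R3 > 1.0:
            g1y = model.g(1, eq.y)
            roots.append(_positive_root_scalar(
                lambda lam: lam + r.b - r.c * g1y * math.exp(-lam * r.tau3)))
    elif eq.label == "E3":
        if t.R4 is not None and t.R4 > 1.0:
            roots.append(r.r * model.g(2, eq.v) - r.h)
    return [lam for lam in roots if lam > 0.0]


# --------------------------------------------------------------------------
# numerical rightmost-root search
# --------------------------------------------------------------------------

def default_rectangle(model: ModelSpec,
                      eq: Equilibrium | None = None) -> tuple[float, float, float]:
    """(σmin, σmax, ωmax) covering the dominant roots at desk scales.

    Root chains of delay equations run off to the left, so σmin only needs
    to reach moderately negative values; ωmax shrinks-inverse with the
    largest delay (longer delays move the first chain closer to the axis).
    When the equilibrium is supplied, σmax additionally covers the scalar
    factor roots ``c·g1(y) − b`` and ``r·g2(v) − h``, which can exceed any
    single rate constant.
    """
    r = model.rates
    sigma = max(r.a, r.u, r.b, r.h)
    rate_max = max(r.a, r.b, r.c, r.k, r.u, r.p, r.q, r.r, r.h)
    if eq is not None and eq.exists:
        rate_max = max(rate_max,
                       r.c * model.g(1, eq.y) - r.b,
                       r.r * model.g(2, eq.v) - r.h)
    tau_max = r.tau_max
    omega = 50.0 / min(1.0, tau_max) if tau_max > 0 else 50.0
    return (-2.0 * sigma, 1.0 + rate_max, omega)


def _newton_refine(delta, lam: complex, tol: float = 1e-10, maxiter: int = 60) -> complex | None:
    try:
        for _ in range(maxiter):
            if abs(lam) > 1e6:  # wandered off; e^{−λτ} would overflow anyway
                return None
            f = delta(lam)
            step_h = 1e-7 * (1.0 + abs(lam))
            df = (delta(lam + step_h) - delta(lam - step_h)) / (2.0 * step_h)
            if df == 0:
                return None
            dlam = f / df
            lam = lam - dlam
            if abs(dlam) < tol * (1.0 + abs(lam)):
                if abs(delta(lam)) < 1e-6 * (1.0 + abs(delta(lam + 0.1))):
                    return lam
                return None
    except (OverflowError, ZeroDivisionError):
        return None
    return None


def _winding_number(delta, re_lo, re_hi, im_lo, im_hi,
                    tau_total: float = 0.0, max_depth: int = 14) -> float:
    """Winding of Δ around 0 along the rectangle boundary (counterclockwise).

    The initial sampling density resolves the e^{−λτ} phase rotation
    (rate ≈ Στ_i along the vertical edges) so that no segment can alias a
    full turn; segments whose phase increment still exceeds π/2 are then
    bisected adaptively.
    """
    corners = [complex(re_hi, im_lo), complex(re_hi, im_hi),
               complex(re_lo, im_hi), complex(re_lo, im_lo)]
    spacing = 1.2 / (1.0 + tau_total)
    pts: list[complex] = []
    for i in range(4):
        a, b = corners[i], corners[(i + 1) % 4]
        n0 = min(6000, max(64, int(math.ceil(abs(b - a) / spacing))))
        for k in range(n0):
            pts.append(a + (b - a) * (k / n0))
    total = 0.0
    n = len(pts)
    vals = [delta(p) for p in pts]
    for i in range(n):
        a, b = pts[i], pts[(i + 1) % n]
        fa, fb = vals[i], vals[(i + 1) % n]
        total += _phase_increment(delta, a, b, fa, fb, max_depth)
    return total / (2.0 * math.pi)


def _phase_increment(delta, a, b, fa, fb, depth: int) -> float:
    """Phase change of Δ from a to b, bisecting until alias-safe.

    A wrapped increment below π/2 can still hide a full turn (a zero just
    off the contour spins the phase by 2π+ε within one segment), so a
    segment is accepted only when a midpoint split reproduces its
    increment exactly; otherwise both halves are refined.
    """
    if fa == 0 or fb == 0:
        raise ZeroDivisionError("characteristic value vanishes on the contour")
    dphi = cmath.phase(fb / fa)
    if depth <= 0:
        return dphi
    mid = 0.5 * (a + b)
    fm = delta(mid)
    if fm == 0:
        raise ZeroDivisionError("characteristic value vanishes on the contour")
    d1 = cmath.phase(fm / fa)
    d2 = cmath.phase(fb / fm)
    if (abs(dphi) <= math.pi / 2.0 and abs(d1) <= math.pi / 2.0
            and abs(d2) <= math.pi / 2.0 and abs(d1 + d2 - dphi) < 1e-9):
        return dphi
    return (_phase_increment(delta, a, mid, fa, fm, depth - 1)
            + _phase_increment(delta, mid, b, fm, fb, depth - 1))


def rightmost_root(problem: CharacteristicProblem,
                   rectangle: tuple[float, float, float],
                   n_starts: tuple[int, int] = (12, 9)) -> StabilityReport:
    """Locate characteristic roots in the rectangle and classify stability.

    ``rectangle = (σmin, σmax, ωmax)``; the imaginary axis is searched on
    [0, ωmax] (roots come in conjugate pairs).  Verdicts:

    * ``unstable``  — a refined root with Re λ > 1e−7 was found;
    * ``marginal``  — the rightmost located root sits on the axis within
      1e−7 (Hopf candidate);
    * ``stable``    — winding count over the right-half sub-rectangle is 0;
    * ``inconclusive`` — the winding integral would not settle.
    """
    sig_lo, sig_hi, om_hi = rectangle
    delta = problem.delta

    res = np.linspace(sig_lo, sig_hi, n_starts[0])
    ims = np.linspace(0.0, om_hi, n_starts[1])
    roots: list[complex] = []
    for a in res:
        for b in ims:
            lam = _newton_refine(delta, complex(a, b))
            if lam is None:
                continue
            if not (sig_lo - 1e-6 <= lam.real <= sig_hi + 1e-6
                    and -1e-6 <= abs(lam.imag) <= om_hi + 1e-6):
                continue
            lam = complex(lam.real, abs(lam.imag))
            if all(abs(lam - r0) > 1e-6 for r0 in roots):
                roots.append(lam)
    roots.sort(key=lambda lam: -lam.real)
    rightmost = roots[0] if roots else None

    verified_unstable = [lam for lam in roots if lam.real > _AXIS_TOL]
    marginal = [lam for lam in roots if abs(lam.real) <= _AXIS_TOL]

    winding = None
    tau_total = sum(problem.delays)
    eps = 1e-4
    for attempt in range(3):
        try:
            w = _winding_number(delta, eps, sig_hi + eps * (1 + attempt),
                                -om_hi - eps * attempt, om_hi + eps * attempt,
                                tau_total)
        except ZeroDivisionError:
            eps *= 3.7
            continue
        if abs(w - round(w)) < 0.25:
            winding = int(round(w))
            break
        eps *= 3.7
    n_unstable = winding if winding is not None else len(verified_unstable)

    if verified_unstable:
        verdict = "unstable"
    elif winding is not None and winding > 0:
        verdict = "inconclusive"  # contour says roots exist, none verified
    elif marginal:
        verdict = "marginal"
    elif winding == 0:
        verdict = "stable"
    else:
        verdict = "inconclusive"
    notes = f"winding={winding}, refined_roots={len(roots)}"
    return StabilityReport(problem.label, rightmost, n_unstable, verdict, notes,
                           tuple(roots))


def analyze_equilibrium(model: ModelSpec, label: str,
                        rectangle: tuple[float, float, float] | None = None) -> StabilityReport:
    """Convenience: solve the equilibrium, build Δ, run the root search."""
    eqs = solve_all(model)
    eq = eqs[label]
    if not eq.exists:
        return StabilityReport(label, None, 0, "inconclusive", "equilibrium does not exist")
    problem = characteristic_problem(model, eq)
    rect = rectangle if rectangle is not None else default_rectangle(model, eq)
    return rightmost_root(problem, rect)
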