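"""Oscillation detection, immune-delay scans and Lyapunov functionals.

The theory settles the τ3 = 0 dynamics completely via five Lyapunov
functionals V1–V5 (one per equilibrium).  For τ3 > 0 the CTL equilibria can
lose stability through Hopf bifurcations and regain it — stability
switches — which this module detects empirically: integrate, discard the
transient, measure post-transient relative amplitudes, and classify each
τ3 grid point as ``converged`` / ``oscillatory`` / ``undecided``.

The Lyapunov functionals are evaluated numerically along simulated
trajectories.  Each uses the building block ``H(ξ) = ξ − 1 − ln ξ ≥ 0``
(zero only at ξ = 1) and compartment terms of Volterra type,

    Φ(u) = u − u* − ∫_{u*}^{u} ĝ(u*)/ĝ(θ) dθ  ≥ 0,

anchored so every functional vanishes at its reference equilibrium.
Delay-window integrals over [−τ_i, 0] are computed by composite Simpson
quadrature on the dense interpolant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad, simpson

from .dde import Trajectory, integrate
from .equilibria import Equilibrium, solve_all, solve_E0, solve_E1, solve_E2, solve_E3, solve_E4
from .model import ModelSpec

__all__ = [
    "OscillationReport",
    "ScanResult",
    "LyapunovValue",
    "H",
    "detect_oscillation",
    "scan_tau3",
    "perturbed_history",
    "evaluate_lyapunov",
    "lyapunov_series",
]

EPS_CONV = 1e-3   # relative amplitude below which a run counts as converged
EPS_OSC = 1e-2    # virus-component relative amplitude for 'oscillatory'


def H(xi: float) -> float:
    """H(ξ) = ξ − 1 − ln ξ, the Volterra–Lyapunov building block."""
    if xi <= 0.0:
        raise ValueError(f"H needs ξ > 0, got {xi}")
    return xi - 1.0 - math.log(xi)


@dataclass(frozen=True)
class OscillationReport:
    """Post-transient amplitude summary of one trajectory."""

    amplitudes: tuple[float, float, float, float, float]  # relative, per state
    period: float | None
    classification: str  # converged | oscillatory | undecided

    @property
    def virus_amplitude(self) -> float:
        return self.amplitudes[2]


@dataclass(frozen=True)
class ScanResult:
    tau3_grid: tuple[float, ...]
    reports: tuple[OscillationReport, ...]
    errors: tuple[str | None, ...]

    @property
    def classifications(self) -> tuple[str, ...]:
        return tuple(r.classification if r is not None else "error" for r in self.reports)

    @property
    def switch_intervals(self) -> tuple[tuple[float, float], ...]:
        """Grid intervals across which the classification changes."""
        out = []
        cls = self.classifications
        for i in range(1, len(cls)):
            if cls[i] != cls[i - 1]:
                out.append((self.tau3_grid[i - 1], self.tau3_grid[i]))
        return tuple(out)


def _relative_amplitude(series: np.ndarray) -> float:
    scale = max(abs(float(np.mean(series))), 1e-12)
    return float(series.max() - series.min()) / scale


def _dominant_period(t: np.ndarray, series: np.ndarray) -> float | None:
    """Median peak-to-peak spacing of interior local maxima."""
    s = series
    peaks = np.nonzero((s[1:-1] > s[:-2]) & (s[1:-1] >= s[2:]))[0] + 1
    if len(peaks) < 2:
        return None
    return float(np.median(np.diff(t[peaks])))


def detect_oscillation(traj: Trajectory, transient_fraction: float = 0.7,
                       eps_conv: float = EPS_CONV,
                       eps_osc: float = EPS_OSC) -> OscillationReport:
    """Classify a trajectory as converged / oscillatory / undecided.

    Amplitudes are relative ranges over the last ``1 − transient_fraction``
    of the run.  ``oscillatory`` additionally requires the virus amplitude
    not to decay across the last two quarters of the window (a damped
    spiral is ``undecided``, not ``oscillatory``).
    """
    if not 0.0 <= transient_fraction < 1.0:
        raise ValueError("transient_fraction must be in [0, 1)")
    t0 = transient_fraction * traj.T
    t, states = traj.window(t0)
    amps = tuple(_relative_amplitude(states[i]) for i in range(5))
    period = _dominant_period(t, states[2])

    if max(amps) < eps_conv:
        return OscillationReport(amps, period, "converged")
    v_amp = amps[2]
    if v_amp >= eps_osc:
        # compare virus amplitude over the 3rd and 4th quarters of the window
        q = len(t) // 4
        a3 = _relative_amplitude(states[2][2 * q:3 * q])
        a4 = _relative_amplitude(states[2][3 * q:])
        if a4 >= 0.5 * a3:
            return OscillationReport(amps, period, "oscillatory")
    return OscillationReport(amps, period, "undecided")


def perturbed_history(eq: Equilibrium, rel: float = 0.1,
                      floor: float = 0.1) -> np.ndarray:
    """Equilibrium + 10% history; zero components get a small positive seed.

    CTL and antibody compartments multiply their own removal terms, so a
    component starting at exactly zero stays zero for all time; testing an
    equilibrium's basin therefore needs strictly positive seeds.
    """
    pt = eq.point
    out = pt * (1.0 + rel)
    out[pt == 0.0] = floor
    return out


def scan_tau3(model: ModelSpec, tau3_grid, T: float = 3000.0,
              h: float | None = None,
              history: np.ndarray | None = None,
              transient_fraction: float = 0.7) -> ScanResult:
    """One integration + oscillation report per τ3 grid point.

    The model is otherwise fixed; the default history perturbs the
    relevant τ3 = 0 equilibrium by +10%.  Integrator failures at one point
    are recorded and the scan continues.
    """
    tau3_grid = tuple(float(t3) for t3 in tau3_grid)
    if any(t3 < 0 for t3 in tau3_grid) or list(tau3_grid) != sorted(tau3_grid):
        raise ValueError("tau3 grid must be sorted and nonnegative")
    if history is None:
        base = model.with_rates(tau3=0.0)
        eqs = solve_all(base)
        eq = next((eqs[lbl] for lbl in ("E4", "E3", "E2", "E1", "E0")
                   if eqs[lbl].exists), eqs["E0"])
        history = perturbed_history(eq)
    reports: list[OscillationReport | None] = []
    errors: list[str | None] = []
    for t3 in tau3_grid:
        m = model.with_rates(tau3=t3)
        try:
            traj = integrate(m, history, T, h)
            reports.append(detect_oscillation(traj, transient_fraction))
            errors.append(None)
        except (RuntimeError, ValueError) as exc:
            reports.append(OscillationReport((math.nan,) * 5, None, "error"))
            errors.append(str(exc))
    return ScanResult(tau3_grid, tuple(reports), tuple(errors))


# --------------------------------------------------------------------------
# Lyapunov functionals V1–V5
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LyapunovValue:
    functional: str  # V1..V5
    t: float
    value: float
    derivative: float | None = None  # central finite difference when requested


def _volterra(u: float, ustar: float, g, gstar: float) -> float:
    """Φ(u) = u − u* − ∫_{u*}^{u} g(u*)/g(θ) dθ (≥ 0, zero at u*)."""
    if u == ustar:
        return 0.0
    val, _ = quad(lambda th: gstar / g(th), ustar, u, limit=100)
    return u - ustar - val


def _delay_window(traj: Trajectory, t: float, tau: float, fun) -> float:
    """∫_{−τ}^{0} fun(state at t+s) ds by composite Simpson (spacing ≤ h)."""
    if tau == 0.0:
        return 0.0
    n = 2 * max(1, int(math.ceil(tau / (2.0 * traj.h))))
    ss = np.linspace(-tau, 0.0, n + 1)
    vals = np.array([fun(traj.dense_eval(t + s)) for s in ss])
    return float(simpson(vals, x=ss))


def evaluate_lyapunov(functional: str, model: ModelSpec, traj: Trajectory,
                      t: float, equilibrium: Equilibrium | None = None,
                      derivative: bool = False, dt: float | None = None) -> LyapunovValue:
    """Evaluate V1..V5 at time ``t`` along a trajectory.

    The reference equilibrium is solved from the model if not supplied.
    ``derivative=True`` adds a central finite-difference time derivative
    with stencil ``dt`` (default: the trajectory step).
    """
    fun = {"V1": _V1, "V2": _V2, "V3": _V3, "V4": _V4, "V5": _V5}.get(functional)
    if fun is None:
        raise ValueError(f"unknown functional {functional!r}; expected V1..V5")
    if equilibrium is None:
        equilibrium = _reference_equilibrium(functional, model)
    tau = traj.history.tau
    if t < 0.0 or t > traj.T:
        raise ValueError("t must lie in [0, T]")
    value = fun(model, traj, t, equilibrium)
    deriv = None
    if derivative:
        dt = dt if dt is not None else traj.h
        lo, hi = max(0.0, t - dt), min(traj.T, t + dt)
        deriv = (fun(model, traj, hi, equilibrium) - fun(model, traj, lo, equilibrium)) / (hi - lo)
    return LyapunovValue(functional, t, value, deriv)


def lyapunov_series(functional: str, model: ModelSpec, traj: Trajectory,
                    times, equilibrium: Equilibrium | None = None) -> np.ndarray:
    if equilibrium is None:
        equilibrium = _reference_equilibrium(functional, model)
    return np.array([
        evaluate_lyapunov(functional, model, traj, t, equilibrium).value
        for t in times])


def _reference_equilibrium(functional: str, model: ModelSpec) -> Equilibrium:
    if functional == "V1":
        return solve_E0(model)
    if functional == "V2":
        return solve_E1(model)
    if functional == "V3":
        return solve_E2(model)[0]
    if functional == "V4":
        return solve_E3(model)[0]
    return solve_E4(model)[0]


def _pos(name: str, val: float) -> float:
    if val <= 0.0:
        raise ValueError(f"Lyapunov term {name} requires a positive state, got {val}")
    return val


def _V1(model: ModelSpec, traj: Trajectory, t: float, eq: Equilibrium) -> float:
    r = model.rates
    xbar = eq.x
    x, y, v, z, w = traj.dense_eval(t)
    em1, em2 = 1.0 / r.survival1, 1.0 / r.survival2
    fv_bar = model.fv(xbar, 0.0)
    # x-term with the v→0 limit ratio f(x̄,v)/f(θ,v) → ∂v f(x̄,0)/∂v f(θ,0)
    xterm = _volterra(x, xbar, lambda th: model.fv(_pos("x", th), 0.0), fv_bar)
    val = (xterm + em1 * y + r.a * em1 * em2 / r.k * v + r.p * em1 / r.c * z
           + r.a * r.q * em1 * em2 / (r.k * r.r) * w)
    val += _delay_window(traj, t, r.tau1, lambda st: model.f(st[0], st[2]))
    val += r.a * em1 * _delay_window(traj, t, r.tau2, lambda st: model.g(1, st[1]))
    val += r.p * em1 * _delay_window(
        traj, t, r.tau3, lambda st: model.g(1, st[1]) * model.g(4, st[3]))
    return val


def _V2(model: ModelSpec, traj: Trajectory, t: float, eq: Equilibrium) -> float:
    r = model.rates
    x1, y1, v1 = eq.x, eq.y, eq.v
    x, y, v, z, w = traj.dense_eval(t)
    em1, em2 = 1.0 / r.survival1, 1.0 / r.survival2
    f1 = model.f(x1, v1)
    g1y1 = model.g(1, y1)
    val = _volterra(x, x1, lambda th: model.f(_pos("x", th), v1), f1)
    val += em1 * _volterra(_pos("y", y), y1, lambda th: model.g(1, th), g1y1)
    val += (r.a * em1 * em2 / r.k) * _volterra(
        _pos("v", v), v1, lambda th: model.g(2, th), model.g(2, v1))
    val += r.p * em1 / r.c * z + r.a * r.q * em1 * em2 / (r.k * r.r) * w
    val += f1 * _delay_window(
        traj, t, r.tau1, lambda st: H(model.f(st[0], st[2]) / f1))
    val += r.p * em1 * _delay_window(
        traj, t, r.tau3, lambda st: model.g(1, st[1]) * model.g(4, st[3]))
    val += r.a * em1 * g1y1 * _delay_window(
        traj, t, r.tau2, lambda st: H(model.g(1, st[1]) / g1y1))
    return val


def _V3(model: ModelSpec, traj: Trajectory, t: float, eq: Equilibrium) -> float:
    r = model.rates
    x2, y2, v2, w2 = eq.x, eq.y, eq.v, eq.w
    x, y, v, z, w = traj.dense_eval(t)
    em1 = 1.0 / r.survival1
    f2 = model.f(x2, v2)
    g1y2 = model.g(1, y2)
    A = f2 / (model.g(2, v2) * (r.u + r.q * model.g(3, w2)))
    val = _volterra(x, x2, lambda th: model.f(_pos("x", th), v2), f2)
    val += em1 * _volterra(_pos("y", y), y2, lambda th: model.g(1, th), g1y2)
    val += A * _volterra(_pos("v", v), v2, lambda th: model.g(2, th), model.g(2, v2))
    val += r.p * em1 / r.c * z
    val += (r.q / r.r) * A * _volterra(
        _pos("w", w), w2, lambda th: model.g(3, th), model.g(3, w2))
    val += f2 * _delay_window(traj, t, r.tau1, lambda st: H(model.f(st[0], st[2]) / f2))
    val += f2 * _delay_window(traj, t, r.tau2, lambda st: H(model.g(1, st[1]) / g1y2))
    val += r.p * em1 * _delay_window(
        traj, t, r.tau3, lambda st: model.g(1, st[1]) * model.g(4, st[3]))
    return val


def _V4(model: ModelSpec, traj: Trajectory, t: float, eq: Equilibrium) -> float:
    r = model.rates
    x3, y3, v3, z3 = eq.x, eq.y, eq.v, eq.z
    x, y, v, z, w = traj.dense_eval(t)
    em1 = 1.0 / r.survival1
    f3 = model.f(x3, v3)
    g1y3 = model.g(1, y3)
    A = f3 / (model.g(2, v3) * r.u)
    val = _volterra(x, x3, lambda th: model.f(_pos("x", th), v3), f3)
    val += em1 * _volterra(_pos("y", y), y3, lambda th: model.g(1, th), g1y3)
    val += A * _volterra(_pos("v", v), v3, lambda th: model.g(2, th), model.g(2, v3))
    val += (r.p * em1 / r.c) * _volterra(
        _pos("z", z), z3, lambda th: model.g(4, th), model.g(4, z3))
    val += (r.q / r.r) * A * w
    val += f3 * _delay_window(traj, t, r.tau1, lambda st: H(model.f(st[0], st[2]) / f3))
    val += f3 * _delay_window(traj, t, r.tau2, lambda st: H(model.g(1, st[1]) / g1y3))
    return val


def _V5(model: ModelSpec, traj: Trajectory, t: float, eq: Equilibrium) -> float:
    r = model.rates
    x4, y4, v4, z4, w4 = eq.x, eq.y, eq.v, eq.z, eq.w
    x, y, v, z, w = traj.dense_eval(t)
    em1 = 1.0 / r.survival1
    f4 = model.f(x4, v4)
    g1y4 = model.g(1, y4)
    A = f4 / (model.g(2, v4) * (r.u + r.q * model.g(3, w4)))
    val = _volterra(x, x4, lambda th: model.f(_pos("x", th), v4), f4)
    val += em1 * _volterra(_pos("y", y), y4, lambda th: model.g(1, th), g1y4)
    val += A * _volterra(_pos("v", v), v4, lambda th: model.g(2, th), model.g(2, v4))
    val += (r.p * em1 / r.c) * _volterra(
        _pos("z", z), z4, lambda th: model.g(4, th), model.g(4, z4))
    val += (r.q / r.r) * A * _volterra(
        _pos("w", w), w4, lambda th: model.g(3, th), model.g(3, w4))
    val += f4 * _delay_window(traj, t, r.tau1, lambda st: H(model.f(st[0], st[2]) / f4))
    val += f4 * _delay_window(traj, t, r.tau2, lambda st: H(model.g(1, st[1]) / g1y4))
    return val
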