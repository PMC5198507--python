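"""Method-of-steps integration of the three-delay system.

A classical fixed-step 4th-order Runge–Kutta advance where every delayed
value is read from the dense piecewise-cubic (Hermite) extension of the
already-computed solution — or from the initial history for arguments
before time zero.  Because the step obeys ``h ≤ min positive delay / 4``,
all delayed stage arguments lie in the computed region, so no implicit
iteration is needed.

The scheme is deliberately not adaptive: a fixed step aligned with the
delays keeps the propagated derivative discontinuities on grid nodes and
makes runs bit-reproducible.  Cubic Hermite dense output preserves the
fourth-order accuracy of the grid values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .model import ModelSpec

__all__ = [
    "HistoryFunction",
    "Trajectory",
    "BlowUpError",
    "solve_dde",
    "integrate",
    "default_step",
]


class BlowUpError(RuntimeError):
    """Non-finite state encountered during integration."""


@dataclass(frozen=True)
class HistoryFunction:
    """Initial history on [−τ, 0]: a constant vector or a callable.

    All values must be nonnegative and the value at 0 strictly positive
    componentwise is *not* required — only nonnegativity, with positivity
    at 0 for the components that should not be identically absorbed.
    """

    dim: int
    tau: float
    _const: np.ndarray | None = None
    _fun: Callable[[float], np.ndarray] | None = None

    @staticmethod
    def constant(phi0: Sequence[float], tau: float) -> "HistoryFunction":
        phi0 = np.asarray(phi0, dtype=float)
        if phi0.min() < 0.0:
            raise ValueError("history values must be nonnegative")
        return HistoryFunction(len(phi0), float(tau), phi0, None)

    @staticmethod
    def from_callable(fun: Callable[[float], Sequence[float]], dim: int,
                      tau: float) -> "HistoryFunction":
        return HistoryFunction(dim, float(tau), None,
                               lambda t: np.asarray(fun(t), dtype=float))

    @property
    def is_constant(self) -> bool:
        return self._const is not None

    def __call__(self, t: float) -> np.ndarray:
        if t > 0.0 or t < -self.tau - 1e-12:
            raise ValueError(f"history queried outside [−τ, 0]: t={t}")
        if self._const is not None:
            return self._const
        return self._fun(t)


@dataclass
class Trajectory:
    """Dense solution over [−τ, T] on a uniform grid with step ``h``.

    ``states``/``derivs`` are (dim, N+1) arrays at the nodes ``i·h``;
    evaluation between nodes is cubic Hermite (C¹ across joins, exact at
    nodes).  Times in [−τ, 0) delegate to the history.
    """

    t: np.ndarray
    states: np.ndarray
    derivs: np.ndarray
    history: HistoryFunction
    h: float
    method: str = "rk4-hermite"

    @property
    def T(self) -> float:
        return float(self.t[-1])

    def dense_eval(self, tt: float) -> np.ndarray:
        if tt < -self.history.tau - 1e-12 or tt > self.T + 1e-12:
            raise ValueError(f"t={tt} outside trajectory domain [−τ, T]")
        if tt < 0.0:
            return np.array(self.history(tt), dtype=float)
        h = self.h
        i = int(tt / h)
        n = self.states.shape[1] - 1
        if i >= n:
            return self.states[:, n].copy()
        th = (tt - i * h) / h
        v0, v1 = self.states[:, i], self.states[:, i + 1]
        d0, d1 = self.derivs[:, i], self.derivs[:, i + 1]
        h00 = (1.0 + 2.0 * th) * (1.0 - th) ** 2
        h10 = th * (1.0 - th) ** 2
        h01 = th * th * (3.0 - 2.0 * th)
        h11 = th * th * (th - 1.0)
        return h00 * v0 + h10 * h * d0 + h01 * v1 + h11 * h * d1

    def window(self, t_from: float, t_to: float | None = None):
        """(times, states) restricted to the stored grid inside a window."""
        t_to = self.T if t_to is None else t_to
        mask = (self.t >= t_from) & (self.t <= t_to)
        return self.t[mask], self.states[:, mask]


def default_step(model: ModelSpec, cap: float = 0.05) -> float:
    """min(positive delay)/20, capped at ``cap`` (0.05 time units)."""
    r = model.rates
    taus = [t for t in (r.tau1, r.tau2, r.tau3) if t > 0.0]
    if not taus:
        return cap
    return min(cap, min(taus) / 20.0)


def _check_step(h: float, taus: Sequence[float], T: float) -> None:
    if h <= 0.0:
        raise ValueError("step h must be positive")
    if T < h:
        raise ValueError("end time T must be at least one step")
    pos = [t for t in taus if t > 0.0]
    if pos and h > min(pos) / 4.0 + 1e-12:
        raise ValueError(
            f"step h={h} exceeds min positive delay / 4 = {min(pos) / 4.0}")


# --------------------------------------------------------------------------
# generic solver (any dimension, any number of delays)
# --------------------------------------------------------------------------

def solve_dde(fun: Callable, delays: Sequence[float], history: HistoryFunction,
              T: float, h: float) -> Trajectory:
    """Integrate ``y'(t) = fun(t, y, Z)`` with ``Z[j] = y(t − delays[j])``.

    Generic (used directly for scalar test problems); the model front-end
    :func:`integrate` uses a specialised fast path with identical
    numerics.
    """
    delays = [float(d) for d in delays]
    _check_step(h, delays, T)
    n = int(round(T / h))
    dim = history.dim
    Y = np.empty((dim, n + 1))
    F = np.empty((dim, n + 1))
    Y[:, 0] = history(0.0)

    def past(tt: float, k: int) -> np.ndarray:
        # value at tt ≤ current front using stored nodes (Hermite) / history
        if tt <= 0.0:
            return history(max(tt, -history.tau))
        i = int(tt / h)
        if i >= k:
            i = k - 1
        th = (tt - i * h) / h
        v0, v1 = Y[:, i], Y[:, i + 1]
        d0, d1 = F[:, i], F[:, i + 1]
        h00 = (1.0 + 2.0 * th) * (1.0 - th) ** 2
        h10 = th * (1.0 - th) ** 2
        h01 = th * th * (3.0 - 2.0 * th)
        h11 = th * th * (th - 1.0)
        return h00 * v0 + h10 * h * d0 + h01 * v1 + h11 * h * d1

    def delayed(tt: float, k: int, y_stage: np.ndarray) -> list[np.ndarray]:
        out = []
        for d in delays:
            if d == 0.0:
                out.append(y_stage)
            else:
                out.append(past(tt - d, k))
        return out

    for k in range(n):
        t0 = k * h
        y0 = Y[:, k]
        k1 = np.asarray(fun(t0, y0, delayed(t0, k + 1, y0)))
        F[:, k] = k1
        y_mid = y0 + 0.5 * h * k1
        k2 = np.asarray(fun(t0 + 0.5 * h, y_mid, delayed(t0 + 0.5 * h, k + 1, y_mid)))
        y_mid2 = y0 + 0.5 * h * k2
        k3 = np.asarray(fun(t0 + 0.5 * h, y_mid2, delayed(t0 + 0.5 * h, k + 1, y_mid2)))
        y_end = y0 + h * k3
        k4 = np.asarray(fun(t0 + h, y_end, delayed(t0 + h, k + 1, y_end)))
        y_next = y0 + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(y_next)):
            raise BlowUpError(f"non-finite state at t={t0 + h:.6g}")
        Y[:, k + 1] = y_next
    y_fin = Y[:, n]
    F[:, n] = np.asarray(fun(n * h, y_fin, delayed(n * h, n, y_fin)))
    t = np.arange(n + 1) * h
    return Trajectory(t, Y, F, history, h)


# --------------------------------------------------------------------------
# specialised model integrator
# --------------------------------------------------------------------------

def integrate(model: ModelSpec, history: HistoryFunction | Sequence[float],
              T: float, h: float | None = None) -> Trajectory:
    """Integrate the five-compartment model from a history over [0, T].

    ``history`` may be a constant 5-vector.  Negative excursions beyond
    −1e−6 trigger a warning and a retry at half the step (twice at most);
    excursions within round-off are clipped implicitly by proceeding.
    """
    r = model.rates
    tau = r.tau_max
    if not isinstance(history, HistoryFunction):
        history = HistoryFunction.constant(history, tau)
    if history.dim != 5:
        raise ValueError("model history must be 5-dimensional")
    if h is None:
        h = default_step(model)
    taus = (r.tau1, r.tau2, r.tau3)
    _check_step(h, taus, T)

    for attempt in range(3):
        traj, ok = _integrate_fast(model, history, T, h)
        if ok:
            return traj
        warnings.warn(
            f"positivity violation beyond −1e−6 at step h={h}; retrying with h/2",
            RuntimeWarning, stacklevel=2)
        h *= 0.5
    return traj  # last attempt, possibly still violating; caller beware


def _integrate_fast(model: ModelSpec, history: HistoryFunction,
                    T: float, h: float) -> tuple[Trajectory, bool]:
    r = model.rates
    tau1, tau2, tau3 = r.tau1, r.tau2, r.tau3
    e1, e2 = r.survival1, r.survival2
    a, b, c, k, u, p, q, rr, hh = r.a, r.b, r.c, r.k, r.u, r.p, r.q, r.r, r.h
    s = model.growth._value
    f = model.incidence._value
    g1 = model.removals[0]._value
    g2 = model.removals[1]._value
    g3 = model.removals[2]._value
    g4 = model.removals[3]._value

    n = int(round(T / h))
    if history.is_constant:
        hx, hy, hv, hz, hw = (float(val) for val in history(0.0))
        hist = None
    else:
        hist = history
        hx = hy = hv = hz = hw = 0.0

    X = [0.0] * (n + 1); Y = [0.0] * (n + 1); V = [0.0] * (n + 1)
    Z = [0.0] * (n + 1); W = [0.0] * (n + 1)
    DX = [0.0] * (n + 1); DY = [0.0] * (n + 1); DV = [0.0] * (n + 1)
    DZ = [0.0] * (n + 1); DW = [0.0] * (n + 1)
    if hist is None:
        X[0], Y[0], V[0], Z[0], W[0] = hx, hy, hv, hz, hw
    else:
        X[0], Y[0], V[0], Z[0], W[0] = (float(val) for val in history(0.0))

    def interp(vals, ders, tt, k_front, hist_idx):
        if tt <= 0.0:
            if hist is None:
                return (hx, hy, hv, hz, hw)[hist_idx]
            return float(hist(max(tt, -hist.tau))[hist_idx])
        i = int(tt / h)
        if i >= k_front:
            i = k_front - 1
        th = (tt - i * h) / h
        v0 = vals[i]; v1 = vals[i + 1]
        om = 1.0 - th
        return (v0 * (1.0 + 2.0 * th) * om * om
                + ders[i] * h * th * om * om
                + v1 * th * th * (3.0 - 2.0 * th)
                + ders[i + 1] * h * th * th * (th - 1.0))

    min_state = 0.0

    def deriv(ts, x, y, v, z, w, kf):
        # delayed reads: (x, v) at ts−τ1, y at ts−τ2, (y, z) at ts−τ3
        if tau1 > 0.0:
            xd = interp(X, DX, ts - tau1, kf, 0)
            vd = interp(V, DV, ts - tau1, kf, 2)
        else:
            xd, vd = x, v
        yd2 = interp(Y, DY, ts - tau2, kf, 1) if tau2 > 0.0 else y
        if tau3 > 0.0:
            yd3 = interp(Y, DY, ts - tau3, kf, 1)
            zd3 = interp(Z, DZ, ts - tau3, kf, 3)
        else:
            yd3, zd3 = y, z
        # clip tiny negative excursions before the nonlinearities
        yc = y if y > 0.0 else 0.0
        vc = v if v > 0.0 else 0.0
        zc = z if z > 0.0 else 0.0
        wc = w if w > 0.0 else 0.0
        g1y = g1(yc); g2v = g2(vc); g3w = g3(wc); g4z = g4(zc)
        return (
            s(x) - f(x if x > 0.0 else 0.0, vc),
            e1 * f(xd if xd > 0.0 else 0.0, vd if vd > 0.0 else 0.0)
            - a * g1y - p * g1y * g4z,
            k * e2 * g1(yd2 if yd2 > 0.0 else 0.0) - u * g2v - q * g2v * g3w,
            c * g1(yd3 if yd3 > 0.0 else 0.0) * g4(zd3 if zd3 > 0.0 else 0.0)
            - b * g4z,
            rr * g2v * g3w - hh * g3w,
        )

    h6 = h / 6.0
    for kk in range(n):
        t0 = kk * h
        x0, y0, v0, z0, w0 = X[kk], Y[kk], V[kk], Z[kk], W[kk]
        kf = kk + 1
        d1 = deriv(t0, x0, y0, v0, z0, w0, kf)
        DX[kk], DY[kk], DV[kk], DZ[kk], DW[kk] = d1
        hm = 0.5 * h
        d2 = deriv(t0 + hm, x0 + hm * d1[0], y0 + hm * d1[1], v0 + hm * d1[2],
                   z0 + hm * d1[3], w0 + hm * d1[4], kf)
        d3 = deriv(t0 + hm, x0 + hm * d2[0], y0 + hm * d2[1], v0 + hm * d2[2],
                   z0 + hm * d2[3], w0 + hm * d2[4], kf)
        d4 = deriv(t0 + h, x0 + h * d3[0], y0 + h * d3[1], v0 + h * d3[2],
                   z0 + h * d3[3], w0 + h * d3[4], kf)
        x1 = x0 + h6 * (d1[0] + 2.0 * (d2[0] + d3[0]) + d4[0])
        y1 = y0 + h6 * (d1[1] + 2.0 * (d2[1] + d3[1]) + d4[1])
        v1 = v0 + h6 * (d1[2] + 2.0 * (d2[2] + d3[2]) + d4[2])
        z1 = z0 + h6 * (d1[3] + 2.0 * (d2[3] + d3[3]) + d4[3])
        w1 = w0 + h6 * (d1[4] + 2.0 * (d2[4] + d3[4]) + d4[4])
        if not (math.isfinite(x1) and math.isfinite(y1) and math.isfinite(v1)
                and math.isfinite(z1) and math.isfinite(w1)):
            raise BlowUpError(f"non-finite state at t={t0 + h:.6g}")
        m = min(x1, y1, v1, z1, w1)
        if m < min_state:
            min_state = m
        X[kk + 1], Y[kk + 1], V[kk + 1], Z[kk + 1], W[kk + 1] = x1, y1, v1, z1, w1

    dN = deriv(n * h, X[n], Y[n], V[n], Z[n], W[n], n)
    DX[n], DY[n], DV[n], DZ[n], DW[n] = dN

    t = np.arange(n + 1) * h
    states = np.array([X, Y, V, Z, W])
    derivs = np.array([DX, DY, DV, DZ, DW])
    traj = Trajectory(t, states, derivs, history, h)
    return traj, min_state > -1e-6
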