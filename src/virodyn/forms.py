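"""Registered functional forms for the within-host infection model.

The model separates its nonlinearities into three families:

* a target-cell growth law ``s(x)`` with a unique positive zero ``x̄``,
* an incidence rate ``f(x, v)`` (new infections per unit time), and
* four removal laws ``g1..g4`` (state-dependent loss of infected cells,
  virus, antibodies and CTLs), normalised so ``g(0) = 0`` and ``g'(0) = 1``.

Each family is a small registry of named forms.  A form is built from a
parameter mapping and exposes its value, its derivative(s), and — for the
removal laws — its inverse.  New forms can be registered at run time with
:func:`register_growth`, :func:`register_incidence` and
:func:`register_removal`; this is the documented plugin hook.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

__all__ = [
    "FormError",
    "GrowthFunction",
    "IncidenceFunction",
    "RemovalFunction",
    "make_growth",
    "make_incidence",
    "make_removal",
    "register_growth",
    "register_incidence",
    "register_removal",
    "GROWTH_FORMS",
    "INCIDENCE_FORMS",
    "REMOVAL_FORMS",
]


class FormError(ValueError):
    """Unknown form name, or bad/missing parameters for a form."""


def _check_params(form: str, params: Mapping[str, float], required: tuple[str, ...]) -> dict:
    params = dict(params or {})
    missing = [k for k in required if k not in params]
    unknown = [k for k in params if k not in required]
    if missing or unknown:
        raise FormError(
            f"form {form!r}: missing parameters {missing}, unknown parameters {unknown}"
        )
    return {k: float(v) for k, v in params.items()}


# --------------------------------------------------------------------------
# growth s(x)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthFunction:
    """Target-cell growth law ``s(x)`` with derivative ``s'(x)``."""

    form: str
    params: dict = field(repr=False)
    _value: Callable[[float], float] = field(repr=False)
    _deriv: Callable[[float], float] = field(repr=False)

    def __call__(self, x: float) -> float:
        return self._value(x)

    def deriv(self, x: float) -> float:
        return self._deriv(x)


GROWTH_FORMS: dict[str, tuple[tuple[str, ...], Callable]] = {}


def register_growth(name: str, required: tuple[str, ...], builder: Callable) -> None:
    """Register a growth form. ``builder(params) -> (value, deriv)``."""
    GROWTH_FORMS[name] = (required, builder)


def make_growth(form: str, params: Mapping[str, float]) -> GrowthFunction:
    if form not in GROWTH_FORMS:
        raise FormError(f"unknown growth form {form!r}; known: {sorted(GROWTH_FORMS)}")
    required, builder = GROWTH_FORMS[form]
    p = _check_params(form, params, required)
    value, deriv = builder(p)
    return GrowthFunction(form, p, value, deriv)


def _build_linear(p):
    lam, d = p["lam"], p["d"]

    def value(x):
        return lam - d * x

    def deriv(x):
        return -d

    return value, deriv


def _build_logistic(p):
    # λ − d·x + r1·x(1 − x/K): production plus logistic proliferation.
    lam, d, r1, K = p["lam"], p["d"], p["r1"], p["K"]

    def value(x):
        return lam - d * x + r1 * x * (1.0 - x / K)

    def deriv(x):
        return -d + r1 * (1.0 - 2.0 * x / K)

    return value, deriv


register_growth("linear", ("lam", "d"), _build_linear)
register_growth("logistic", ("lam", "d", "r1", "K"), _build_logistic)


# --------------------------------------------------------------------------
# incidence f(x, v)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IncidenceFunction:
    """Incidence rate ``f(x, v)`` with partial derivatives.

    Analytic partials are used when the form ships them; otherwise a
    Richardson-extrapolated central difference stands in (plugin forms).
    """

    form: str
    params: dict = field(repr=False)
    _value: Callable[[float, float], float] = field(repr=False)
    _dfdx: Callable[[float, float], float] | None = field(repr=False)
    _dfdv: Callable[[float, float], float] | None = field(repr=False)

    def __call__(self, x: float, v: float) -> float:
        return self._value(x, v)

    def partial_x(self, x: float, v: float) -> float:
        if self._dfdx is not None:
            return self._dfdx(x, v)
        return _richardson(lambda t: self._value(t, v), x)

    def partial_v(self, x: float, v: float) -> float:
        if self._dfdv is not None:
            return self._dfdv(x, v)
        return _richardson(lambda t: self._value(x, t), v)


def _richardson(fun: Callable[[float], float], t: float, h0: float | None = None) -> float:
    """Central difference with one Richardson step (O(h^4))."""
    h = h0 if h0 is not None else 1e-4 * (1.0 + abs(t))
    d1 = (fun(t + h) - fun(t - h)) / (2.0 * h)
    d2 = (fun(t + h / 2.0) - fun(t - h / 2.0)) / h
    return (4.0 * d2 - d1) / 3.0


INCIDENCE_FORMS: dict[str, tuple[tuple[str, ...], Callable]] = {}


def register_incidence(name: str, required: tuple[str, ...], builder: Callable) -> None:
    """Register an incidence form. ``builder(params) -> (value, dfdx, dfdv)``.

    ``dfdx``/``dfdv`` may be ``None``; finite differences are used then.
    """
    INCIDENCE_FORMS[name] = (required, builder)


def make_incidence(form: str, params: Mapping[str, float]) -> IncidenceFunction:
    if form not in INCIDENCE_FORMS:
        raise FormError(f"unknown incidence form {form!r}; known: {sorted(INCIDENCE_FORMS)}")
    required, builder = INCIDENCE_FORMS[form]
    p = _check_params(form, params, required)
    value, dfdx, dfdv = builder(p)
    return IncidenceFunction(form, p, value, dfdx, dfdv)


def _build_bilinear(p):
    beta = p["beta"]
    return (
        lambda x, v: beta * x * v,
        lambda x, v: beta * v,
        lambda x, v: beta * x,
    )


def _build_saturated(p):
    beta, b = p["beta"], p["b"]
    return (
        lambda x, v: beta * x * v / (1.0 + b * v),
        lambda x, v: beta * v / (1.0 + b * v),
        lambda x, v: beta * x / (1.0 + b * v) ** 2,
    )


def _build_holling2(p):
    beta, a = p["beta"], p["a"]
    return (
        lambda x, v: beta * x * v / (1.0 + a * x),
        lambda x, v: beta * v / (1.0 + a * x) ** 2,
        lambda x, v: beta * x / (1.0 + a * x),
    )


def _build_beddington_deangelis(p):
    beta, a, b = p["beta"], p["a"], p["b"]

    def value(x, v):
        return beta * x * v / (1.0 + a * x + b * v)

    def dfdx(x, v):
        den = 1.0 + a * x + b * v
        return beta * v * (1.0 + b * v) / (den * den)

    def dfdv(x, v):
        den = 1.0 + a * x + b * v
        return beta * x * (1.0 + a * x) / (den * den)

    return value, dfdx, dfdv


def _build_crowley_martin(p):
    # (1 + ax + bv + abxv) factors as (1 + ax)(1 + bv)
    beta, a, b = p["beta"], p["a"], p["b"]

    def value(x, v):
        return beta * x * v / ((1.0 + a * x) * (1.0 + b * v))

    def dfdx(x, v):
        return beta * v / ((1.0 + a * x) ** 2 * (1.0 + b * v))

    def dfdv(x, v):
        return beta * x / ((1.0 + a * x) * (1.0 + b * v) ** 2)

    return value, dfdx, dfdv


def _build_exp_shift(p):
    # β·x·((v − b1)·e^{−c1 v} + b1); slope at v = 0 is β·x·(1 + c1·b1).
    beta, b1, c1 = p["beta"], p["b1"], p["c1"]

    def value(x, v):
        return beta * x * ((v - b1) * math.exp(-c1 * v) + b1)

    def dfdx(x, v):
        return beta * ((v - b1) * math.exp(-c1 * v) + b1)

    def dfdv(x, v):
        return beta * x * math.exp(-c1 * v) * (1.0 - c1 * (v - b1))

    return value, dfdx, dfdv


register_incidence("bilinear", ("beta",), _build_bilinear)
register_incidence("saturated", ("beta", "b"), _build_saturated)
register_incidence("holling2", ("beta", "a"), _build_holling2)
register_incidence("beddington_deangelis", ("beta", "a", "b"), _build_beddington_deangelis)
register_incidence("crowley_martin", ("beta", "a", "b"), _build_crowley_martin)
register_incidence("exp_shift", ("beta", "b1", "c1"), _build_exp_shift)


# --------------------------------------------------------------------------
# removal g_i(ξ)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RemovalFunction:
    """Removal law ``g(ξ)`` with derivative, inverse, and linear lower bound.

    ``k_lower`` is the constant with ``g(ξ) ≥ k_lower·ξ`` on ``[0, ∞)``.
    """

    form: str
    params: dict = field(repr=False)
    _value: Callable[[float], float] = field(repr=False)
    _deriv: Callable[[float], float] = field(repr=False)
    _inverse: Callable[[float], float] | None = field(repr=False)
    k_lower: float = 1.0

    def __call__(self, xi: float) -> float:
        return self._value(xi)

    def deriv(self, xi: float) -> float:
        return self._deriv(xi)

    def inverse(self, eta: float) -> float:
        """Solve g(ξ) = η for ξ ≥ 0."""
        if eta < 0.0:
            raise ValueError(f"removal inverse needs η ≥ 0, got {eta}")
        if self._inverse is not None:
            return self._inverse(eta)
        return _monotone_inverse(self._value, eta)


def _monotone_inverse(g: Callable[[float], float], eta: float, rtol: float = 1e-12) -> float:
    """Bisection on an adaptively expanded bracket [0, 2^k]."""
    if eta == 0.0:
        return 0.0
    hi = 1.0
    for _ in range(200):
        if g(hi) >= eta:
            break
        hi *= 2.0
    else:  # pragma: no cover - H3 requires g → ∞
        raise ValueError("removal function does not reach target value")
    lo = 0.0
    while hi - lo > rtol * (1.0 + hi):
        mid = 0.5 * (lo + hi)
        if g(mid) < eta:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


REMOVAL_FORMS: dict[str, tuple[tuple[str, ...], Callable]] = {}


def register_removal(name: str, required: tuple[str, ...], builder: Callable) -> None:
    """Register a removal form.

    ``builder(params) -> (value, deriv, inverse_or_None, k_lower)``.
    """
    REMOVAL_FORMS[name] = (required, builder)


def make_removal(form: str, params: Mapping[str, float] | None = None) -> RemovalFunction:
    if form not in REMOVAL_FORMS:
        raise FormError(f"unknown removal form {form!r}; known: {sorted(REMOVAL_FORMS)}")
    required, builder = REMOVAL_FORMS[form]
    p = _check_params(form, params or {}, required)
    value, deriv, inverse, k_lower = builder(p)
    return RemovalFunction(form, p, value, deriv, inverse, k_lower)


def _build_identity(p):
    return (lambda xi: xi, lambda xi: 1.0, lambda eta: eta, 1.0)


def _build_power_affine(p):
    # ξ(1 + εξ): superlinear removal, still g(0)=0, g'(0)=1, g(ξ) ≥ ξ.
    eps = p["eps"]
    if eps <= 0.0:
        raise FormError("power_affine needs eps > 0")

    def value(xi):
        return xi * (1.0 + eps * xi)

    def deriv(xi):
        return 1.0 + 2.0 * eps * xi

    def inverse(eta):
        return (-1.0 + math.sqrt(1.0 + 4.0 * eps * eta)) / (2.0 * eps)

    return value, deriv, inverse, 1.0


register_removal("identity", (), _build_identity)
register_removal("power_affine", ("eps",), _build_power_affine)
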