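"""Characteristic equations, analytic instability roots, root searches."""

import math

import numpy as np
import pytest

from virodyn.equilibria import compute_R0, compute_thresholds, solve_all
from virodyn.model import ModelSpec, RateParameters
from virodyn.sampling import random_model_in_regime
from virodyn.stability import (
    CharacteristicProblem,
    analytic_unstable_roots,
    analyze_equilibrium,
    characteristic_problem,
    delay_jacobians,
    rightmost_root,
)


def _scale_R0(model, target):
    return model.with_rates(k=model.rates.k * target / compute_R0(model))


def test_infection_free_characteristic_value_at_zero(m17, m18, rng):
    """The delay-quadratic factor satisfies f(0) = a·u·(1 − R0)."""
    from virodyn.sampling import random_model
    for m in [m17, m18] + [random_model(rng) for _ in range(10)]:
        r = m.rates
        eq = solve_all(m)["E0"]
        R0 = compute_R0(m)
        f0 = (r.a * r.u
              - r.k * m.fv(eq.x, 0.0) * r.survival1 * r.survival2)
        assert f0 == pytest.approx(r.a * r.u * (1.0 - R0), rel=1e-10, abs=1e-12)
        # and it appears as a factor of Δ(0)
        pr = characteristic_problem(m, eq)
        scalar = (r.h * m.gp(3, 0.0)) * (r.b * m.gp(4, 0.0)) * (-m.sp(eq.x))
        assert pr.delta(0.0).real == pytest.approx(scalar * f0, rel=1e-8)


def test_example18_unstable_infection_free(m18):
    """R0 ≈ 5.32 > 1 ⇒ f(0) < 0 and a positive real root exists."""
    eq = solve_all(m18)["E0"]
    roots = analytic_unstable_roots(m18, eq)
    assert len(roots) == 1 and roots[0] > 0.0
    pr = characteristic_problem(m18, eq)
    assert abs(pr.delta(roots[0])) < 1e-6


def test_delay_free_reduction_is_quadratic(m18):
    """At τ1 = τ2 = 0 the E0 factor is λ² + (a+u)λ + au(1−R0)."""
    m0 = m18.with_rates(tau1=0.0, tau2=0.0, tau3=0.0)
    r = m0.rates
    eq = solve_all(m0)["E0"]
    R0 = compute_R0(m0)
    disc = (r.a + r.u) ** 2 - 4.0 * r.a * r.u * (1.0 - R0)
    lam_plus = (-(r.a + r.u) + math.sqrt(disc)) / 2.0
    pr = characteristic_problem(m0, eq)
    assert abs(pr.delta(lam_plus)) < 1e-6 * (1.0 + abs(pr.delta(lam_plus + 1.0)))


def test_factored_forms_agree_with_generic_determinant(m17, m18):
    """Printed factorizations at E0–E3 equal det(M(λ)) on a random λ grid."""
    rng = np.random.default_rng(11)
    for m in (m17, m18):
        eqs = solve_all(m)
        for lbl in ("E0", "E1", "E2", "E3"):
            eq = eqs[lbl]
            if not eq.exists:
                continue
            pr = characteristic_problem(m, eq)
            assert pr.factored is not None
            for _ in range(100):
                lam = complex(rng.uniform(-1.5, 1.5), rng.uniform(-6.0, 6.0))
                full = pr.delta(lam)
                fac = pr.factored(lam)
                assert abs(full - fac) <= 1e-8 * (1.0 + abs(full))


def test_delay_free_characteristic_equals_ode_jacobian(m18):
    """With all delays 0, Δ(λ) = det(λI − J) of the ordinary Jacobian."""
    m0 = m18.with_rates(tau1=0.0, tau2=0.0, tau3=0.0)
    eqs = solve_all(m0)
    rng = np.random.default_rng(3)
    for lbl, eq in eqs.items():
        if not eq.exists:
            continue
        J0, J1, J2, J3 = delay_jacobians(m0, eq)
        J = J0 + J1 + J2 + J3
        pr = characteristic_problem(m0, eq)
        for _ in range(20):
            lam = complex(rng.uniform(-2, 2), rng.uniform(-5, 5))
            poly = np.linalg.det(lam * np.eye(5) - J)
            assert abs(pr.delta(lam) - poly) <= 1e-8 * (1.0 + abs(poly))


def test_analytic_roots_at_E3(m17, m18):
    """λ* = r·g2(v3) − h is a characteristic root at E3 iff R4 > 1."""
    eq18 = solve_all(m18)["E3"]
    roots = analytic_unstable_roots(m18, eq18)
    expected = m18.rates.r * m18.g(2, eq18.v) - m18.rates.h
    assert roots == pytest.approx([expected])
    assert expected > 0.0
    assert abs(characteristic_problem(m18, eq18).delta(expected)) < 1e-8
    # Example A has R4 ≈ 0.285 < 1: no analytic unstable root at E3
    eq17 = solve_all(m17)["E3"]
    assert analytic_unstable_roots(m17, eq17) == []


def test_analytic_root_at_E1_identity_removals():
    """With identity g2, λ* = r·v1 − h > 0 exactly when v1 > v2 = h/r."""
    rates = RateParameters(a=0.5, b=5.0, c=0.1, k=0.4, u=3.0, p=1.0, q=1.0,
                           r=1.5, h=0.1, m1=0.01, m2=0.01, tau1=0.5, tau2=0.5,
                           tau3=0.0)
    m = ModelSpec.build("linear", {"lam": 10.0, "d": 0.1},
                        "bilinear", {"beta": 0.05}, ["identity"] * 4, rates)
    eqs = solve_all(m)
    t = compute_thresholds(m)
    assert t.R1 > 1.0
    roots = analytic_unstable_roots(m, eqs["E1"], t)
    lam_star = m.rates.r * eqs["E1"].v - m.rates.h
    assert lam_star in [pytest.approx(val) for val in roots]
    assert (lam_star > 0) == (eqs["E1"].v > m.rates.h / m.rates.r)


def test_rightmost_root_scalar_problem():
    """Δ(λ) = λ + 1: no unstable roots, rightmost at −1."""
    pr = CharacteristicProblem("toy", (0.0, 0.0, 0.0),
                               lambda lam: np.array([[lam + 1.0]], dtype=complex))
    rep = rightmost_root(pr, (-3.0, 2.0, 5.0))
    assert rep.verdict == "stable"
    assert rep.rightmost == pytest.approx(-1.0, abs=1e-8)


def test_rightmost_root_subcritical_model_stable(m18):
    """R0 = 0.5 with delays τ1 = τ2 = 1: infection-free state is stable."""
    m = _scale_R0(m18.with_rates(tau1=1.0, tau2=1.0), 0.5)
    rep = analyze_equilibrium(m, "E0")
    assert rep.verdict == "stable"
    assert rep.unstable_count == 0


def test_rightmost_root_supercritical_model_unstable(m18):
    rep = analyze_equilibrium(m18, "E0")
    assert rep.verdict == "unstable"
    assert rep.rightmost.real > 1e-7


def test_verdicts_match_theorems_on_regime_models(rng):
    """Predicted-stable equilibria test stable; fired instability clauses
    test unstable, over random models drawn in each threshold regime."""
    for regime in ("E0", "E1", "E2", "E3", "E4"):
        m = random_model_in_regime(rng, regime)
        t = compute_thresholds(m)
        eqs = solve_all(m)
        rep = analyze_equilibrium(m, regime)
        assert rep.verdict == "stable", (regime, rep)
        for lbl in ("E0", "E1", "E2", "E3"):
            eq = eqs[lbl]
            if not eq.exists or lbl == regime:
                continue
            if analytic_unstable_roots(m, eq, t):
                rep = analyze_equilibrium(m, lbl)
                assert rep.verdict == "unstable", (regime, lbl, rep)
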