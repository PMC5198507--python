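"""Equilibrium constructions E0–E4, thresholds R0–R4, regime labels."""

import math

import numpy as np
import pytest

from virodyn.equilibria import (
    classify_regime,
    compute_R0,
    compute_thresholds,
    find_xbar,
    solve_E1,
    solve_E2,
    solve_E3,
    solve_E4,
    solve_all,
)
from virodyn.model import ModelSpec, RateParameters
from virodyn.sampling import random_model


def _scale_R0(model, target):
    """Rescale virus production k so that R0 hits a target value."""
    R0 = compute_R0(model)
    return model.with_rates(k=model.rates.k * target / R0)


# -- x̄ ---------------------------------------------------------------------

def test_xbar_linear_growth_closed_form():
    rates = RateParameters(a=0.5, b=0.15, c=0.1, k=0.4, u=3.0, p=1.0, q=1.0,
                           r=1.5, h=0.1, m1=0.01, m2=0.01, tau1=0, tau2=0, tau3=0)
    m = ModelSpec.build("linear", {"lam": 10.0, "d": 0.01},
                        "bilinear", {"beta": 1e-3}, ["identity"] * 4, rates)
    assert find_xbar(m) == pytest.approx(1000.0, rel=1e-12)


def test_xbar_logistic_quadratic_formula(m17):
    # 10 + 0.59x − 0.0012x² = 0 ⇒ x̄ = (0.59 + √(0.59² + 4·0.0012·10))/0.0024
    expected = (0.59 + math.sqrt(0.59 ** 2 + 4 * 0.0012 * 10.0)) / 0.0024
    assert find_xbar(m17) == pytest.approx(expected, rel=1e-10)


def test_xbar_logistic_degenerates_to_linear():
    rates = RateParameters(a=0.5, b=0.15, c=0.1, k=0.4, u=3.0, p=1.0, q=1.0,
                           r=1.5, h=0.1, m1=0.01, m2=0.01, tau1=0, tau2=0, tau3=0)
    m = ModelSpec.build("logistic", {"lam": 10.0, "d": 0.01, "r1": 1e-300, "K": 500.0},
                        "bilinear", {"beta": 1e-3}, ["identity"] * 4, rates)
    assert find_xbar(m) == pytest.approx(1000.0, rel=1e-9)


# -- R0 --------------------------------------------------------------------

def test_R0_example18_hand_value(m18):
    # (k e^{−m1τ1−m2τ2}/(a·u)) · βx̄/(1+a1·x̄) = 0.4·e^{−0.13}/1.5 · 250/11
    expected = 0.4 * math.exp(-0.13) / 1.5 * 250.0 / 11.0
    assert compute_R0(m18) == pytest.approx(expected, rel=1e-12)
    assert compute_R0(m18) == pytest.approx(5.3218, rel=1e-3)


def test_R0_survival_factor_is_one_without_delays(m18):
    m0 = m18.with_rates(tau1=0.0, tau2=0.0)
    r = m18.rates
    expected = r.k * m18.fv(find_xbar(m18), 0.0) / (r.a * r.u)
    assert compute_R0(m0) == pytest.approx(expected, rel=1e-12)


def test_R0_bilinear_closed_form():
    rates = RateParameters(a=0.5, b=0.15, c=0.1, k=0.4, u=3.0, p=1.0, q=1.0,
                           r=1.5, h=0.1, m1=0.02, m2=0.03, tau1=2.0, tau2=1.0, tau3=0)
    beta = 2e-3
    m = ModelSpec.build("linear", {"lam": 10.0, "d": 0.01},
                        "bilinear", {"beta": beta}, ["identity"] * 4, rates)
    expected = 0.4 * beta * 1000.0 * math.exp(-0.02 * 2 - 0.03 * 1) / (0.5 * 3.0)
    assert compute_R0(m) == pytest.approx(expected, rel=1e-12)


def test_R0_nonincreasing_in_tau1(m18):
    """R0 ∝ e^{−m1·τ1}: longer eclipse delay cannot raise R0."""
    values = [compute_R0(m18.with_rates(tau1=t1)) for t1 in (0.0, 1.0, 5.0, 20.0)]
    assert all(b <= a for a, b in zip(values, values[1:]))


# -- E1 --------------------------------------------------------------------

def test_E1_exists_with_small_residual(m17):
    e1 = solve_E1(m17)
    assert e1.exists
    assert e1.z == 0.0 and e1.w == 0.0
    assert e1.residual < 1e-8 * (1.0 + np.linalg.norm(e1.point))


def test_E1_absent_below_threshold(m18):
    e1 = solve_E1(_scale_R0(m18, 0.5))
    assert not e1.exists


def test_E1_uniqueness_by_dense_scan(m17, m18):
    """The defining function G has exactly one sign change on (0, x̄)."""
    for m in (m17, m18):
        r = m.rates
        xbar = find_xbar(m)
        scale = r.a * r.u / (r.k * r.survival1 * r.survival2)

        def G(x):
            v = m.ginv(2, max(m.s(x), 0.0) / scale)
            return m.f(x, v) - scale * m.g(2, v)

        xs = np.linspace(1e-6 * xbar, xbar * (1.0 - 1e-6), 10_000)
        signs = np.sign([G(x) for x in xs])
        changes = np.sum(np.abs(np.diff(signs)) > 0)
        assert changes == 1
        x1 = solve_E1(m).x
        i = np.searchsorted(xs, x1)
        assert signs[i - 1] != signs[i]  # the root found is the sign change


# -- E2 / R1 ---------------------------------------------------------------

def test_E2_virus_component_identity_removal(m17):
    e2, _ = solve_E2(m17)
    assert e2.v == pytest.approx(m17.rates.h / m17.rates.r, rel=1e-12)


def test_lemma_sign_relation_E1_E2(m17, m18, rng):
    """sign(x2−x1) = sign(v1−v2) = sign(R1−1) on the examples and random draws."""
    models = [m17, m18] + [random_model(rng) for _ in range(20)]
    checked = 0
    for m in models:
        if compute_R0(m) <= 1.0:
            continue
        e1 = solve_E1(m)
        e2, R1 = solve_E2(m)
        s = np.sign(R1 - 1.0)
        assert np.sign(e2.x - e1.x) == s
        assert np.sign(e1.v - e2.v) == s
        checked += 1
    assert checked >= 10


def test_E2_without_antibody_threshold():
    rates = RateParameters(a=0.5, b=0.15, c=0.1, k=0.4, u=3.0, p=1.0, q=1.0,
                           r=1.5, h=3.0, m1=0.01, m2=0.01, tau1=0, tau2=0, tau3=0)
    m = ModelSpec.build("linear", {"lam": 10.0, "d": 0.01},
                        "bilinear", {"beta": 3e-3}, ["identity"] * 4, rates)
    e2, R1 = solve_E2(m)
    assert R1 <= 1.0 and not e2.exists and math.isnan(e2.w)


# -- E3 / R2 ---------------------------------------------------------------

def test_E3_example17_printed_components(m17):
    e3, R2 = solve_E3(m17)
    assert e3.exists
    assert R2 == pytest.approx(34.4139, rel=1e-3)
    assert e3.y == pytest.approx(1.5000, rel=1e-12)
    assert e3.v == pytest.approx(0.1902, rel=1e-3)
    assert e3.x == pytest.approx(462.1965, rel=1e-3)
    # Printed z3 = 15.3959 is inconsistent with z3 = g4⁻¹(a(R2−1)/p);
    # the construction value is reported instead.
    assert e3.z == pytest.approx(0.5 * (R2 - 1.0), rel=1e-12)


def test_E3_virus_closed_form_no_delay():
    rates = RateParameters(a=0.5, b=0.15, c=0.1, k=0.4, u=3.0, p=1.0, q=1.0,
                           r=1.5, h=0.1, m1=0.01, m2=0.01, tau1=0, tau2=0.0, tau3=0)
    m = ModelSpec.build("linear", {"lam": 10.0, "d": 0.01},
                        "bilinear", {"beta": 3e-3}, ["identity"] * 4, rates)
    e3, _ = solve_E3(m)
    assert e3.v == pytest.approx(0.15 * 0.4 / (0.1 * 3.0), rel=1e-12)


def test_lemma_sign_relation_E1_E3(m17, m18, rng):
    """sign(x3−x1) = sign(v1−v3) = sign(y1−y3) = sign(R2−1)."""
    models = [m17, m18] + [random_model(rng) for _ in range(20)]
    checked = 0
    for m in models:
        if compute_R0(m) <= 1.0:
            continue
        e1 = solve_E1(m)
        e3, R2 = solve_E3(m)
        s = np.sign(R2 - 1.0)
        assert np.sign(e3.x - e1.x) == s
        assert np.sign(e1.v - e3.v) == s
        assert np.sign(e1.y - e3.y) == s
        checked += 1
    assert checked >= 10


# -- E4 / R3, R4 -----------------------------------------------------------

def test_E4_example18_printed_components(m18):
    e4, R3, R4 = solve_E4(m18)
    assert e4.exists
    assert R3 == pytest.approx(1.8912, rel=1e-3)
    assert R4 == pytest.approx(2.7693, rel=1e-3)
    assert e4.y == pytest.approx(1.5, rel=1e-12)
    assert e4.v == pytest.approx(0.1 / 1.5, rel=1e-12)  # printed 0.6667 is a decimal-shift typo
    assert e4.x == pytest.approx(850.8857, rel=1e-3)


def test_E4_absent_for_example17(m18, m17):
    e4, R3, R4 = solve_E4(m17)
    assert R4 == pytest.approx(0.2854, rel=1e-3)
    assert R4 < 1.0 and not e4.exists


def test_E4_identity_closed_forms(m18):
    e4, _, _ = solve_E4(m18)
    assert e4.v == pytest.approx(m18.rates.h / m18.rates.r, rel=1e-12)
    assert e4.y == pytest.approx(m18.rates.b / m18.rates.c, rel=1e-12)


# -- thresholds and classification -----------------------------------------

def test_remark_R1_R2_below_R0_on_random_models(rng):
    """R1 < R0 and R2 < R0 whenever defined, over 100 random admissible models."""
    for _ in range(100):
        m = random_model(rng)
        t = compute_thresholds(m)
        if t.R1 is not None:
            assert t.R1 < t.R0
        if t.R2 is not None:
            assert t.R2 < t.R0


def test_equilibrium_residuals_small(rng):
    for _ in range(20):
        m = random_model(rng)
        for eq in solve_all(m).values():
            if eq.exists:
                assert eq.residual < 1e-8 * (1.0 + np.linalg.norm(eq.point))


def test_classification_of_examples(m17, m18):
    assert classify_regime(m17, tau3_zero=True) == "E3-stable"
    assert classify_regime(m18, tau3_zero=True) == "E4-stable"


def test_classification_infection_free(m18):
    assert classify_regime(_scale_R0(m18, 0.5)) == "E0-stable"


def test_classification_needs_tau3_zero_for_ctl_regimes(m17):
    label = classify_regime(m17, tau3_zero=False)
    assert label.startswith("indeterminate")
    assert "R2" in label  # the satisfied conditions are listed
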