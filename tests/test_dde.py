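"""Method-of-steps integrator: exactness, order, positivity, fixed points."""

import numpy as np
import pytest

from virodyn.dde import BlowUpError, HistoryFunction, default_step, integrate, solve_dde
from virodyn.equilibria import solve_all
from virodyn.sampling import random_model


def _scalar_delay_problem():
    """y'(t) = −y(t−1) with constant history 1 on [−1, 0]."""
    hist = HistoryFunction.constant([1.0], tau=1.0)
    return (lambda t, y, Z: -Z[0]), hist


def test_scalar_problem_early_exact_values():
    """Exact piecewise-polynomial solution: y(1) = 0, y(2) = −1/2."""
    fun, hist = _scalar_delay_problem()
    traj = solve_dde(fun, [1.0], hist, 2.0, 0.1)
    assert traj.dense_eval(1.0)[0] == pytest.approx(0.0, abs=1e-12)
    assert traj.dense_eval(2.0)[0] == pytest.approx(-0.5, abs=1e-12)


def test_scalar_problem_order_slope():
    """Global error vs the exact solution decays at order ≥ 3.5.

    At t = 6 the method-of-steps solution is the degree-6 piece with
    y(6) = −41/720 (exact polynomial integration of the history).
    """
    fun, hist = _scalar_delay_problem()
    exact = -41.0 / 720.0
    hs = [0.2, 0.1, 0.05, 0.025]
    errs = [abs(solve_dde(fun, [1.0], hist, 6.0, h).states[0, -1] - exact)
            for h in hs]
    slope = np.polyfit(np.log(hs), np.log(errs), 1)[0]
    assert slope >= 3.5


def test_dense_eval_exact_at_nodes_and_on_linear_data():
    fun, hist = _scalar_delay_problem()
    traj = solve_dde(fun, [1.0], hist, 2.0, 0.1)
    for i in (0, 3, 11, 20):
        assert traj.dense_eval(traj.t[i])[0] == traj.states[0, i]
    # a linear synthetic trajectory is reproduced exactly by cubic Hermite
    lin = solve_dde(lambda t, y, Z: np.array([2.0]), [1.0],
                    HistoryFunction.constant([0.0], 1.0), 1.0, 0.1)
    for tt in (0.05, 0.333, 0.74):
        assert lin.dense_eval(tt)[0] == pytest.approx(2.0 * tt, abs=1e-13)


def test_dense_eval_domain_error():
    fun, hist = _scalar_delay_problem()
    traj = solve_dde(fun, [1.0], hist, 2.0, 0.1)
    with pytest.raises(ValueError):
        traj.dense_eval(2.5)
    with pytest.raises(ValueError):
        traj.dense_eval(-1.5)


def test_dense_output_step_refinement_consistency():
    """Off-grid dense values converge ~O(h⁴) under step halving."""
    fun, hist = _scalar_delay_problem()
    tprobe = 5.513
    vals = [solve_dde(fun, [1.0], hist, 6.0, h).dense_eval(tprobe)[0]
            for h in (0.2, 0.1, 0.05, 0.025)]
    diffs = [abs(a - b) for a, b in zip(vals, vals[1:])]
    slope = np.polyfit(np.log([0.2, 0.1, 0.05]), np.log(diffs), 1)[0]
    assert slope >= 3.5


def test_step_precondition_enforced(m18):
    eq = solve_all(m18)["E1"]
    with pytest.raises(ValueError):
        integrate(m18.with_rates(tau3=0.1), eq.point, 10.0, 0.05)  # h > τ3/4
    with pytest.raises(ValueError):
        integrate(m18, eq.point, 0.001, 0.05)  # T < h


def test_equilibrium_is_a_fixed_point(m17):
    """Constant history at solved E3 (τ3 = 0) stays put to 1e−6."""
    e3 = solve_all(m17)["E3"]
    traj = integrate(m17, e3.point, 500.0, 0.05)
    assert np.abs(traj.states - e3.point[:, None]).max() < 1e-6


def test_convergence_to_ctl_equilibrium(m17):
    """An off-equilibrium history converges to E3 (global stability, τ3=0)."""
    e3 = solve_all(m17)["E3"]
    traj = integrate(m17, np.array([400.0, 2.0, 0.5, 10.0, 0.1]), 3000.0, 0.05)
    rel = np.abs(traj.states[:, -1] - e3.point) / (1.0 + np.abs(e3.point))
    assert rel.max() < 1e-3
    # half-step rerun agrees
    traj2 = integrate(m17, np.array([400.0, 2.0, 0.5, 10.0, 0.1]), 3000.0, 0.025)
    rel2 = np.abs(traj.states[:, -1] - traj2.states[:, -1]) / (1.0 + np.abs(traj2.states[:, -1]))
    assert rel2.max() < 1e-6


def test_step_halving_agreement_example18(m18):
    eq = solve_all(m18)["E4"]
    hist = eq.point * 1.1
    hist[hist == 0.0] = 0.1
    a = integrate(m18, hist, 400.0, 0.05).states[:, -1]
    b = integrate(m18, hist, 400.0, 0.025).states[:, -1]
    assert (np.abs(a - b) / (1.0 + np.abs(b))).max() < 1e-6


def test_positivity_and_boundedness_random_models(rng):
    """States stay ≥ −1e−8 and below 10× an a-priori scale on [0, 2000]."""
    for _ in range(5):
        m = random_model(rng)
        xbar = m.s(0.0) / -m.sp(0.0)  # λ/d for the linear growth draws
        hist = rng.uniform(0.1, 1.0, size=5) * np.array([xbar, 1.0, 1.0, 1.0, 1.0])
        traj = integrate(m, hist, 2000.0, None)
        assert traj.states.min() > -1e-8
        bound = 10.0 * max(xbar, m.rates.k * xbar / m.rates.u, hist.max(), 10.0)
        assert traj.states.max() < bound


def test_default_step_respects_delays(m17, m18):
    assert default_step(m17) == pytest.approx(0.05)          # min τ = 2 → cap
    assert default_step(m17.with_rates(tau3=0.2)) == pytest.approx(0.01)
    assert default_step(m18.with_rates(tau1=0.0, tau2=0.0, tau3=0.0)) == 0.05


def test_blowup_is_reported_with_timestamp():
    fun = lambda t, y, Z: y * y  # finite-time blow-up
    hist = HistoryFunction.constant([3.0], tau=1.0)
    with np.errstate(over="ignore"), pytest.raises(BlowUpError):
        solve_dde(fun, [1.0], hist, 10.0, 0.1)
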