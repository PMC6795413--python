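"""Incremental 4D-Var: cost, gradient, inner CG loop and outer cycling."""

import numpy as np
import pytest

from dualda.ecosystem import ColumnGrid, ColumnModel, default_initial_state
from dualda.engine import taylor_test
from dualda.fourdvar import (
    CostFunctionSpec,
    CurvatureError,
    MinimizerConfig,
    cost_and_gradient,
    inner_loop,
    outer_loop,
)
from dualda.obs import Observation, ObservationSet

from conftest import random_positive_state


WINDOW = 12


def make_spec(model, obs, sigma_b_scale=0.3, window=WINDOW):
    bg = default_initial_state(model.grid)
    sigma_b = np.maximum(sigma_b_scale * bg.values, 0.02)
    return CostFunctionSpec(model, bg, sigma_b, obs, window)


def observations_from_trajectory(model, traj, sigma=0.1, stride=3,
                                 noise=None):
    """Direct observations of NO3 and PS at the surface cell."""
    recs = []
    rng = np.random.default_rng(0)
    for t in range(0, traj.shape[0], stride):
        for q in ("NO3", "PS"):
            v = float(traj[t, model.layout.index(0, q)])
            if noise:
                v += rng.normal(0.0, noise)
            recs.append(Observation(t, 0, q, v, sigma))
    return ObservationSet(recs)


@pytest.fixture(scope="module")
def twin_setup(model3):
    """A truth trajectory distinct from the background, plus observations."""
    bg = default_initial_state(model3.grid)
    truth0 = random_positive_state(model3, seed=42, scale=0.2)
    truth_traj = model3.run(truth0, WINDOW)
    obs = observations_from_trajectory(model3, truth_traj)
    return truth0, truth_traj, obs


class TestCostAndGradient:
    def test_no_observations_reduces_to_background_term(self, model3):
        spec = make_spec(model3, ObservationSet())
        rng = np.random.default_rng(1)
        dx = 0.05 * rng.standard_normal(model3.n)
        j, g = cost_and_gradient(dx, spec)
        assert j == pytest.approx(0.5 * np.sum((dx / spec.sigma_b) ** 2))
        assert g == pytest.approx(dx / spec.sigma_b**2, rel=1e-12)

    def test_perfect_background_fit_has_zero_cost_and_gradient(self, model3):
        bg_traj = model3.run(default_initial_state(model3.grid).values, WINDOW)
        obs = observations_from_trajectory(model3, bg_traj)
        spec = make_spec(model3, obs)
        j, g = cost_and_gradient(np.zeros(model3.n), spec)
        assert j == pytest.approx(0.0, abs=1e-20)
        assert np.all(g == 0.0)

    def test_gradient_matches_finite_differences(self, model3, twin_setup):
        _, _, obs = twin_setup
        spec = make_spec(model3, obs)
        dx0 = np.zeros(model3.n)
        j0, g = cost_and_gradient(dx0, spec)
        rng = np.random.default_rng(2)
        for _ in range(5):
            d = rng.standard_normal(model3.n)
            h = 1e-6
            jp, _ = cost_and_gradient(dx0 + h * d, spec)
            jm, _ = cost_and_gradient(dx0 - h * d, spec)
            fd = (jp - jm) / (2 * h)
            assert fd == pytest.approx(float(g @ d), rel=1e-5)

    def test_taylor_slope_at_background_and_analysis(self, model3, twin_setup):
        _, _, obs = twin_setup
        spec = make_spec(model3, obs)
        result = outer_loop(spec, MinimizerConfig())
        rng = np.random.default_rng(3)
        d = rng.standard_normal(model3.n)
        for point in (np.zeros(model3.n), result.increment):
            rep = taylor_test(lambda v: cost_and_gradient(v, spec), point, d)
            assert rep.slope >= 1.9

    def test_observation_outside_window_is_rejected(self, model3):
        obs = ObservationSet([Observation(WINDOW + 1, 0, "NO3", 5.0, 0.1)])
        with pytest.raises(IndexError, match="outside"):
            make_spec(model3, obs)


class TestInnerLoop:
    def test_single_observation_reaches_analytic_minimizer(self, model3):
        """Observing the initial state makes the quadratic solvable by hand."""
        bg = default_initial_state(model3.grid)
        j = model3.layout.index(0, "NO3")
        obs = ObservationSet(
            [Observation(0, 0, "NO3", float(bg.values[j]) + 1.0, 0.1)]
        )
        spec = make_spec(model3, obs, window=1)
        traj = model3.run(bg.values, 1)
        delta, costs, _ = inner_loop(
            spec, traj, np.zeros(model3.n), MinimizerConfig(n_inner=2)
        )
        # analytic: delta_j = d / (1 + sigma_r^2 / sigma_b^2), others 0
        sb2 = spec.sigma_b[j] ** 2
        expected = 1.0 / (1.0 + 0.01 / sb2)
        assert delta[j] == pytest.approx(expected, rel=1e-10)
        mask = np.ones(model3.n, bool)
        mask[j] = False
        assert np.all(delta[mask] == 0.0)

    def test_quadratic_cost_monotonically_nonincreasing(self, model3, twin_setup):
        _, _, obs = twin_setup
        spec = make_spec(model3, obs)
        traj = model3.run(spec.background.values, WINDOW)
        _, costs, _ = inner_loop(
            spec, traj, np.zeros(model3.n), MinimizerConfig(n_inner=10)
        )
        assert all(b <= a + 1e-12 for a, b in zip(costs, costs[1:]))

    def test_weak_background_full_observability_recovers_truth(self, model3):
        """With B -> inf and every variable observed at t=0, the analysis
        reproduces the synthetic truth initial condition to < 1% RMS."""
        truth0 = random_positive_state(model3, seed=11, scale=0.15)
        traj_t = model3.run(truth0, 4)
        recs = [
            Observation(0, c, v, float(traj_t[0, model3.layout.index(c, v)]),
                        0.01)
            for c in range(model3.layout.n_cells)
            for v in model3.layout.variables
        ]
        spec = make_spec(model3, ObservationSet(recs), sigma_b_scale=1e4,
                         window=4)
        result = outer_loop(spec, MinimizerConfig(n_outer=1, n_inner=10))
        rms = np.sqrt(np.mean((result.analysis.values - truth0) ** 2))
        assert rms / np.sqrt(np.mean(truth0**2)) < 0.01

    def test_inconsistent_adjoint_triggers_curvature_diagnostic(self, model3):
        bg = default_initial_state(model3.grid)
        j = model3.layout.index(0, "NO3")
        obs = ObservationSet([Observation(1, 0, "NO3", 20.0, 1e-4)])
        spec = make_spec(model3, obs, window=1)
        traj = model3.run(bg.values, 1)
        broken = _BrokenAdjointModel(model3)
        spec.model = broken
        with pytest.raises(CurvatureError, match="dot_product_test"):
            inner_loop(spec, traj, np.zeros(model3.n), MinimizerConfig())


class _BrokenAdjointModel:
    """Wraps a model but negates its adjoint: an inconsistent TLM/AD pair."""

    def __init__(self, model):
        self._m = model
        self.layout = model.layout
        self.params = model.params
        self.n = model.n

    def __getattr__(self, name):
        return getattr(self._m, name)

    def step_adjoint(self, x, w, k=0):
        return -self._m.step_adjoint(x, w, k)


class TestOuterLoop:
    def test_nonlinear_cost_decreases_on_twin_problem(self, model3, twin_setup):
        _, _, obs = twin_setup
        spec = make_spec(model3, obs)
        result = outer_loop(spec, MinimizerConfig())
        assert result.final_cost < result.initial_cost
        assert all(b <= a + 1e-9 for a, b in
                   zip(result.nonlinear_costs, result.nonlinear_costs[1:]))

    def test_zero_innovation_fixed_point(self, model3):
        bg_traj = model3.run(default_initial_state(model3.grid).values, WINDOW)
        obs = observations_from_trajectory(model3, bg_traj)
        spec = make_spec(model3, obs)
        result = outer_loop(spec, MinimizerConfig())
        assert np.abs(result.increment).max() < 1e-12

    def test_call_counters(self, model3, twin_setup):
        """n_outer+1 trajectories; per CG iteration one TLM and one adjoint
        sweep, plus one adjoint sweep per outer loop for the CG right-hand
        side."""
        _, _, obs = twin_setup
        spec = make_spec(model3, obs)
        cfg = MinimizerConfig(n_outer=2, n_inner=4)
        result = outer_loop(spec, cfg)
        c = result.counters
        assert c["nonlinear_trajectories"] == cfg.n_outer + 1
        assert c["tlm_sweeps"] == c["cg_iterations"]
        assert c["adjoint_sweeps"] == c["cg_iterations"] + cfg.n_outer

    def test_defaults_are_ten_inner_two_outer(self):
        cfg = MinimizerConfig()
        assert cfg.n_inner == 10 and cfg.n_outer == 2 and cfg.precondition
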