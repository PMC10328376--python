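"""Tests of the RMSD objective, gradient estimation and the
random-mutation / estimated-gradient optimizer."""

import numpy as np
import pytest

import phuzsim as pz
from phuzsim.calibrate import (
    OptimizationConfig,
    ParameterVector,
    _eval_seed,
    estimate_gradient,
    make_objective,
    objective,
    optimize_parameters,
    rmsd_surface,
)
from phuzsim.params import ParameterError, SimulationConfig
from phuzsim.stats import position_histogram


def tiny_sim(kin, cell, n_runs=100, seed=5):
    return SimulationConfig(
        kinetics=kin, cell=cell, dt=0.05, duration=240.0, n_runs=n_runs, seed=seed
    )


@pytest.fixture(scope="module")
def pv():
    return ParameterVector.from_dict(
        {"v_poly_mean": 0.045, "t_cat_mean": 50.0},
        {"v_poly_mean": (0.01, 0.15), "t_cat_mean": (10.0, 150.0)},
        {"v_poly_mean": 0.01, "t_cat_mean": 10.0},
    )


class TestParameterVector:
    def test_unknown_name_rejected(self):
        with pytest.raises(ParameterError):
            ParameterVector.from_dict({"bogus": 1.0}, {"bogus": (0, 2)})

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ParameterError):
            ParameterVector.from_dict({"v_poly_mean": 5.0}, {"v_poly_mean": (0.0, 1.0)})

    def test_apply_to_overrides_only_free_fields(self, pv, calibrated_kinetics):
        kin = pv.with_values(np.array([0.08, 60.0])).apply_to(calibrated_kinetics)
        assert kin.v_poly_mean == 0.08
        assert kin.t_cat_mean == 60.0
        assert kin.v_depoly_mean == calibrated_kinetics.v_depoly_mean


class TestObjective:
    def test_self_comparison_with_common_seeds_is_zero(
        self, pv, calibrated_kinetics, calibrated_cell
    ):
        sim = tiny_sim(calibrated_kinetics, calibrated_cell)
        seed = 11
        ens = pz.run_ensemble(sim.replace(seed=_eval_seed(seed, 0)))
        measured = position_histogram(ens.normalized_positions, 10)
        f = make_objective(measured, sim, None, pv, replicates=1)
        assert f(pv.values, seed) == 0.0

    def test_independent_seeds_within_noise_floor(
        self, pv, calibrated_kinetics, calibrated_cell
    ):
        sim = tiny_sim(calibrated_kinetics, calibrated_cell)
        measured = position_histogram(
            pz.run_ensemble(sim.replace(seed=901)).normalized_positions, 10
        )
        # noise floor: RMSD spread among independent same-parameter ensembles
        self_rmsds = [
            objective(pv, measured, sim, replicates=1, seed=s) for s in range(6)
        ]
        floor = max(self_rmsds)
        assert floor > 0.0
        # grossly wrong parameters (static spindle) sit far above the floor
        static = pv.with_values(np.array([0.0100, 10.0]))
        wrong = objective(static, measured, sim, replicates=1, seed=0)
        assert wrong > 3.0 * floor


class TestEstimateGradient:
    xstar = np.array([0.07, 80.0])

    def quad(self, x, seed):
        # scaled so both coordinates contribute comparably
        z = (x - self.xstar) / np.array([0.01, 10.0])
        return float(np.sum(z * z))

    def test_quadratic_gradient_matches_closed_form(self, pv):
        point = pv.with_values(np.array([0.05, 60.0]))
        grad = estimate_gradient(self.quad, point, perturbation_scale=0.01)
        expected = 2 * (point.values - self.xstar) / np.array([0.01, 10.0]) ** 2
        np.testing.assert_allclose(grad, expected, rtol=0.01)

    def test_gradient_vanishes_at_minimum(self, pv):
        point = pv.with_values(self.xstar)
        grad = estimate_gradient(self.quad, point, perturbation_scale=0.01)
        assert np.linalg.norm(grad) == pytest.approx(0.0, abs=1e-9)

    def test_linear_objective_has_constant_gradient(self, pv):
        lin = lambda x, seed: float(3.0 * x[0] - 0.25 * x[1])
        g1 = estimate_gradient(lin, pv.with_values(np.array([0.05, 50.0])), 0.05)
        g2 = estimate_gradient(lin, pv.with_values(np.array([0.10, 120.0])), 0.05)
        np.testing.assert_allclose(g1, [3.0, -0.25], rtol=1e-9)
        np.testing.assert_allclose(g1, g2, rtol=1e-9)

    def test_one_sided_at_bounds(self, pv):
        point = pv.with_values(np.array([0.01, 10.0]))  # at the lower bounds
        grad = estimate_gradient(self.quad, point, perturbation_scale=0.25)
        assert np.all(np.isfinite(grad))
        assert np.all(grad < 0)  # objective decreases toward the interior? no: points downhill

    def test_spsa_mode_descends_quadratic(self, pv):
        def quad(x, seed):
            z = (x - self.xstar) / np.array([0.01, 10.0])
            return float(3.0 * z[0] ** 2 + z[1] ** 2)

        point = pv.with_values(np.array([0.05, 60.0]))
        grad = estimate_gradient(
            quad, point, 0.05, seed=3, rng=np.random.default_rng(3), mode="spsa"
        )
        # the simultaneous-perturbation estimate points uphill on average;
        # for this single draw it must at least correlate with the truth
        true = np.array([6.0, 2.0]) * (point.values - self.xstar) / np.array([0.01, 10.0]) ** 2
        assert np.dot(grad, true) > 0


class TestOptimizer:
    xstar = np.array([0.3, 1.7])

    def quad(self, x, seed):
        return float(np.sum((x - self.xstar) ** 2))

    def make_init(self):
        return ParameterVector.from_dict(
            {"v_poly_mean": 1.0, "t_cat_mean": 0.5},
            {"v_poly_mean": (0.0, 5.0), "t_cat_mean": (0.0, 5.0)},
            {"v_poly_mean": 0.5, "t_cat_mean": 0.5},
        )

    def quad_opt_config(self, seed=0):
        return OptimizationConfig(
            replicates_per_eval=1,
            max_iterations=80,
            n_initial_mutations=4,
            step_decay=0.85,
            convergence_tol=1e-12,
            convergence_window=200,
            seed=seed,
        )

    def test_quadratic_minimum_recovered_to_1e3_relative(self):
        res = optimize_parameters(None, self.make_init(), self.quad_opt_config(),
                                  None, func=self.quad)
        np.testing.assert_allclose(res.params.values, self.xstar, rtol=1e-3)

    def test_best_seen_trace_is_monotone_and_bounded(self):
        res = optimize_parameters(None, self.make_init(), self.quad_opt_config(),
                                  None, func=self.quad)
        rmsds = res.trace["rmsd"].to_numpy()
        assert np.all(np.diff(rmsds) <= 0)
        assert np.all(res.params.values >= res.params.lower)
        assert np.all(res.params.values <= res.params.upper)

    def test_identical_seeds_give_identical_traces(self):
        a = optimize_parameters(None, self.make_init(), self.quad_opt_config(7),
                                None, func=self.quad)
        b = optimize_parameters(None, self.make_init(), self.quad_opt_config(7),
                                None, func=self.quad)
        assert a.trace.equals(b.trace)

    def test_init_at_truth_never_worsens(self):
        init = self.make_init().with_values(self.xstar)
        cfg = OptimizationConfig(replicates_per_eval=1, max_iterations=5,
                                 n_initial_mutations=2, seed=1)
        res = optimize_parameters(None, init, cfg, None, func=self.quad)
        assert res.rmsd <= self.quad(self.xstar, 0) + 1e-12


class TestRmsdSurface:
    def test_constant_objective_is_flat(self):
        res = rmsd_surface("v_poly_mean", "v_depoly_mean", (0, 1), (0, 1),
                           n_points=50, func=lambda x, s: 2.5)
        assert np.all(res.values == 2.5)
        _, _, grid = res.to_grid(10, 10)
        inner = grid[~np.isnan(grid)]
        np.testing.assert_allclose(inner, 2.5)

    def test_quadratic_minimum_located_within_sample_spacing(self):
        xstar = np.array([0.4, 0.6])
        quad = lambda x, s: float(np.sum((x - xstar) ** 2))
        res = rmsd_surface("v_poly_mean", "v_depoly_mean", (0, 1), (0, 1),
                           n_points=200, seed=3, func=quad)
        assert len(res.values) == 200  # the documented sampling count
        best = res.points[np.argmin(res.values)]
        spacing = 1.0 / np.sqrt(200)
        assert np.linalg.norm(best - xstar) < 2 * spacing

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ParameterError):
            rmsd_surface("v_poly_mean", "v_depoly_mean", (1, 1), (0, 1),
                         func=lambda x, s: 0.0)
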