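"""Unit tests of the stochastic filament/nucleus simulator."""

import numpy as np
import pytest
from scipy import integrate, stats as sps

import phuzsim as pz
from phuzsim.params import CellConfig, KineticParams, ParameterError, SimulationConfig
from phuzsim.simulate import (
    CATASTROPHE,
    GROWING,
    FilamentState,
    SimState,
    make_initial_state,
    run_ensemble,
    run_simulation,
    sample_speed,
    step,
)


def rectified_normal_mean(mu: float, sigma: float) -> float:
    """Quadrature oracle for E[max(0, N(mu, sigma))]."""
    f = lambda x: x * sps.norm.pdf(x, loc=mu, scale=sigma)
    val, _ = integrate.quad(f, 0.0, mu + 12 * sigma)
    return val


class TestSampleSpeed:
    def test_zero_variance_returns_mean(self, rng):
        assert sample_speed(0.05, 0.0, rng) == 0.05
        assert sample_speed(0.0, 0.0, rng) == 0.0

    def test_negative_parameters_rejected(self, rng):
        with pytest.raises(ParameterError):
            sample_speed(-0.1, 0.0, rng)
        with pytest.raises(ParameterError):
            sample_speed(0.1, -0.1, rng)

    def test_mean_matches_quadrature_oracle(self, rng):
        mu, sigma, n = 0.05, 0.02, 100_000
        draws = np.array([sample_speed(mu, sigma, rng) for _ in range(n)])
        expected = rectified_normal_mean(mu, sigma)
        se = draws.std(ddof=1) / np.sqrt(n)
        assert abs(draws.mean() - expected) < 3 * se
        assert draws.min() >= 0.0


class TestStokesEinstein:
    def test_reference_value(self):
        # 1 um sphere, 310 K, water viscosity
        assert pz.stokes_einstein_D(1.0, 310.0, 1.0e-3) == pytest.approx(0.227, abs=1e-3)

    @pytest.mark.parametrize("factor", [2.0, 5.0])
    def test_inverse_proportionality(self, factor):
        base = pz.stokes_einstein_D(1.0, 310.0, 1.0e-3)
        assert pz.stokes_einstein_D(factor, 310.0, 1.0e-3) == pytest.approx(base / factor)
        assert pz.stokes_einstein_D(1.0, 310.0, factor * 1.0e-3) == pytest.approx(base / factor)

    def test_nonpositive_arguments_rejected(self):
        for args in [(-1.0, 310.0, 1e-3), (1.0, 0.0, 1e-3), (1.0, 310.0, 0.0)]:
            with pytest.raises(ParameterError):
                pz.stokes_einstein_D(*args)


def _static_state(length=4.0, radius=0.5, center=None, left=0.5, right=3.5,
                  v_poly=0.0, phase=GROWING, D=0.0):
    cell = CellConfig(length=length, nucleus_radius=radius, nucleus_diffusion_coeff=D)
    c = length / 2.0 if center is None else center
    mk = lambda origin, tip: FilamentState(
        origin=origin,
        length=tip if origin == "left" else length - tip,
        phase=phase,
        v_poly=v_poly,
        next_phase_change=1e9,
    )
    return SimState(t=0.0, left=mk("left", left), right=mk("right", right),
                    nucleus_offset=c - length / 2.0, cell=cell)


class TestStep:
    def test_no_dynamics_leaves_state_unchanged(self, rng):
        state = _static_state()
        out = step(state, KineticParams.zero(), 0.01, rng)
        assert out.t == pytest.approx(0.01)
        assert out.nucleus_center == state.nucleus_center
        assert out.left_tip == state.left_tip
        assert out.right_tip == state.right_tip

    def test_jammed_state_is_frozen(self, rng):
        # both tips in contact, both growing: the two-sided jam rule
        state = _static_state(left=1.5, right=2.5, v_poly=0.1, D=0.3)
        out = step(state, KineticParams.zero().replace(v_poly_mean=0.1), 0.01, rng)
        assert out.nucleus_center == state.nucleus_center
        assert out.left_tip == 1.5
        assert out.right_tip == 2.5

    def test_free_tip_advances_exactly(self, rng):
        state = _static_state(left=0.5, right=4.0, v_poly=0.05)
        state.right.v_poly = 0.0  # only the left filament grows
        out = step(state, KineticParams.zero(), 0.01, rng)
        assert out.left_tip == pytest.approx(0.5 + 0.05 * 0.01, abs=1e-15)
        assert out.right_tip == 4.0

    def test_invalid_dt_rejected(self, rng):
        with pytest.raises(ParameterError):
            step(_static_state(), KineticParams.zero(), 0.0, rng)

    def test_invariant_violating_state_rejected(self, rng):
        state = _static_state(left=2.0)  # left tip overlaps the nucleus
        with pytest.raises(pz.StateError):
            step(state, KineticParams.zero(), 0.01, rng)


class TestRunSimulation:
    def test_zero_duration_yields_initial_state(self, static_config):
        cfg = static_config.replace(duration=0.0, record_trajectory=True)
        res = run_simulation(cfg)
        assert len(res.trajectory.t) == 1
        assert res.final_state.t == 0.0
        # nucleus at clamp(0.9 L) = min(3.15, 3.0)
        assert res.final_state.nucleus_center == pytest.approx(3.0)

    def test_static_cell_keeps_clamped_start(self, static_config):
        res = run_simulation(static_config)
        assert res.final_state.nucleus_center == pytest.approx(
            min(0.9 * 3.5, 3.5 - 0.5)
        )
        assert res.final_state.left_tip == 0.0
        assert res.final_state.right_tip == 3.5

    def test_identical_seed_identical_output(self, fast_config):
        a = run_simulation(fast_config, run_seed=7)
        b = run_simulation(fast_config, run_seed=7)
        assert a.final_state.nucleus_center == b.final_state.nucleus_center
        assert a.final_state.left_tip == b.final_state.left_tip

    def test_cell_too_short_rejected(self, fast_config):
        with pytest.raises(ParameterError):
            run_simulation(fast_config, cell_length=0.9)

    def test_calibrated_run_moves_nucleus_toward_midcell(self, fast_config):
        cfg = fast_config.replace(duration=600.0, record_trajectory=True)
        res = run_simulation(cfg, run_seed=3)
        traj = res.trajectory
        start_dev = abs(traj.nucleus_center[0] / 3.5 - 0.5)
        end_dev = abs(res.final_state.nucleus_center / 3.5 - 0.5)
        assert end_dev < start_dev
        # dynamic instability: tips both grow and collapse over the run
        assert traj.left_in_catastrophe.any() and traj.right_in_catastrophe.any()
        assert (~traj.left_in_catastrophe).any()


def test_centering_fraction_converged_in_dt():
    """Halving the timestep from 0.02 to 0.01 s changes ensemble
    centering by less than the between-seed spread: the discretization
    is converged at the reference dt."""
    def mean_fraction(dt):
        fr = []
        for seed in (0, 1):
            cfg = pz.default_config(3.5, dt=dt, duration=900.0, n_runs=200, seed=seed)
            fr.append(pz.centering_fraction(pz.run_ensemble(cfg).normalized_positions))
        return np.mean(fr), np.ptp(fr)

    m_fine, spread_fine = mean_fraction(0.01)
    m_coarse, spread_coarse = mean_fraction(0.02)
    assert abs(m_fine - m_coarse) < max(0.05, spread_fine + spread_coarse)


class TestRunEnsemble:
    def test_singleton_matches_run_simulation(self, fast_config):
        cfg = fast_config.replace(n_runs=1)
        ens = run_ensemble(cfg)
        single = run_simulation(cfg)
        assert ens.final_positions[0] == single.final_state.nucleus_center

    def test_master_seed_determinism(self, fast_config):
        a = run_ensemble(fast_config)
        b = run_ensemble(fast_config)
        assert np.array_equal(a.final_positions, b.final_positions)
        assert np.array_equal(a.seed_record, b.seed_record)

    def test_first_runs_stable_when_n_runs_grows(self, fast_config):
        small = run_ensemble(fast_config.replace(n_runs=5))
        large = run_ensemble(fast_config.replace(n_runs=10))
        assert np.array_equal(small.final_positions, large.final_positions[:5])

    def test_gaussian_length_sampler(self, fast_config):
        cfg = fast_config.replace(n_runs=40)
        ens = run_ensemble(cfg, lambda g: g.normal(5.0, 1.0))
        assert len(ens) == 40
        assert ens.cell_lengths.std() > 0
        r = cfg.cell.nucleus_radius
        norm = ens.normalized_positions
        assert np.all(ens.cell_lengths > 2 * r)
        assert np.all(norm >= r / ens.cell_lengths - 1e-12)
        assert np.all(norm <= 1 - r / ens.cell_lengths + 1e-12)

    def test_infeasible_sampler_errors_after_retries(self, fast_config):
        with pytest.raises(ParameterError):
            run_ensemble(fast_config.replace(n_runs=2), lambda g: 0.5)

    def test_endpoint_frame_schema(self, fast_config):
        df = run_ensemble(fast_config.replace(n_runs=3)).to_dataframe()
        assert list(df.columns) == [
            "run", "seed", "cell_length_um", "final_position_um", "normalized_position",
        ]
        assert len(df) == 3
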