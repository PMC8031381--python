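import math

import numpy as np
import pytest
from scipy.integrate import quad

from rowerchain.errors import ConfigurationError, IntegrationError
from rowerchain.geometry import ChainSpec, build_chain
from rowerchain.hydrodynamics import projected_mobility
from rowerchain.dynamics import (
    RowerState,
    calibrate_trap_strength,
    driving_force,
    simulate,
    step,
    switch_update,
    thermal_energy,
    thermal_step,
)

GAMMA = 6 * math.pi  # drag for a = eta = 1


class TestDrivingForce:
    def test_linear_potential_constant_force(self):
        # alpha = 1: magnitude k, independent of position
        for u in (-10.0, 0.0, 10.0):
            f = driving_force(u, +1, 30.0, 5.0, 1.0, 2.5)
            assert f == pytest.approx(5.0)

    def test_closed_form_at_stroke_start(self):
        # u = -A/2, sigma = +1: distance to vertex is A + x_s
        a, xs, k = 30.0, 2.5, 7.0
        f = driving_force(-a / 2, +1, a, k, 0.5, xs)
        assert f == pytest.approx(0.5 * k * (a + xs) ** -0.5)

    def test_monotone_increase_toward_switch_point(self):
        us = np.linspace(-15.0, 14.9, 50)
        f = driving_force(us, +1, 30.0, 7.0, 0.5, 2.5)
        assert np.all(f > 0)
        assert np.all(np.diff(f) > 0)

    def test_sign_follows_vertex(self):
        assert driving_force(0.0, -1, 30.0, 7.0, 0.5, 2.5) < 0
        # past the vertex the force pulls back
        assert driving_force(17.6, +1, 30.0, 7.0, 0.5, 2.5) < 0

    def test_at_vertex_raises(self):
        with pytest.raises(ValueError):
            driving_force(17.5, +1, 30.0, 7.0, 0.5, 2.5)


class TestSwitchUpdate:
    @pytest.mark.parametrize("u,sigma,expected", [
        (0.0, +1, +1),  # mid-stroke
        (15.0, +1, -1),  # threshold crossing
        (15.0, -1, -1),  # already heading away
        (-15.0, -1, +1),
        (14.999, +1, +1),
    ])
    def test_cases(self, u, sigma, expected):
        assert switch_update(u, sigma, 30.0) == expected

    def test_vectorised(self):
        out = switch_update(np.array([0.0, 15.0]), np.array([1, 1]), 30.0)
        np.testing.assert_array_equal(out, [1, -1])


class TestCalibration:
    def test_alpha_one_closed_form(self):
        # constant-force stroke: T = 2 gamma A / k
        k = calibrate_trap_strength(GAMMA, 30.0, 2.5, 1.0, 2.0)
        assert k == pytest.approx(2 * GAMMA * 30.0 / 2.0)

    def test_against_quadrature_oracle(self):
        """Closed form matches the independent half-stroke quadrature
        T/2 = (gamma/(alpha k)) * int_{x_s}^{A+x_s} r^(1-alpha) dr."""
        for alpha in (0.25, 0.5, 0.75, 1.0):
            a, xs, t_target = 30.0, 2.5, 2.0
            k = calibrate_trap_strength(GAMMA, a, xs, alpha, t_target)
            integral, _ = quad(lambda r: r ** (1 - alpha), xs, a + xs)
            t_quad = 2 * GAMMA * integral / (alpha * k)
            assert t_quad == pytest.approx(t_target, rel=1e-8)

    def test_published_alpha_half_form(self):
        k = calibrate_trap_strength(GAMMA, 30.0, 2.5, 0.5, 2.0)
        expected = (8 * GAMMA / (3 * 2.0)) * (32.5 ** 1.5 - 2.5 ** 1.5)
        assert k == pytest.approx(expected, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            calibrate_trap_strength(-1.0, 30.0, 2.5, 0.5, 2.0)
        with pytest.raises(ValueError):
            calibrate_trap_strength(GAMMA, 30.0, 2.5, 1.5, 2.0)


class TestSingleRowerPeriod:
    def test_noise_free_period_matches_target(self):
        """Simulated noise-free rower oscillates with the calibrated 2 s
        period to within one time step, strictly periodically."""
        spec = ChainSpec(n_rowers=1, noise_level=0.0)
        dt_cycles = 2e-3
        traj = simulate(spec, n_cycles=40, dt_cycles=dt_cycles, seed=0,
                        sample_cycles=dt_cycles)
        s = traj.trap_signs[:, 0]
        flips = traj.times[1:][(s[1:] == -1) & (s[:-1] == 1)]
        periods = np.diff(flips) * spec.target_period
        assert abs(periods.mean() - spec.target_period) < dt_cycles * spec.target_period
        # switch count per cycle: exactly 2 sign changes per period
        switches = np.sum(s[1:] != s[:-1])
        assert switches == pytest.approx(2 * traj.n_cycles, abs=2)

    def test_amplitude_modified_rower_keeps_period(self):
        """Recalibrated modified rowers preserve the single-rower period
        to < 0.5% when simulated in isolation."""
        for a_x in (-12.0, 9.0):
            mod = ChainSpec(n_rowers=1, amplitude=30.0 + a_x, noise_level=0.0)
            traj = simulate(mod, n_cycles=30, dt_cycles=2e-3, seed=0,
                            sample_cycles=2e-3)
            s = traj.trap_signs[:, 0]
            flips = traj.times[1:][(s[1:] == -1) & (s[:-1] == 1)]
            period = np.diff(flips).mean() * mod.target_period
            assert period == pytest.approx(2.0, rel=5e-3)

    def test_first_order_convergence_under_dt_halving(self):
        spec = ChainSpec(n_rowers=2, spacing=7.0, noise_level=0.0)
        u0 = RowerState(track_coord=np.array([3.0, -5.0]),
                        trap_sign=np.array([1, -1]))
        ref = simulate(spec, n_cycles=1, dt_cycles=2.5e-5, seed=0,
                       sample_cycles=1.0, initial_state=u0).track_coords[-1]
        errs = []
        for dtc in (4e-3, 2e-3, 1e-3):
            got = simulate(spec, n_cycles=1, dt_cycles=dtc, seed=0,
                           sample_cycles=1.0, initial_state=u0).track_coords[-1]
            errs.append(np.abs(got - ref).max())
        assert errs[0] > errs[1] > errs[2]
        # at least first-order: halving dt at least halves the error
        assert errs[1] / errs[0] < 0.55
        assert errs[2] / errs[1] < 0.55


class TestThermalStep:
    def test_zero_temperature(self, default_chain, rng):
        M = projected_mobility(default_chain, np.zeros(60))
        np.testing.assert_array_equal(thermal_step(M, 0.0, 1.0, rng), np.zeros(60))

    def test_diagonal_mobility_variances(self, rng):
        from rowerchain.hydrodynamics import MobilityMatrix

        diag = np.array([1.0, 2.0, 0.5])
        M = MobilityMatrix(entries=np.diag(diag), positions=np.zeros((3, 3)),
                           viscosity=1.0)
        draws = np.array([thermal_step(M, 0.7, 0.01, rng) for _ in range(40000)])
        np.testing.assert_allclose(draws.var(axis=0), 2 * 0.7 * diag * 0.01, rtol=0.05)
        np.testing.assert_allclose(draws.mean(axis=0), 0.0, atol=2e-3)

    def test_covariance_small_matrix_oracle(self, rng):
        """Empirical covariance of 1e5 draws on a fixed 5x5 SPD matrix
        within 3% (Frobenius) of 2 kT M dt."""
        from rowerchain.hydrodynamics import MobilityMatrix

        A = rng.normal(size=(5, 5))
        m = A @ A.T + 5 * np.eye(5)
        M = MobilityMatrix(entries=m, positions=np.zeros((5, 3)), viscosity=1.0)
        k_t, dt = 0.3, 0.02
        draws = np.array([thermal_step(M, k_t, dt, rng) for _ in range(100000)])
        target = 2 * k_t * m * dt
        emp = np.cov(draws.T)
        rel = np.linalg.norm(emp - target) / np.linalg.norm(target)
        assert rel < 0.03

    def test_covariance_full_chain_matrix(self, default_chain, rng):
        """Same check on the coupled 60-rower mobility at track centers."""
        M = projected_mobility(default_chain, np.zeros(60))
        k_t, dt = 0.0368, 0.004
        n = 150000
        z = rng.standard_normal((n, 60))
        L = M.cholesky()
        draws = math.sqrt(2 * k_t * dt) * z @ L.T
        target = 2 * k_t * dt * M.entries
        emp = np.cov(draws.T)
        rel = np.linalg.norm(emp - target) / np.linalg.norm(target)
        assert rel < 0.03


class TestThermalEnergy:
    def test_scales_with_noise_level(self):
        s1 = ChainSpec(noise_level=3.7e-5)
        s2 = ChainSpec(noise_level=7.4e-5)
        assert thermal_energy(s2) == pytest.approx(2 * thermal_energy(s1))
        assert thermal_energy(ChainSpec(noise_level=0.0)) == 0.0

    def test_is_fraction_of_potential_drop(self):
        spec = ChainSpec()
        k = calibrate_trap_strength(spec.drag, 30.0, 2.5, 0.5, 2.0)
        drop = k * (32.5 ** 0.5 - 2.5 ** 0.5)
        assert thermal_energy(spec) == pytest.approx(3.7e-5 * drop)


class TestStep:
    def test_zero_force_zero_noise_is_identity(self, tiny_spec):
        cfg = build_chain(tiny_spec.with_(noise_level=0.0))
        state = RowerState(track_coord=np.zeros(6), trap_sign=np.ones(6, dtype=int))
        out = step(state, cfg, k_t=0.0, dt=0.0)
        np.testing.assert_array_equal(out.track_coord, state.track_coord)
        np.testing.assert_array_equal(out.trap_sign, state.trap_sign)

    def test_single_rower_matches_high_resolution_quadrature(self):
        """One deterministic step tracks the 1-D ODE gamma du/dt = F(u)."""
        spec = ChainSpec(n_rowers=1, noise_level=0.0)
        cfg = build_chain(spec)
        u = 0.0
        dt = 2e-3 * 2.0
        state = RowerState(track_coord=np.array([u]), trap_sign=np.array([1]))
        out = step(state, cfg, k_t=0.0, dt=dt)
        # fine-grained Euler reference with 1000 substeps
        uu = u
        k = cfg.per_rower_trap_strength[0]
        for _ in range(1000):
            f = driving_force(uu, 1, 30.0, k, 0.5, 2.5)
            uu += (dt / 1000) * f / spec.drag
        assert out.track_coord[0] == pytest.approx(uu, abs=1e-6)

    def test_far_separated_pair_behaves_as_isolated(self):
        spec2 = ChainSpec(n_rowers=2, spacing=5000.0, noise_level=0.0)
        spec1 = ChainSpec(n_rowers=1, noise_level=0.0)
        u0 = RowerState(track_coord=np.array([2.0, -4.0]), trap_sign=np.array([1, 1]))
        u0_iso = RowerState(track_coord=np.array([2.0]), trap_sign=np.array([1]))
        pair = simulate(spec2, n_cycles=2, dt_cycles=2e-3, seed=0,
                        initial_state=u0).track_coords
        iso = simulate(spec1, n_cycles=2, dt_cycles=2e-3, seed=0,
                       initial_state=u0_iso).track_coords
        assert np.abs(pair[:, 0] - iso[:, 0]).max() < 1e-2

    def test_instability_detected(self, tiny_spec):
        cfg = build_chain(tiny_spec.with_(noise_level=0.0))
        state = RowerState(track_coord=np.zeros(6), trap_sign=np.ones(6, dtype=int))
        with pytest.raises(IntegrationError):
            step(state, cfg, k_t=0.0, dt=50.0)  # absurd step


class TestSimulate:
    def test_deterministic_given_seed(self, tiny_spec):
        a = simulate(tiny_spec, n_cycles=3, dt_cycles=2e-3, seed=42)
        b = simulate(tiny_spec, n_cycles=3, dt_cycles=2e-3, seed=42)
        np.testing.assert_array_equal(a.track_coords, b.track_coords)
        np.testing.assert_array_equal(a.trap_signs, b.trap_signs)

    def test_seed_changes_initial_conditions(self, tiny_spec):
        a = simulate(tiny_spec, n_cycles=1, dt_cycles=2e-3, seed=1)
        b = simulate(tiny_spec, n_cycles=1, dt_cycles=2e-3, seed=2)
        assert not np.array_equal(a.track_coords[0], b.track_coords[0])

    def test_initial_conditions_distribution(self):
        spec = ChainSpec(n_rowers=200, noise_level=0.0)
        traj = simulate(spec, n_cycles=0.01, dt_cycles=1e-2, seed=7)
        u0 = traj.track_coords[0]
        assert np.all(np.abs(u0) <= 15.0)
        assert np.abs(u0).max() > 10.0  # actually spreads over the range
        s0 = traj.trap_signs[0]
        assert set(np.unique(s0)) == {-1, 1}

    def test_symmetry_preservation_without_noise(self):
        """Identical rowers started identically stay identical forever."""
        spec = ChainSpec(n_rowers=6, noise_level=0.0)
        state = RowerState(track_coord=np.full(6, 3.0),
                           trap_sign=np.ones(6, dtype=int))
        traj = simulate(spec, n_cycles=5, dt_cycles=2e-3, seed=0,
                        initial_state=state)
        spread = traj.track_coords.max(axis=1) - traj.track_coords.min(axis=1)
        assert spread.max() < 1e-12

    def test_engines_agree(self, tiny_spec):
        fast = simulate(tiny_spec, n_cycles=2, dt_cycles=2e-3, seed=9, engine="fast")
        ref = simulate(tiny_spec, n_cycles=2, dt_cycles=2e-3, seed=9, engine="reference")
        np.testing.assert_allclose(fast.track_coords, ref.track_coords, atol=1e-9)
        np.testing.assert_array_equal(fast.trap_signs, ref.trap_signs)

    def test_sampling_grid(self, tiny_spec):
        traj = simulate(tiny_spec, n_cycles=2, dt_cycles=2e-3, seed=0)
        assert traj.times[0] == 0.0
        assert traj.times[-1] == pytest.approx(2.0)
        np.testing.assert_allclose(np.diff(traj.times), 0.1)

    def test_rejects_bad_args(self, tiny_spec):
        with pytest.raises(ConfigurationError):
            simulate(tiny_spec, n_cycles=0, seed=0)
        with pytest.raises(ConfigurationError):
            simulate(tiny_spec, n_cycles=1, seed=0, engine="warp-drive")

    def test_phase_locking_uniform_chain(self):
        """Small uniform ring with weak noise settles into a phase-locked
        state: late-time pairwise phase-difference drift is tiny."""
        from rowerchain.phase_analysis import phase_profile

        spec = ChainSpec(n_rowers=12, group_size=4)
        traj = simulate(spec, n_cycles=300, dt_cycles=2e-3, seed=3)
        early = phase_profile(traj, 200.0).values
        late = phase_profile(traj, 300.0).values
        drift = np.abs(late - early).max() / 100.0  # per cycle, radians
        assert drift < 0.01 * 2 * np.pi
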