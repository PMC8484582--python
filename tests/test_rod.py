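"""Langevin rod model: drag, torque, stationary law, integrator behaviour."""

import numpy as np
import pytest
from scipy import integrate, stats

from windsock.rod import (
    AngleTrajectory,
    RodParams,
    StabilityError,
    ThermalEnv,
    drag_coefficients,
    flow_torque,
    kappa,
    mixing_time,
    rotational_diffusion,
    sample_population,
    simulate_spherical,
    simulate_trajectory,
    speed_for_kappa,
    stability_bound_dt,
    stationary_density,
    wrap_angle,
)


class TestDragCoefficients:
    def test_reference_values(self):
        alpha, gamma = drag_coefficients(5e-6, 12e-9, 1e-3)
        assert gamma == pytest.approx(2.44e-20, rel=0.01)
        assert alpha == pytest.approx(4 * np.pi / (np.log(5e-6 / 12e-9) + 0.84))

    def test_gamma_cubic_in_length(self):
        # doubling ℓ with d scaled keeps the log factor fixed → γ ∝ ℓ³
        _, g1 = drag_coefficients(5e-6, 12e-9, 1e-3)
        _, g2 = drag_coefficients(10e-6, 24e-9, 1e-3)
        assert g2 / g1 == pytest.approx(8.0, rel=1e-12)

    def test_alpha_monotone_in_aspect(self):
        alphas = [drag_coefficients(5e-6, d, 1e-3)[0] for d in (50e-9, 20e-9, 5e-9)]
        assert np.all(np.diff(alphas) < 0)

    def test_domain_guard(self):
        with pytest.raises(ValueError, match="slender-body"):
            drag_coefficients(1e-6, 0.9e-6, 1e-3)


class TestFlowTorque:
    def test_zeros_at_alignment(self, rod):
        assert flow_torque(0.0, 1e-4, rod, 1e-3) == 0.0
        assert flow_torque(np.pi, 1e-4, rod, 1e-3) == pytest.approx(0.0, abs=1e-30)

    def test_maximal_lever_arm(self):
        rod = RodParams(length_m=5e-6, alpha=2.0, gamma=1e-20)
        m = flow_torque(np.pi / 2, 1e-4, rod, 1e-3)
        assert m == pytest.approx(-0.5 * 2.0 * 1e-3 * 1e-4 * (5e-6) ** 2)
        assert m == pytest.approx(-1.25e-18, rel=1e-6)

    def test_odd_in_phi(self, rod):
        phi = np.linspace(-3, 3, 13)
        np.testing.assert_allclose(
            flow_torque(phi, 2e-4, rod, 1e-3),
            -np.asarray(flow_torque(-phi, 2e-4, rod, 1e-3)),
            rtol=1e-12,
        )


class TestStationaryDensity:
    def test_uniform_at_zero_kappa(self):
        phi = np.linspace(-np.pi, np.pi, 7)
        np.testing.assert_allclose(stationary_density(phi, 0.0), 1 / (2 * np.pi))

    def test_normalization(self):
        for kap in (0.0, 0.5, 2.0, 10.0):
            val, _ = integrate.quad(
                lambda p: stationary_density(p, kap), -np.pi, np.pi
            )
            assert val == pytest.approx(1.0, abs=1e-10)

    def test_mode_ratio(self):
        ratio = stationary_density(0.0, 2.0) / stationary_density(np.pi, 2.0)
        assert ratio == pytest.approx(np.exp(4.0), rel=1e-10)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            stationary_density(0.0, -1.0)


class TestSimulateTrajectory:
    def test_determinism(self, rod, env):
        t1 = simulate_trajectory(rod, env, 1e-5, 0.1, seed=42)
        t2 = simulate_trajectory(rod, env, 1e-5, 0.1, seed=42)
        np.testing.assert_array_equal(t1.phi_rad, t2.phi_rad)
        t3 = simulate_trajectory(rod, env, 1e-5, 0.1, seed=43)
        assert not np.array_equal(t1.phi_rad, t3.phi_rad)

    def test_trajectory_invariants(self, rod, env):
        tr = simulate_trajectory(rod, env, 1e-5, 0.2, seed=0, record_every=10)
        assert np.all(np.diff(tr.times_s) > 0)
        assert tr.phi_rad[0] == tr.phi0_rad

    def test_deterministic_relaxation_at_zero_temperature(self, rod):
        env0 = ThermalEnv(temperature_k=0.0)
        tr = simulate_trajectory(rod, env0, 1e-4, 0.05, seed=1, phi0_rad=0.5)
        assert np.all(np.diff(tr.phi_rad) < 0)
        assert abs(tr.phi_rad[-1]) < 0.05

    def test_stability_refusal(self, rod):
        bound = stability_bound_dt(rod, ThermalEnv(), 1e-3)
        env_bad = ThermalEnv(dt_s=bound * 2)
        with pytest.raises(StabilityError, match="safe"):
            simulate_trajectory(rod, env_bad, 1e-3, 0.01, seed=0)

    def test_free_diffusion_variance(self, rod, env):
        """At U=0 the unwrapped angle diffuses with Var = 2(k_BT/γ)t."""
        d = rotational_diffusion(rod, env)
        lag = 1.0
        trajs = sample_population(
            10_000, rod, env, 0.0, np.array([0.0, lag]), seed=11
        )
        incr = np.array([t.phi_rad[-1] - t.phi_rad[0] for t in trajs])
        assert incr.var() == pytest.approx(2 * d * lag, rel=0.03)


class TestStationaryConvergence:
    def _stationary_samples(self, rod, kap, n_chains, n_per, seed):
        env = ThermalEnv()
        u = speed_for_kappa(rod, env, kap)
        d = rotational_diffusion(rod, env)
        dt = 0.02 / (d * max(1.0, kap))
        dt = min(dt, 0.5 * stability_bound_dt(rod, env, u))
        env = ThermalEnv(dt_s=dt)
        tm = mixing_time(rod, env, u)
        times = np.arange(n_per + 1) * 10 * tm
        trajs = sample_population(
            n_chains, rod, env, u, times, seed, equilibrate=True
        )
        return np.concatenate([wrap_angle(t.phi_rad) for t in trajs])

    def test_matches_von_mises(self, rod):
        """Long-run wrapped ϕ follows the Boltzmann/von Mises law (FDT noise)."""
        samples = self._stationary_samples(rod, 2.0, 400, 60, seed=5)
        ks = stats.kstest(samples, stats.vonmises(2.0).cdf).statistic
        assert ks < 0.02

    def test_as_printed_noise_runs_cold(self, rod):
        """The halved noise variance concentrates like von Mises(2κ)."""
        env = ThermalEnv()
        u = speed_for_kappa(rod, env, 1.0)
        d = rotational_diffusion(rod, env)
        env = ThermalEnv(dt_s=0.02 / d)
        tm = mixing_time(rod, env, u)
        times = np.arange(41) * 10 * tm
        trajs = sample_population(
            300, rod, env, u, times, seed=7,
            noise_convention="as_printed", equilibrate=True,
        )
        samples = np.concatenate([wrap_angle(t.phi_rad) for t in trajs])
        ks2 = stats.kstest(samples, stats.vonmises(2.0).cdf).statistic
        ks1 = stats.kstest(samples, stats.vonmises(1.0).cdf).statistic
        assert ks2 < 0.03 < ks1

    def test_reversed_flow_moves_mode_to_pi(self, rod):
        env = ThermalEnv()
        u = speed_for_kappa(rod, env, 5.0)
        d = rotational_diffusion(rod, env)
        env = ThermalEnv(dt_s=0.02 / (5 * d))
        tm = mixing_time(rod, env, u)
        times = np.arange(21) * 10 * tm
        trajs = sample_population(200, rod, env, -u, times, seed=9, equilibrate=True)
        samples = np.concatenate([wrap_angle(t.phi_rad) for t in trajs])
        assert np.mean(np.cos(samples)) < -0.8  # concentrated around ϕ=π


class TestSamplePopulation:
    def test_initial_angles_uniform(self, rod, env):
        trajs = sample_population(
            10_000, rod, env, 0.0, np.array([0.0, 0.001]), seed=3
        )
        phi0 = np.array([t.meta["phi0_drawn"] for t in trajs])
        counts, _ = np.histogram(phi0, bins=20, range=(-np.pi, np.pi))
        chi2 = ((counts - 500.0) ** 2 / 500.0).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=19)

    def test_determinism(self, rod, env):
        a = sample_population(5, rod, env, 1e-5, np.arange(4) * 0.1, seed=21)
        b = sample_population(5, rod, env, 1e-5, np.arange(4) * 0.1, seed=21)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.phi_rad, tb.phi_rad)

    def test_kappa_speed_round_trip(self, rod, env):
        u = speed_for_kappa(rod, env, 3.7)
        assert kappa(rod, env, u) == pytest.approx(3.7, rel=1e-12)


class TestTrajectoryIO:
    def test_csv_round_trip_bit_exact(self, rod, env, tmp_path):
        tr = simulate_trajectory(rod, env, 1e-5, 0.05, seed=13, record_every=5)
        path = tmp_path / "traj.csv"
        tr.to_csv(path)
        back = AngleTrajectory.from_csv(path)
        np.testing.assert_array_equal(tr.phi_rad, back.phi_rad)
        np.testing.assert_array_equal(tr.times_s, back.times_s)
        assert back.meta["noise_convention"] == "fdt"

    def test_rejects_nonincreasing_times(self):
        with pytest.raises(ValueError, match="increasing"):
            AngleTrajectory(np.array([0.0, 0.0]), np.array([0.1, 0.2]), 0.1)


class TestSphericalExtension:
    def test_zero_flow_samples_hemisphere(self, rod, env):
        """Without drive the polar angle equilibrates to density ∝ sinθ
        (mean θ = 1 rad on the quarter-sphere)."""
        d = rotational_diffusion(rod, env)
        env2 = ThermalEnv(dt_s=min(1e-3 / d, 1e-2))
        st_ = simulate_spherical(rod, env2, 0.0, 60.0, seed=2, record_every=20)
        burn = st_.theta_rad.size // 5
        assert st_.theta_rad[burn:].mean() == pytest.approx(1.0, abs=0.1)

    def test_strong_flow_flattens_rod(self, rod, env):
        """At strong drive θ stays near π/2: the planar reduction holds at
        κ≈30 (expected offset √(2/πκ) ≈ 0.15); at κ=10 the offset is ≈0.25."""
        d = rotational_diffusion(rod, env)
        for kap, bound in ((30.0, 0.15), (10.0, 0.32)):
            u = speed_for_kappa(rod, env, kap)
            dt = 0.01 / (d * kap)
            st_ = simulate_spherical(
                rod, ThermalEnv(dt_s=dt), u, 3000 * dt * 20, seed=4, record_every=20
            )
            burn = st_.theta_rad.size // 5
            mean_off = np.pi / 2 - st_.theta_rad[burn:].mean()
            assert 0 < mean_off < bound

    def test_phi_marginal_near_von_mises(self, rod, env):
        d = rotational_diffusion(rod, env)
        kap = 10.0
        u = speed_for_kappa(rod, env, kap)
        dt = 0.01 / (d * kap)
        st_ = simulate_spherical(
            rod, ThermalEnv(dt_s=dt), u, 20000 * dt * 10, seed=6, record_every=10
        )
        burn = st_.phi_rad.size // 5
        phi = wrap_angle(st_.phi_rad[burn:])
        kap_eff = kap * float(np.sin(st_.theta_rad[burn:]).mean())
        ks = stats.kstest(phi, stats.vonmises(kap_eff).cdf).statistic
        assert ks < 0.05
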