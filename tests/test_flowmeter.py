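"""Total-rotation-angle statistic, calibration curve, shear inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from windsock.flowmeter import (
    STUDY_PROTOCOL,
    CalibrationCurve,
    CoverageError,
    SamplingProtocol,
    build_calibration,
    circular_range_deg,
    estimate_shear,
    population_stat,
    total_angle,
)
from windsock.rod import AngleTrajectory


def brute_force_circular_range(angles_deg):
    """Independent oracle: cut the circle at each sample and take the
    smallest resulting linear span."""
    a = np.mod(np.asarray(angles_deg, dtype=float), 360.0)
    best = 360.0
    for cut in a:
        shifted = np.mod(a - cut, 360.0)
        best = min(best, float(shifted.max() - shifted.min()))
    return best


def make_traj(phi_deg, interval_s=5.0):
    phi_deg = np.asarray(phi_deg, dtype=float)
    times = np.arange(phi_deg.size) * interval_s
    return AngleTrajectory(times, np.radians(phi_deg), float(np.radians(phi_deg[0])))


class TestCircularRange:
    def test_single_and_constant(self):
        assert circular_range_deg(np.array([1.3])) == 0.0
        assert circular_range_deg(np.full(30, 0.7)) == pytest.approx(0.0, abs=1e-9)

    def test_quarter_points(self):
        phi = np.radians([0.0, 90.0, 180.0, 270.0])
        assert circular_range_deg(phi) == pytest.approx(270.0)
        assert brute_force_circular_range([0, 90, 180, 270]) == pytest.approx(270.0)

    def test_dense_circle_caps_at_360(self):
        phi = np.radians(np.linspace(0, 359.9, 720))
        assert circular_range_deg(phi) == pytest.approx(360.0, abs=0.6)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=720.0), min_size=1, max_size=40)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force(self, angles_deg):
        got = circular_range_deg(np.radians(angles_deg))
        expect = brute_force_circular_range(angles_deg)
        assert got == pytest.approx(expect, abs=1e-8)


class TestTotalAngle:
    def test_set_statistic_invariances(self):
        rng = np.random.default_rng(0)
        phi = rng.uniform(0, 200, size=30)
        base = total_angle(make_traj(phi))
        # time-order permutation
        assert total_angle(make_traj(rng.permutation(phi))) == pytest.approx(base)
        # global rotation
        assert total_angle(make_traj(phi + 123.4)) == pytest.approx(base, abs=1e-8)

    def test_coverage_error(self):
        short = make_traj(np.zeros(10))  # 45 s < 145 s protocol span
        with pytest.raises(CoverageError):
            total_angle(short, STUDY_PROTOCOL)

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            SamplingProtocol(n_frames=1)
        with pytest.raises(ValueError):
            SamplingProtocol(interval_s=0)


@pytest.fixture(scope="module")
def small_curve(rod, env, glass_channel):
    grid = np.array([0.05, 0.4, 2.0])
    return build_calibration(grid, 15, rod, env, glass_channel, STUDY_PROTOCOL, seed=42)


@pytest.fixture(scope="module")
def curve(rod, env, glass_channel):
    grid = np.array([0.05, 0.1, 0.2, 0.4, 0.8, 1.6])
    return build_calibration(grid, 200, rod, env, glass_channel, STUDY_PROTOCOL, seed=7)


class TestCalibration:
    def test_determinism(self, rod, env, glass_channel, small_curve):
        again = build_calibration(
            np.array([0.05, 0.4, 2.0]), 15, rod, env, glass_channel,
            STUDY_PROTOCOL, seed=42,
        )
        np.testing.assert_array_equal(small_curve.phi_rods_deg, again.phi_rods_deg)

    def test_monotone_decreasing(self, small_curve):
        assert np.all(np.diff(small_curve.phi_mean_deg) < 0)

    def test_phi_bounds(self, small_curve):
        assert np.all(small_curve.phi_rods_deg >= 0)
        assert np.all(small_curve.phi_rods_deg <= 360)

    def test_grid_validation(self, rod, env, glass_channel):
        with pytest.raises(ValueError, match="increasing"):
            build_calibration(
                np.array([0.4, 0.1]), 5, rod, env, glass_channel,
                STUDY_PROTOCOL, seed=0,
            )

    def test_length_heterogeneity_widens_spread(self, rod, env, glass_channel):
        """Drawing rod lengths from a 30%-CV lognormal inflates the per-rod
        Φ spread (κ ∝ ℓ²) without breaking the overall trend."""
        grid = np.array([0.1, 1.6])
        fixed = build_calibration(
            grid, 40, rod, env, glass_channel, STUDY_PROTOCOL, seed=3
        )
        hetero = build_calibration(
            grid, 40, rod, env, glass_channel, STUDY_PROTOCOL, seed=3, length_cv=0.3
        )
        assert hetero.phi_sd_deg[0] > fixed.phi_sd_deg[0]
        assert np.all(np.diff(hetero.phi_mean_deg) < 0)
        assert hetero.params["length_cv"] == 0.3

    def test_csv_round_trip(self, small_curve, tmp_path):
        path = tmp_path / "cal.csv"
        small_curve.to_csv(path)
        back = CalibrationCurve.from_csv(path)
        np.testing.assert_array_equal(back.phi_rods_deg, small_curve.phi_rods_deg)
        np.testing.assert_array_equal(back.stress_dyn_cm2, small_curve.stress_dyn_cm2)
        assert back.params["seed"] == 42


class TestEstimateShear:
    def test_grid_point_identity(self, curve):
        """Reading back a grid-point mean recovers that grid stress."""
        i = 3
        est = estimate_shear(float(curve.phi_mean_deg[i]), curve.n_rods, curve, seed=1)
        assert est.tau_dyn_cm2 == pytest.approx(curve.stress_dyn_cm2[i], rel=0.15)
        assert est.ci_low <= curve.stress_dyn_cm2[i] <= est.ci_high

    def test_saturation_flag(self, curve):
        est = estimate_shear(360.0, 15, curve, seed=2)
        assert est.saturated
        assert est.tau_dyn_cm2 == pytest.approx(curve.stress_dyn_cm2[0])
        est_hi = estimate_shear(0.0, 15, curve, seed=3)
        assert est_hi.saturated
        assert est_hi.tau_dyn_cm2 == pytest.approx(curve.stress_dyn_cm2[-1])

    def test_ci_ordering(self, curve):
        est = estimate_shear(float(curve.phi_mean_deg[2]), 15, curve, seed=4)
        assert est.ci_low <= est.tau_dyn_cm2 <= est.ci_high


def test_population_stat_matches_t_interval():
    phi = np.array([100.0, 110.0, 120.0, 130.0])
    s = population_stat(phi)
    assert s.mean_deg == pytest.approx(115.0)
    from scipy import stats as sps

    half = sps.t.ppf(0.975, 3) * phi.std(ddof=1) / 2.0
    assert s.ci95_halfwidth_deg == pytest.approx(half)
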