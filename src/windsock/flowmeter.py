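"""The total-rotation-angle ("windsock") statistic and its calibration.

A surface-anchored filament imaged every few seconds sweeps an angular
range that shrinks as flow aligns it: Φ is defined as the *circular range*
of the sampled orientations — 360° minus the largest angular gap between
consecutive sorted wrapped samples — matching the angular extent read off a
maximum time projection.  Φ is a set statistic: invariant to global
rotation of all samples and to their time order, and capped at 360°.

``build_calibration`` simulates rod populations over a shear-stress grid to
produce the mean-Φ̄ vs τ calibration curve; ``estimate_shear`` inverts an
observed Φ̄ through the isotonically smoothed curve and attaches a
test-inversion confidence interval built from bootstrap quantiles of the
per-stress rod populations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from . import channels as ch
from . import rod as rodmod
from .units import DYN_CM2_TO_PA

__all__ = [
    "SamplingProtocol",
    "STUDY_PROTOCOL",
    "WindsockStat",
    "CalibrationCurve",
    "ShearEstimate",
    "CoverageError",
    "total_angle",
    "circular_range_deg",
    "population_stat",
    "build_calibration",
    "estimate_shear",
]


class CoverageError(ValueError):
    """Trajectory does not cover the sampling protocol."""


@dataclass(frozen=True)
class SamplingProtocol:
    """Imaging protocol: ``n_frames`` frames, one every ``interval_s``."""

    n_frames: int = 30
    interval_s: float = 5.0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least two frames")
        if self.interval_s <= 0:
            raise ValueError("frame interval must be positive")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.interval_s

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) * self.interval_s


#: 30 frames taken every 5 s.
STUDY_PROTOCOL = SamplingProtocol(n_frames=30, interval_s=5.0)


def circular_range_deg(angles_rad: np.ndarray) -> float:
    """Smallest arc (degrees) containing all angles; 0 for a single point.

    Equals 360° minus the largest gap between consecutive sorted wrapped
    angles (including the wrap-around gap); capped at 360°.
    """
    a = np.sort(np.mod(np.asarray(angles_rad, dtype=float), 2.0 * np.pi))
    if a.size == 0:
        raise ValueError("need at least one angle")
    if a.size == 1:
        return 0.0
    gaps = np.diff(a)
    wrap_gap = a[0] + 2.0 * np.pi - a[-1]
    largest = max(float(gaps.max()), float(wrap_gap))
    return float(np.degrees(2.0 * np.pi - largest))


def total_angle(
    trajectory: rodmod.AngleTrajectory,
    protocol: SamplingProtocol = STUDY_PROTOCOL,
) -> float:
    """Φ (degrees, [0, 360]): circular range of the protocol-sampled angles."""
    try:
        phi = trajectory.phi_at(protocol.times_s)
    except ValueError as exc:
        raise CoverageError(str(exc)) from exc
    return circular_range_deg(phi)


@dataclass(frozen=True)
class WindsockStat:
    """Population summary of Φ over rods (mean, sd, t-based 95% CI)."""

    phi_deg: np.ndarray
    mean_deg: float
    sd_deg: float
    ci95_halfwidth_deg: float


def population_stat(phi_deg: np.ndarray) -> WindsockStat:
    phi = np.asarray(phi_deg, dtype=float)
    n = phi.size
    mean = float(phi.mean())
    sd = float(phi.std(ddof=1)) if n > 1 else 0.0
    half = (
        float(stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)) if n > 1 and sd > 0 else 0.0
    )
    return WindsockStat(phi_deg=phi, mean_deg=mean, sd_deg=sd, ci95_halfwidth_deg=half)


@dataclass
class CalibrationCurve:
    """Mean Φ̄ vs wall shear stress, with the per-rod Φ samples retained."""

    stress_dyn_cm2: np.ndarray
    phi_mean_deg: np.ndarray
    phi_sd_deg: np.ndarray
    ci95_halfwidth_deg: np.ndarray
    phi_rods_deg: np.ndarray  # shape (n_stress, n_rods)
    n_rods: int
    params: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        path = Path(path)
        pd.DataFrame(
            {
                "shear_dyn_cm2": self.stress_dyn_cm2,
                "phi_mean_deg": self.phi_mean_deg,
                "phi_sd_deg": self.phi_sd_deg,
                "phi_ci95_deg": self.ci95_halfwidth_deg,
                "n_rods": self.n_rods,
            }
        ).to_csv(path, index=False, float_format="%.17g")
        rods = path.with_name(path.stem + "_rods.csv")
        pd.DataFrame(
            self.phi_rods_deg,
            index=pd.Index(self.stress_dyn_cm2, name="shear_dyn_cm2"),
        ).to_csv(rods, float_format="%.17g")
        if sidecar:
            path.with_suffix(".json").write_text(json.dumps(self.params, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "CalibrationCurve":
        path = Path(path)
        df = pd.read_csv(path, float_precision="round_trip")
        rods_path = path.with_name(path.stem + "_rods.csv")
        rods = pd.read_csv(rods_path, index_col=0, float_precision="round_trip").to_numpy()
        sidecar = path.with_suffix(".json")
        params = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(
            stress_dyn_cm2=df["shear_dyn_cm2"].to_numpy(),
            phi_mean_deg=df["phi_mean_deg"].to_numpy(),
            phi_sd_deg=df["phi_sd_deg"].to_numpy(),
            ci95_halfwidth_deg=df["phi_ci95_deg"].to_numpy(),
            phi_rods_deg=rods,
            n_rods=rods.shape[1],
            params=params,
        )


def _phi_population(
    stress_dyn_cm2: float,
    n_rods: int,
    rod: rodmod.RodParams,
    env: rodmod.ThermalEnv,
    geom: ch.ChannelGeometry,
    protocol: SamplingProtocol,
    seed: int,
    *,
    mu_pa_s: float | None = None,
    noise_sd_deg: float = 0.0,
    length_cv: float = 0.0,
) -> np.ndarray:
    """Per-rod Φ (deg) for one shear stress; simulation + optional angular noise.

    ``length_cv > 0`` draws each rod's length from a lognormal with the
    given coefficient of variation around the nominal ℓ (sensitivity knob
    for the length heterogeneity of real filament preparations).
    """
    mu = env.viscosity_pa_s if mu_pa_s is None else mu_pa_s
    q = ch.shear_to_flow(geom, stress_dyn_cm2 * DYN_CM2_TO_PA, mu)
    speed = ch.mean_velocity(geom, q)
    if length_cv > 0:
        len_rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1E0]))
        sigma = np.sqrt(np.log1p(length_cv**2))
        lengths = rod.length_m * len_rng.lognormal(-0.5 * sigma**2, sigma, n_rods)
        trajs = []
        for k, ell in enumerate(lengths):
            rod_k = rodmod.RodParams(
                length_m=float(ell),
                diameter_m=rod.diameter_m,
                persistence_length_m=rod.persistence_length_m,
            )
            trajs.extend(
                rodmod.sample_population(
                    1, rod_k, env, speed, protocol.times_s,
                    int(np.random.SeedSequence([seed, 0x1E1, k]).generate_state(1)[0]
                        % (2**31)),
                    equilibrate=True,
                )
            )
    else:
        trajs = rodmod.sample_population(
            n_rods, rod, env, speed, protocol.times_s, seed, equilibrate=True
        )
    phi = np.stack([tr.phi_rad for tr in trajs], axis=1)  # (frames, rods)
    if noise_sd_deg > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA26]))
        phi = phi + np.radians(noise_sd_deg) * rng.standard_normal(phi.shape)
    return np.array([circular_range_deg(phi[:, k]) for k in range(n_rods)])


def build_calibration(
    stress_grid_dyn_cm2: np.ndarray,
    n_rods: int,
    rod: rodmod.RodParams,
    env: rodmod.ThermalEnv,
    geom: ch.ChannelGeometry,
    protocol: SamplingProtocol,
    seed: int,
    *,
    mu_pa_s: float | None = None,
    noise_sd_deg: float = 0.0,
    length_cv: float = 0.0,
) -> CalibrationCurve:
    """Simulate ``n_rods`` rods per grid stress and summarise Φ.

    The grid must be non-negative and strictly increasing.  Deterministic
    for a fixed seed (independent substream per stress).  ``length_cv``
    adds lognormal rod-length heterogeneity (default: fixed length).
    """
    grid = np.asarray(stress_grid_dyn_cm2, dtype=float)
    if np.any(grid < 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("stress grid must be non-negative and strictly increasing")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(grid.size)
    phi_rods = np.empty((grid.size, n_rods))
    for i, tau in enumerate(grid):
        phi_rods[i] = _phi_population(
            tau,
            n_rods,
            rod,
            env,
            geom,
            protocol,
            int(children[i].generate_state(1)[0] % (2**31)),
            mu_pa_s=mu_pa_s,
            noise_sd_deg=noise_sd_deg,
            length_cv=length_cv,
        )
    summaries = [population_stat(phi_rods[i]) for i in range(grid.size)]
    return CalibrationCurve(
        stress_dyn_cm2=grid,
        phi_mean_deg=np.array([s.mean_deg for s in summaries]),
        phi_sd_deg=np.array([s.sd_deg for s in summaries]),
        ci95_halfwidth_deg=np.array([s.ci95_halfwidth_deg for s in summaries]),
        phi_rods_deg=phi_rods,
        n_rods=n_rods,
        params={
            "seed": seed,
            "n_rods": n_rods,
            "protocol": {"n_frames": protocol.n_frames, "interval_s": protocol.interval_s},
            "rod": {"length_m": rod.length_m, "diameter_m": rod.diameter_m},
            "env": {
                "temperature_k": env.temperature_k,
                "viscosity_pa_s": env.viscosity_pa_s,
            },
            "geometry": {"height_m": geom.height_m, "width_m": geom.width_m},
            "noise_sd_deg": noise_sd_deg,
            "length_cv": length_cv,
        },
    )


@dataclass(frozen=True)
class ShearEstimate:
    """Inverted shear-stress reading with a 95% confidence interval."""

    tau_dyn_cm2: float
    ci_low: float
    ci_high: float
    saturated: bool


def _monotone_decreasing(grid: np.ndarray, y: np.ndarray) -> np.ndarray:
    iso = IsotonicRegression(increasing=False)
    return iso.fit_transform(grid, y)


def _invert_decreasing(grid: np.ndarray, y: np.ndarray, target: float) -> float:
    """τ where the decreasing curve y(τ) crosses ``target`` (clamped)."""
    # reverse so x is increasing for np.interp
    return float(np.interp(target, y[::-1], grid[::-1]))


def estimate_shear(
    phi_mean_deg: float,
    n_observed: int,
    curve: CalibrationCurve,
    *,
    n_boot: int = 1000,
    seed: int = 0,
) -> ShearEstimate:
    """Estimate shear stress from an observed mean Φ̄ over ``n_observed`` rods.

    The point estimate inverts the isotonically smoothed (decreasing)
    calibration curve.  The CI inverts a bootstrap acceptance band: for each
    grid stress, the 2.5/97.5% quantiles of the mean of ``n_observed`` Φ
    values resampled from that stress's simulated rods are computed; the CI
    is the set of stresses whose band contains Φ̄.  Readings beyond the
    curve's dynamic range are clamped and flagged ``saturated``.
    """
    if not np.isfinite(phi_mean_deg):
        raise ValueError("observed mean must be finite")
    if n_observed < 1:
        raise ValueError("n_observed must be >= 1")
    grid = curve.stress_dyn_cm2
    mean_smooth = _monotone_decreasing(grid, curve.phi_mean_deg)

    rng = np.random.default_rng(seed)
    lo = np.empty(grid.size)
    hi = np.empty(grid.size)
    for i in range(grid.size):
        idx = rng.integers(0, curve.n_rods, size=(n_boot, n_observed))
        boot_means = curve.phi_rods_deg[i][idx].mean(axis=1)
        lo[i], hi[i] = np.quantile(boot_means, [0.025, 0.975])
    lo = _monotone_decreasing(grid, lo)
    hi = _monotone_decreasing(grid, hi)

    saturated = bool(
        phi_mean_deg >= mean_smooth[0] or phi_mean_deg <= mean_smooth[-1]
    )
    tau_hat = _invert_decreasing(grid, mean_smooth, phi_mean_deg)
    # Φ̄ >= lo(τ) ⇔ τ <= lo⁻¹(Φ̄);  Φ̄ <= hi(τ) ⇔ τ >= hi⁻¹(Φ̄)
    ci_high = _invert_decreasing(grid, lo, phi_mean_deg)
    ci_low = _invert_decreasing(grid, hi, phi_mean_deg)
    ci_low, ci_high = min(ci_low, ci_high), max(ci_low, ci_high)
    ci_low = min(ci_low, tau_hat)
    ci_high = max(ci_high, tau_hat)
    return ShearEstimate(
        tau_dyn_cm2=tau_hat, ci_low=ci_low, ci_high=ci_high, saturated=saturated
    )
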