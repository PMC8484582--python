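"""End-to-end validation experiments.

Each function runs one self-contained numerical experiment on synthetic
data — the quantities a user would check before trusting the package on
real measurements — and returns plain numbers.  They are driven both by
the statistical test suite and by ``scripts/acceptance.py``.

Problem sizes (documented in docs/methods.md): 10⁵ stationary samples per
concentration, 200 decay replicates, 100 inversion replicates, 15-rod
populations under the 30-frame/5-s protocol.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import channels as ch
from . import flowmeter as fm
from . import imaging
from . import kinetics as kin
from . import rod as rodmod
from . import synth
from .coloc import (
    Mask,
    PointPattern,
    coloc_fraction,
    poisson_coloc_fraction,
    randomized_null,
)
from .units import DYN_CM2_TO_PA, ML_MIN_TO_M3_S

__all__ = [
    "operating_point_shear",
    "decay_recovery",
    "stationary_ks",
    "windsock_curve",
    "zero_flow_phi",
    "inversion_coverage",
    "coloc_closed_form",
    "coloc_p_uniformity",
    "spytag_rate",
    "image_pipeline_agreement",
]


def _child_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31))


def operating_point_shear() -> float:
    """Wall shear stress (dyn/cm²) at the published cell-channel operating
    point: 0.18 mL/min in the µ-slide VI 0.4 with water-like viscosity."""
    geom = ch.get_channel("ibidi_VI_0.4")
    return ch.wall_shear_stress_dyn_cm2(geom, 0.18 * ML_MIN_TO_M3_S, 1.0e-3)


def decay_recovery(
    which: str, n_replicates: int = 200, seed: int = 0
) -> dict[str, float]:
    """CI coverage of the persistence decay rate over stochastic replicates.

    Generates per-cell series from the fitted decay parameters (seeds:
    b=3.3 h⁻¹ over 70 min at 10-min sampling; nanotubes: b=0.52 h⁻¹ at
    15-min sampling), fits the pooled single-exponential, and counts how
    often the fit's 95% CI contains the generating rate.
    """
    pars = synth.STUDY_PRESETS["decay"][which]
    grid = np.array(synth.STUDY_PRESETS[f"decay_time_grid_{which}_h"])
    n_cells = synth.STUDY_PRESETS["decay_n_cells"]
    noise = synth.STUDY_PRESETS["decay_noise_sd"]
    b_true = pars["b_per_h"]
    covered = 0
    b_hats = []
    for rep in range(n_replicates):
        series = synth.gen_decay_dataset(
            pars["a"], b_true, grid, noise, n_cells, seed=_child_seed(seed, rep)
        )
        fit = kin.fit_decay(kin.DecaySeries.concat(series))
        b_hats.append(fit.b_per_h)
        if fit.b_ci95[0] <= b_true <= fit.b_ci95[1]:
            covered += 1
    return {
        "coverage": covered / n_replicates,
        "b_mean": float(np.mean(b_hats)),
        "b_true": b_true,
        "n": n_replicates,
    }


def stationary_ks(
    kappa_value: float,
    n_samples: int = 100_000,
    seed: int = 0,
    n_chains: int = 1000,
) -> float:
    """KS distance between long-run wrapped ϕ and the von Mises(κ) law.

    Samples are taken from many independent chains at spacings of ten
    mixing times, after equilibration, so they are effectively independent
    draws from the stationary distribution.
    """
    rod = rodmod.RodParams()
    env0 = rodmod.ThermalEnv()
    d = rodmod.rotational_diffusion(rod, env0)
    u = rodmod.speed_for_kappa(rod, env0, kappa_value)
    # step small enough that the Euler discretisation bias is far below the
    # 0.02 KS budget; at zero drive any step integrates pure diffusion exactly
    if kappa_value > 0:
        dt = min(
            0.02 / (d * max(1.0, kappa_value)),
            0.5 * rodmod.stability_bound_dt(rod, env0, u),
        )
    else:
        dt = 0.05
    env = rodmod.ThermalEnv(dt_s=dt)
    tm = rodmod.mixing_time(rod, env, u)
    n_per = int(np.ceil(n_samples / n_chains))
    times = np.arange(n_per) * 10.0 * tm if n_per > 1 else np.array([0.0])
    trajs = rodmod.sample_population(
        n_chains, rod, env, u, times, _child_seed(seed, int(kappa_value * 1000)),
        equilibrate=True,
    )
    samples = np.concatenate([rodmod.wrap_angle(t.phi_rad) for t in trajs])
    samples = samples[:n_samples]
    if kappa_value == 0:
        cdf = stats.uniform(loc=-np.pi, scale=2 * np.pi).cdf
    else:
        cdf = stats.vonmises(kappa_value).cdf
    return float(stats.kstest(samples, cdf).statistic)


def windsock_curve(
    seed: int = 0,
    stress_grid=None,
    n_rods: int | None = None,
) -> fm.CalibrationCurve:
    """Mean-Φ calibration over the published shear grid, 15 rods each."""
    grid = np.array(
        stress_grid
        if stress_grid is not None
        else synth.STUDY_PRESETS["shear_grid_phi_dyn_cm2"]
    )
    n_rods = n_rods or synth.STUDY_PRESETS["n_rods_per_stress"]
    rod = rodmod.RodParams()
    env = rodmod.ThermalEnv()
    geom = ch.get_channel("ibidi_VI_0.5")
    return fm.build_calibration(
        grid, n_rods, rod, env, geom, fm.STUDY_PROTOCOL, seed=_child_seed(seed, 0x10)
    )


def zero_flow_phi(seed: int = 0, n_frames: int = 300, n_rods: int = 15) -> float:
    """Mean Φ (deg) of unloaded rods over a long imaging protocol.

    Free rotational diffusion explores all azimuths, so with enough frames
    the swept range approaches the full circle.  Pure diffusion is
    integrated exactly by the Euler scheme at any step, so a coarse 50 ms
    step is used.
    """
    rod = rodmod.RodParams()
    env = rodmod.ThermalEnv(dt_s=0.05)
    protocol = fm.SamplingProtocol(n_frames=n_frames, interval_s=5.0)
    trajs = rodmod.sample_population(
        n_rods, rod, env, 0.0, protocol.times_s, _child_seed(seed, 0x20)
    )
    phis = [fm.total_angle(t, protocol) for t in trajs]
    return float(np.mean(phis))


def inversion_coverage(
    n_replicates: int = 100,
    tau_true: float = 0.4,
    n_observed: int = 15,
    seed: int = 0,
) -> dict[str, float]:
    """Coverage of the flow-meter's 95% CI at a known shear stress.

    Builds a 500-rod calibration curve, then repeatedly simulates fresh
    15-rod readings at ``tau_true`` and checks whether the inverted CI
    contains the truth.
    """
    rod = rodmod.RodParams()
    env = rodmod.ThermalEnv()
    geom = ch.get_channel("ibidi_VI_0.5")
    grid = np.array([0.05, 0.1, 0.2, 0.3, 0.4, 0.6, 0.8, 1.2, 1.6, 2.0])
    curve = fm.build_calibration(
        grid, 500, rod, env, geom, fm.STUDY_PROTOCOL, seed=_child_seed(seed, 0x30)
    )
    covered = 0
    for rep in range(n_replicates):
        phi = fm._phi_population(
            tau_true, n_observed, rod, env, geom, fm.STUDY_PROTOCOL,
            _child_seed(seed, 0x31000 + rep),
        )
        est = fm.estimate_shear(
            float(phi.mean()), n_observed, curve, seed=_child_seed(seed, 0x32000 + rep)
        )
        if est.ci_low <= tau_true <= est.ci_high:
            covered += 1
    return {"coverage": covered / n_replicates, "n": n_replicates}


def coloc_closed_form(
    seed: int = 0,
    intensity_per_um2: float = 2.0,
    radius_um: float = 0.5,
    n_seeds: int = 10_000,
    side_um: float = 100.0,
    n_perm: int = 200,
) -> dict[str, float]:
    """Observed and null colocalized fractions against 1-exp(-λπr²).

    Antibodies form a Poisson pattern over the full square; the observed
    seeds are kept ≥r from the border so no disc is clipped and the void
    formula is exact.  The randomized null redraws seeds over the whole
    mask (the boundary band is ~2% of the area, a sub-percent effect).
    """
    rng = np.random.default_rng(_child_seed(seed, 0x40))
    expected = poisson_coloc_fraction(intensity_per_um2, radius_um)
    n_ab = rng.poisson(intensity_per_um2 * side_um**2)
    ab_xy = rng.uniform(0, side_um, size=(n_ab, 2))
    seed_xy = rng.uniform(radius_um, side_um - radius_um, size=(n_seeds, 2))
    observed = coloc_fraction(seed_xy, ab_xy, radius_um)

    px = 0.5
    mask = Mask(np.ones((int(side_um / px), int(side_um / px)), bool), px)
    res = randomized_null(
        PointPattern(seed_xy, mask=mask),
        PointPattern(ab_xy % side_um, mask=mask),
        radius_um,
        n_perm=n_perm,
        seed=_child_seed(seed, 0x41),
    )
    return {
        "expected": expected,
        "observed": observed,
        "null_mean": res.null_mean,
        "observed_rel_err": abs(observed - expected) / expected,
        "null_rel_err": abs(res.null_mean - expected) / expected,
        "n": n_seeds,
    }


def coloc_p_uniformity(
    seed: int = 0, n_replicates: int = 100, n_perm: int = 100
) -> dict[str, float]:
    """KS test of permutation p-values against Uniform(0, 1) under the null."""
    mask = Mask.ellipse()
    rng = np.random.default_rng(_child_seed(seed, 0x50))
    ab = PointPattern(mask.sample_uniform(90, rng), mask=mask)
    pvals = []
    for rep in range(n_replicates):
        seeds = PointPattern(mask.sample_uniform(150, rng), mask=mask)
        res = randomized_null(
            seeds, ab, 0.5, n_perm=n_perm, seed=_child_seed(seed, 0x51000 + rep)
        )
        pvals.append(res.p_value)
    ks = stats.kstest(pvals, "uniform")
    return {"ks_stat": float(ks.statistic), "ks_pvalue": float(ks.pvalue),
            "n": n_replicates}


def spytag_rate() -> float:
    """Attachment rate (per cell per hour) for the SpyTag scenario."""
    return kin.attachment_rate(synth.spytag_step())


def image_pipeline_agreement(
    seed: int = 0, kappas=(0.5, 2.0, 10.0), n_rods: int = 5
) -> dict[str, float]:
    """Worst disagreement (deg) between image-measured and trajectory Φ.

    Renders 30-frame stacks at peak SNR ≈ 5.8, runs the blur → maximum
    time projection → angular-extent pipeline, and compares with the
    trajectory statistic rod by rod.
    """
    rod = rodmod.RodParams()
    env0 = rodmod.ThermalEnv()
    d = rodmod.rotational_diffusion(rod, env0)
    cfg = imaging.ImagingConfig(amplitude=200.0, background=100.0, noise_sd=30.0)
    diffs = []
    for kap in kappas:
        u = rodmod.speed_for_kappa(rod, env0, kap)
        dt = min(
            0.05 / (d * max(1.0, kap)),
            0.5 * rodmod.stability_bound_dt(rod, env0, u),
        )
        env = rodmod.ThermalEnv(dt_s=dt)
        trajs = rodmod.sample_population(
            n_rods, rod, env, u, fm.STUDY_PROTOCOL.times_s,
            _child_seed(seed, 0x60000 + int(kap * 10)), equilibrate=True,
        )
        for i, tr in enumerate(trajs):
            phi_tr = fm.total_angle(tr, fm.STUDY_PROTOCOL)
            stack = imaging.render_trajectory(
                tr, fm.STUDY_PROTOCOL, 5.0, cfg, seed=_child_seed(seed, 0x61000 + i)
            )
            phi_im = imaging.measure_angle_extent(
                imaging.max_time_projection(stack), cfg.anchor_px, 5.0
            )
            diffs.append(abs(phi_im - phi_tr))
    return {
        "max_abs_diff_deg": float(np.max(diffs)),
        "median_abs_diff_deg": float(np.median(diffs)),
        "snr": cfg.peak_snr,
        "n": len(diffs),
    }
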