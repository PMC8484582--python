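"""Synthetic datasets with the statistical structure the analyses assume.

Every generator is deterministic under a fixed seed, returns ground truth
alongside the observations, and can write its outputs plus a JSON manifest
of all parameters.  ``STUDY_PRESETS`` collects the study conditions used
throughout: channel geometries, the 30-frame/5-s imaging protocol, the
shear-stress grids, the surface-persistence decay parameters
(seeds: a=1.0, b=3.3 h⁻¹; seeded nanotubes: a=1.0, b=0.52 h⁻¹), the
SpyTag kinetic scenario, and the cohort sizes (12 cells, 15 rods per
stress, 6 cells per decay condition).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import rod as rodmod
from .coloc import Mask, PointPattern
from .flowmeter import STUDY_PROTOCOL, SamplingProtocol
from .kinetics import BindingStep, DecaySeries

__all__ = [
    "STUDY_PRESETS",
    "AngleDataset",
    "ColocDataset",
    "gen_angle_dataset",
    "gen_decay_dataset",
    "gen_coloc_dataset",
]


STUDY_PRESETS: dict = {
    "persistence_length_um": 8.7,
    "channels": {
        "ibidi_VI_0.4": {"height_mm": 0.4, "width_mm": 3.8, "length_mm": 17.0},
        "ibidi_VI_0.5": {"height_mm": 0.54, "width_mm": 3.8, "length_mm": 17.0},
    },
    "protocol": {"n_frames": 30, "interval_s": 5.0},
    "shear_grid_coarse_dyn_cm2": [0.0, 0.05, 0.2, 1.0],
    "shear_grid_fine_dyn_cm2": [0.0, 0.1, 0.4, 1.2, 1.6],
    "shear_grid_phi_dyn_cm2": [0.05, 0.1, 0.4, 1.2, 1.6, 2.0],
    "decay": {
        "seeds": {"a": 1.0, "b_per_h": 3.3},
        "nanotubes": {"a": 1.0, "b_per_h": 0.52},
    },
    # seeds were followed every 10 min over 70 min; nanotubes every 15 min
    # over a few hours (they persist ~1/0.52 h)
    "decay_time_grid_seeds_h": [i / 6.0 for i in range(8)],
    "decay_time_grid_nanotubes_h": [i * 0.25 for i in range(13)],
    "decay_n_cells": 6,
    "decay_noise_sd": 0.02,
    "spytag": {"k_on_m_s": 1400.0, "concentration_m": 64e-12, "receptors_per_cell": 1e4},
    "coloc": {"n_cells": 12, "true_fraction": 0.76, "radius_um": 0.5},
    "n_rods_per_stress": 15,
    "version": 1,
}


def spytag_step() -> BindingStep:
    s = STUDY_PRESETS["spytag"]
    return BindingStep(
        k_on_m_s=s["k_on_m_s"],
        concentration_m=s["concentration_m"],
        receptors_per_cell=s["receptors_per_cell"],
    )


def _write_manifest(out_dir: Path, name: str, params: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / f"{name}_manifest.json").write_text(json.dumps(params, indent=2))


@dataclass
class AngleDataset:
    """Ground-truth trajectories plus noisy frame-sampled angles."""

    trajectories: list[rodmod.AngleTrajectory]
    frame_times_s: np.ndarray
    noisy_phi_rad: np.ndarray  # (frames, rods)
    clean_phi_rad: np.ndarray
    params: dict = field(default_factory=dict)


def gen_angle_dataset(
    n_rods: int,
    speed_m_s: float,
    seed: int,
    *,
    rod: rodmod.RodParams | None = None,
    env: rodmod.ThermalEnv | None = None,
    protocol: SamplingProtocol = STUDY_PROTOCOL,
    noise_sd_deg: float = 3.0,
    equilibrate: bool = True,
    out_dir: str | Path | None = None,
) -> AngleDataset:
    """Anchored-rod angle series under flow, plus angular measurement noise.

    Wraps :func:`windsock.rod.sample_population` and adds wrapped-Gaussian
    reader noise (default sd 3°) to the frame samples; the clean ground
    truth is retained alongside.
    """
    rod = rod or rodmod.RodParams()
    env = env or rodmod.ThermalEnv()
    ss = np.random.SeedSequence([seed, 0x517])
    sim_seed = int(ss.generate_state(1)[0] % (2**31))
    trajs = rodmod.sample_population(
        n_rods, rod, env, speed_m_s, protocol.times_s, sim_seed, equilibrate=equilibrate
    )
    clean = np.stack([t.phi_rad for t in trajs], axis=1)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA01]))
    noisy = clean + np.radians(noise_sd_deg) * rng.standard_normal(clean.shape)
    params = {
        "generator": "gen_angle_dataset",
        "n_rods": n_rods,
        "speed_m_s": speed_m_s,
        "seed": seed,
        "noise_sd_deg": noise_sd_deg,
        "protocol": {"n_frames": protocol.n_frames, "interval_s": protocol.interval_s},
        "rod": {"length_m": rod.length_m, "diameter_m": rod.diameter_m},
        "env": {"temperature_k": env.temperature_k, "viscosity_pa_s": env.viscosity_pa_s},
    }
    ds = AngleDataset(
        trajectories=trajs,
        frame_times_s=protocol.times_s,
        noisy_phi_rad=noisy,
        clean_phi_rad=clean,
        params=params,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for k, tr in enumerate(trajs):
            tr.to_csv(out_dir / f"trajectory_{k:03d}.csv")
        import pandas as pd

        pd.DataFrame(
            noisy, columns=[f"rod_{k:03d}" for k in range(n_rods)]
        ).assign(time_s=protocol.times_s).to_csv(
            out_dir / "noisy_frames.csv", index=False, float_format="%.17g"
        )
        _write_manifest(out_dir, "angles", params)
    return ds


def gen_decay_dataset(
    a: float,
    b_per_h: float,
    time_grid_h: np.ndarray,
    noise_sd: float,
    n_cells: int,
    seed: int,
    *,
    out_dir: str | Path | None = None,
) -> list[DecaySeries]:
    """Per-cell persistence fractions y = a·e^(-b·t) + noise.

    Values are clipped at zero and renormalised so fraction(0) = 1, as
    measured counts normalised to the first frame would be.
    """
    if b_per_h < 0:
        raise ValueError("decay rate must be non-negative")
    t = np.asarray(time_grid_h, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xDEC]))
    series = []
    for c in range(n_cells):
        y = a * np.exp(-b_per_h * t) + rng.normal(0.0, noise_sd, size=t.size)
        y = np.clip(y, 0.0, None)
        if y[0] <= 0:
            y[0] = max(a, 1e-6)
        y = y / y[0]
        series.append(DecaySeries(times_h=t, fraction=y, label=f"cell_{c:02d}"))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for s in series:
            s.to_csv(out_dir / f"decay_{s.label}.csv")
        _write_manifest(
            out_dir,
            "decay",
            {
                "generator": "gen_decay_dataset",
                "a": a,
                "b_per_h": b_per_h,
                "time_grid_h": t.tolist(),
                "noise_sd": noise_sd,
                "n_cells": n_cells,
                "seed": seed,
            },
        )
    return series


@dataclass
class ColocDataset:
    """Per-cell seed/antibody patterns with known colocalized fraction."""

    seeds: list[PointPattern]
    antibodies: list[PointPattern]
    mask: Mask
    true_fraction: float
    params: dict = field(default_factory=dict)


def gen_coloc_dataset(
    true_fraction: float,
    intensity_per_um2: float,
    n_cells: int,
    seed: int,
    *,
    mask: Mask | None = None,
    n_seeds: int = 150,
    radius_um: float = 0.5,
    out_dir: str | Path | None = None,
) -> ColocDataset:
    """Point patterns with a controllable truly-colocalized seed fraction.

    Per cell: antibodies are a Poisson pattern of the given intensity over
    the mask; each seed is placed within ``radius_um`` of a random antibody
    with probability ``true_fraction`` (uniform over the disc, re-drawn
    until inside the mask), otherwise uniformly over the mask.
    """
    if not 0.0 <= true_fraction <= 1.0:
        raise ValueError("true_fraction must lie in [0, 1]")
    mask = mask or Mask.ellipse()
    if intensity_per_um2 * mask.area_um2 < 1:
        raise ValueError("antibody intensity too low for this mask")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC01]))
    seeds_all, abs_all = [], []
    for c in range(n_cells):
        n_ab = rng.poisson(intensity_per_um2 * mask.area_um2)
        n_ab = max(n_ab, 1)
        ab_xy = mask.sample_uniform(n_ab, rng)
        seed_xy = np.empty((n_seeds, 2))
        for k in range(n_seeds):
            if rng.uniform() < true_fraction:
                centre = ab_xy[rng.integers(0, n_ab)]
                while True:
                    r = radius_um * np.sqrt(rng.uniform())
                    th = rng.uniform(0.0, 2.0 * np.pi)
                    pt = centre + r * np.array([np.cos(th), np.sin(th)])
                    if mask.contains(pt[None])[0]:
                        break
                seed_xy[k] = pt
            else:
                seed_xy[k] = mask.sample_uniform(1, rng)[0]
        seeds_all.append(PointPattern(seed_xy, mask=mask, label="seed"))
        abs_all.append(PointPattern(ab_xy, mask=mask, label="antibody"))
    params = {
        "generator": "gen_coloc_dataset",
        "true_fraction": true_fraction,
        "intensity_per_um2": intensity_per_um2,
        "n_cells": n_cells,
        "n_seeds": n_seeds,
        "radius_um": radius_um,
        "seed": seed,
        "mask_area_um2": mask.area_um2,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        for c in range(n_cells):
            df = pd.concat(
                [
                    pd.DataFrame(
                        {
                            "x_um": p.xy_um[:, 0],
                            "y_um": p.xy_um[:, 1],
                            "channel": p.label,
                        }
                    )
                    for p in (seeds_all[c], abs_all[c])
                ]
            )
            df.to_csv(out_dir / f"points_cell_{c:02d}.csv", index=False,
                      float_format="%.17g")
        _write_manifest(out_dir, "coloc", params)
    return ColocDataset(
        seeds=seeds_all,
        antibodies=abs_all,
        mask=mask,
        true_fraction=true_fraction,
        params=params,
    )
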