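"""Overdamped Langevin dynamics of a surface-anchored rigid rod in flow.

A micron-scale filament (here a DNA nanotube, persistence length ~8.7 µm,
so effectively rigid at ~5 µm contour length) is anchored at one end by a
freely swivelling linker to the bottom wall of a flow chamber.  Uniform flow
of speed ``U`` drags the rod with force ``F = (αµUℓ, 0)`` applied at the
centre of mass ``r = (ℓ/2·cosϕ, ℓ/2·sinϕ)``, giving the restoring torque

    M(ϕ) = r × F = -½·α·µ·U·ℓ²·sinϕ,

where ϕ is the in-plane (azimuthal) angle between rod and flow.  The angle
evolves by the overdamped Langevin equation

    γ dϕ/dt = M(ϕ) + R(t),

integrated by Euler–Maruyama.  With the fluctuation–dissipation noise
(``Var(R) = 2·k_B·T·γ/Δt``, the default) the stationary law is the
Boltzmann distribution of the potential E(ϕ) = -½αµUℓ²cosϕ, i.e. a von
Mises density with concentration

    κ = α·µ·U·ℓ² / (2·k_B·T).

``noise_convention="as_printed"`` halves the noise variance
(``Var(R) = k_B·T·γ/Δt``), which equilibrates at temperature T/2 — kept for
literal reproduction of the published update rule; see docs/methods.md.

Drag coefficients default to slender-body theory:
``α = 4π/(ln(ℓ/d) + 0.84)`` (perpendicular translation) and
``γ = πµℓ³/(3(ln(ℓ/d) - 0.66))`` (rotation about one end).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .units import KB

__all__ = [
    "RodParams",
    "ThermalEnv",
    "AngleTrajectory",
    "SphericalState",
    "StabilityError",
    "drag_coefficients",
    "flow_torque",
    "torque_amplitude",
    "kappa",
    "speed_for_kappa",
    "default_dt",
    "stability_bound_dt",
    "mixing_time",
    "rotational_diffusion",
    "stationary_density",
    "simulate_trajectory",
    "sample_population",
    "simulate_spherical",
    "wrap_angle",
]


class StabilityError(ValueError):
    """Requested time step exceeds the explicit-integrator stability bound."""


def drag_coefficients(
    length_m: float, diameter_m: float, mu_pa_s: float
) -> tuple[float, float]:
    """Slender-body drag: (α dimensionless, γ in J·s).

    α is the perpendicular translational drag coefficient entering
    ``F = αµUℓ``; γ is the rotational damping coefficient for rotation of a
    rod about one end.  Valid for ℓ ≫ d.
    """
    if length_m <= 0 or diameter_m <= 0 or mu_pa_s <= 0:
        raise ValueError("length, diameter and viscosity must be positive")
    ratio = length_m / diameter_m
    log_ratio = math.log(ratio)
    if log_ratio <= 0.66:
        raise ValueError(
            f"aspect ratio ℓ/d = {ratio:.3g} too small for the slender-body "
            "log correction (need ln(ℓ/d) > 0.66)"
        )
    alpha = 4.0 * math.pi / (log_ratio + 0.84)
    gamma = math.pi * mu_pa_s * length_m**3 / (3.0 * (log_ratio - 0.66))
    return alpha, gamma


@dataclass(frozen=True)
class RodParams:
    """Rigid-rod filament parameters.

    ``alpha``/``gamma`` override the slender-body defaults when given.
    ``persistence_length_m`` is informational: it justifies the rigid-rod
    idealization (Lp ≈ 8.7 µm for DNA tile nanotubes, on the order of ℓ).
    """

    length_m: float = 5e-6
    diameter_m: float = 12e-9
    persistence_length_m: float = 8.7e-6
    alpha: float | None = None
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.length_m <= 0 or self.diameter_m <= 0:
            raise ValueError("length and diameter must be positive")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha override must be positive")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma override must be positive")

    def coefficients(self, mu_pa_s: float) -> tuple[float, float]:
        """Resolved (α, γ) at viscosity µ — overrides win, else slender-body."""
        if self.alpha is not None and self.gamma is not None:
            return self.alpha, self.gamma
        alpha_sb, gamma_sb = drag_coefficients(self.length_m, self.diameter_m, mu_pa_s)
        return (
            self.alpha if self.alpha is not None else alpha_sb,
            self.gamma if self.gamma is not None else gamma_sb,
        )


@dataclass(frozen=True)
class ThermalEnv:
    """Thermal bath and integration settings.

    ``dt_s=None`` selects the automatic step
    ``min(0.1·γ/A, 1 ms)`` where ``A = ½αµ|U|ℓ²`` is the torque amplitude;
    an explicit step is refused above the stability bound ``0.5·γ/A``.
    """

    temperature_k: float = 293.15
    viscosity_pa_s: float = 1.0e-3
    dt_s: float | None = None

    def __post_init__(self) -> None:
        if self.temperature_k < 0:
            raise ValueError("temperature must be non-negative")
        if self.viscosity_pa_s <= 0:
            raise ValueError("viscosity must be positive")
        if self.dt_s is not None and self.dt_s <= 0:
            raise ValueError("time step must be positive")


def torque_amplitude(rod: RodParams, env: ThermalEnv, speed_m_s: float) -> float:
    """A = ½·α·µ·|U|·ℓ², the flow-torque amplitude (N·m)."""
    alpha, _ = rod.coefficients(env.viscosity_pa_s)
    return 0.5 * alpha * env.viscosity_pa_s * abs(speed_m_s) * rod.length_m**2


def flow_torque(
    phi_rad: float | np.ndarray, speed_m_s: float, rod: RodParams, mu_pa_s: float
) -> float | np.ndarray:
    """Flow-induced torque M(ϕ) = -½αµUℓ²·sinϕ (N·m); odd in ϕ."""
    alpha, _ = rod.coefficients(mu_pa_s)
    return -0.5 * alpha * mu_pa_s * speed_m_s * rod.length_m**2 * np.sin(phi_rad)


def kappa(rod: RodParams, env: ThermalEnv, speed_m_s: float) -> float:
    """Stationary von Mises concentration κ = αµ|U|ℓ²/(2·k_B·T)."""
    if env.temperature_k == 0:
        return math.inf if speed_m_s != 0 else 0.0
    return torque_amplitude(rod, env, speed_m_s) / (KB * env.temperature_k)


def speed_for_kappa(rod: RodParams, env: ThermalEnv, kappa_target: float) -> float:
    """Flow speed (m/s) that yields a given stationary concentration κ."""
    if kappa_target < 0:
        raise ValueError("kappa must be non-negative")
    alpha, _ = rod.coefficients(env.viscosity_pa_s)
    return (
        2.0
        * KB
        * env.temperature_k
        * kappa_target
        / (alpha * env.viscosity_pa_s * rod.length_m**2)
    )


def stability_bound_dt(rod: RodParams, env: ThermalEnv, speed_m_s: float) -> float:
    """Hard upper step bound 0.5·γ/A (s); infinite at zero flow."""
    amp = torque_amplitude(rod, env, speed_m_s)
    _, gamma = rod.coefficients(env.viscosity_pa_s)
    return math.inf if amp == 0 else 0.5 * gamma / amp


def default_dt(rod: RodParams, env: ThermalEnv, speed_m_s: float) -> float:
    """Automatic step: min(0.1·γ/A, 1 ms)."""
    amp = torque_amplitude(rod, env, speed_m_s)
    _, gamma = rod.coefficients(env.viscosity_pa_s)
    if amp == 0:
        return 1e-3
    return min(0.1 * gamma / amp, 1e-3)


def _resolve_dt(rod: RodParams, env: ThermalEnv, speed_m_s: float) -> float:
    if env.dt_s is None:
        return default_dt(rod, env, speed_m_s)
    bound = stability_bound_dt(rod, env, speed_m_s)
    if env.dt_s > bound:
        raise StabilityError(
            f"time step {env.dt_s:.3g} s exceeds the stability bound "
            f"0.5·γ/A = {bound:.3g} s at this flow speed; "
            f"a safe choice is {default_dt(rod, env, speed_m_s):.3g} s"
        )
    return env.dt_s


def rotational_diffusion(rod: RodParams, env: ThermalEnv) -> float:
    """D = k_B·T/γ, rad²/s."""
    _, gamma = rod.coefficients(env.viscosity_pa_s)
    return KB * env.temperature_k / gamma


def mixing_time(rod: RodParams, env: ThermalEnv, speed_m_s: float) -> float:
    """Approximate relaxation time of ϕ toward its stationary law (s).

    Diffusive (~1/D) at weak drive, drift-dominated (~γ/A = 1/(κD)) when
    the flow torque dominates: ``1/(D·max(1, κ))``.
    """
    d = rotational_diffusion(rod, env)
    if d == 0:
        amp = torque_amplitude(rod, env, speed_m_s)
        _, gamma = rod.coefficients(env.viscosity_pa_s)
        return math.inf if amp == 0 else gamma / amp
    return 1.0 / (d * max(1.0, kappa(rod, env, speed_m_s)))


def wrap_angle(phi_rad: np.ndarray | float) -> np.ndarray | float:
    """Wrap to (-π, π]."""
    return -np.mod(-np.asarray(phi_rad) + np.pi, 2.0 * np.pi) + np.pi


def stationary_density(
    phi_rad: np.ndarray | float, kappa_value: float
) -> np.ndarray | float:
    """Stationary density of ϕ on (-π, π]: von Mises(κ), uniform at κ=0."""
    if kappa_value < 0:
        raise ValueError(f"kappa must be non-negative, got {kappa_value}")
    phi = np.asarray(phi_rad, dtype=float)
    if kappa_value == 0:
        out = np.full_like(phi, 1.0 / (2.0 * np.pi))
    else:
        out = stats.vonmises.pdf(phi, kappa_value)
    return out if out.shape else float(out)


@dataclass
class AngleTrajectory:
    """Time-stamped azimuth series, stored unwrapped (no mod-2π jumps)."""

    times_s: np.ndarray
    phi_rad: np.ndarray
    phi0_rad: float
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.phi_rad = np.asarray(self.phi_rad, dtype=float)
        if self.times_s.shape != self.phi_rad.shape:
            raise ValueError("times and angles must have the same shape")
        if self.times_s.size and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        if self.times_s.size and not math.isclose(
            self.phi_rad[0], self.phi0_rad, rel_tol=0, abs_tol=1e-12
        ):
            raise ValueError("phi0 must equal the first sample")

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0])

    def phi_at(self, times_s: np.ndarray) -> np.ndarray:
        """Unwrapped angle linearly interpolated at the requested times."""
        t = np.asarray(times_s, dtype=float)
        eps = 1e-9
        if t.min() < self.times_s[0] - eps or t.max() > self.times_s[-1] + eps:
            raise ValueError(
                f"requested times [{t.min()}, {t.max()}] s exceed trajectory "
                f"coverage [{self.times_s[0]}, {self.times_s[-1]}] s"
            )
        return np.interp(t, self.times_s, self.phi_rad)

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        path = Path(path)
        df = pd.DataFrame({"time_s": self.times_s, "phi_rad": self.phi_rad})
        df.to_csv(path, index=False, float_format="%.17g")
        if sidecar:
            meta = dict(self.meta)
            meta.update({"phi0_rad": self.phi0_rad, "seed": self.seed})
            path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "AngleTrajectory":
        path = Path(path)
        df = pd.read_csv(path, float_precision="round_trip")
        meta: dict = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(
            times_s=df["time_s"].to_numpy(),
            phi_rad=df["phi_rad"].to_numpy(),
            phi0_rad=float(meta.get("phi0_rad", df["phi_rad"].iloc[0])),
            seed=meta.get("seed"),
            meta={k: v for k, v in meta.items() if k not in ("phi0_rad", "seed")},
        )


def _noise_step_sd(noise_convention: str, d: float, dt: float) -> float:
    """Per-step sd of the angular noise increment (Δt/γ)·R."""
    if noise_convention == "fdt":
        return math.sqrt(2.0 * d * dt)
    if noise_convention == "as_printed":
        return math.sqrt(d * dt)
    raise ValueError(
        f"unknown noise_convention {noise_convention!r}; use 'fdt' or 'as_printed'"
    )


def _advance(
    phi: np.ndarray,
    n_steps: int,
    dt: float,
    drift_rate: float,
    noise_sd: float,
    rngs: Sequence[np.random.Generator],
    chunk: int = 4096,
) -> np.ndarray:
    """Euler–Maruyama: ϕ ← ϕ - (A/γ)·sinϕ·Δt + noise, vectorised over rods.

    Each rod consumes its own substream, so results are independent of the
    chunk size and of how many rods are integrated together.
    """
    phi = np.array(phi, dtype=float, copy=True)
    done = 0
    while done < n_steps:
        m = min(chunk, n_steps - done)
        if noise_sd > 0:
            noise = np.stack([rng.standard_normal(m) for rng in rngs])
        else:
            noise = None
        for j in range(m):
            phi -= drift_rate * np.sin(phi) * dt
            if noise is not None:
                phi += noise_sd * noise[:, j]
        done += m
    return phi


def simulate_trajectory(
    rod: RodParams,
    env: ThermalEnv,
    speed_m_s: float,
    duration_s: float,
    seed: int,
    *,
    phi0_rad: float | None = None,
    noise_convention: str = "fdt",
    record_every: int = 1,
) -> AngleTrajectory:
    """Integrate one rod for ``duration_s`` seconds; bit-reproducible by seed.

    ``phi0_rad=None`` draws ϕ₀ ~ Uniform(-π, π].  ``record_every`` thins the
    stored samples (step 0 is always recorded).
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    dt = _resolve_dt(rod, env, speed_m_s)
    amp = torque_amplitude(rod, env, speed_m_s)
    _, gamma = rod.coefficients(env.viscosity_pa_s)
    drift = amp / gamma * math.copysign(1.0, speed_m_s) if speed_m_s else 0.0
    d = rotational_diffusion(rod, env)
    noise_sd = _noise_step_sd(noise_convention, d, dt)

    ss = np.random.SeedSequence(seed)
    rng_init, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    phi0 = (
        float(rng_init.uniform(-np.pi, np.pi)) if phi0_rad is None else float(phi0_rad)
    )

    n_steps = max(1, int(round(duration_s / dt)))
    n_rec = n_steps // record_every + 1
    out = np.empty(n_rec)
    out[0] = phi0
    phi = np.array([phi0])
    for i in range(1, n_rec):
        phi = _advance(phi, record_every, dt, drift, noise_sd, [rng_noise])
        out[i] = phi[0]
    times = np.arange(n_rec) * (dt * record_every)
    return AngleTrajectory(
        times_s=times,
        phi_rad=out,
        phi0_rad=phi0,
        seed=seed,
        meta={
            "model": "overdamped-langevin-rod",
            "noise_convention": noise_convention,
            "dt_s": dt,
            "speed_m_s": speed_m_s,
            "kappa": kappa(rod, env, speed_m_s),
            "length_m": rod.length_m,
            "temperature_k": env.temperature_k,
        },
    )


def sample_population(
    n_rods: int,
    rod: RodParams,
    env: ThermalEnv,
    speed_m_s: float,
    record_times_s: np.ndarray,
    seed: int,
    *,
    noise_convention: str = "fdt",
    equilibrate: bool = False,
    decorrelate_gaps: bool = True,
    decorrelation_factor: float = 10.0,
) -> list[AngleTrajectory]:
    """Independent rods recorded at the given times; ϕ₀ ~ Uniform(-π, π].

    Per-rod noise substreams are derived deterministically from the master
    seed.  ``equilibrate=True`` burns in for ``decorrelation_factor``
    mixing times before the first record, so samples start from the
    stationary law.  ``decorrelate_gaps=True`` caps the *integrated* time of
    any inter-record gap at the same horizon: once a gap exceeds many mixing
    times the recorded angles are statistically independent anyway, so
    integrating the full gap only burns CPU (see docs/methods.md).
    """
    if n_rods < 1:
        raise ValueError("need at least one rod")
    times = np.asarray(record_times_s, dtype=float)
    if times.ndim != 1 or times.size < 1 or np.any(np.diff(times) <= 0):
        raise ValueError("record times must be a strictly increasing 1-D array")

    dt = _resolve_dt(rod, env, speed_m_s)
    amp = torque_amplitude(rod, env, speed_m_s)
    _, gamma = rod.coefficients(env.viscosity_pa_s)
    drift = amp / gamma * math.copysign(1.0, speed_m_s) if speed_m_s else 0.0
    d = rotational_diffusion(rod, env)
    noise_sd = _noise_step_sd(noise_convention, d, dt)
    horizon = decorrelation_factor * mixing_time(rod, env, speed_m_s)

    ss = np.random.SeedSequence(seed)
    init_ss, *rod_ss = ss.spawn(n_rods + 1)
    rng_init = np.random.default_rng(init_ss)
    rngs = [np.random.default_rng(s) for s in rod_ss]
    phi = rng_init.uniform(-np.pi, np.pi, size=n_rods)
    phi0_drawn = phi.copy()

    if equilibrate and amp > 0 and math.isfinite(horizon):
        n_burn = int(round(horizon / dt))
        phi = _advance(phi, n_burn, dt, drift, noise_sd, rngs)

    recorded = np.empty((times.size, n_rods))
    prev_t = times[0]
    recorded[0] = phi
    for i, t in enumerate(times[1:], start=1):
        gap = t - prev_t
        sim_time = min(gap, horizon) if decorrelate_gaps else gap
        n_steps = max(1, int(round(sim_time / dt)))
        phi = _advance(phi, n_steps, dt, drift, noise_sd, rngs)
        recorded[i] = phi
        prev_t = t

    meta_common = {
        "model": "overdamped-langevin-rod",
        "noise_convention": noise_convention,
        "dt_s": dt,
        "speed_m_s": speed_m_s,
        "kappa": kappa(rod, env, speed_m_s),
        "length_m": rod.length_m,
        "temperature_k": env.temperature_k,
        "equilibrated": bool(equilibrate),
        "decorrelate_gaps": bool(decorrelate_gaps),
        "master_seed": seed,
    }
    return [
        AngleTrajectory(
            times_s=times,
            phi_rad=recorded[:, k],
            phi0_rad=float(recorded[0, k]),
            seed=seed,
            meta={**meta_common, "rod_index": k, "phi0_drawn": float(phi0_drawn[k])},
        )
        for k in range(n_rods)
    ]


# ---------------------------------------------------------------------------
# Optional 2-DOF extension: Brownian dynamics on the hemisphere.
# ---------------------------------------------------------------------------


@dataclass
class SphericalState:
    """Rod orientation on the upper hemisphere (θ from z-axis, azimuth ϕ)."""

    times_s: np.ndarray
    theta_rad: np.ndarray
    phi_rad: np.ndarray


def simulate_spherical(
    rod: RodParams,
    env: ThermalEnv,
    speed_m_s: float,
    duration_s: float,
    seed: int,
    *,
    record_every: int = 1,
    theta_min: float = 1e-3,
) -> SphericalState:
    """Brownian dynamics of the rod direction on the wall-bounded hemisphere.

    Potential E(θ, ϕ) = -½αµUℓ²·sinθ·cosϕ, whose ϕ-gradient at θ=π/2
    reproduces the planar torque.  Itô dynamics in spherical coordinates
    with the metric (cotθ) drift; reflecting boundaries at θ=π/2 (the wall)
    and θ=0 (coordinate pole).  At zero flow the stationary law is uniform
    on the hemisphere's solid angle (density ∝ sinθ).
    """
    dt = _resolve_dt(rod, env, speed_m_s)
    amp = torque_amplitude(rod, env, speed_m_s)
    _, gamma = rod.coefficients(env.viscosity_pa_s)
    d = rotational_diffusion(rod, env)
    rng = np.random.default_rng(seed)

    n_steps = max(1, int(round(duration_s / dt)))
    n_rec = n_steps // record_every + 1
    theta = float(rng.uniform(theta_min, np.pi / 2))
    phi = float(rng.uniform(-np.pi, np.pi))
    thetas = np.empty(n_rec)
    phis = np.empty(n_rec)
    thetas[0], phis[0] = theta, phi
    sq = math.sqrt(2.0 * d * dt)
    c = amp / gamma  # drift scale, 1/s
    k = 0
    for i in range(1, n_steps + 1):
        sin_t, cos_t = math.sin(theta), math.cos(theta)
        # drift: -(1/γ)∂θE + D·cotθ, with the pole term tamed near θ=0
        cot = cos_t / max(sin_t, math.sin(theta_min))
        theta += (c * cos_t * math.cos(phi) + d * cot) * dt
        theta += sq * rng.standard_normal()
        # reflect into [theta_min, π/2]
        theta = abs(theta - theta_min) + theta_min
        if theta > math.pi / 2:
            theta = math.pi - theta
            theta = max(theta, theta_min)
        sin_t = max(math.sin(theta), math.sin(theta_min))
        phi += -(c / sin_t) * math.sin(phi) * dt + (sq / sin_t) * rng.standard_normal()
        if i % record_every == 0:
            k += 1
            thetas[k], phis[k] = theta, phi
    times = np.arange(k + 1) * (dt * record_every)
    return SphericalState(times_s=times, theta_rad=thetas[: k + 1], phi_rad=phis[: k + 1])
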