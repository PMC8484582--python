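"""Receptor-attachment kinetics and surface-persistence decay.

Back-of-envelope feasibility numbers for anchoring nanostructures to
cell-surface receptors:

* ``attachment_rate`` — well-mixed pseudo-first-order encounter rate
  ``k_on·C·N`` per cell (reported per hour).  At the SpyTag–SpyCatcher rate
  constant (1400 M⁻¹s⁻¹), 64 pM structures and 10⁴ receptors/cell this is a
  few events per hour — far too slow — while antibody/DNA-speed reactions
  (10⁵–10⁶ M⁻¹s⁻¹) give thousands.
* ``equilibrium_occupancy`` — Langmuir bound fraction ``C/(C+K_d)``:
  picomolar structures on >nM-affinity antibodies stay mostly unbound,
  whereas a 15-nt duplex (sub-picomolar K_d) stays bound.
* ``multivalent_retention`` — minimal avidity model: a structure held by
  ``n`` independent sites detaches only when all release before any
  rebinds, so the effective off-rate is ``k_off·p^(n-1)`` with release
  probability ``p = k_off/(k_off + k_rebind)``.
* ``duplex_kd`` — K_d from the duplex standard free energy,
  ``K_d = exp(ΔG°/RT)``.

``fit_decay`` fits the single-exponential surface-persistence model
``y = a·exp(-b·t)`` by nonlinear least squares with non-negativity bounds
and asymptotic t-based 95% confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .units import R_GAS_KCAL

__all__ = [
    "BindingStep",
    "DecaySeries",
    "DecayFit",
    "DecayFitError",
    "attachment_rate",
    "equilibrium_occupancy",
    "multivalent_retention",
    "duplex_kd",
    "fit_decay",
]


@dataclass(frozen=True)
class BindingStep:
    """One binding reaction: rate constant, affinity, concentrations.

    ``k_off_s`` and ``kd_m`` are cross-checked for consistency
    (k_off = k_on·K_d) when both are supplied.
    """

    k_on_m_s: float
    concentration_m: float
    receptors_per_cell: float
    kd_m: float | None = None
    k_off_s: float | None = None
    valency: int = 1

    def __post_init__(self) -> None:
        for name in ("k_on_m_s", "concentration_m", "receptors_per_cell"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.valency < 1:
            raise ValueError("valency must be >= 1")
        if self.kd_m is not None and self.k_off_s is not None:
            expected = self.k_on_m_s * self.kd_m
            if not math.isclose(self.k_off_s, expected, rel_tol=1e-6):
                raise ValueError(
                    f"inconsistent kinetics: k_off={self.k_off_s} but "
                    f"k_on*K_d={expected}"
                )


def attachment_rate(step: BindingStep) -> float:
    """Pseudo-first-order encounter rate, events per cell per hour.

    ``k_on · C · N · 3600`` — well-mixed, no diffusion limitation.  The
    published feasibility argument for the same inputs lands within an
    order of magnitude of this product.
    """
    return step.k_on_m_s * step.concentration_m * step.receptors_per_cell * 3600.0


def equilibrium_occupancy(concentration_m: float, kd_m: float) -> float:
    """Langmuir bound fraction C/(C + K_d)."""
    if concentration_m < 0 or kd_m < 0:
        raise ValueError("concentration and K_d must be non-negative")
    if concentration_m == 0 and kd_m == 0:
        raise ValueError("occupancy undefined for C = K_d = 0")
    return concentration_m / (concentration_m + kd_m)


def multivalent_retention(
    k_off_single_s: float, n_sites: int, rebind_factor_s: float
) -> float:
    """Effective off-rate of an ``n_sites``-valent tether (all-sites-release).

    Each transiently free site rebinds at ``rebind_factor_s`` or releases at
    ``k_off_single_s``; the structure leaves only if the remaining n-1 sites
    all release first:  k_eff = k_off · p^(n-1), p = k_off/(k_off+rebind).
    Monotone decreasing in both ``n_sites`` and ``rebind_factor_s``.
    """
    if k_off_single_s < 0 or rebind_factor_s < 0:
        raise ValueError("rates must be non-negative")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if k_off_single_s == 0:
        return 0.0
    p_release = k_off_single_s / (k_off_single_s + rebind_factor_s)
    return k_off_single_s * p_release ** (n_sites - 1)


def duplex_kd(delta_g_kcal_mol: float, temperature_k: float = 310.0) -> float:
    """Duplex dissociation constant K_d = exp(ΔG°/RT), in M.

    ``delta_g_kcal_mol`` is the standard free energy of duplex *formation*
    (negative for a stable duplex); ΔG° ≈ -17 kcal/mol at 310 K puts a
    15-nt duplex at ~1 pM.
    """
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(delta_g_kcal_mol / (R_GAS_KCAL * temperature_k))


@dataclass
class DecaySeries:
    """Fractions of structures remaining on the surface vs time (hours).

    Normalised so fraction(0) = 1; small noise excursions above 1 are
    allowed.  Pooled multi-cell data may repeat time points.
    """

    times_h: np.ndarray
    fraction: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.times_h.shape != self.fraction.shape:
            raise ValueError("times and fractions must have the same shape")
        if self.times_h.size and self.times_h.min() > 0:
            raise ValueError("series must include the t=0 reference point")

    @classmethod
    def concat(cls, series: list["DecaySeries"], label: str = "") -> "DecaySeries":
        return cls(
            times_h=np.concatenate([s.times_h for s in series]),
            fraction=np.concatenate([s.fraction for s in series]),
            label=label,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_h": self.times_h, "fraction": self.fraction}).to_csv(
            path, index=False, float_format="%.17g"
        )

    @classmethod
    def from_csv(cls, path, label: str = "") -> "DecaySeries":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(
            times_h=df["time_h"].to_numpy(),
            fraction=df["fraction"].to_numpy(),
            label=label,
        )


@dataclass(frozen=True)
class DecayFit:
    """Fitted y = a·exp(-b·t): estimates, 95% CIs and residual summary."""

    a: float
    b_per_h: float
    a_ci95: tuple[float, float]
    b_ci95: tuple[float, float]
    residual_sd: float
    n_points: int


class DecayFitError(RuntimeError):
    """Nonlinear fit failed; the log-linear fallback is attached."""

    def __init__(self, message: str, fallback: DecayFit | None = None) -> None:
        super().__init__(message)
        self.fallback = fallback


def _loglinear_start(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    pos = y > 0
    if pos.sum() < 2:
        return max(float(y.max()), 1e-9), 0.0
    slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
    return float(np.exp(intercept)), max(-float(slope), 0.0)


def fit_decay(series: DecaySeries) -> DecayFit:
    """Nonlinear least squares of y = a·e^(-b·t), a, b ≥ 0.

    Exact on noiseless exponential data; asymptotic 95% CIs from the
    parameter covariance with a t(n-2) multiplier.  On non-convergence
    raises :class:`DecayFitError` carrying the log-linear fallback.
    """
    t, y = series.times_h, series.fraction
    if t.size < 3:
        raise ValueError("need at least three time points")
    a0, b0 = _loglinear_start(t, y)
    model = lambda tt, a, b: a * np.exp(-b * tt)  # noqa: E731
    try:
        popt, pcov = optimize.curve_fit(
            model,
            t,
            y,
            p0=[max(a0, 1e-9), b0],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        fallback = DecayFit(
            a=a0,
            b_per_h=b0,
            a_ci95=(math.nan, math.nan),
            b_ci95=(math.nan, math.nan),
            residual_sd=math.nan,
            n_points=t.size,
        )
        raise DecayFitError(f"exponential fit did not converge: {exc}", fallback)
    a_hat, b_hat = map(float, popt)
    resid = y - model(t, a_hat, b_hat)
    dof = max(t.size - 2, 1)
    resid_sd = float(np.sqrt(resid @ resid / dof))
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    tcrit = float(stats.t.ppf(0.975, dof))
    return DecayFit(
        a=a_hat,
        b_per_h=b_hat,
        a_ci95=(a_hat - tcrit * perr[0], a_hat + tcrit * perr[0]),
        b_ci95=(b_hat - tcrit * perr[1], b_hat + tcrit * perr[1]),
        residual_sd=resid_sd,
        n_points=t.size,
    )
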