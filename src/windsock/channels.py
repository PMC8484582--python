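"""Rectangular-microchannel hydrodynamics.

Converts volumetric flow in a shallow rectangular duct (Ibidi µ-slide style)
to the mean velocity ``U = Q/(H·W)`` and the shear stress at the centre of
the bottom wall under fully developed laminar (Poiseuille) flow.

The wall shear stress uses the exact Fourier-series solution for a
rectangular duct.  With pressure gradient ``G = -dp/dx``, duct height ``H``
(short dimension, wall-normal) and width ``W``::

    Q   = (G·H³·W / 12µ) · [1 - (192·H / π⁵·W) · Σ_odd tanh(nπW/2H)/n⁵]
    τ_w = (G·H / 2)      · [1 - (8/π²)         · Σ_odd sech(nπW/2H)/n²]

Both correction series converge rapidly (the slowly convergent 1/n² and
1/n⁴ parts are summed in closed form, π²/8 and π⁴/96).  As ``W/H → ∞`` the
result approaches the parallel-plate formula ``τ = 6µQ/(W·H²)``, available
explicitly via ``method="parallel_plate"``.

Units: geometry is stored in SI; shear-stress interfaces are offered both in
Pa and in dyn/cm² because flow-chamber work reports dyn/cm².
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import yaml

from .units import DYN_CM2_TO_PA, MM_TO_M

__all__ = [
    "ChannelGeometry",
    "FlowCondition",
    "InvalidGeometryError",
    "SeriesConvergenceError",
    "channel_presets",
    "get_channel",
    "mean_velocity",
    "wall_shear_stress",
    "wall_shear_stress_dyn_cm2",
    "shear_to_flow",
    "VISCOSITY_WATER_20C",
    "VISCOSITY_WATER_37C",
]

#: Dynamic viscosity of water, Pa·s (0.01 dyn·s/cm² at 20 °C).
VISCOSITY_WATER_20C = 1.0e-3
#: Water at 37 °C (0.0069 dyn·s/cm²).
VISCOSITY_WATER_37C = 6.9e-4


class InvalidGeometryError(ValueError):
    """Channel dimensions are not a valid wide rectangular duct."""


class SeriesConvergenceError(RuntimeError):
    """The duct series did not reach the requested tolerance."""


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular duct: height (wall-normal, short side), width, length.

    All stored in metres.  ``length_m`` is informational (entrance effects
    are not modelled).
    """

    height_m: float
    width_m: float
    length_m: float | None = None

    def __post_init__(self) -> None:
        if not (self.height_m > 0 and self.width_m > 0):
            raise InvalidGeometryError(
                f"channel dimensions must be positive, got "
                f"H={self.height_m}, W={self.width_m}"
            )
        if self.width_m < self.height_m:
            raise InvalidGeometryError(
                "expected wide-channel orientation (W >= H); "
                f"got H={self.height_m} m > W={self.width_m} m"
            )

    @classmethod
    def from_mm(
        cls, height_mm: float, width_mm: float, length_mm: float | None = None
    ) -> "ChannelGeometry":
        return cls(
            height_m=height_mm * MM_TO_M,
            width_m=width_mm * MM_TO_M,
            length_m=None if length_mm is None else length_mm * MM_TO_M,
        )

    @property
    def cross_section_m2(self) -> float:
        return self.height_m * self.width_m

    @property
    def aspect_ratio(self) -> float:
        """W/H ≥ 1."""
        return self.width_m / self.height_m


def channel_presets() -> dict[str, ChannelGeometry]:
    """Shipped channel registry (Ibidi µ-slide VI 0.4 / 0.5)."""
    text = (
        importlib.resources.files("windsock").joinpath("data/channels.yml").read_text()
    )
    raw = yaml.safe_load(text)
    return {
        name: ChannelGeometry.from_mm(
            entry["height_mm"], entry["width_mm"], entry.get("length_mm")
        )
        for name, entry in raw.items()
    }


def get_channel(name: str) -> ChannelGeometry:
    presets = channel_presets()
    try:
        return presets[name]
    except KeyError:
        raise KeyError(
            f"unknown channel preset {name!r}; available: {sorted(presets)}"
        ) from None


def mean_velocity(geom: ChannelGeometry, q_m3_s: float) -> float:
    """Mean channel velocity U = Q/(H·W), m/s."""
    if q_m3_s < 0:
        raise ValueError(f"volumetric rate must be non-negative, got {q_m3_s}")
    return q_m3_s / geom.cross_section_m2


def _duct_corrections(aspect: float, n_modes: int, rtol: float) -> tuple[float, float]:
    """Correction sums (s_Q, s_tau) for the duct series at aspect ratio W/H.

    s_Q multiplies the parallel-plate flow rate, s_tau the wall shear:
    Q ∝ (1 - s_Q), τ ∝ (1 - s_tau).  Raises if the flow-rate series tail
    (the slower of the two, ~1/n⁴ at the truncation point) exceeds rtol.
    """
    n = np.arange(1, 2 * n_modes, 2, dtype=float)  # odd modes
    x = n * np.pi * aspect / 2.0
    # sech overflows for x > ~700; those terms are exactly 0 at double precision
    sech = np.where(x < 700, 1.0 / np.cosh(np.minimum(x, 700.0)), 0.0)
    tanh = np.tanh(x)
    sum_q = float(np.sum(tanh / n**5))
    sum_tau = float(np.sum(sech / n**2))
    s_q = (192.0 / (np.pi**5 * aspect)) * sum_q
    s_tau = (8.0 / np.pi**2) * sum_tau
    # tail bound for Σ tanh/n⁵ over odd n > n_max: ∫ dn/n⁵ /2 = 1/(8 n_max⁴)
    n_max = n[-1]
    tail = (192.0 / (np.pi**5 * aspect)) / (8.0 * n_max**4)
    if tail > rtol * max(1.0 - s_q, np.finfo(float).tiny):
        raise SeriesConvergenceError(
            f"{n_modes} odd modes leave a series tail {tail:.2e} above the "
            f"requested relative tolerance {rtol:.2e}; increase n_modes"
        )
    return s_q, s_tau


def wall_shear_stress(
    geom: ChannelGeometry,
    q_m3_s: float,
    mu_pa_s: float,
    *,
    method: str = "series",
    n_modes: int = 101,
    rtol: float = 1e-8,
) -> float:
    """Shear stress (Pa) at the centre of the bottom wall.

    ``method="series"`` (default) is the exact rectangular-duct solution;
    ``method="parallel_plate"`` is the infinite-aspect approximation
    ``6µQ/(W·H²)``.  Linear in both Q and µ.
    """
    if q_m3_s < 0:
        raise ValueError(f"volumetric rate must be non-negative, got {q_m3_s}")
    if mu_pa_s <= 0:
        raise ValueError(f"viscosity must be positive, got {mu_pa_s}")
    h, w = geom.height_m, geom.width_m
    tau_pp = 6.0 * mu_pa_s * q_m3_s / (w * h * h)
    if method == "parallel_plate":
        return tau_pp
    if method != "series":
        raise ValueError(f"unknown method {method!r}")
    s_q, s_tau = _duct_corrections(geom.aspect_ratio, n_modes, rtol)
    return tau_pp * (1.0 - s_tau) / (1.0 - s_q)


def wall_shear_stress_dyn_cm2(
    geom: ChannelGeometry, q_m3_s: float, mu_pa_s: float, **kwargs
) -> float:
    """Bottom-wall shear stress in dyn/cm² (the reporting unit)."""
    return wall_shear_stress(geom, q_m3_s, mu_pa_s, **kwargs) / DYN_CM2_TO_PA


def shear_to_flow(
    geom: ChannelGeometry, tau_pa: float, mu_pa_s: float, **kwargs
) -> float:
    """Volumetric rate (m³/s) producing bottom-wall shear stress ``tau_pa``.

    Exploits linearity of τ(Q): one forward evaluation at a reference rate.
    """
    if tau_pa < 0:
        raise ValueError(f"target shear stress must be non-negative, got {tau_pa}")
    if tau_pa == 0:
        return 0.0
    q_ref = 1e-9  # arbitrary reference, τ is linear in Q
    tau_ref = wall_shear_stress(geom, q_ref, mu_pa_s, **kwargs)
    return tau_pa / tau_ref * q_ref


@dataclass(frozen=True)
class FlowCondition:
    """A flow state in a given channel, with derived quantities."""

    geometry: ChannelGeometry
    q_m3_s: float
    mu_pa_s: float

    def __post_init__(self) -> None:
        if self.q_m3_s < 0:
            raise ValueError("volumetric rate must be non-negative")
        if self.mu_pa_s <= 0:
            raise ValueError("viscosity must be positive")

    @property
    def mean_velocity_m_s(self) -> float:
        return mean_velocity(self.geometry, self.q_m3_s)

    @property
    def wall_shear_pa(self) -> float:
        return wall_shear_stress(self.geometry, self.q_m3_s, self.mu_pa_s)

    @property
    def wall_shear_dyn_cm2(self) -> float:
        return self.wall_shear_pa / DYN_CM2_TO_PA
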