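"""Unit constants and conversions.

Internal computations are SI (m, s, kg, Pa, Pa·s).  Interfaces use the units
common in the flow-chamber literature: channel dimensions in mm, volumetric
flow in mL/min, shear stress in dyn/cm², viscosity in poise (dyn·s/cm²).
All conversions are exact multiplicative factors, so round-trips are exact.
"""

from __future__ import annotations

#: Boltzmann constant, J/K (2019 SI definition, exact).
KB = 1.380649e-23

#: Gas constant in kcal/(mol·K), for duplex free energies quoted in kcal/mol.
R_GAS_KCAL = 1.987204259e-3

#: 1 poise = 1 dyn·s/cm² = 0.1 Pa·s.
POISE_TO_PA_S = 0.1

#: 1 dyn/cm² = 0.1 Pa.
DYN_CM2_TO_PA = 0.1

MM_TO_M = 1e-3
UM_TO_M = 1e-6
NM_TO_M = 1e-9

#: 1 mL/min in m³/s.
ML_MIN_TO_M3_S = 1e-6 / 60.0


def dyn_cm2_to_pa(tau: float) -> float:
    return tau * DYN_CM2_TO_PA


def pa_to_dyn_cm2(tau: float) -> float:
    return tau / DYN_CM2_TO_PA


def poise_to_pa_s(mu: float) -> float:
    return mu * POISE_TO_PA_S


def pa_s_to_poise(mu: float) -> float:
    return mu / POISE_TO_PA_S


def ml_min_to_m3_s(q: float) -> float:
    return q * ML_MIN_TO_M3_S


def m3_s_to_ml_min(q: float) -> float:
    return q / ML_MIN_TO_M3_S
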