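# windsock

Micron-scale DNA nanotubes anchored by one end to cell-surface receptors
behave like microscopic windsocks: fluid flow aligns them, thermal noise
randomises them, and the angular range they sweep during a short
time-lapse reads out the local wall shear stress — right at the cell
surface, in the 0–2 dyn/cm² range where mechanosensitive ion channels
operate. `windsock` implements the computational side of that sensing
scheme for people who model, calibrate, or analyse such experiments:

* **Anchored-rod Langevin model** — a rigid rod of length ℓ tethered by a
  free swivel in uniform flow of speed U experiences the torque
  `M(ϕ) = −½αµUℓ² sinϕ` and evolves by `γ dϕ/dt = M + R`. With
  fluctuation–dissipation noise the stationary azimuth law is von Mises
  with concentration `κ = αµUℓ²/(2k_BT)`; slender-body theory supplies
  the drag coefficients α and γ.
* **Channel hydrodynamics** — exact rectangular-duct Poiseuille series for
  the bottom-wall shear stress, with presets for the Ibidi µ-slide VI 0.4
  and VI 0.5 chambers and exact inversion from a target stress to a pump
  rate.
* **The windsock statistic Φ** — the circular range of a rod's sampled
  orientations under the 30-frame / 5-s imaging protocol; calibration
  curves Φ̄(τ) over a stress grid and their inversion back to a shear
  estimate with bootstrap confidence intervals.
* **Imaging simulation** — synthetic fluorescence time-lapses of the
  anchored filament (PSF, background, Poisson–Gaussian noise), maximum
  time projections, and an automated angular-extent reader that validates
  the image pipeline against the trajectory ground truth.
* **Attachment kinetics** — pseudo-first-order attachment rates,
  equilibrium occupancies, a minimal multivalent-avidity model, duplex
  affinities from ΔG°, and single-exponential surface-persistence fits
  `y = a·e^(−bt)` with confidence intervals.
* **Colocalization** — fraction of seed localizations within a radius of
  antibody localizations, against a randomized-placement permutation null.
* **Synthetic data** — deterministic generators (with ground truth and
  JSON manifests) for angle series, persistence decays and point
  patterns, plus the study-condition presets.

## Worked example

Shear stress at a pump setting, from the exact duct solution:

```bash
$ windsock shear --channel ibidi_VI_0.4 --flow 0.18mL/min --viscosity 0.01P
mean velocity: 0.1974 cm/s
wall shear stress: 0.3171 dyn/cm2
```

0.18 mL/min of water-like medium through the 0.4 mm × 3.8 mm channel
produces ≈0.32 dyn/cm² at the bottom wall — a gentle flow used to stretch
anchored nanotubes for imaging.

Calibrate the windsock and invert a reading:

```bash
$ windsock calibrate --grid 0.05,0.1,0.4,1.2,1.6,2.0 --n-rods 15 --seed 0 --out cal.csv
tau= 0.050 dyn/cm2  phi_mean=   5.14 deg  ±0.60
tau= 0.100 dyn/cm2  phi_mean=   3.52 deg  ±0.30
tau= 0.400 dyn/cm2  phi_mean=   1.68 deg  ±0.16
tau= 1.200 dyn/cm2  phi_mean=   1.02 deg  ±0.10
tau= 1.600 dyn/cm2  phi_mean=   0.87 deg  ±0.07
tau= 2.000 dyn/cm2  phi_mean=   0.91 deg  ±0.34
wrote cal.csv

$ windsock estimate --phi 1.6 --n 15 --curve cal.csv
tau = 0.4953 dyn/cm2 (95% CI 0.3881-0.6602)
```

The mean swept angle shrinks as flow pins the rods (`κ ∝ τ`, so
`Φ̄ ∝ τ^(−1/2)`, with Monte-Carlo wiggle at 15 rods that the isotonic
smoothing absorbs), and a 15-rod reading of Φ̄ = 1.6° inverts to
τ ≈ 0.50 dyn/cm² with its confidence interval. Without flow the same rods
explore essentially all azimuths (mean Φ → 360° as the protocol
lengthens).

The same operations are available as a library:

```python
import numpy as np
from windsock import (RodParams, ThermalEnv, get_channel, build_calibration,
                      STUDY_PROTOCOL, estimate_shear)

curve = build_calibration(np.array([0.05, 0.1, 0.4, 1.2, 1.6, 2.0]),
                          n_rods=15, rod=RodParams(), env=ThermalEnv(),
                          geom=get_channel("ibidi_VI_0.5"),
                          protocol=STUDY_PROTOCOL, seed=0)
est = estimate_shear(1.6, n_observed=15, curve=curve)
```

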