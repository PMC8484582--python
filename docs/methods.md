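# Methods

`windsock` models micron-scale filaments (DNA tile nanotubes grown from
origami seeds) anchored by one end to a surface — a coverslip or a
cell-surface receptor — and used as microscopic flow sensors. This note
records the models, the parameter choices, the numerics, and what the
synthetic-data experiments do and do not demonstrate.

## The anchored-rod model

A nanotube of contour length ℓ ≈ 5 µm and persistence length
Lp = 8.7 µm is treated as a rigid rod: bending modes are neglected because
Lp is of the order of ℓ. The anchor is a free swivel (the linker's
torsional stiffness is unknown and assumed negligible). Under uniform flow
of speed U, the drag force on the rod is F = (αµUℓ, 0) applied at the
centre of mass r = (ℓ/2·cosϕ, ℓ/2·sinϕ), where ϕ is the in-plane angle
between rod and flow, µ the fluid viscosity and α a dimensionless drag
coefficient. The resulting torque is

    M(ϕ) = −½ α µ U ℓ² sin ϕ,

and the overdamped dynamics are

    γ dϕ/dt = M(ϕ) + R(t),

with rotational damping coefficient γ and thermal torque noise R.

**Polar angle.** A full treatment would track the rod direction on the
wall-bounded hemisphere. Except at very small drive the polar angle sits
near π/2, so the default model is the 1-DOF azimuthal equation; the 2-DOF
hemisphere dynamics (`simulate_spherical`, potential
E = −½αµUℓ²·sinθ·cosϕ with the metric drift and reflecting boundaries)
are provided to check that reduction. At equilibrium the polar offset from
π/2 scales as √(2/πκ): ≈0.25 rad at κ = 10, below 0.15 rad for κ ≳ 30.

**Noise convention.** Thermal noise is drawn i.i.d. each step. Two
variances are implemented:

* `"fdt"` (default): Var(R) = 2·k_B·T·γ/Δt, the fluctuation–dissipation
  choice. The stationary law is then the Boltzmann distribution of
  E(ϕ) = −½αµUℓ²cosϕ, a von Mises density with concentration
  κ = αµUℓ²/(2 k_B T), and the zero-flow mean-square displacement is
  2(k_BT/γ)t.
* `"as_printed"`: Var(R) = k_B·T·γ/Δt. This literal form of the published
  update rule equilibrates at temperature T/2 (the long-run density is von
  Mises with 2κ); it is kept only for reproducing that rule verbatim.

**Drag coefficients.** Defaults come from slender-body theory with a
hydrodynamic diameter d = 12 nm:

    α = 4π / (ln(ℓ/d) + 0.84)          (perpendicular translation)
    γ = π µ ℓ³ / (3 (ln(ℓ/d) − 0.66))  (rotation about one end)

For ℓ = 5 µm, d = 12 nm, µ = 1 mPa·s: α ≈ 1.83, γ ≈ 2.4×10⁻²⁰ J·s, hence
a rotational diffusion coefficient D = k_BT/γ ≈ 0.17 rad²/s at 20 °C.
Both coefficients can be overridden on `RodParams`. Wall corrections to
the drag are not modelled.

**Velocity felt by the rod.** The rod is driven by the mean channel
velocity U = Q/(H·W): the chambers are hundreds of times taller than the
rod, so the flow around it is treated as uniform. A near-wall
alternative (U = τ·h/µ at a configurable height h) can be emulated by
passing the corresponding speed directly; it is not the default. This
choice makes κ large even at 0.05 dyn/cm², i.e. the simulated sensor
saturates toward alignment quickly — consistent with the observation that
small stresses already align the filaments.

**Integration.** Euler–Maruyama with step Δt. Default
Δt = min(0.1·γ/A, 1 ms), where A = ½αµ|U|ℓ² is the torque amplitude; an
explicit step above the deterministic stability bound 0.5·γ/A is refused
with a suggested safe value. At zero drive the scheme integrates pure
diffusion exactly, so coarse steps are legitimate there and are used in
the long zero-flow experiments (50 ms). Angles are stored unwrapped;
wrapping happens only in statistics. Every rod consumes its own
counter-based substream spawned from the master seed, so populations are
reproducible bit-for-bit and independent of batch size.

**Stiff-protocol acceleration.** Under the imaging protocol (30 frames
every 5 s) at experimental stresses, the rod relaxes in γ/A ~ milliseconds:
successive frames are statistically independent. `sample_population`
therefore caps the *integrated* time of an inter-record gap at ten mixing
times (mixing time 1/(D·max(1, κ))), which preserves the joint law of the
recorded angles to within a residual inter-frame correlation of e⁻¹⁰ while
reducing the cost by orders of magnitude. The cap never engages when gaps
are genuinely shorter than the mixing horizon (e.g. at zero flow), and
`simulate_trajectory` always integrates continuously.

## Channel hydrodynamics

Shear stress at the centre of the bottom wall of a rectangular duct under
fully developed laminar flow, from the exact Fourier series with the
slowly convergent parts summed in closed form:

    Q  = (G·H³·W/12µ)·[1 − (192·H/π⁵·W)·Σ_odd tanh(nπW/2H)/n⁵]
    τw = (G·H/2)·[1 − (8/π²)·Σ_odd sech(nπW/2H)/n²]

The default 101 odd modes reach relative accuracy far below the 10⁻⁸
tolerance (the guard computes the series tail and raises if it exceeds the
request). As W/H → ∞ this approaches the parallel-plate formula
6µQ/(W·H²), available as `method="parallel_plate"`; at the VI-family
aspect ratio (9.5) the exact solution is 7.1% above the parallel-plate
value, and the published operating point (0.18 mL/min in the 0.4 mm
channel, water) evaluates to 0.317 dyn/cm² against the vendor-method
0.32. Default viscosities are water: 1.0 mPa·s at 20 °C, 0.69 mPa·s at
37 °C — always overridable. Entrance effects, pulsatile flow and flow
perturbation by the cell body are out of scope.

## The windsock statistic Φ

Φ is the angular range a filament sweeps during the imaging protocol,
read off a maximum time projection. It is formalised as the *circular
range* of the frame-sampled orientations: 360° minus the largest angular
gap between consecutive sorted wrapped samples, capped at 360°. This is a
set statistic — invariant to the time order and to global rotation — and
sidesteps the question of how a manual reading would treat inter-frame
arcs larger than 180°. A brute-force cut-the-circle scan serves as the
oracle in tests.

With 30 discrete frames the circular range of even a uniformly exploring
rod cannot reach 360° (the expected largest gap of 30 uniform points is
≈48°): the zero-flow mean Φ under the standard protocol is ≈300°, and the
"explores all azimuths" limit is demonstrated with a longer protocol
(300 frames → Φ̄ ≈ 352°), where the residual deficit is the unavoidable
largest gap of finitely many samples.

**Calibration and inversion.** `build_calibration` simulates N rods per
stress on a grid (stresses converted to mean velocity through the channel
model), records per-rod Φ, and summarises with mean, SD and t-based 95%
CI. Because Φ̄(τ) ∝ τ^(−1/2) over the working range, Monte-Carlo noise can
locally invert the curve; isotonic regression (decreasing) restores a
well-defined inverse. The confidence interval of `estimate_shear` inverts
a bootstrap acceptance band: at each grid stress the 2.5–97.5% quantiles
of the mean of n observed Φ values resampled from that stress's simulated
rods, smoothed isotonically and inverted at the observed Φ̄. Readings
outside the calibrated range are clamped and flagged saturated (sensor
dynamic-range limit). Measured coverage at τ = 0.4 dyn/cm² with a 500-rod
curve is 91–97% over 100 replicates. Rod-length heterogeneity is not
simulated by default (fixed ℓ); cell-surface curvature is out of scope.

## Imaging simulation

Frames are rendered as a Gaussian transverse profile (sd = PSF σ, default
1.5 px) around the rod segment — an analytically PSF-convolved line — plus
a constant background, Poisson shot noise and Gaussian read noise; the
default quality index is peak SNR = amplitude/√(read² + shot). The
measurement chain mirrors the published reading: Gaussian blur of radius
1.00 px, maximum time projection, then an automated angular-extent
measurement replacing the manual one: Otsu threshold (fixed-quantile
fallback for low SNR), polar histogram of foreground pixels about the
anchor in 5° bins restricted to an annulus (0.25–1.3 ℓ; pixels near the
pivot carry no angular information), occupancy by pixel count (a filament
crossing the annulus lights ≈ one pixel per radius step however briefly
the angle was visited), erosion of one bin per run edge to remove the
filament's transverse broadening, and finally the circular range of
occupied bins. At peak SNR ≈ 5.8 the image-measured Φ tracks the
trajectory statistic within 10° across weak to strong alignment
(κ = 0.5–10); the bin width (5°) sits below the 15° agreement tolerance
used in validation. Segmentation of real micrographs is out of scope.

## Attachment kinetics and persistence decay

Feasibility numbers are deliberately back-of-envelope, matching how such
estimates are used to choose an anchoring chemistry:

* attachment rate = k_on·C·N per cell (well-mixed pseudo-first-order; no
  diffusion limitation). The SpyTag scenario (1400 M⁻¹s⁻¹, 64 pM, 10⁴
  receptors) gives 3.2 h⁻¹ — the same order as the published "about one
  per hour", which likely includes an additional accessibility factor;
  the discrepancy (~3×) is within the order-of-magnitude nature of the
  argument and is not forced to agree.
* equilibrium occupancy = C/(C+K_d): 64 pM ligand on a 1 nM-affinity
  antibody stays 94% unbound, while a 15-nt duplex
  (K_d = exp(ΔG°/RT) ≈ 1 pM at ΔG° = −17 kcal/mol, 310 K) stays bound.
  ΔG° is an input; nearest-neighbour sequence thermodynamics are out of
  scope.
* multivalent retention: minimal independent-sites avidity,
  k_eff = k_off·p^(n−1) with release probability
  p = k_off/(k_off+k_rebind); six sites at p = 0.1 slow release 10⁵-fold.
  No cooperative or geometric effects.

Surface persistence is the single-exponential y = a·e^(−bt), fitted by
bounded nonlinear least squares (log-linear start, exact on noiseless
data) with asymptotic t-based 95% CIs; a log-linear fallback is attached
to any non-convergence error. Whether structures detach or are
internalised is not distinguished, and two-population decays are not
modelled. The synthetic persistence generator emulates the assay design —
per-cell fractions on a fixed time grid (seeds: every 10 min over 70 min;
nanotubes: every 15 min over 3 h, chosen to span ~1.5 decay times of the
slower process), Gaussian noise sd 0.02, 6 cells, clipped at zero and
renormalised to fraction(0) = 1. CI coverage of the decay rate is 92–97%
over 200 replicates at both published rates.

## Colocalization

The observed statistic is the fraction of seed localizations with at
least one antibody localization within radius r (default 0.5 µm ≈ two
confocal pixels at ×60; the radius is always an explicit, logged
parameter). The null redraws the *seed* positions uniformly over the cell
mask, preserving the count — randomising the structures, not the
receptors — and the p-value is (1 + #{null ≥ obs})/(1 + n_perm). For
Poisson antibodies of intensity λ the closed form 1 − exp(−λπr²) is the
oracle; away from mask edges the simulated fractions match it to <0.5%.
Intensity-based (Pearson/Manders) colocalization and spot detection from
raw images are out of scope: patterns enter as coordinates.

The synthetic cohort generator places each seed near a random antibody
with probability f (the truly-colocalized fraction) and uniformly
otherwise, so the expected observed fraction is f + (1−f)·baseline; the
default mask is a 30 µm × 20 µm ellipse at 0.1 µm/px — a typical
adherent-cell footprint.

## What the synthetic experiments do and do not show

The generators reproduce the statistical structure the analyses assume —
Markovian rotational dynamics with the stated stationary law, exponential
decay with homoscedastic noise, Poisson point patterns with a controlled
bound fraction, shot-plus-read-noise imaging of a thin filament. Passing
tests therefore demonstrate the *estimators and pipelines are correct and
calibrated under the model*, not that the model captures every feature of
real data: real nanotubes vary in length and flex, cells are curved and
move, antibody localizations cluster, and manual angle readings have
reader-specific error. Those effects are documented as out of scope above.

## Problem sizes and tolerances

Validation runs use: 10⁵ stationary samples per κ (KS budget 0.02;
measured ≈0.003, with the Euler bias kept below the budget by
Δt ≤ 0.02/(D·max(1,κ))); 200 decay replicates; 100 inversion replicates
against a 500-rod calibration; 10⁴ seeds for the Poisson closed form (2%
budget); 100 permutation replicates for p-uniformity; 15 rods × 3
concentrations for image agreement. These sizes make every Monte-Carlo
check decisively tighter than its tolerance while keeping the whole
validation run under a minute on one core.
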