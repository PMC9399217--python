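# Methods

This note documents the models, defaults and numerical choices behind
`petquant`, and what the synthetic-data tests do and do not establish.

## Two-tissue compartment model

The tissue signal is modelled as

    dC1/dt = K1·Cp − (k2 + k3)·C1 + k4·C2
    dC2/dt = k3·C1 − k4·C2
    C_T(t) = (1 − vB)·(C1 + C2) + vB·C_b(t)

with K1 in mL·cm⁻³·min⁻¹, k2–k4 in min⁻¹ and vB the fractional blood
volume. The whole-blood curve serves both as the input `Cp` and as the
blood-volume term `C_b`: the workflow this package targets has no
arterial sampling, plasma separation or metabolite correction, so no
plasma/whole-blood distinction is available. Macro-parameters for the
reversible model are `VT = K1/k2·(1 + k3/k4)` and `BP = k3/k4`; `k4 = 0`
is flagged as the irreversible limit (VT diverges, BP undefined), and
fitted values of k4 or BP below 10⁻³ are rendered as "< 0.001", the way
kinetic tables print them.

**Forward solution.** The impulse response of `C1 + C2` is
`B1·e^{−α1 t} + B2·e^{−α2 t}` with

    α_{1,2} = [(k2+k3+k4) ∓ √((k2+k3+k4)² − 4·k2·k4)] / 2.

The input is taken piecewise-linear between its samples and zero before
the first. Each convolution integral over a linear segment has a closed
form; a first-order recurrence propagates the state between knots, so
the forward model is exact for the piecewise-linear input (no quadrature
error). For `α·h` below 10⁻⁴ per segment the moment integrals switch to
4-term series to avoid cancellation; a repeated eigenvalue
(`(k2+k3+k4)² = 4·k2·k4`) is handled by the confluent limit with a
`t·e^{−αt}` kernel, not treated as an error. On uniform knot grids the
recurrence has constant coefficients and is evaluated with a C-level
linear filter; non-uniform grids fall back to an explicit loop. A stiff
ODE integration of the same system serves as an independent oracle in
the tests; the two routes agree to ≤ 10⁻⁴ relative.

**Fitting.** Bounded least squares over (K1, k2, k3, k4) ∈ [0, 10]⁴ with
vB fixed (default 0.05), from eight fixed starting points spanning slow
and fast kinetics and near-irreversible corners; the lowest residual
wins, near-ties resolving toward the smaller k4. Residuals are uniform
by default; frame-duration weighting (√duration) is available by flag.
Standard errors come from the Gauss–Newton covariance at the optimum.
Fits use the nine dynamic time points (1.5–25 min); the ~45-min
whole-body point is carried in the data but not required for the fit.

## Internal dosimetry

Organ %IA is voxel sum × voxel volume over injected activity, with the
body remainder defined as whole-volume activity minus all segmented
organs. Residence times (TIACs) are computed by first expressing the
series decay-corrected, fitting `Σ Aᵢ·e^{−βᵢ t}` with Aᵢ, βᵢ ≥ 0 (one
exponential, or two when at least six samples exist, selected by
small-sample-corrected AIC), then re-applying physical decay
analytically:

    TIAC = Σ Aᵢ / (βᵢ + λ),   λ = ln 2 / 20.364 min (¹¹C).

This keeps the decay-corrected and raw interpretations of an input table
in one formula, and makes the integral exact for the fitted model (the
tests confirm agreement with adaptive quadrature to 10⁻⁶ relative). A
`trapezoid-tail` alternative integrates the decaying samples directly
with a terminal-slope tail; a growing fitted tail falls back to physical
decay only and is flagged. The bladder is integrated as a non-voiding
source — no voiding model. The summed residence time of a full organ set
is validated against the physical bound T½/ln 2 = 0.4897 h; the bound is
skipped only when no isotope half-life applies (abstract toy tables).

Organ equivalent doses are the MIRD sums `H_T = Σ_S Ã_S·S(T←S)` (for
¹¹C the radiation weighting factor is 1, so mSv/MBq equals mGy/MBq), and
the effective dose is `E = Σ_T w_T·H_T` under ICRP 60 or ICRP 103
tissue-weighting factors (bundled as CSV). A scheme tissue with no organ
dose receives the arithmetic mean of the available organ doses — the
multi-tissue remainder convention — with a diagnostic. The bundled
S-value table is a **synthetic toy phantom** (plausible magnitudes,
self-dose ≫ cross-dose); it supports engine validation and end-to-end
runs but does not reproduce any published phantom's absolute doses.

## SUV quantification

Volume space is mm with the origin at the corner of the first voxel and
centers at (i+0.5)·spacing. A voxel belongs to a sphere iff its center
is inside or on the boundary — the simplest rule with an analytic voxel
count to test against. SUV uses body-weight normalization only:
`SUV = C·weight(g)/injected(Bq)`. SUVmax is the hottest voxel in the
VOI; SUVpeak is the mean over a fixed 1-cm sphere centered on that
voxel's center (ties broken toward the lowest linear index). The peak
sphere may extend beyond its parent VOI; only clipping by the volume
edge is flagged. Strict mode enforces the study's class diameters:
50 mm joints, 20 mm blood pool, 10 mm background. No partial-volume
correction is applied anywhere.

## Cohort statistics

Summaries are mean, sample SD (n−1), min, max. The group comparison runs
a one-way ANOVA across VOI classes at each time point, then pairwise
pooled-variance t tests of the affected joint against each other class,
Sidak-adjusted over the pairs tested at that time point
(`p_adj = 1 − (1−p)^m`). Stars: \* < 0.05, \*\* < 0.01, \*\*\* < 0.001,
\*\*\*\* < 0.0001. Whether to pool time points is a genuinely open
design choice; per-timepoint testing is the default because the uptake
contrast is strongly time-dependent.

## Synthetic data

The generator's defaults encode the acquisition and biology the
analyses assume:

* **Input function** — tri-exponential bolus
  `ΣAᵢ·e^{−rᵢ(t−d)}` with A = (40000, −20000, −20000) Bq/mL,
  r = (0.12, 1.2, 6.0) min⁻¹, delay 0.5 min: non-negative, zero at the
  delay, peaking so that the sampled maximum on the 1.5–25-min dynamic
  grid falls at the first frame (1.5 min), as observed for the blood
  pool.
* **Organ %IA** — normalized bateman shapes per organ: washout organs
  (lung, heart, kidney) peak before the first whole-body frame and
  decline ~2.6-fold by 81 min; the brain peaks near 40 min at ~2.4 %IA;
  the bladder fills to ~8 %IA near 60 min; the liver combines an early
  perfusion plateau with a slow component peaking near 80 min at
  ~9.6 %IA; the remainder decays from ~76 %IA. Sums over organs stay in
  (86, 98) %IA across the six frames. Curves are decay-corrected;
  noise is Gaussian with variance ∝ mean/frame-duration, truncated at 0
  (a counting-statistics proxy — no reconstruction, attenuation or
  scatter modelling).
* **Phantom** — 96³ voxels at 2 mm (default): two 5-cm joint spheres,
  a 16-mm-radius artery cylinder carrying the input function, and
  uniform muscle elsewhere. Region centers snap to voxel centers so the
  two joints voxelize congruently; the joints must clear each other by
  ≥ 10 mm so a 1-cm peak sphere seeded in one VOI cannot sample the
  other. Joint tissue curves come from the 2TC forward model driven by
  the **frame-sampled** blood curve — the same image-derived input the
  downstream fit uses — so noiseless end-to-end parameter recovery is
  exact by construction. Default joint kinetics
  (K1 = 0.3, k2 = 0.2, k3 = 0.5, k4 = 0.02, vB = 0.05) give a tissue
  curve that rises monotonically over the dynamic grid, peaks at the
  25-min frame and declines by the ~45-min point, with ~2% margins.
  The affected joint is the contralateral curve scaled by
  `joint_contrast` (default 1.5); muscle is the affected curve divided
  by `background_contrast` (default 6). Subject defaults sit at the
  cohort means (84 kg, 614.5 MBq).
* **Seeding** — one integer seed; each consumer draws from a named
  `SeedSequence`-derived stream, so outputs are bit-identical per seed
  and independent across purposes.

**What passing tests show and do not show.** The phantom establishes
internal consistency — VOI extraction recovers generating curves to
voxelization error (≤ 2% for the 5-cm sphere at 2 mm), fits recover
generating rates, the dose chain is linear and bounded. It does not
establish performance on reconstructed clinical images: no point-spread
function, partial-volume effects, motion, attenuation artifacts or
metal implants near prostheses are modelled, and absolute SUV levels in
patients are not reproduced — only the printed group-mean contrast
ratio (~1.5× affected vs unaffected) is carried as bundled reference
data.

## Problem sizes

Default test and acceptance runs use the study's own grids: 9-point
dynamic fits, 6-point dosimetry series, 96³ phantoms, and 100 Monte-
Carlo replicates at 5% noise for the VT-recovery study — sizes chosen
to keep a full run on a laptop-class single core in minutes.

## Known limitations

* No Logan/Patlak graphical methods, spectral analysis or metabolite
  correction.
* No voxel-level dosimetry or specific-absorbed-fraction computation;
  published-phantom absolute doses require external S-value tables.
* No automatic VOI placement or registration; segmentation masks are
  inputs.
* The %IA table interpretation (decay-corrected vs raw) is a flag the
  caller owns; the bundled reference table defaults to the
  decay-corrected reading.
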