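# Methods

This note records the model assumptions, numerical choices and study
conditions behind `climbfocus`, in the spirit of a methods section: enough
detail to reproduce or criticise every decision.

## Focus evaluation function

The sharpness of a frame is the population variance (divisor N) of the
discrete Laplacian over the image interior. The 4-neighbour stencil
`[[0,1,0],[1,−4,1],[0,1,0]]` is the default; the 8-neighbour variant is a
flag. The one-pixel border, where the stencil would run off the image, is
excluded from N rather than padded — padding conventions contaminate the
variance with edge artefacts, and excluding the border makes N well defined.
Integer images are promoted to float64 before filtering to avoid wraparound.

Denoising is a constant-background subtraction: the 10th percentile of the
pixel intensities is subtracted and the result clipped at zero. A constant
model is the simplest member of the "linear background" family; the 10th
percentile is robust to sparse bright signal (beads, puncta) while tracking
the camera offset. The estimator is a parameter, so a planar or other fit
can be slotted in. For brightfield images the subtraction is disabled
(`denoise=False`): contrast there is bidirectional and a dark-level
subtraction is not meaningful.

Two exact invariances pin the implementation: adding a constant to the image
leaves σ² unchanged (the Laplacian annihilates constants), and scaling the
image by a scales σ² by a².

## Search controller

* **Direction**: least-squares line through the first five (z, σ²) points;
  slope > 0 keeps the probe direction, otherwise the climb reverses,
  returning to the start position and reusing the start sample. Five points
  average out noise that flips two-frame comparisons at large defocus.
* **Local slope** ("first-step fit"): quadratic least squares over the
  trailing ten samples, evaluated at the newest z. The fit is computed in
  z − z̄ for conditioning; the derivative is unaffected.
* **Refinement**: the step is halved when, for three consecutive slope
  evaluations, |S| ≤ T_fix *and* |S| ≤ T_dyn. "Reach the threshold" is read
  as the magnitude falling into the plateau band (≤), since the fixed
  threshold detects the approach of a plateau and the dynamic one demands a
  still-shrinking slope. T_dyn uses the population (÷3) standard deviation of
  the three preceding slopes, matching the population convention of σ²; the
  slope being tested is excluded from its own threshold. After a halving, the
  three qualifying points must all be post-halving (pre-halving slopes may
  still feed T_dyn). At most two halvings occur.
* **Termination**: three consecutive *strictly* decreasing sharpness values.
  Ties do not count, so noise plateaus cannot stop the climb prematurely.
* **Final fit** ("second-step fit"): degree-2 polynomial in the Legendre
  basis over z mapped to [−1, 1]. The orthogonal basis keeps the normal
  equations well conditioned; the vertex of the equivalent monomial form is
  the predicted focus. A fit is degenerate — and the best measured plane is
  used instead — when the curvature is non-negative, the system is
  rank-deficient, or the vertex falls outside the sampled range; the stored
  fit-peak value is always clamped to the sampled range.
* **Fit window selection**: the fit uses the ten acquired samples nearest in
  z to the best measured sample. On the normal forward climb these are
  exactly the final ten search points. The distinction matters only when the
  search starts within a step or two of focus: the probes then straddle the
  peak, the line fit (legitimately) reports "decreasing" and the reversed
  climb walks downhill and terminates after three steps. Fitting the literal
  last ten points would regress a receding downhill tail (bias up to
  ~0.8 μm in simulation) while discarding the probe samples that bracket the
  peak; the nearest-window choice uses them and keeps the near-focus error
  at the few-tens-of-nanometre level of the far-start case.
* **Range guard**: the total traversed span is capped by `max_range_um`;
  exceeding it raises an error carrying the full trace. Stage travel limits
  are enforced by the adapter and propagate as hardware errors.
* **Timing**: each run records the four wall-clock components — direction
  determination, image capture, stage movement, algorithm processing — and
  their total.

The baseline controller with a preset absolute sharpness threshold (halve
once σ² ≥ 2000) is retained for benchmarking only: it never refines on dim
fields whose peak sharpness stays below the threshold and refines far from
focus on bright ones, which is precisely the failure mode the slope
thresholds remove.

## NIQE error check

The standard construction: MSCN coefficients from a 7×7 Gaussian-weighted
local mean/deviation window with stabiliser c = 1; paired products in four
orientations; AGGD moment-matching fits (shape α inverted through the
generalised-Gaussian ratio function on a grid α ∈ [0.2, 10], step 0.001);
18 features per scale (2 for the MSCN fit, 4 × 4 for the products), two
scales (the second from 2×2 block averaging), 96-pixel patches tiled on the
full-scale grid. Training pools the sharpest 75 % of patches per image
(ranked by mean local deviation) and summarises them by sample mean and
covariance; the score of a test image is

    sqrt( (ν₁−ν₂)ᵀ ((Σ₁+Σ₂)/2)⁻¹ (ν₁−ν₂) )

with a pseudo-inverse when the pooled covariance is singular. Exact score
ties prefer the measured peak: it is empirical evidence, while the fitted
peak is a model extrapolation.

NIQE scores are comparable only under a single model. The bundled model
(`data/niqe_model_synthetic.json`, regenerable with
`scripts/train_default_niqe_model.py`) is trained on 16 seeded synthetic
textures with a 1/f^1.2 amplitude spectrum — natural-scene-like second-order
statistics with no external data dependency. For real micrographs, retrain
on in-domain pristine images (`climbfocus niqe train`); the acceptance
properties are deliberately orderings (sharp vs blurred), not absolute
scores.

## Restoration

The Born–Wolf widefield PSF is evaluated from the scalar diffraction
integral by Simpson quadrature with 257 nodes over the aperture coordinate —
convergence was checked against finer grids; the model is aberration-free
and hence exactly even in defocus. Richardson–Lucy uses the multiplicative
update with circular (FFT) convolution and a 10⁻¹² floor in the divisor.
Periodic convolution makes flux conservation exact (total intensity of every
iterate equals the data total), which the tests assert at 10⁻⁶ relative; no
edge-taper pre-padding is applied in the core for that reason — callers with
strongly non-periodic content can pad before calling. 20 iterations is the
default, balancing restoration against noise amplification. Stack assembly
takes the trailing run of constant-spacing frames from the trace (up to the
fit window) and rejects uneven spacing rather than interpolating.

## Virtual microscope and study conditions

Each emitter renders as a 2-D Gaussian with width
σ(dz)² = σ_e² + σ₀²(1 + (dz/z_R)²), where σ₀ = 0.21 λ/NA is the in-focus
spot, z_R = n λ/NA² the axial scale and σ_e the emitter's physical size;
peak amplitude falls as 1/σ² so flux is conserved (blurring is periodic
across the field, making conservation exact). This hyperbolic-width model
produces a unimodal sharpness curve, locally quadratic at the peak and even
in defocus — the regime the search is designed for — without the cost of a
full diffraction model; restoration tests use Born–Wolf blurring where
self-consistency with the deconvolver matters. The camera adds a 100-count
offset, Poisson shot noise on the signal and Gaussian read noise
(σ = 2 counts), clipped to 16 bits. One top-level seed plus a per-capture
counter makes every acquisition reproducible.

Standard conditions used by the tests and the acceptance script:

* **Default path**: 10×/0.2 detection with 13 μm (2×2-binned) camera pixels
  — z_R = 13 μm, 1.3 μm sample pixels, 384×384 frames; bead monolayer at
  0.072 emitters/μm² with 200 nm beads; photon scale 110 counts per unit
  amplitude, i.e. ≈10 peak-pixel SNR. Binning during autofocus is standard
  practice and matters here: it concentrates per-pixel signal so the
  sharpness estimator's noise floor stays well below the curve's rise across
  the whole ±20 μm search range (direction finding and the strict-decrease
  stop rule both need that margin, as real specimens provide).
* **Low-mag path** (objective-switching searches): 4×/0.1, z_R = 52 μm.
  Long-range runs use a "wide" phantom of 8 μm structures, which widens the
  sharpness curve by sqrt(1 + σ_e²/σ₀²) ≈ 7× — at a 10 μm coarse step the
  peak is then sampled as densely, relative to its width, as the default
  path samples its own. Direction-robustness trials use this path with a
  bright exposure (photon scale 1000, ≈30 peak SNR, typical for beads) and
  2 μm probe steps so that the five probes never straddle the peak at the
  5–100 μm offsets tested.
* **Figure-of-merit scenes**: dim/bright field-of-view pairs are the same
  scene with intensity rescaled so the peak sharpness is ≈1200 (below a
  2000 preset threshold) and ≈8000 (crossing it ~10 μm before focus).

The NA values were chosen so that one coarse step is ≈ z_R/13: much coarser
and the quadratic top of the curve is under-sampled (the final fit degrades);
much finer and refinement triggers many steps before the peak. These
conditions were fixed once from that geometry and the SNR analysis above.

What the simulator does *not* model: optical aberrations and PSF asymmetry
(real sharpness curves can be skewed about focus), sample drift and
photobleaching during the search, structured backgrounds, vibration, and
stage backlash/repeatability (the simulated stage is exact; the adapter
contract lets hardware report achieved positions). Passing tests therefore
demonstrate the control logic, the estimators and their numerics — not
performance on any particular instrument.

## Scale of the shipped experiments

Closed-loop acceptance properties run 50 seeded searches per condition
(tests) and 20 per condition in `scripts/acceptance.py`; direction trials
100/60; NIQE ordering 50/20 fixtures; AGGD recovery 10⁵ draws per shape.
These sizes give stable pass/fail behaviour across seeds at desk scale.

## Known limitations

* The fixed threshold T_fix inherits the instrument's sharpness units; on a
  new setup it is meaningful only after the single calibration trial that
  sets `step_pre` and `T_pre`. With the simulator's default (dim) scenes
  T_fix is deliberately non-binding and the dynamic criterion governs.
* Replay mode snaps commanded positions to the nearest recorded plane, so
  step halving should be disabled unless the stack is finer than the step.
* The AGGD shape grid bounds recoverable α to [0.2, 10]; heavier or lighter
  tails saturate at the grid edge.
* Richardson–Lucy with periodic boundaries can wrap bright structure at the
  field edge; crop or pad such stacks before restoration.
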