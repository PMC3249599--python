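# Methods

`ustex` studies a measurement problem, not a classifier: when cirrhosis
(Metavir F4) is detected from the speckle texture of B-mode liver
ultrasound, how much of the measured performance belongs to the *person*
who chose the 64×64 region of interest (ROI)?  The package implements the
whole experimental chain on synthetic speckle cohorts — the original
patient images are not publicly available — so every claim a test makes is
about the pipeline's behaviour under a known generative model, and the
model itself is documented here.

## Imaging model

Frames are modelled as a convex-probe fan: scan lines emanate from a
virtual point source above the image, and a pixel is inside the fan when
its polar coordinates about that source satisfy
`probe_radius ≤ ρ ≤ depth` and `|θ| ≤ aperture` (θ signed from the
downward vertical, negative left).  Defaults: 400×500 pixels, source 60 px
above the top edge on the central column, 30° half-aperture, 16 cm depth.
The pixel spacing is fixed at 2.62/64 = 0.0409375 cm/px so that a 64-px
ROI spans exactly 2.62 cm; this is the only choice that makes the two
nominal ROI dimensions (64 px, 2.62 cm) mutually consistent.  Windows are
half-open and 0-based: a side-64 ROI at (cx, cy) covers
`[cx−32, cx+32) × [cy−32, cy+32)` and must lie entirely inside the fan.

## Speckle and cohort generator

The generator is the package's stand-in for the study conditions, with the
cohort composition taken from the study group: 125 patients, 51 F0 / 74 F4,
and 12.97 ± 6.06 frames per patient (truncated normal on [2, 33]).

One frame is produced as follows.

1. **Reflectivity.**  A unit-mean Gaussian random field with correlation
   length `ℓ` (px) and contrast 0.5.  `ℓ` is a *patient trait*: lognormal
   around the class mean (F0: 1.5 px, F4: 4.0 px; σ_log = 0.22).  The
   trait spread is essential — with deterministic class values every
   pipeline variant separates the classes perfectly and expert skill has
   nothing left to influence.  F4 frames additionally carry a 10 %
   low-frequency reflectivity modulation (correlation length 40 px).
2. **Position-dependent quality.**  Oblique insonification decorrelates
   parenchymal speckle, so away from the beam axis and beyond the focal
   depth the class-informative field is blended into a class-*neutral*
   field (ℓ = 2.5 px); the blend weight grows linearly in `|θ|/aperture`
   (gain 5) and in depth beyond 6 cm (0.4 /cm).  The log-compressed image
   is additionally blurred (σ = 2 px) with a weight growing off-axis
   (gain 4) and with depth beyond 4 cm (0.2 /cm).  This is the mechanism
   that makes ROI *placement* matter: a poorly placed window measures
   diluted, smoothed texture.  It is also what produces depth/angle
   position effects in the statistics.
3. **Anatomy.**  Vessels (0–3 hypoechoic ellipses, reflectivity ×0.05), at
   most one acoustic shadow ray (×0.08 beyond a random depth) and the
   bright capsule arc (×4.5 at a constant radius 0.7–1.4 cm below the
   probe face) are drawn *once per patient* and re-rendered in every frame
   with small acquisition jitter.  Persistence across frames is what lets
   a fixed-position tool fail consistently for some patients.
4. **Speckle.**  The reflectivity is multiplied by i.i.d. Rayleigh(1)
   amplitude samples and log-compressed (`135 + 38·ln a`, clipped to
   8 bits).  The compression constants were calibrated once so that in-fan
   mean gray sits near 135 and the artifact detector's nominal thresholds
   separate inserted artifacts (≥ 90 % of a vessel core flagged) from
   clean speckle (< 2 % of the fan flagged).

A ground-truth artifact mask accompanies every frame.

### Simulated experts

Five ROI providers, one ROI per patient per iteration, 5 iterations.
Within an iteration all experts see the patients and each patient's frames
in the same randomized order; orders are redrawn between iterations.
Human experts (1–4) aim at the guideline target — on-axis, window top 1 cm
below the capsule — with Gaussian placement jitter, a systematic depth
bias, and an artifact-handling flaw: an ROI overlapping a ground-truth
artifact is re-drawn (up to 20 widening attempts per frame) unless the
expert overlooks it, with probability `miss`.  Experts also skip frames
they idiosyncratically dislike (p = 0.35), so two experts usually work on
different images of the same patient.  Frozen profiles:

| expert | jitter (px) | miss | depth bias (px) | give-up |
|-------:|------------:|-----:|----------------:|--------:|
| 1      | 3           | 0.02 | 0               | 0.02    |
| 2      | 8           | 0.10 | 4               | 0.03    |
| 3      | 20          | 0.45 | 16              | 0.02    |
| 4      | 32          | 0.70 | 28              | 0.08    |

These were chosen (before the acceptance suite was frozen) so that the
per-expert AUROC and ROI-count orderings reproduce the study's structure:
experts 1 ≈ 2 ≈ automatic, expert 3 lower, expert 4 lowest; humans
establish ROIs for 90–98 % of patients.

Expert 5 is the automatic tool: it detects artifacts (below), anchors a
*fixed* candidate window 1 cm below the detected capsule on the axis,
browses the frames in the shared random order and accepts the first frame
whose window — plus an 8-px guard band against focal artifacts — is
flag-free.  Patients whose persistent anatomy blocks the fixed position in
every frame are excluded; on default cohorts the tool accepts ~55–70 % of
patients, the lowest of the five providers, as in the study.

### Artifact detector

The reference detector is not published, so the tool uses a three-rule
stand-in that reproduces its behavioural contract (fixed position,
accept/reject, patient dropout):

* **hypoechoic blobs** — in-fan pixels below 0.4× the in-fan median gray,
  closed with a 3×3 structuring element and size-filtered at ≥ 30 px;
* **shadow rays** — 1° angular rays whose distal half is darker than half
  the proximal mean;
* **capsule margin** — the capsule is found as the strongest peak of the
  radial gray profile over the proximal third of the fan (the arc has
  constant radius, so a radial — not row-wise — profile is the right
  axis); the peak must exceed 1.18× the profile baseline, otherwise no
  capsule is declared.  Everything proximal of 1 cm below the capsule is
  off limits.  Out-of-fan pixels are always flagged.

## The 234-feature texture suite

Twelve families, 234 features, all total (finite on any valid input; every
degenerate case has an explicit convention).  The per-family counts are a
reconstruction — the original inventory was never published — chosen to
keep each method in its standard form while totalling exactly 234; the
registry lives in one file so alternates are a one-line edit.

* **First-order statistics (6)** — 256-bin histogram mean, SD, skewness,
  kurtosis (population moments; 0 at zero variance), energy Σp², entropy
  −Σp log₂p.
* **NGTDM (5)** — Amadasun–King coarseness, contrast, busyness,
  complexity, strength on 32 gray levels, 3×3 neighbourhoods, interior
  centers; denominators guarded by 1e−12.
* **GLCM/Haralick (104)** — 13 classic Haralick features × distances
  {1, 2} × angles {0°, 45°, 90°, 135°}, 32 levels, symmetric, normalized.
  Diagonal displacements scale the unit offset (distance 2 at 45° means
  (−2, +2)); the matrix is built in-house because the obvious library
  routine rounds `d·sin θ` per axis and collapses that displacement to
  (−1, +1).  Conventions: correlation 0 at zero marginal variance, IMC1 0
  when `max(HX, HY) = 0`, IMC2 clipped at 0; logs base 2; sum variance is
  taken about the sum average.
* **Multiresolution fractal (5)** — fBm increment model: mean absolute
  gray difference over all pixel pairs at Chebyshev distance k ∈
  {1, 2, 4, 8}; local Hurst slopes between consecutive lags and a global
  least-squares slope give FD = 3 − H (clipped to [2, 3]) plus the fit
  intercept.  Flat input → (2, 2, 2, 2, 0).
* **Differential box counting (1)** — grids s ∈ {2 … 32}, box height
  256·s/64, cell count `ceil(max/h) − ceil(min/h) + 1`; FD = slope of
  log N vs log(1/s), clipped to [2, 3].
* **Morphological/blanket (4)** — upper/lower blankets grown with a 3×3
  cross for ε = 1…8; A(ε) = (V_dil − V_ero)/2ε; FD = 2 − slope, global
  plus local fits on ε-triplets (1,2,3), (3,4,5), (6,7,8).
* **Fourier power spectrum (14)** — windowless 2-D spectrum, DC removed;
  8 equal-width radial rings (4 cycles/image each, corners folded into
  the last) and 6 angular wedges of 30° (half-plane symmetry); each
  feature is band power over total non-DC power, so each group sums to 1.
* **Gabor bank (48)** — 4 center frequencies (0.05–0.4 cy/px) × 6
  orientations (0°–150°), ≈ 1 octave, as analytic Gaussian envelopes
  built directly in the frequency plane with the DC bin zeroed (hence
  exactly offset-invariant); features are mean and SD of the response
  magnitude.  Filtering is circular (full-patch FFT).
* **Laws energies (25)** — 15×15 local-mean removal, the 25 outer
  products of L5/E5/S5/W5/R5 applied by correlation (reflected borders),
  mean |response| over the valid interior.  The first vector of a pair
  filters along rows, the second along columns.
* **Edge co-occurrence (13)** — Sobel magnitude quantized to 16 levels
  over [0, max], distance-1 co-occurrence averaged over the four angles,
  then the 13 Haralick features.  Invariant to gray inversion.
* **Phase congruency (5)** — log-Gabor quadrature bank (4 scales, min
  wavelength 3 px, mult 2, σ_onf 0.55; 6 orientations), Kovesi-style
  energy-over-amplitude with the noise threshold estimated from the
  finest scale (k = 2); map clipped to [0, 1].  Features: mean, SD,
  skewness, kurtosis, edge density (PC > 0.5).
* **Texture feature coding (4)** — per interior pixel, the signs (± with
  tolerance Δ = 2) of the gray change to the two opposite neighbours
  along each of the 4 scan directions classify the direction as
  no-change / partial / monotone / extremum; the pixel code is the sum of
  the four classes.  Features: coarseness (mean no-change fraction),
  homogeneity (all-quiet pixels), mean convergence (extremum fraction),
  code variance.  The published coding is only sketched; this is a
  defined reconstruction with a brute-force oracle in the tests.

## Selection, evaluation, statistics

**CFS under subsample-and-exclude.**  Per round, k = 10 class-balanced
rows are *moved* out of each of the S instance sets (pool size S·k; 250 in
the full design); correlation-based feature selection (best-first forward
search on the merit `m·r̄_cf / sqrt(m + m(m−1)·r̄_ff)`, absolute Pearson /
point-biserial correlations, stop after 5 non-improving expansions,
registry-order tie-breaks) runs on the pool alone, and the source sets —
pooled rows excluded — are filtered to the selected features.  Rounds are
independent redraws from the original sets.

**Evaluation.**  Features are min-max normalized to [0, 1] with
coefficients fitted on the training part only (zero-range features map to
0; test values are not clipped).  The classifier is an L2-regularized
logistic model (C = 1; a linear SVM is available as a sensitivity switch).
Performance is the AUROC of the *pooled* prediction vector of one
stratified 10-fold CV pass, computed from the Mann–Whitney U statistic
with midrank ties, averaged over 10 random refolds (per-fold AUROC
averaging is deliberately not offered).  Sets too small for the requested
folds fall back to fewer folds with a logged warning.

**Transfer scenarios.**  Scenario 1 trains on one iteration's set and
tests on every other iteration of the same expert (the automatic expert is
excluded: its fixed placement re-selects the same patients and would
positively bias the reading).  Scenario 2 trains on one expert and tests
on every other expert; by default train and test iterations differ —
pairing equal iterations would let the shared frame order leak nearly
identical patches across experts, and the published protocol does not fix
the pairing.  The humans-only cross-expert mean is reported alongside the
all-expert mean so it can be compared with scenario 1 on the same expert
population.

**Statistics.**  Two-way additive ANOVA (type-II sums of squares — the
layout is mildly unbalanced because the automatic expert covers fewer
patients) of mean AUROC against expert and selection round; Tukey HSD on
the expert factor; tie-corrected Kruskal–Wallis per scenario; Pearson
correlations of the per-(expert, iteration) mean ρ and θ of the ROI
centers with mean AUROC (25 points in the full design); and one-way
ANOVAs of mean Ox/Oy across AUROC tertiles (a reconstruction — the
grouping behind the published one-way ANOVA is not stated), with the
automatic expert excluded since its position never varies.  Significance
is read at α = 0.01 with the secondary 0.05 level reported alongside.

## Problem sizes

The full design (125 patients, 5×5 sets, 20 rounds, 10×10-fold CV) is
hours of compute; two presets scale the sizes, never the algorithms:
`ci` (48 patients, 5 iterations, 5 rounds, 3 repeats; a few minutes) and
`mini` (40 patients, ~5 frames/patient, 3 iterations, 3 rounds, 3
repeats; ~20 s), used for multi-seed sweeps.  The acceptance script runs
the `ci` preset.

## What the synthetic cohorts do and do not show

Passing tests demonstrate that the *pipeline* reproduces the study's
structure when the generative model contains the corresponding mechanisms:
a weak patient-level texture signal, position-dependent image quality and
persistent anatomy.  They do not validate the speckle model against real
livers — the mapping from Metavir stage to speckle statistics is a
modelling choice, the effect sizes are calibration constants of this
package, and absolute AUROC levels are not comparable with the clinical
values.  The texture-bank harness accepts externally supplied texture
images (`validate-textures --images-dir`) for validation against real
material.

## Known limitations

* No beamforming, RF simulation or attenuation modelling beyond the
  shadow artifact and the phenomenological position-quality terms.
* The artifact detector is a behavioural stand-in, not a reimplementation
  of the unpublished reference method.
* The per-family feature counts summing to 234 are a reconstruction, not
  the original inventory.
* DICOM support extracts the 8-bit pixel grid only; geometry always comes
  from configuration.
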