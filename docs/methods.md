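# Methods

## The measurement model

A multispectral acquisition produces, per sample area, one grayscale image
per spectral channel plus a brightfield image (a "data block"). A channel
is an excitation line (±5 nm) paired with an emission bandpass. The default
table is a grid of 7 excitation centers {340, 370, 400, 430, 460, 490,
510 nm} × 6 emission bands {420–460, 460–500, 500–540, 540–580, 580–620,
610–650 nm}, keeping only pairs whose emission band lies strictly above the
excitation center — exactly 34 channels spanning Ex 340–510 / Em 420–650.
Instrument-specific band lists can be supplied as a JSON/CSV sidecar; the
grid is a documented stand-in, not a claim about any particular microscope.

Cells are segmented manually on the brightfield image; masks are stored as
a single 16-bit label image per block (0 = background), which makes
disjointness structural.

## Synthetic cohorts

The generator emulates everything upstream of the analysis so the chain is
testable end to end with known ground truth:

* **Fluorophores** have separable Gaussian excitation/emission profiles
  (no vibronic structure). The response of fluorophore *f* in channel *c*
  is `brightness × exp(−(exc_c−μ_x)²/2σ_x²) × [Φ((em_hi−μ_m)/σ_m) −
  Φ((em_lo−μ_m)/σ_m)]` — deterministic, additive over emission partitions.
  Defaults are an NADH-like (350/45, 460/50 nm) and a FAD-like
  (450/45, 535/50 nm) species.
* **Cells** are non-overlapping ellipses (rejection-sampled placement with
  a 2 px guard band) with a smooth multiplicative intra-cell texture
  (SD 10%) so SD/skewness features are non-degenerate.
* **Hierarchy**: group-mean abundances × a per-patient log-normal
  multiplier (σ = 0.15 by default, drawn per fluorophore — this is what
  creates the within-patient correlation that grouped cross-validation must
  respect) × per-cell log-normal variation at CV 0.2.
* **Optics/sensor**: a radial-quadratic illumination field (1 at center,
  1−g at the corner, g = 0.3, shared across channels), per-channel
  background fluorescence also under the illumination field, Poisson shot
  noise, dead pixels (2×10⁻⁴, drawn once per block — camera defects are
  common across channels) and saturated pixels (1×10⁻⁴ per channel, clipped
  at a 16-bit full well).
* **References**: water frames `Poisson(bg × illum)` and calibration-fluid
  frames `Poisson((bg + R_c·gain) × illum)`, where `R_c` is the exact
  spectrum of the simulated NADH+FAD calibration fluid (30:18 abundance,
  matching the 30 µM / 18 µM mixture) plus a weak broadband baseline
  (solvent/optics background). The baseline keeps `R_c` bounded away from
  zero on all 34 channels; without it, grid channels far from both
  fluorophores' peaks would be uncalibratable by construction.

Cohort defaults mirror the study scale: 3 groups × 10 patients, 3–8 cells
per patient (~160 cells), 1024×1024 fields. The default group means differ
in NADH-like/FAD-like balance (ATN 130/55, REJECTION 95/80, IFTA 115/65),
graded so acute injury vs rejection separates most easily — a choice of
plausible redox-shift structure, not a fit to any dataset. Tests and the
acceptance script use proportionally scaled cohorts (96–128 px fields,
2–5 patients per group, 8–13 px cell radii) with the same spectral and
noise structure.

What the generator does **not** model: optical PSF blur, photobleaching,
cell occlusion or clumping, segmentation error, spectral channel cross-talk
beyond the Gaussian tails, and any real biological heterogeneity beyond
log-normal abundance spread. Passing tests therefore demonstrate the
*pipeline's* correctness and statistical calibration, not clinical
performance on real cells.

## Calibration

Order of operations: 3×3 median filter (removes isolated dead/saturated
pixels exactly), Gaussian smoothing (σ = 1 px), per-pixel subtraction of
the smoothed water frame, division by a unit-mean flat field, then a scalar
alignment so the calibration fluid's spatial mean equals its
spectrofluorometer reference value:

    b_c = smooth(water_c)
    F_c = smooth(calib_c − water_c, σ_flat) / mean(·),   floored at 0.05
    k_c = R_c / mean(calib_c − water_c)
    out = max(0, smooth(in) − b_c) / F_c × k_c

Background is kept as a per-pixel image (the water frame carries the same
illumination field as the data, so background and unevenness are handled
jointly). The flat field is smoothed harder (σ_flat = 4 px) than the data:
illumination fields are spatially smooth by nature, and the extra averaging
is what pushes the per-channel field estimate above 0.99 correlation with
the true field in photon-rich channels; in channels with only a few counts
of calibration excess the estimate is proportionally noisier, which is a
physical limit, not an implementation artifact. Negative intensities after
subtraction are clamped to zero (fluorescence is nonnegative); the clamp
sits at the noise floor and is the only nonlinearity in the chain, so
linearity holds for signals above background. Calibrating twice is an
error rather than a no-op.

Channels whose mean calibration excess is nonpositive raise an
"uncalibratable channel" error naming the channel — better loud than a
silently negative scale.

## Features

Per cell and channel: arithmetic mean, population SD (divisor *n*), and
Fisher–Pearson skewness g₁ = m₃/m₂^{3/2} with population moments (g₁ := 0
when m₂ = 0); plus all ordered channel-mean ratios (μ_i+ε)/(μ_j+ε) with
ε = 10⁻⁶ × the block's global mean intensity (recorded in the table
metadata). Both ratio orientations are emitted since selection may prefer
either. Total 3C + C(C−1) features; 1224 for the 34-channel default.
Families are individually switchable through the catalog. Sample-moment
(n−1) conventions would differ by ~2% at typical cell areas; population
moments are used and documented so external tables can be compared under
either convention.

## Feature selection

Information gain of a continuous feature is the drop in class-label Shannon
entropy under the best binary threshold, searched exhaustively over
midpoints between consecutive distinct sorted values (an equal-frequency
multi-bin discretisation is available via config). This makes IG invariant
to any strictly increasing transform of the feature and bounded by H(Y).
Ranking ties break lexicographically by feature name, so runs are
reproducible. A greedy pass admits features in rank order unless their
absolute Spearman correlation with an already-selected feature exceeds 0.95,
stopping at k = 8.

Selection placement defaults to *inside* each training fold (leakage-safe).
A global mode — one selection on all cells before cross-validation — is
available to mirror the common fixed-feature-set workflow, and its results
are labelled optimistically biased in the status field.

## Classification and evaluation

Method 1 is a random forest (500 trees, √p features per split, unlimited
depth, fixed seed). Method 2 is a registry-based backend interface for
automated model selection; the repository ships only a logistic-regression
baseline behind it, and an absent or failing backend is recorded and
skipped, never fatal. Scores are test-fold class probabilities.

AUC is computed by the rank (Mann–Whitney) statistic with ties counted ½ —
identical to the trapezoidal area under the step ROC. Five-fold CV is
stratified by class; the per-fold AUCs give the mean, sample variance, and
a 95% CI `mean ± t₀.₉₇₅,ₙ₋₁ √(var/n)`. Pooled ROC curves are emitted for
plotting only; all metrics come from per-fold AUCs. Cell-level folding is
the default; patient-grouped folding assigns each patient's cells to one
fold, dealing each class round-robin from fold 0 so test folds stay
class-balanced (a fold count infeasible for the patient count fails loudly
as an empty fold). Patient grouping is recommended whenever patient random
effects are plausible — see the leakage benchmark below.

## Validation benchmarks (`autofluor.benchmarks`)

* **Planted effect** — two groups identical except for three independent
  narrow-band markers (Ex370Em480, Ex430Em560, Ex490Em630 regions), each
  doubled in abundance in one group. Marker widths are chosen analytically
  so exactly those three channels exceed the 10% relative-difference
  informativeness margin and the expected shifts are balanced (~0.25–0.46
  relative). Selection recovery is benchmarked on the per-channel *mean*
  features, where the channel↔feature map is one-to-one: with the full
  catalog, ratio features that cancel cell-brightness variation can
  legitimately outrank raw means, and means informative through one shared
  fluorophore would be mutually redundant under the Spearman filter —
  three *independent* markers avoid conflating recovery with redundancy.
* **Null cohort** — identical generative parameters in both groups with the
  patient effect switched off (~50+50 exchangeable cells). This isolates
  classifier calibration: with a handful of patients per group, realised
  patient effects create genuine in-sample group differences, which is
  precisely the separate leakage phenomenon below, not a calibration error.
* **Leakage demonstration** — no group effect, strong patient signatures
  (log-normal σ = 0.4, 4 patients per group). Cell-level CV with global
  selection inflates the AUC relative to patient-grouped CV; both arms use
  4 folds (8 patients → 4 class-balanced folds).
* **Gaussian shift** — one feature, class B shifted by δ; the population
  AUC is Φ(δ/√2) in closed form (0.921 at δ = 2), checked against the
  measured five-fold mean at 60+60 cells within the fold-derived CI.

## Numerical and degenerate-input conventions

Zero-variance pixel sets have skewness 0; constant features have IG 0;
rank-correlation against a constant column counts as non-redundant (ρ = 0);
AUC requires both classes in every scored fold; flat fields are floored at
0.05 to keep division defined; all seeds are explicit and every stochastic
path flows from a single configured seed, making cohort generation and the
full pipeline byte-deterministic under repetition.

## Known limitations

The default 34-channel grid and fluorophore parameters are plausible
stand-ins, not instrument calibrations. The between- vs within-patient
variance ratio of real cohorts is unknown; the defaults state a structure
rather than fit one. Only per-channel intensity alignment is implemented —
no spectral-response correction across channels and no spectral unmixing.
No morphology/texture features beyond the four spectral families. Binary
comparisons only; no three-way classifier.
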