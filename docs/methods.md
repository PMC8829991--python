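# Methods

This note records the model, its assumptions, the defaults that matter, and
the design choices made where the design was genuinely open.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Screening model

The screening task is binary: osteoporosis vs normal BMD, with the label an
input (it comes from DXA, the clinical gold standard; the package never
computes it).  The model is hierarchical because real cohorts are nested —
almost everyone has demographics, many have routine laboratory results, few
have a usable CT.  Three layers use, respectively, demographics;
demographics + laboratory values; and clinical data + CT texture features.
Shape features of the inter-trabecular space are extracted, audited and
reported, but feed none of the layers: in layered evaluation the texture
block alone carried the image signal, and adding shape did not help, so the
third layer is clinical + texture.  A subject is routed to the highest
layer whose inputs are complete; layers are trained and evaluated
independently.

## Image descriptors

Inputs are 64×64 8-bit mid-sagittal vertebral ROIs (L1–L4), either
pre-windowed BMP/PNG or DICOM rescaled and windowed at width 1500 / level
300 HU.  Windowing maps `[level−width/2, level+width/2]` linearly onto
[0, 255] with round-half-up — the half-up rule is chosen purely so the map
is bit-exactly testable.  Resizing is bilinear with the same rounding.

* **GLCM (10 values).**  Unit distance, all 256 gray levels (no
  re-quantisation), accumulated symmetrically so the four orientations
  0°/45°/90°/135° cover all eight neighbours.  Statistics on the normalised
  matrix: entropy (bits), energy Σp² (the angular second moment), contrast,
  correlation, homogeneity Σp/(1+|i−j|).  Each is summarised by its mean
  and population SD over the four orientations.  Degenerate case: a
  constant image has a single-cell matrix; its correlation is defined as 1
  so feature tables stay NaN-free.
* **Gradient (4 values).**  Mean, population variance, skewness and
  non-excess kurtosis of the Sobel gradient magnitude (integer kernels,
  reflected borders; central differences available as an option).  A
  zero-variance gradient field returns 0 for skewness and kurtosis.  The
  scalar-moment reading of "gradient information" is a deliberate choice; a
  joint gray/gradient co-occurrence matrix would be a different descriptor
  family with its own parameter set.
* **Histogram (6 values).**  Moments of the 256-bin gray-level
  distribution plus energy Σh² and entropy (bits).

* **Shape (28 values).**  Within the cancellous mask only — cortical bone
  is brighter and would drag the threshold — Otsu's criterion picks the
  integer threshold t ∈ [0, 254] maximising between-class variance of
  {≤t} vs {>t} (exhaustive sweep; ties to the smallest t).  The
  *below*-threshold class is the marrow space (darker than the struts).
  Its 8-connected components of ≥ 5 px (smaller specks have ill-defined
  perimeter and moments) are measured by 14 parameters; each is summarised
  over regions by mean and population SD.  Perimeter follows the
  region-properties boundary-length convention of scikit-image, frozen by a
  unit test (4·(n−1) for an axis-aligned n×n square): perimeter conventions
  differ between packages and determinism matters more than the choice.
  The minimum-area bounding rectangle is the *rotated* one, computed from
  pixel-corner point sets so an axis-aligned square scores rectangularity
  exactly 1; 1-pixel-wide regions get their width floored at 1 px.  Hu
  moments are reported raw (no signed-log transform) — downstream min–max
  scaling absorbs the magnitude disparities.

Since manual cortical segmentation is unavailable, the cancellous mask is a
fixed-margin erosion of the ROI extent (default 10 % of the short side,
configurable).  This is a deterministic proxy, not an anatomical
segmentation.

Per subject, every one of the 48 per-vertebra descriptors is aggregated
across the 1–4 intact vertebrae by mean and population SD: 96 image
features.  A vertebra with no surviving marrow region contributes texture
but is excluded from shape aggregation rather than contributing fabricated
zeros.  Fractured vertebrae are represented by simply omitting their ROI
file.

## Selection ledger

Stages run in the order ICC → univariate → correlation → protocol
(configurable); ICC is placed first because it is a label-free data-quality
gate.  Every feature receives exactly one verdict with its statistics.

* ICC(2,1) — two-way random effects, absolute agreement, single measure —
  across repeated segmentations; keep iff ICC > 0.8.  Image features only.
* Mann–Whitney U, two-sided, tie-corrected normal approximation (numeric);
  Pearson χ² without continuity correction (nominal); keep iff p < 0.05.
  No multiple-testing correction, deliberately: the design filters on raw
  p-values, and the type-I consequence (≈ α of pure-noise features kept) is
  measured by a calibration test rather than corrected away.  Columns that
  are all-tied get p = 1 explicitly (the normal approximation divides by
  zero there).
* Correlation pruning: pairs with |r| ≥ 0.8 visited in descending |r|;
  from each still-alive pair, the member with the larger univariate p is
  dropped (ties: lexicographically later name).  The survivor set provably
  contains no high-correlation pair, and the rule keeps the more
  discriminative member.
* Kruskal–Wallis across tube-voltage groups (≥ 2 members each), image
  features only; p < 0.05 means the feature tracks the scanner protocol
  and is dropped.  With fewer than two usable groups the stage is a logged
  no-op.

## Classifier bank

Grids (all configurable; listed least-complex-first so grid-search ties
resolve to the simplest candidate) — **default**: LR C ∈ {0.01…100}; SVM
C ∈ {0.1…100}, γ ∈ {scale, 1e−3, 1e−2, 1e−1}; ANN hidden ∈ {16, 32, 64};
RF trees ∈ {100, 300}, depth ∈ {∅, 5, 10}; XGB trees ∈ {100, 300},
depth ∈ {2, 4, 6}, lr ∈ {0.05, 0.1}.  A **compact** preset (LR 3, SVM 4,
ANN 1, RF 2, XGB 4 candidates) trades grid resolution for runtime and is
the preset used in the large repeated simulations below.

Selection metric is ROC AUC under stratified tenfold CV on the training
split only.  Min–max scaling is applied to LR by default (it is
scale-sensitive); extending it to SVM and ANN via `scaled=("LR","SVM","ANN")`
is recommended and used in the repeated evaluations — an unscaled RBF or
MLP on features spanning four orders of magnitude cannot train usefully.
The ANN is a single-hidden-layer MLP optimised with lbfgs: at cohort scale
(a few hundred subjects) a stochastic optimiser with an early-stopping
validation split of ~10 samples halts long before the decision function
ranks the training set correctly, so full quasi-Newton convergence with L2
regularisation is the dependable choice.

Stacking builds its meta-features as out-of-fold predictions of the five
tuned bases (internal stratified 5-fold), the standard leakage-free
construction; the meta-learner is an LR over exactly those five columns.

Evaluation: five stratified 80/20 splits (per-repeat seed = seed + repeat);
per layer, the rows complete for that layer's columns; optionally the
selection ledger re-runs on each training split (leakage-safe default; the
ICC gate, being label-free, may be applied once globally instead).  One
caveat recorded here because it is easy to miss: a *stratified* splitter
necessarily reads the whole label vector to stratify, so label-scrambling
leakage audits must hold the split fixed — `evaluate` accepts precomputed
splits for exactly this purpose.

## Synthetic cohorts

The generator emulates the statistical contrasts the pipeline measures, not
bone physics.  Defaults are the study conditions:

* n = 300 subjects, prevalence 0.43.
* Age ~ N(65.67, 9.691²) osteoporotic, N(55.77, 10.066²) normal — the
  group-wise shift observed in a large clinical screening cohort.  MPS odds
  are class-dependent (osteoporotic subjects mostly post-menopausal women);
  BMI shifts −0.3 SD; 8 of 29 analytes shift 0.5 SD (direction chosen per
  analyte); the rest are pure noise.
* Images: cancellous texture = Gaussian noise smoothed at the pore scale
  (σ 1.6 px normal / 2.2 px osteoporotic), thresholded at the marrow
  fraction (0.40 / 0.52) into dark marrow (70) and bright struts (170),
  plus acquisition noise (SD 8), a cortical rim (4 px / 2 px), and an
  intensity deficit Δμ = 12 gray levels for the osteoporotic class.
* Tube voltage ∈ {80, 120, 140} kV with probabilities {0.08, 0.91, 0.01}
  — the real mix is ≈ {0.08, 0.91, 0.01} but at n = 300 the smallest group
  must still reach the protocol filter's ≥ 2-members precondition, hence
  the slight widening of the minor voltages.  Per-voltage intensity
  offsets (default 0) inject a protocol confound when wanted.
* Replicate segmentations re-crop the texture canvas with ±2 px jitter and
  re-draw the rim, emulating a second manual ROI placement.

Ground truth (class labels, which analytes are informative) is stored
beside the feature table and never enters it.  `null_cohort_config()`
zeroes every class effect; `strong_cohort_config()` doubles the image
effect so that the image-equipped layer dominates.

**What passing tests do and do not show.**  The generator produces
stationary Gaussian-derived textures, exact class-conditional distributions
and clean labels.  Real vertebral CTs have anatomy, noise spectra, scanner
physics and label noise none of which are modelled, so synthetic AUCs —
including the near-perfect layer-3 separation under the strong-effect
configuration — validate the *machinery* (no leakage, correct routing,
faithful effect dials, chance-level behaviour on null data), not clinical
performance.  Cohort-specific results such as published AUC values or
selected-feature lists are not reproducible without the original data and
are not targets of this package.

## Problem sizes and numerical choices

The repeated simulations run at n = 300 subjects, 5 repeats, all three
layers and all six classifiers with the compact grid preset; the full
default grids are exercised on smaller cohorts.  Oracle-equivalence checks
use 100 random 8×8 (GLCM) and 12×12 masked (Otsu) images; the type-I
calibration uses 200 features × 20 seeds.  Entropies are log₂; SDs are
population (ddof = 0) throughout; kurtosis is non-excess; degenerate cases
(constant images, zero-variance gradients, constant min–max columns →
0.5) are defined explicitly rather than propagating NaN.  All randomness
flows from explicit integer seeds; identical seeds reproduce every output
byte-identically.

## Known limitations

* The 35-column clinical schema is a plausible synthetic stand-in; the
  exact analyte panel of any given hospital differs and is configurable.
* The cancellous mask is a geometric erosion, not a segmentation.
* GLGM is read as scalar gradient-magnitude moments (see above).
* The protocol filter tests tube voltage only; other acquisition
  parameters (slice thickness, reconstruction kernel) are not modelled.
* Single 2-D mid-sagittal slice per vertebra; no 3-D texture.
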