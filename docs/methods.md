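# Methods

This note documents the models, numerical choices and limitations behind
`noduletex`.  It is the place where every genuinely open design decision is
recorded in the package's own terms.

## The classification problem

One CT slice of a solitary pulmonary nodule, cropped to a rectangular
region of interest (ROI), is to be classified benign vs malignant.  Each
patient contributes several ROIs (adjacent slices of the same nodule), and
clinical practice also records 19 patient variables — 7 demographic (age,
gender, smoking, tuberculosis/dust/genetic/tumour history) and 12
morphological (calcification, cavitation, uniform density, ground-glass,
lobulation, lymphadenectasis, spiculation, vacuoles, pleural indentation,
pleural fluid, substantial changes, diameter).  The pipeline compares
three feature sets: patient information alone, contourlet texture alone,
and both.

## Contourlet transform

### Laplacian pyramid

`lp_decompose` uses the difference scheme: at each scale the image is
lowpass-filtered (CDF 9/7 analysis kernel, DC gain 1) and decimated by 2
per axis; the bandpass level is the difference between the current image
and the re-expanded coarse image (zero-upsampling followed by twice the
9/7 synthesis kernel, whose polyphase sums are each 1/2, so constants are
reproduced exactly).  Reconstruction adds the bandpass back and is
therefore exact to floating precision for *any* filter pair.  The pyramid
is 4/3-overcomplete — bandpass levels for a `N×N` input have sizes `N`,
`N/2`, `N/4`, … — which is the standard structure for this transform; the
directional stage below, by contrast, is strictly critically sampled, and
the tests pin exact coefficient-count conservation through every
directional split.  Boundary handling is periodic by default (`symmetric`
is available for the pyramid).

### Directional filter bank

Each bandpass level is split into `D = 2^l` orientation subbands by a
binary tree of two-channel stages.  One stage is:

1. optional unimodular pre-shears `(i, j) → (i + s·j, j)` or
   `(i, j) → (i, j + s·i)` on the periodic grid (exact permutations);
2. fan modulation: multiply by `(−1)^i` or `(−1)^j`, which maps the
   fan-shaped half of the frequency plane onto the diamond `|ω₁|+|ω₂| ≤ π`;
3. a quincunx lifting step on the checkerboard cosets: predict the odd
   coset from the even one with a diamond interpolation kernel, subtract
   to get the detail channel, then update the even coset with half the
   same kernel;
4. relabel each coset onto a half-size rectangular grid via a sheared
   quincunx downsampling.

Because every step is a permutation, a modulation, or a lifting step, the
inverse is exact by construction regardless of the predictor, and each
split conserves the coefficient count exactly.  Only the *directional
selectivity* depends on the predictor quality.  The default predictor
(`diamond7`, with `diamond11` and the classic Neville filters also
available) is a least-squares diamond-halfband design whose symmetric
weight classes sum to one (constants are interpolated exactly).

The per-node stage parameters (shears, modulation axis, relabelling axes)
for the 2/4/8/16-direction trees were chosen by a purity-driven design
search — each node's stage must route oriented probe energy to the two
slope-half-wedges of its target and keep its children's frequency content
separable for the remaining tree levels — and then frozen as constants in
`contourlet.py`.  Wedges are uniform in *slope* (tan of the orientation
angle), the natural geometry of fan filter banks: wedge `d` of `D` covers
the slope coordinate `v ∈ [−1 + 4d/D, −1 + 4(d+1)/D)` where `v = tanθ`
for |θ| ≤ 45° and `v = 2 − cotθ` beyond.  Consequences worth knowing:

* wedge **edges** fall on the image axes for `D ≥ 4` (a perfectly
  axis-aligned grating straddles two wedges); directional tests therefore
  probe at wedge centres;
* at 8 directions every centre grating concentrates ≥ 60–100% of its
  energy in the correct wedge across the usable band;
* at 16 directions (the default 3 × 16 = 48-subband profile) the wedges
  adjacent to the ±45° family boundary have wider transition overlap:
  averaged over orientations and radii, about 55% of a centre grating's
  energy lands in the correct wedge and 70% within one wedge of it.  For
  texture *features*, which aggregate whole-subband statistics, this
  moderate leakage blurs directional resolution without breaking any
  reconstruction or sampling contract; the 8-direction profile is the one
  to use when sharp wedge attribution matters.

Inputs that are not admissible squares are zero-padded
(`pad_to_admissible`) and the original shape recorded.

## Texture features

Per subband, `mean` and `std` are first-order moments of raw
coefficients.  The remaining twelve statistics come from one pooled
symmetric co-occurrence matrix: coefficients are uniformly quantized over
their own [min, max] into G = 16 levels (a constant band maps to level
0), pairs are counted for the four unit offsets (0,1), (1,0), (1,1),
(1,−1) *and* their negations, pooled, and normalised.  Pooling keeps the
feature count at 14 per subband rather than 14 per offset.  Formulas are
the standard Haralick/Conners definitions (frozen in
`features.compute_features`); entropies are base-2 with 0·log 0 = 0, and
correlation of a zero-variance matrix is defined as 0 so constant
subbands (which arise for constant inputs) stay finite.  The canonical
column order is level-major, then direction, then the fourteen names in
the order listed in `FEATURE_NAMES`.

Whether the original analysis quantized subband coefficients, and with
what G, is not recoverable; G and the offset set are configuration here,
and the defaults are common radiomics practice.

## SMOTE and balancing

`smote_oversample` follows the original algorithm: each minority row
spawns `amount_pct/100` synthetic rows uniformly on segments to one of
its k = 5 nearest minority neighbours (Euclidean metric on the raw
feature scale; neighbours may repeat).  `balance_dataset` augments the
minority and subsamples the majority without replacement, either to an
explicit target or to the new minority size (`"match"`).  A target larger
than the majority class is an error — under-sampling cannot grow a class —
and the 300%-of-1,454 profile (5,816 minority rows) therefore cannot be
paired with a matching 5,815-row majority drawn from 4,845 rows; the
explicit-target and match modes are provided instead of guessing an
undocumented procedure.  Synthetic rows carry a `synthetic` flag and no
patient id.

Applying SMOTE to the whole dataset before cross-validation leaks
synthetic copies of held-out rows into training folds; `cross_validate`
therefore applies it within training folds by default and retains a
`whole-dataset` mode for comparison with the original design.

## Classifier and evaluation

The SVM uses the Gaussian RBF kernel with C = 1 and γ = 1/(d·var) on
features standardized with training-fold statistics (RBF distances are
scale-sensitive and the original hyper-parameters are unreported; a
fixed γ can be passed explicitly).  Metrics derive from confusion counts
pooled over held-out predictions (fold-averaged variants are not
implemented; pooling is the package's default and is stated in reports
via `n_folds`/`per_fold`).  The ROC ranking variable is the decision
value mapped through a logistic to [0, 1] ("malignant rate"); since AUC
is invariant under strictly monotone maps, any monotone reading of that
variable yields the same AUC.  `roc_auc` sweeps distinct thresholds with
trapezoidal integration, which equals the Mann–Whitney pair-counting
estimator with ties counted one half; `auc_pvalue` uses the no-tie normal
approximation to the Mann–Whitney null.

Diameter strata are A: 7–10 mm, B: 11–20 mm, C: 21–30 mm and pooled A+B,
on diameters rounded to whole millimetres (clinical diameters are
reported in cm to one decimal, so rounding is unavoidable and is
documented rather than hidden).  Strata whose class sizes cannot support
the fold count are reported as absent, never as zeros.

ROI-level stratified folds are the default, mirroring the original
design; patient-grouped folds (`grouping="patient"`) are provided because
ROI-level folds leak: a classifier can match a held-out ROI to its
patient's training ROIs (same nodule, same rendered diameter) and recover
the label without any class signal.  The package's own calibration tests
use patient grouping for exactly this reason.

## Synthetic cohorts

`generate_cohort` emulates what the pipeline consumes, not anatomy:

* every ROI is a bright disc (nodule, mean gray 100) on a darker
  background (mean 40) with soft vessel-like streaks, Gaussian noise
  (`noise_sd`, default 1 gray unit) and a 2-px sigmoidal margin;
* malignant nodules add, *scaled by* `texture_contrast`: 2–4 oriented
  sinusoidal gratings (wavelengths 4–12 px, random phases; amplitude 12
  gray units per unit contrast, split across gratings), high-frequency
  speckle, and a low-order radial margin perturbation.  At contrast 0 the
  two classes are generated by the identical process, so their feature
  distributions are exchangeable by construction — including the margin
  irregularity, which is deliberately contrast-scaled rather than
  unconditional so that the null case is a true null;
* each patient's ROIs share one rendered diameter, drawn uniformly from
  `diameter_range_mm` independently of class, so the image channel
  carries class signal only through `texture_contrast`.  The patient
  *table's* diameter variable is drawn separately from the published
  class-conditional distributions (1.80 ± 0.68 cm benign vs 2.22 ± 0.73
  cm malignant) — it models the reported clinical measurement feeding the
  "info" dataset, not the rendered pixel size;
* the 17 binary table variables use the published class-conditional rates
  (e.g. smoking 24/84 benign vs 154/252 malignant) and age the published
  moments, all overridable per variable;
* defaults are the study scale (84 benign / 252 malignant patients,
  17–20 ROIs each, 128-px crops, 7–30 mm nodules, 0.7 mm pixels); the
  test suite uses a 14/42-patient, 64-px reduction (~450 ROIs) chosen
  once as the smallest cohort at which patient-grouped AUC estimates are
  stable enough for calibration assertions.

What passing tests on these cohorts shows: the pipeline recovers known
oriented-texture signal monotonically in its amplitude, stays at chance
under the null, and combines image and tabular information without losing
discrimination.  What it does not show: performance on real CT textures,
whose class differences are subtler and not band-limited gratings; no
claim about the original study's headline numbers is made or tested.

## Numerical conventions

* Gray values are floats internally; 16-bit PNG storage uses a fixed
  linear scale (×64) recorded in `io.py`.
* Region growing is 4-connected, FIFO order, with either a running-mean
  (`adaptive`, default) or fixed seed-difference (`fixed`) criterion; the
  fixed mode is exactly a gray-band flood fill, is monotone in the
  tolerance, and is the one checked against a brute-force oracle.  The
  seed is the brightest pixel in the central 25% window; masks smaller
  than 9 px raise a segmentation-failure error.
* Quartiles use linear interpolation (numpy default); SDs of summaries
  are n−1.
* Chi-square is uncorrected Pearson (the published statistics match the
  uncorrected form exactly); the t statistic is Welch (the published age
  statistic 3.45 matches Welch, not the pooled-variance 3.57); Fisher's
  exact test replaces chi-square when an expected count is below 5.
* Per-stage seeds derive from the global seed by SHA-256 of
  `"{seed}:{stage}"` reduced mod 2³¹−1 (`pipeline.derive_seed`), so
  stages are independently reproducible.
* Monte Carlo slack in behavioural tests (monotonicity ladder, paired
  variant comparison) is a fixed 0.02 on AUC, chosen in advance from the
  binormal standard error at the fixture cohort size.

## Known limitations

* The DFB's 16-direction wedge boundaries are slope-uniform, not
  angle-uniform, and the near-diagonal wedges have the widest transition
  bands (see above).
* The DFB operates periodically; strongly non-periodic image borders
  alias energy across the frame.  ROIs here are background-zeroed crops,
  for which this is minor; the zeroed background itself biases
  co-occurrence statistics toward the (0, ·) bins, a deliberate trade-off
  for keeping the transform input rectangular.
* Patient-information and texture channels of the generator are
  statistically independent given the label; real cohorts have
  label-conditional dependence (e.g. diameter affects both), so the
  combined-dataset gain here is a best-case geometry.
* `run_study` holds the whole cohort in memory; study-scale runs
  (6,000+ ROIs at 128 px) need roughly 1 GB and tens of minutes.
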