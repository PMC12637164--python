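# Methods

## Problem and overall design

Pfirrmann grading of intervertebral disc (IVD) degeneration from T2-weighted
sagittal MRI is ordinal (grades 2–5 here, with grades 1–2 pooled), subjective
and coarse. The package implements a quantitative alternative built from 2D
radiomics: per-disc shape, intensity and texture features are extracted from
segmentation masks, screened for relevance, robustness to segmentation error
and redundancy, and fed to a sparse PLS-DA grade classifier, with the
conventional disc height index (DHI) and peak signal intensity difference
(PSID) as baselines.

Because no suitable MRI cohort is redistributable, every stage is exercised on
a synthetic phantom cohort whose grade-dependent structure is known by
construction. The phantoms are the package's ground truth: passing tests
demonstrate that the pipeline recovers a planted degeneration signal under the
stated noise and segmentation-error model, not that it reproduces any clinical
cohort's numbers.

## Synthetic phantom model

Each `DiscSample` is a small multi-slice sagittal crop: one elliptical disc
between two rounded-rectangle vertebral bodies, plus a bright CSF band
posterior to the disc column. Grade enters through four monotone encodings:

| parameter | grade 2 | 3 | 4 | 5 | unit |
|---|---|---|---|---|---|
| disc-height / vertebral-height ratio (mean) | 0.40 | 0.33 | 0.25 | 0.15 | – |
| nucleus–annulus contrast (mean) | 90 | 55 | 25 | 8 | gray levels |
| nucleus heterogeneity SD (mean) | 25 | 30 | 20 | 10 | gray levels |
| osteophyte probability | 0.05 | 0.15 | 0.35 | 0.50 | – |

Per-disc draws are Gaussian around these means with deliberately wide spreads
(height-ratio SD 0.08, contrast SD 10): disc geometry varies substantially
between individuals at the same degeneration stage, which is why height-based
indices correlate only moderately with grade in population cohorts, and the
phantom is calibrated so its per-feature grade correlations sit in that
reported range rather than near ±1. Structure size additionally follows the
caudally increasing lumbar trend (L1/L2 ≈ 0.90× to L5/S1 ≈ 1.12×) with an
individual width SD of 3.5 mm, which decorrelates size-driven features
(areas, axis lengths) from compactness features (sphericity, elongation) as
in real anatomy. Osteophytes are small anterior mask protrusions and drive
the perimeter-to-surface-ratio signal. A minority of discs carry focal
high-intensity zones — small bright foci from fluid signal in annular
fissures, most prevalent in moderate degeneration (probabilities
0.02/0.10/0.15/0.05 for grades 2–5) — which create a spurious second
histogram peak that degrades the peak-based PSID while leaving quartile-based
dispersion features essentially untouched. Pixel noise is additive Gaussian
with SD 6 clipped to [0, 255] — deliberately below the perturbation-suite
noise SD of 8 so that perturbation effects remain detectable. The default
grade mix (46.6/31.7/16.4/5.3% for grades 2–5) mirrors the population
prevalence in a middle-aged birth cohort, so classifiers face the same class
imbalance as in practice. Four slices per disc are rendered with mild
through-plane tapering.

With these choices, mean disc-mask sphericity, disc-intensity interquartile
range, DHI and PSID are all strictly decreasing in grade — the planted signal
the pipeline must recover.

As in a deployed automatic pipeline, the experiment's main feature table and
conventional indices are computed from the emulated imperfect (DL-like) disc
masks; the truth masks serve as the robustness reference. The mask emulator
low-pass filters its jittered boundary because segmentation networks produce
smooth contours; per-pixel-rough boundaries would destroy shape-feature
reliability in a way real models do not.

What the phantoms do *not* emulate: realistic MR tissue contrast and bias
fields, partial-volume effects, scoliosis and transitional vertebrae,
inter-scanner variation, or anatomically shaped vertebral endplates. Results
on phantoms therefore validate the pipeline's mechanics and internal
consistency, not clinical performance.

The imperfect-segmentation emulator (`make_dl_like_mask`) applies a small
random translation plus per-boundary-pixel erode/dilate jitter, retrying with
rescaled amplitude until the Jaccard index against truth falls in a
configurable band (default 0.75–0.90, matching reported automatic-segmentation
agreement for this task).

## Geometry

The clinical acquisition is a 280×280 mm field of view on a 512×512 matrix
(0.546875 mm/pixel), 3 mm slices with a 1 mm gap. Tests and the acceptance
script use a 70 mm / 128-pixel crop — the same pixel spacing on a
single-disc field of view — because every feature is computed inside the
disc's bounding box, so full-frame rendering adds nothing but pixels. Cohort
sizes of 300 subjects (1500 discs, with 60 discs in the robustness arm) give
stable Spearman and balanced-accuracy estimates for the recovery checks.

## Preprocessing and filter bank

Order: z-score normalization over the whole slice (×100) → twofold
up-sampling (bilinear image, nearest-neighbour mask) → filtering →
fixed-bin-width discretisation (width 16, edges anchored at
`floor(min_in_mask/width)·width`, bins from 1). Normalization uses
whole-image statistics so mask perturbations cannot leak into the intensity
scale. Whether normalization precedes or follows resampling is a stipulation;
the chosen order is fixed and documented.

The filter bank holds 8 image sets: the original, Laplacian-of-Gaussian at
σ ∈ {1, 2, 3} mm (σ expressed in pixels through the current spacing; the
truncated kernel's DC gain is removed so constant images map to zero), and
the four subbands of a single-level Haar DWT, replicated back to the input
shape so masks apply unchanged. Three LoG scales and one wavelet level are
forced by the feature-count arithmetic: 9 shape + 91 × 8 = 737 features.

## Features

- **Shape (9)**: mesh surface, pixel surface, perimeter, perimeter/surface
  ratio, sphericity 2√(πA)/P, maximum diameter, major/minor axis lengths
  (4√eigenvalue of the pixel covariance) and elongation (minor/major axis
  ratio). Mesh quantities use the half-level marching-squares contour. Note
  that this polygon overestimates smooth perimeters by up to ~5%, so a
  digital disk's sphericity tops out near 0.95; comparisons between shapes
  are unaffected.
- **First order (18)** on each filtered set; percentiles use linear
  interpolation; entropy/uniformity use the same fixed-bin histogram as the
  texture matrices; kurtosis is non-excess.
- **Texture (73 per set)**: GLCM (22; distance 1, four 2D directions,
  symmetric, features averaged over directions), GLRLM (16, direction-
  averaged), GLSZM (16, 8-connected zones), GLDM (14, zero gray-level
  tolerance, dependence = 1 + equal-level neighbours), NGTDM (5). Formulas
  follow the standard definitions; every one is locked to a brute-force
  enumeration oracle in the test suite (all 512 binary 3×3 ROIs plus random
  6×6 ROIs, tolerance 1e-9).

Per-slice values are mean-aggregated over retained slices; slices with empty
masks are dropped (mirroring screening of failed segmentations). Degenerate
cases (single-pixel ROIs, matrices with no entries) yield NaN and a per-disc
flag; flagged features are excluded from selection, never imputed.

## Perturbation suite

Six operators probe feature robustness: 2×2 dilation and erosion (the 2×2
element has no center, so the top-left anchor is fixed and the enumeration
tests are exact), per-boundary-pixel Bernoulli(0.5) contour randomization,
random 1–10 px translations and 1–360° rotations applied jointly to image and
mask, and Gaussian image noise (SD 8, clipped to [0, 255]). The suite is
seeded end to end; stochastic operators can be replicated to grow the suite
(6 operators, 10 specs at two replicates). A perturbation that empties a mask
is flagged and excluded, never silently dropped.

## Robustness screening and selection cascade

Reference features come from truth masks; perturbed features from the
emulated imperfect masks under each suite operator. Agreement is ICC(A,1) —
two-way, absolute agreement, single measurement — with the F-based 95% CI
(Satterthwaite degrees of freedom). Absolute agreement is the stricter,
standard choice for test–retest radiomics; the implementation matches
pingouin's ICC(A,1) row to 1e-9 in the tests.

The cascade order is fixed: (1) relevance — drop features whose Spearman
correlation with grade has p > 0.05 (computed on development data only, to
avoid leakage); (2) robustness — Ward-linkage clustering (k = 2) of the
per-feature ICC vectors, keeping the cluster with the higher mean ICC (k = 2
realises "the highest-ICC cluster" directly and is oracle-testable on planted
partitions; NaN ICCs are treated as non-robust); (3) redundancy — among
pairs with |Spearman ρ| > 0.90, processed in descending |ρ|, drop the
lower-variance member; (4) area adjustment — features with
|Spearman(feature, 2D mesh area)| ≥ 0.90 get a linear de-trend fitted on
development data; the stored coefficients (never refits) are applied to any
later data, returning residual + development grand mean. A ledger records
each stage's removals.

## Models

`SPLSDA` follows the statsmodels model/results idiom: the model holds the
data and hyperparameters, `fit()` returns an `SPLSDAResults` with loadings,
scores, the prediction rule and `summary()`. Components are extracted by
NIPALS on centred, unit-variance X against the centred/scaled one-hot class
matrix; per-component sparsity soft-thresholds the X weight vector at the
(keepX+1)-th largest magnitude; X and Y are deflated on the X scores.
Prediction is by maximum predicted class indicator (the `max.dist` rule —
the distance rule is not dictated by the problem, and this is the simplest
deterministic choice). With keepX = p the estimator coincides with dense
PLS2 regression on the dummy matrix; the tests pin each weight vector to the
dominant singular vector of the deflated cross-covariance (1e-8) and to
scikit-learn's `PLSRegression` (1e-3, its looser convergence tolerance).

Tuning is greedy per component: each candidate keepX is scored by mean
balanced error rate over repeated stratified 5-fold CV grouped by subject
(no participant spans folds — grouping is enforced to prevent twin-disc
leakage even though nothing forces it mathematically), holding earlier
components' keepX fixed; the component count is the BER-minimal prefix.
Stability is the per-feature selection frequency across all folds of the
winning configuration. The module-level default grid is components 1–25 with
keepX ∈ {1, 2, 5, 10, 25, 50, 100, all}; the experiment configuration uses a
smaller grid (components 1–3, keepX ∈ {2, 5, 10, all}) appropriate to the
phantom cohort's effective dimensionality.

Baselines are RBF-kernel SVMs with inverse-frequency class weights on exactly
two features: the conventional pair (DHI, PSID) and the two most stable
sPLS-DA features; hyperparameters (C, γ) by the same grouped repeated CV on
balanced accuracy.

## Conventional indices

DHI uses the area-based construction: each structure's effective height is
area / extent along its principal axis (with a pixel-corner correction that
reduces to +1 px for axis-aligned structures, keeping the estimate
rotation-invariant to ~1%), and DHI = 2·h_disc / (h_supVB + h_infVB).

PSID normalizes in-disc intensities by the mean of a 3 mm circular CSF
reference (all pixels within 1.5 mm of the CSF point), builds a Gaussian KDE
with absolute bandwidth 0.02 on the normalized scale, finds local maxima with
prominence ≥ 5% of the peak density, and reports the distance between the
brightest and darkest peak locations (0 if unimodal). Bandwidth and
prominence are package choices: the bandwidth resolves the two synthetic
compartments without splitting noise modes, and the prominence floor ignores
ripple. Both indices are computed per slice (the CSF ROI per slice) and
mean-aggregated.

## Evaluation

Balanced accuracy (mean per-class recall), macro F1, macro one-vs-rest AUC,
Cohen's kappa, quadratic-weighted kappa, and Lin's concordance on the ordinal
labels; bootstrap CIs are percentile intervals over disc-level resampling
(default 1000 resamples). Segmentation agreement: Dice, Jaccard and HD95 (the
95th percentile of pooled directed boundary-to-boundary nearest distances, in
mm), with boundary pixels defined by 4-connected erosion.

## Numerical and degenerate-input policy

- Discretisation guarantees levels 1..n inside the mask; 0 marks outside.
- GLCM correlation of a zero-variance marginal is defined as 1; NGTDM
  coarseness of a flat ROI is capped at 1e6; strength/busyness with zero
  denominators are 0.
- Zero-variance images normalize to all-zeros with a warning.
- Ties in Spearman ranks use average ranks (scipy convention).
- Empty-mask inputs raise; emptied perturbation replicates are flagged.
- All randomness flows through `numpy.random.Generator` seeds; identical
  seeds give bit-identical cohorts, suites and model fits.

## Known limitations

- Phantom realism, as above; absolute metric values on phantoms say nothing
  about clinical accuracy.
- The 22-feature GLCM subset, LoG scale set and wavelet basis are fixed by
  count arithmetic and convention rather than uniquely determined.
- The sparse-PLS soft threshold retains *at most* keepX nonzeros (exact ties
  at the threshold magnitude are all shrunk); in practice ties are measure
  zero.
- 2D features only; no 3D aggregation beyond the per-slice mean.
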