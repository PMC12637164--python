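# discradiomics

Robust 2D radiomic phenotyping of intervertebral disc (IVD) degeneration from
sagittal T2-weighted MRI — as a fully synthetic-testable pipeline.

## The problem

Pfirrmann grading (ordinal 2–5 here, grades 1–2 pooled) scores disc
degeneration visually: loss of nucleus signal and homogeneity, blurring of the
nucleus–annulus boundary, and collapse of disc height. It is subjective and
coarse. Quantitative alternatives extract features from segmentation masks of
the disc: either the two conventional indices — the area-based **disc height
index** (DHI = 2·h_disc / (h_supVB + h_infVB), heights measured as
area/extent along each structure's principal axis) and the CSF-normalized
**peak signal intensity difference** (PSID, the spread between the brightest
and darkest modes of the disc's intensity histogram) — or a full **radiomic
signature**: 9 shape-2D features plus 18 first-order and 73 texture features
(GLCM/GLDM/GLRLM/GLSZM/NGTDM) on each of 8 filtered image sets (original,
Laplacian-of-Gaussian at σ ∈ {1,2,3} mm, four Haar wavelet subbands), i.e.
**9 + 91 × 8 = 737 features per disc**, computed in 2D per slice and
mean-aggregated.

Because automatic segmentations are imperfect, features must be screened for
robustness: each feature's agreement between reference-mask and
perturbed-mask values is measured by the intraclass correlation ICC(A,1)
under six image/mask perturbations (2×2 dilation/erosion, contour
randomization, ±1–10 px translation, 1–360° rotation, Gaussian image noise SD
8). The screening cascade is: grade-relevance filter (Spearman p ≤ 0.05) →
highest-ICC Ward cluster → redundancy removal (|ρ| > 0.90, lower variance
dropped) → disc-area de-trending. Surviving features feed a **sparse PLS-DA**
classifier (NIPALS with per-component soft-thresholded loadings, tuned by
subject-grouped repeated 5-fold CV on balanced error rate), compared against
RBF-SVM baselines on the conventional pair and on the two most stable
radiomic features.

No clinical images ship with the package. A synthetic phantom generator
renders multi-slice disc crops whose grade-dependent structure (flattening,
intensity homogenization, osteophytes, focal high-intensity zones, imperfect
"DL-like" segmentations with Jaccard 0.75–0.90 against truth) is known by
construction, so every stage of the pipeline is testable end to end. See
`docs/methods.md` for the model details and limitations.

## Worked example

```python
import numpy as np
from discradiomics import (
    make_geometry, sample_phenotype, render_disc,
    extract_disc_features, indices_for_disc,
)

geom = make_geometry(fov_mm=70, matrix_size=128)   # 0.546875 mm/pixel
rng = np.random.default_rng(0)
disc = render_disc(sample_phenotype(grade=2, rng=rng), geom, rng)

feats = extract_disc_features(disc)                # 737 features
pair = indices_for_disc(disc)
print(len(feats))
print(round(feats["original_shape2D_Sphericity"], 3),
      round(feats["original_firstorder_InterquartileRange"], 1))
print(round(pair.disc_height_index, 3),
      round(pair.peak_signal_intensity_difference, 3))
```

prints

```
737
0.677 122.0
0.317 0.378
```

— the full 737-feature vector; a healthy-disc sphericity of 0.68 (flatter,
degenerated discs drop toward 0.45) with a wide intensity interquartile range
(bright heterogeneous nucleus against a dark annulus; it shrinks toward ~13
by grade 5); a disc height of ~32% of the adjacent vertebral heights; and a
nucleus–annulus histogram-peak separation of ~38% of the CSF reference
signal.

The whole experiment (synthesize → extract → perturb → screen → train →
evaluate) runs from the command line:

```bash
discradiomics all --seed 7 --outdir experiment_out
```

or programmatically through `run_experiment(PipelineConfig(...))`, which
returns a results bundle whose `summary()` tabulates balanced accuracy and
kappas for the four model variants (conventional-index SVM, top-two-radiomics
SVM, texture-only sPLS-DA, all-features sPLS-DA).

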