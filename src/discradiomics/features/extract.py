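"""Per-disc feature extraction: preprocessing, filter bank and aggregation.

For every retained slice the image is normalized (whole-image statistics),
cropped to the mask neighbourhood, up-sampled twofold, passed through the
filter bank (original + LoG sigmas + wavelet subbands), discretised per image
set and reduced to 18 first-order + 73 texture features per set; 9 shape
features come from the resampled mask.  Per-feature values are aggregated
across slices by unweighted mean, giving 9 + 91 x 8 = 737 values under the
default configuration.  Feature names follow ``<set>_<class>_<feature>``
(for example ``original_shape2D_Sphericity`` or
``log-sigma-3mm_glszm_ZonePercentage``).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from ..preprocess import (
    PreprocessConfig,
    build_filter_bank,
    discretise,
    normalize_image,
    resample2d,
)
from .firstorder import FIRSTORDER_FEATURES, firstorder_features
from .shape2d import SHAPE2D_FEATURES, shape2d_features
from .texture import TEXTURE_FEATURE_NAMES, texture_features

__all__ = [
    "extract_disc_features",
    "extract_cohort_features",
    "feature_names",
    "image_set_names",
]


def image_set_names(config: PreprocessConfig | None = None) -> tuple[str, ...]:
    config = config or PreprocessConfig()
    names = ["original"]
    names += [f"log-sigma-{s:g}mm" for s in config.log_sigmas_mm]
    names += ["wavelet-LL", "wavelet-LH", "wavelet-HL", "wavelet-HH"]
    return tuple(names)


def feature_names(config: PreprocessConfig | None = None) -> tuple[str, ...]:
    """Canonical ordered feature names (737 under the default config)."""
    config = config or PreprocessConfig()
    names = [f"original_shape2D_{f}" for f in SHAPE2D_FEATURES]
    for s in image_set_names(config):
        names += [f"{s}_firstorder_{f}" for f in FIRSTORDER_FEATURES]
        names += [f"{s}_{f}" for f in TEXTURE_FEATURE_NAMES]
    return tuple(names)


def _crop_slices(mask: np.ndarray, margin: int) -> tuple[slice, slice]:
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    return (
        slice(max(r0 - margin, 0), min(r1 + margin + 1, mask.shape[0])),
        slice(max(c0 - margin, 0), min(c1 + margin + 1, mask.shape[1])),
    )


def _slice_features(
    image: np.ndarray,
    mask: np.ndarray,
    spacing: float,
    config: PreprocessConfig,
) -> dict[str, float]:
    if config.normalize:
        image = normalize_image(image, mask, config.normalization_scale)
    else:
        image = np.asarray(image, dtype=float)

    # crop to the mask neighbourhood; the margin covers the widest filter
    # support so in-mask filter responses are unaffected by the crop
    max_sigma = max(config.log_sigmas_mm, default=0.0)
    margin = int(math.ceil(4.0 * max_sigma / spacing)) + 4
    rs, cs = _crop_slices(mask, margin)
    image = image[rs, cs]
    mask = np.asarray(mask, dtype=bool)[rs, cs]

    image_r, mask_r = resample2d(image, mask, config.resample_factor)
    spacing_r = spacing / config.resample_factor

    out: dict[str, float] = {}
    for f, v in shape2d_features(mask_r, spacing_r).items():
        out[f"original_shape2D_{f}"] = v

    sets = build_filter_bank(image_r, mask_r, config, spacing_r)
    # tight crop: filter responses are already computed, so texture and
    # first-order statistics only need the mask bounding box
    trs, tcs = _crop_slices(mask_r, 1)
    mask_r = mask_r[trs, tcs]
    sets = {k: v[trs, tcs] for k, v in sets.items()}
    for set_name, arr in sets.items():
        fo = firstorder_features(arr, mask_r, spacing_r, config.bin_width)
        for f, v in fo.items():
            out[f"{set_name}_firstorder_{f}"] = v
        disc_arr, n_levels = discretise(arr, mask_r, config.bin_width)
        for f, v in texture_features(disc_arr, mask_r, n_levels).items():
            out[f"{set_name}_{f}"] = v
    return out


def extract_disc_features(
    disc,
    config: PreprocessConfig | None = None,
    masks: list[np.ndarray] | None = None,
    images: list[np.ndarray] | None = None,
) -> dict[str, float]:
    """Extract the full per-IVD feature vector, mean-aggregated over slices.

    ``masks``/``images`` optionally override the disc's own per-slice disc
    masks and images (used for imperfect-segmentation and perturbation
    experiments).  Slices whose mask is empty are dropped, mirroring the
    screening of failed segmentations; if every slice is empty a ValueError
    is raised.
    """
    config = config or PreprocessConfig()
    spacing = disc.geometry.in_plane_spacing
    names = feature_names(config)
    rows = []
    for k, sl in enumerate(disc.slices):
        mask = masks[k] if masks is not None else sl.disc_mask
        image = images[k] if images is not None else sl.image
        if mask is None or not np.asarray(mask, dtype=bool).any():
            continue
        rows.append(_slice_features(image, mask, spacing, config))
    if not rows:
        raise ValueError("no valid slices: all masks empty")
    return {f: float(np.mean([r[f] for r in rows])) for f in names}


def extract_cohort_features(
    cohort,
    config: PreprocessConfig | None = None,
    discs=None,
) -> pd.DataFrame:
    """Feature table with one row per disc.

    Columns: subject_id, level, grade, the 737 features in canonical order,
    and a boolean ``degenerate`` flag marking rows with any NaN feature.
    """
    config = config or PreprocessConfig()
    discs = cohort.discs if discs is None else discs
    records = []
    for disc in discs:
        feats = extract_disc_features(disc, config)
        rec = {"subject_id": disc.subject_id, "level": disc.level, "grade": disc.grade}
        rec.update(feats)
        rec["degenerate"] = any(np.isnan(v) for v in feats.values())
        records.append(rec)
    return pd.DataFrame.from_records(records)
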