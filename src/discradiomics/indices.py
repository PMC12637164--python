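"""Conventional disc indices: height index and peak signal intensity difference.

The disc height index (DHI) uses an area-based construction: each structure's
effective height is its area divided by its anteroposterior extent (measured
along the structure's principal axis), and DHI = 2 h_disc / (h_supVB +
h_infVB), i.e. disc height normalized by the mean height of the adjacent
vertebral bodies.  DHI is invariant to isotropic scaling.

Peak signal intensity difference (PSID) normalizes in-disc intensities by the
mean of a 3 mm circular cerebrospinal-fluid reference region, builds a kernel
density estimate of the normalized in-disc values, finds its local maxima
(prominence at least 5% of the peak density), and reports the intensity
distance between the brightest and darkest peaks; a unimodal disc scores 0.
Both indices are computed per slice and mean-aggregated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "IndexPair",
    "disc_height_index",
    "peak_signal_intensity_difference",
    "indices_for_disc",
]


@dataclass
class IndexPair:
    disc_height_index: float
    peak_signal_intensity_difference: float
    per_slice_dhi: list[float]
    per_slice_psid: list[float]


def _effective_height(mask: np.ndarray, spacing: float) -> float:
    """Area / anteroposterior extent, extent along the principal axis."""
    coords = np.argwhere(mask).astype(float)
    if len(coords) == 0:
        raise ValueError("empty mask")
    coords = coords - coords.mean(axis=0)
    if len(coords) < 2:
        raise ValueError("degenerate mask: zero extent")
    cov = np.cov(coords, rowvar=False)
    w, v = np.linalg.eigh(cov)
    principal = v[:, np.argmax(w)]
    proj = coords @ principal
    # pixel-corner correction: a pixel's corners project +-(|cy|+|cx|)/2
    # around its center, so the support extent exceeds the center span by
    # the projected pixel diagonal (reduces to +1 px when axis-aligned)
    corner = abs(principal[0]) + abs(principal[1])
    extent = (proj.max() - proj.min() + corner) * spacing
    if extent <= 0:
        raise ValueError("zero-extent structure")
    area = mask.sum() * spacing * spacing
    return float(area / extent)


def disc_height_index(
    disc_mask: np.ndarray,
    sup_vb_mask: np.ndarray,
    inf_vb_mask: np.ndarray,
    spacing: float,
) -> float:
    """Area-based disc height index for one slice."""
    masks = [np.asarray(m, dtype=bool) for m in (disc_mask, sup_vb_mask, inf_vb_mask)]
    if any(not m.any() for m in masks):
        raise ValueError("all three masks must be non-empty")
    h_disc = _effective_height(masks[0], spacing)
    h_sup = _effective_height(masks[1], spacing)
    h_inf = _effective_height(masks[2], spacing)
    return 2.0 * h_disc / (h_sup + h_inf)


def _csf_roi(
    shape: tuple[int, int], center: tuple[int, int], spacing: float, radius_mm: float
) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    r_px = radius_mm / spacing
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r_px**2


def peak_signal_intensity_difference(
    image: np.ndarray,
    disc_mask: np.ndarray,
    csf_center: tuple[int, int],
    spacing: float,
    bandwidth: float = 0.02,
    prominence_frac: float = 0.05,
) -> float:
    """CSF-normalized distance between the brightest and darkest density peaks.

    The CSF reference region contains all pixels within 1.5 mm of
    ``csf_center`` (3 mm diameter).  The in-disc normalized values are
    smoothed with a Gaussian KDE of absolute bandwidth ``bandwidth`` on the
    CSF-normalized scale; peaks need prominence >= ``prominence_frac`` of the
    maximum density.  Single-peak (or constant) discs return 0.
    """
    image = np.asarray(image, dtype=float)
    disc_mask = np.asarray(disc_mask, dtype=bool)
    if not disc_mask.any():
        raise ValueError("empty disc mask")
    roi = _csf_roi(image.shape, csf_center, spacing, 1.5)
    if not roi.any():
        raise ValueError("CSF ROI outside image")
    csf_mean = float(image[roi].mean())
    if csf_mean == 0:
        raise ValueError("CSF mean intensity is zero")
    vals = image[disc_mask] / csf_mean
    if np.ptp(vals) == 0:
        return 0.0
    lo = vals.min() - 4 * bandwidth
    hi = vals.max() + 4 * bandwidth
    grid = np.linspace(lo, hi, 512)
    # Gaussian KDE with a fixed absolute bandwidth on the normalized scale
    diff = (grid[:, None] - vals[None, :]) / bandwidth
    density = np.exp(-0.5 * diff**2).sum(axis=1)
    density /= density.max()
    peaks, _ = find_peaks(density, prominence=prominence_frac)
    if len(peaks) < 2:
        return 0.0
    return float(grid[peaks.max()] - grid[peaks.min()])


def indices_for_disc(disc, disc_masks=None, sup_masks=None, inf_masks=None) -> IndexPair:
    """Per-slice DHI and PSID, unweighted mean aggregation.

    Optional per-slice mask lists override the disc's own segmentations
    (imperfect-segmentation experiments).  Slices with any empty constituent
    mask are skipped; a disc whose every slice is invalid raises.
    """
    spacing = disc.geometry.in_plane_spacing
    dhis: list[float] = []
    psids: list[float] = []
    for k, sl in enumerate(disc.slices):
        dm = disc_masks[k] if disc_masks is not None else sl.disc_mask
        sm = sup_masks[k] if sup_masks is not None else sl.sup_vb_mask
        im = inf_masks[k] if inf_masks is not None else sl.inf_vb_mask
        if not (dm.any() and sm.any() and im.any()):
            continue
        dhis.append(disc_height_index(dm, sm, im, spacing))
        psids.append(
            peak_signal_intensity_difference(sl.image, dm, sl.csf_center, spacing)
        )
    if not dhis:
        raise ValueError("no valid slices for conventional indices")
    return IndexPair(
        disc_height_index=float(np.mean(dhis)),
        peak_signal_intensity_difference=float(np.mean(psids)),
        per_slice_dhi=dhis,
        per_slice_psid=psids,
    )
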