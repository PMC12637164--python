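"""Image normalization, resampling, discretisation and the filter bank.

The preprocessing chain mirrors standard 2D radiomics practice: z-score
normalization over the whole image (rescaled to a configurable gray-level
scale), twofold bilinear up-sampling (nearest-neighbour for masks),
fixed-bin-width discretisation anchored at the per-ROI minimum, and a filter
bank of the original image, Laplacian-of-Gaussian responses at sigmas given
in millimetres, and the four single-level 2D wavelet subbands.  Under the
defaults this yields exactly 8 image sets, which together with 91
intensity/texture features per set and 9 shape features gives the 737-feature
vector the extraction module produces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage

__all__ = [
    "PreprocessConfig",
    "normalize_image",
    "resample2d",
    "discretise",
    "log_filter",
    "wavelet_bank",
    "build_filter_bank",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing and filter-bank settings.

    bin_width
        Fixed gray-level bin width for discretisation (default 16).
    resample_factor
        Integer in-plane up-sampling factor (default 2, i.e. twofold).
    normalize / normalization_scale
        Whether to z-score the image over the whole slice and the gray-level
        scale of the result (default 100).
    log_sigmas_mm
        Laplacian-of-Gaussian scales in millimetres (default [1, 2, 3]).
    wavelet_basis / wavelet_level
        2D discrete wavelet basis (default Haar) and decomposition level.
    """

    bin_width: float = 16.0
    resample_factor: int = 2
    normalize: bool = True
    normalization_scale: float = 100.0
    log_sigmas_mm: tuple[float, ...] = (1.0, 2.0, 3.0)
    wavelet_basis: str = "haar"
    wavelet_level: int = 1

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.resample_factor < 1:
            raise ValueError("resample_factor must be >= 1")

    @property
    def n_image_sets(self) -> int:
        return 1 + len(self.log_sigmas_mm) + 4

    def to_dict(self) -> dict:
        return {
            "bin_width": self.bin_width,
            "resample_factor": self.resample_factor,
            "normalize": self.normalize,
            "normalization_scale": self.normalization_scale,
            "log_sigmas_mm": list(self.log_sigmas_mm),
            "wavelet_basis": self.wavelet_basis,
            "wavelet_level": self.wavelet_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        d = dict(d)
        if "log_sigmas_mm" in d:
            d["log_sigmas_mm"] = tuple(d["log_sigmas_mm"])
        return cls(**d)


def normalize_image(
    image: np.ndarray, mask: np.ndarray | None = None, scale: float = 100.0
) -> np.ndarray:
    """Z-score the image over the whole slice and rescale.

    Returns ``(image - mu) / sigma * scale`` with mu and sigma computed over
    all pixels.  A zero-variance image yields an all-zero output with a
    warning.  The ``mask`` argument is accepted for interface symmetry; the
    statistics are deliberately whole-image so that mask perturbations do not
    leak into the normalization.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    mu = image.mean()
    sigma = image.std()
    if sigma == 0:
        warnings.warn("zero-variance image: normalized output is all zeros")
        return np.zeros_like(image)
    return (image - mu) / sigma * scale


def resample2d(
    image: np.ndarray, mask: np.ndarray, factor: int
) -> tuple[np.ndarray, np.ndarray]:
    """Integer up-sampling: bilinear for the image, nearest for the mask.

    The effective pixel spacing is divided by ``factor``.  Nearest-neighbour
    resampling of the mask is pixel replication, so the mask stays binary and
    its support scales exactly.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if factor == 1:
        return image.copy(), mask.copy()
    img_up = ndimage.zoom(image, factor, order=1, grid_mode=True, mode="nearest")
    mask_up = np.kron(mask, np.ones((factor, factor), dtype=bool))
    return img_up, mask_up


def discretise(
    image: np.ndarray, mask: np.ndarray, bin_width: float
) -> tuple[np.ndarray, int]:
    """Fixed-bin-width discretisation of in-mask gray levels.

    Bin edges are anchored at ``floor(min_in_mask / width) * width``; bin
    indices start at 1.  Returns the integer bin array (0 outside the mask)
    and ``n_levels`` (the maximum in-mask bin index).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = image[mask]
    anchor = np.floor(vals.min() / bin_width) * bin_width
    bins = np.zeros(image.shape, dtype=np.int64)
    bins[mask] = np.floor((image[mask] - anchor) / bin_width).astype(np.int64) + 1
    n_levels = int(bins[mask].max())
    return bins, n_levels


def log_filter(image: np.ndarray, sigma_mm: float, spacing: float) -> np.ndarray:
    """Laplacian-of-Gaussian response with sigma given in millimetres.

    The truncated sampled kernel has a tiny nonzero DC gain; it is removed by
    subtracting that gain times the Gaussian-smoothed image, so a constant
    image maps to an exactly zero response.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    sigma_px = sigma_mm / spacing
    if sigma_px < 1.0:
        warnings.warn(
            f"LoG sigma {sigma_mm} mm is below one pixel ({sigma_px:.2f} px); "
            "response will be poorly resolved"
        )
    image = np.asarray(image, dtype=float)
    out = ndimage.gaussian_laplace(image, sigma_px)
    probe = np.ones((1, 1))
    dc = float(ndimage.gaussian_laplace(probe, sigma_px, mode="nearest")[0, 0])
    if dc != 0.0:
        out = out - dc * ndimage.gaussian_filter(image, sigma_px)
    return out


def wavelet_bank(
    image: np.ndarray, basis: str = "haar", level: int = 1
) -> dict[str, np.ndarray]:
    """Single-level 2D wavelet decomposition, subbands upsampled to input shape.

    Returns the LL/LH/HL/HH subbands of a decimated 2D DWT at ``level``,
    each replicated back to the input shape so the (resampled) masks apply
    unchanged.
    """
    if basis not in pywt.wavelist(kind="discrete"):
        raise ValueError(f"unknown wavelet basis {basis!r}")
    image = np.asarray(image, dtype=float)
    if min(image.shape) < 2**level:
        raise ValueError("image too small for requested wavelet level")
    coeffs = pywt.wavedec2(image, basis, level=level)
    ll = coeffs[0]
    lh, hl, hh = coeffs[1]  # (cH, cV, cD) at the coarsest level
    out = {}
    for name, band in (("LL", ll), ("LH", lh), ("HL", hl), ("HH", hh)):
        up = np.kron(band, np.ones((2**level, 2**level)))
        out[name] = up[: image.shape[0], : image.shape[1]]
        if out[name].shape != image.shape:  # pad if image dims were odd
            pad = (
                (0, image.shape[0] - out[name].shape[0]),
                (0, image.shape[1] - out[name].shape[1]),
            )
            out[name] = np.pad(out[name], pad, mode="edge")
    return out


def build_filter_bank(
    image: np.ndarray,
    mask: np.ndarray,
    config: PreprocessConfig,
    spacing: float,
) -> dict[str, np.ndarray]:
    """Produce the named filtered image sets for one (preprocessed) slice.

    ``image`` must already be normalized/resampled; ``spacing`` is the
    post-resampling pixel spacing used to express LoG sigmas in pixels.
    Returns ``original``, one ``log-sigma-<s>mm`` set per sigma and the four
    ``wavelet-XX`` subbands — 8 sets under the default configuration.
    """
    image = np.asarray(image, dtype=float)
    sets: dict[str, np.ndarray] = {"original": image}
    for s in config.log_sigmas_mm:
        name = f"log-sigma-{s:g}mm"
        sets[name] = log_filter(image, s, spacing)
    wav = wavelet_bank(image, config.wavelet_basis, config.wavelet_level)
    for sub, arr in wav.items():
        sets[f"wavelet-{sub}"] = arr
    return sets
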