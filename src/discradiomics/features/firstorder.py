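"""First-order (histogram) intensity features on a masked 2D image."""

from __future__ import annotations

import numpy as np

__all__ = ["firstorder_features", "FIRSTORDER_FEATURES"]

FIRSTORDER_FEATURES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def firstorder_features(
    image: np.ndarray,
    mask: np.ndarray,
    spacing: float = 1.0,
    bin_width: float = 16.0,
) -> dict[str, float]:
    """Compute the 18 first-order features over in-mask pixel values.

    Percentiles use linear interpolation between closest ranks (the numpy
    default), so InterquartileRange = P75 - P25 under that convention.
    Entropy and Uniformity are computed on the fixed-bin-width histogram of
    in-mask values (same anchor rule as the discretiser); Kurtosis is the
    plain fourth standardised moment (not excess).  TotalEnergy scales Energy
    by the pixel area in mm^2.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    x = np.asarray(image, dtype=float)[mask]

    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    mean = float(x.mean())
    var = float(x.var())  # population variance
    energy = float(np.sum(x**2))

    # histogram probabilities on fixed-width bins anchored at the ROI minimum
    anchor = np.floor(x.min() / bin_width) * bin_width
    idx = np.floor((x - anchor) / bin_width).astype(np.int64)
    p = np.bincount(idx) / x.size
    p = p[p > 0]
    entropy = float(-np.sum(p * np.log2(p)))
    uniformity = float(np.sum(p**2))

    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else float("nan")

    if var > 0:
        z = x - mean
        skew = float(np.mean(z**3) / var**1.5)
        kurt = float(np.mean(z**4) / var**2)
    else:
        skew = 0.0
        kurt = 0.0

    return {
        "Energy": energy,
        "TotalEnergy": energy * spacing * spacing,
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": uniformity,
    }
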