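"""Gray-level texture-matrix features on a discretised 2D ROI.

Implements the five standard texture families on a fixed-bin discretised
image (levels 1..n_levels inside the mask, 0 outside):

* GLCM — co-occurrence at distance 1 over the 4 unique 2D directions,
  symmetric, features computed per direction and averaged (22 features);
* GLRLM — run lengths along the same 4 directions, per-direction features
  averaged (16);
* GLSZM — 8-connected equal-level zones, single matrix (16);
* GLDM — dependence counts over the 8-neighbourhood with zero gray-level
  tolerance, dependence size = 1 + number of equal-level neighbours (14);
* NGTDM — neighbourhood gray-tone difference over the 8-neighbourhood (5).

Degenerate ROIs (for example a single pixel, which admits no pixel pairs)
yield NaN for the features whose defining matrix is empty; callers flag and
exclude such values rather than imputing.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "texture_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
    "GLCM_FEATURES",
    "GLRLM_FEATURES",
    "GLSZM_FEATURES",
    "GLDM_FEATURES",
    "NGTDM_FEATURES",
    "TEXTURE_FEATURE_NAMES",
]

_EIGHT_NEIGHBOURS = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
]
_DIRECTIONS = [(0, 1), (1, 1), (1, 0), (1, -1)]  # 0, 45, 90, 135 degrees

GLCM_FEATURES = (
    "Autocorrelation",
    "JointAverage",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "JointEnergy",
    "JointEntropy",
    "Imc1",
    "Imc2",
    "Idm",
    "Idmn",
    "Id",
    "Idn",
    "InverseVariance",
    "MaximumProbability",
    "SumEntropy",
    "SumSquares",
)

GLRLM_FEATURES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM_FEATURES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

GLDM_FEATURES = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

NGTDM_FEATURES = (
    "Coarseness",
    "Contrast",
    "Busyness",
    "Complexity",
    "Strength",
)

TEXTURE_FEATURE_NAMES = tuple(
    [f"glcm_{f}" for f in GLCM_FEATURES]
    + [f"gldm_{f}" for f in GLDM_FEATURES]
    + [f"glrlm_{f}" for f in GLRLM_FEATURES]
    + [f"glszm_{f}" for f in GLSZM_FEATURES]
    + [f"ngtdm_{f}" for f in NGTDM_FEATURES]
)


def _nan_dict(names: tuple[str, ...]) -> dict[str, float]:
    return {n: float("nan") for n in names}


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrices(
    arr: np.ndarray, mask: np.ndarray, n_levels: int
) -> list[np.ndarray]:
    """Symmetric normalized distance-1 co-occurrence matrix per direction.

    Directions with no valid pixel pairs are omitted.
    """
    arr = np.asarray(arr)
    mask = np.asarray(mask, dtype=bool)
    mats = []
    for dy, dx in _DIRECTIONS:
        h, w = arr.shape
        ys = slice(max(dy, 0), h + min(dy, 0))
        xs = slice(max(dx, 0), w + min(dx, 0))
        ys2 = slice(max(-dy, 0), h + min(-dy, 0))
        xs2 = slice(max(-dx, 0), w + min(-dx, 0))
        valid = mask[ys, xs] & mask[ys2, xs2]
        if not valid.any():
            continue
        i = arr[ys, xs][valid] - 1
        j = arr[ys2, xs2][valid] - 1
        counts = np.bincount(i * n_levels + j, minlength=n_levels * n_levels)
        c = counts.reshape(n_levels, n_levels).astype(float)
        c = c + c.T  # symmetrise
        mats.append(c / c.sum())
    return mats


def _glcm_features_single(p: np.ndarray, n_levels: int) -> dict[str, float]:
    eps = np.finfo(float).eps
    lv = np.arange(1, n_levels + 1, dtype=float)
    i = lv[:, None]
    j = lv[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float(np.sum(lv * px))
    uy = float(np.sum(lv * py))
    sx = float(np.sqrt(np.sum((lv - ux) ** 2 * px)))
    sy = float(np.sqrt(np.sum((lv - uy) ** 2 * py)))

    # difference and sum distributions
    k_diff = np.arange(0, n_levels, dtype=float)
    p_diff = np.zeros(n_levels)
    k_sum = np.arange(2, 2 * n_levels + 1, dtype=float)
    p_sum = np.zeros(2 * n_levels - 1)
    absdiff = np.abs(i - j).astype(int)
    summ = (i + j).astype(int)
    np.add.at(p_diff, absdiff.ravel(), p.ravel())
    np.add.at(p_sum, (summ - 2).ravel(), p.ravel())

    nz = p > 0
    joint_entropy = float(-np.sum(p[nz] * np.log2(p[nz])))
    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0])))
    hy = float(-np.sum(py[py > 0] * np.log2(py[py > 0])))
    pxpy = np.outer(px, py)
    hxy1 = float(-np.sum(p[nz] * np.log2(pxpy[nz] + eps)))
    nz2 = pxpy > 0
    hxy2 = float(-np.sum(pxpy[nz2] * np.log2(pxpy[nz2])))

    if max(hx, hy) > 0:
        imc1 = (joint_entropy - hxy1) / max(hx, hy)
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)), 0.0)))

    if sx > 0 and sy > 0:
        corr = (float(np.sum(i * j * p)) - ux * uy) / (sx * sy)
    else:
        corr = 1.0

    da = float(np.sum(k_diff * p_diff))
    nz_d = p_diff > 0
    nz_s = p_sum > 0
    off = ~np.eye(n_levels, dtype=bool)
    inv_var = float(np.sum(p[off] / (i - j)[off] ** 2)) if n_levels > 1 else 0.0

    return {
        "Autocorrelation": float(np.sum(i * j * p)),
        "JointAverage": ux,
        "ClusterProminence": float(np.sum((i + j - ux - uy) ** 4 * p)),
        "ClusterShade": float(np.sum((i + j - ux - uy) ** 3 * p)),
        "ClusterTendency": float(np.sum((i + j - ux - uy) ** 2 * p)),
        "Contrast": float(np.sum((i - j) ** 2 * p)),
        "Correlation": float(corr),
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-np.sum(p_diff[nz_d] * np.log2(p_diff[nz_d]))),
        "DifferenceVariance": float(np.sum((k_diff - da) ** 2 * p_diff)),
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": joint_entropy,
        "Imc1": float(imc1),
        "Imc2": imc2,
        "Idm": float(np.sum(p / (1.0 + (i - j) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + ((i - j) / n_levels) ** 2))),
        "Id": float(np.sum(p / (1.0 + np.abs(i - j)))),
        "Idn": float(np.sum(p / (1.0 + np.abs(i - j) / n_levels))),
        "InverseVariance": inv_var,
        "MaximumProbability": float(p.max()),
        "SumEntropy": float(-np.sum(p_sum[nz_s] * np.log2(p_sum[nz_s]))),
        "SumSquares": float(np.sum((i - ux) ** 2 * p)),
    }


def glcm_features(arr: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    mats = glcm_matrices(arr, mask, n_levels)
    if not mats:
        return _nan_dict(GLCM_FEATURES)
    per_dir = [_glcm_features_single(m, n_levels) for m in mats]
    return {f: float(np.mean([d[f] for d in per_dir])) for f in GLCM_FEATURES}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _direction_lines(a: np.ndarray, direction: tuple[int, int]) -> list[np.ndarray]:
    if direction == (0, 1):
        return [a[r] for r in range(a.shape[0])]
    if direction == (1, 0):
        return [a[:, c] for c in range(a.shape[1])]
    if direction == (1, 1):
        return [
            np.diagonal(a, offset=o)
            for o in range(-a.shape[0] + 1, a.shape[1])
        ]
    if direction == (1, -1):
        f = np.fliplr(a)
        return [
            np.diagonal(f, offset=o)
            for o in range(-f.shape[0] + 1, f.shape[1])
        ]
    raise ValueError(f"unknown direction {direction}")


def _runs(lines: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode all lines at once; zeros are out-of-mask separators."""
    parts = []
    for s in lines:
        parts.append(np.asarray(s))
        parts.append(np.zeros(1, dtype=parts[-1].dtype))
    flat = np.concatenate(parts)
    change = np.flatnonzero(np.diff(flat) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(flat)]])
    vals = flat[starts]
    lens = ends - starts
    keep = vals > 0
    return vals[keep].astype(np.int64), lens[keep].astype(np.int64)


def glrlm_matrix(
    arr: np.ndarray, mask: np.ndarray, n_levels: int, direction: tuple[int, int]
) -> np.ndarray:
    """Run-length count matrix P[gray-1, runlength-1] for one direction."""
    a = np.where(np.asarray(mask, dtype=bool), np.asarray(arr), 0)
    vals, lens = _runs(_direction_lines(a, direction))
    if len(vals) == 0:
        return np.zeros((n_levels, 1))
    max_len = int(lens.max())
    counts = np.bincount(
        (vals - 1) * max_len + (lens - 1), minlength=n_levels * max_len
    )
    return counts.reshape(n_levels, max_len).astype(float)


def _size_weighted_features(
    p_counts: np.ndarray, n_pixels: int, prefix: str
) -> dict[str, float]:
    """Shared gray-level x size feature formulas for GLRLM/GLSZM-type matrices.

    ``prefix`` chooses the naming family: "Run" or "Area"/"Zone" handled by
    the callers; this helper returns values keyed by canonical role.
    """
    n = p_counts.sum()
    ng, ns = p_counts.shape
    iv = np.arange(1, ng + 1, dtype=float)
    jv = np.arange(1, ns + 1, dtype=float)
    pg = p_counts.sum(axis=1)
    ps = p_counts.sum(axis=0)
    p = p_counts / n
    mu_i = float(np.sum(iv * pg) / n)
    mu_j = float(np.sum(jv * ps) / n)
    nz = p > 0
    ent = float(-np.sum(p[nz] * np.log2(p[nz])))
    i2 = iv**2
    j2 = jv**2
    return {
        "small": float(np.sum(ps / j2) / n),
        "large": float(np.sum(ps * j2) / n),
        "gln": float(np.sum(pg**2) / n),
        "glnn": float(np.sum(pg**2) / n**2),
        "sn": float(np.sum(ps**2) / n),
        "snn": float(np.sum(ps**2) / n**2),
        "pct": float(n / n_pixels),
        "glv": float(np.sum((iv - mu_i) ** 2 * pg) / n),
        "sv": float(np.sum((jv - mu_j) ** 2 * ps) / n),
        "entropy": ent,
        "lgl": float(np.sum(pg / i2) / n),
        "hgl": float(np.sum(pg * i2) / n),
        "s_lgl": float(np.sum(p_counts / np.outer(i2, j2)) / n),
        "s_hgl": float(np.sum(p_counts * np.outer(i2, 1.0 / j2)) / n),
        "l_lgl": float(np.sum(p_counts * np.outer(1.0 / i2, j2)) / n),
        "l_hgl": float(np.sum(p_counts * np.outer(i2, j2)) / n),
    }


def glrlm_features(
    arr: np.ndarray, mask: np.ndarray, n_levels: int
) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    n_pixels = int(mask.sum())
    per_dir = []
    for d in _DIRECTIONS:
        pm = glrlm_matrix(arr, mask, n_levels, d)
        if pm.sum() == 0:
            continue
        r = _size_weighted_features(pm, n_pixels, "Run")
        per_dir.append(
            {
                "ShortRunEmphasis": r["small"],
                "LongRunEmphasis": r["large"],
                "GrayLevelNonUniformity": r["gln"],
                "GrayLevelNonUniformityNormalized": r["glnn"],
                "RunLengthNonUniformity": r["sn"],
                "RunLengthNonUniformityNormalized": r["snn"],
                "RunPercentage": r["pct"],
                "GrayLevelVariance": r["glv"],
                "RunVariance": r["sv"],
                "RunEntropy": r["entropy"],
                "LowGrayLevelRunEmphasis": r["lgl"],
                "HighGrayLevelRunEmphasis": r["hgl"],
                "ShortRunLowGrayLevelEmphasis": r["s_lgl"],
                "ShortRunHighGrayLevelEmphasis": r["s_hgl"],
                "LongRunLowGrayLevelEmphasis": r["l_lgl"],
                "LongRunHighGrayLevelEmphasis": r["l_hgl"],
            }
        )
    if not per_dir:
        return _nan_dict(GLRLM_FEATURES)
    return {f: float(np.mean([d[f] for d in per_dir])) for f in GLRLM_FEATURES}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def glszm_matrix(arr: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone count matrix P[gray-1, zonesize-1]; zones are 8-connected."""
    mask = np.asarray(mask, dtype=bool)
    arr = np.asarray(arr)
    structure = np.ones((3, 3), dtype=bool)
    zones: list[tuple[int, int]] = []
    for g in np.unique(arr[mask]):
        lab, nlab = ndimage.label((arr == g) & mask, structure=structure)
        if nlab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((int(g), int(s)) for s in sizes)
    if not zones:
        return np.zeros((n_levels, 1))
    max_size = max(s for _, s in zones)
    p = np.zeros((n_levels, max_size))
    for g, s in zones:
        p[g - 1, s - 1] += 1
    return p


def glszm_features(
    arr: np.ndarray, mask: np.ndarray, n_levels: int
) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    pm = glszm_matrix(arr, mask, n_levels)
    if pm.sum() == 0:
        return _nan_dict(GLSZM_FEATURES)
    r = _size_weighted_features(pm, int(mask.sum()), "Zone")
    return {
        "SmallAreaEmphasis": r["small"],
        "LargeAreaEmphasis": r["large"],
        "GrayLevelNonUniformity": r["gln"],
        "GrayLevelNonUniformityNormalized": r["glnn"],
        "SizeZoneNonUniformity": r["sn"],
        "SizeZoneNonUniformityNormalized": r["snn"],
        "ZonePercentage": r["pct"],
        "GrayLevelVariance": r["glv"],
        "ZoneVariance": r["sv"],
        "ZoneEntropy": r["entropy"],
        "LowGrayLevelZoneEmphasis": r["lgl"],
        "HighGrayLevelZoneEmphasis": r["hgl"],
        "SmallAreaLowGrayLevelEmphasis": r["s_lgl"],
        "SmallAreaHighGrayLevelEmphasis": r["s_hgl"],
        "LargeAreaLowGrayLevelEmphasis": r["l_lgl"],
        "LargeAreaHighGrayLevelEmphasis": r["l_hgl"],
    }


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def gldm_matrix(arr: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Dependence count matrix P[gray-1, dependence-1].

    A neighbour is dependent when it is in-mask and has the same discretised
    level (gray-level tolerance 0); dependence size = 1 + dependent count.
    """
    arr = np.asarray(arr)
    mask = np.asarray(mask, dtype=bool)
    h, w = arr.shape
    dep = np.zeros(arr.shape, dtype=np.int64)
    for dy, dx in _EIGHT_NEIGHBOURS:
        ys = slice(max(dy, 0), h + min(dy, 0))
        xs = slice(max(dx, 0), w + min(dx, 0))
        ys2 = slice(max(-dy, 0), h + min(-dy, 0))
        xs2 = slice(max(-dx, 0), w + min(-dx, 0))
        ok = mask[ys, xs] & mask[ys2, xs2] & (arr[ys, xs] == arr[ys2, xs2])
        dep[ys, xs] += ok
    sizes = dep[mask] + 1
    levels = arr[mask]
    max_dep = int(sizes.max())
    counts = np.bincount(
        (levels - 1) * max_dep + (sizes - 1), minlength=n_levels * max_dep
    )
    return counts.reshape(n_levels, max_dep).astype(float)


def gldm_features(
    arr: np.ndarray, mask: np.ndarray, n_levels: int
) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return _nan_dict(GLDM_FEATURES)
    pm = gldm_matrix(arr, mask, n_levels)
    r = _size_weighted_features(pm, int(mask.sum()), "Dependence")
    return {
        "SmallDependenceEmphasis": r["small"],
        "LargeDependenceEmphasis": r["large"],
        "GrayLevelNonUniformity": r["gln"],
        "DependenceNonUniformity": r["sn"],
        "DependenceNonUniformityNormalized": r["snn"],
        "GrayLevelVariance": r["glv"],
        "DependenceVariance": r["sv"],
        "DependenceEntropy": r["entropy"],
        "LowGrayLevelEmphasis": r["lgl"],
        "HighGrayLevelEmphasis": r["hgl"],
        "SmallDependenceLowGrayLevelEmphasis": r["s_lgl"],
        "SmallDependenceHighGrayLevelEmphasis": r["s_hgl"],
        "LargeDependenceLowGrayLevelEmphasis": r["l_lgl"],
        "LargeDependenceHighGrayLevelEmphasis": r["l_hgl"],
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_table(
    arr: np.ndarray, mask: np.ndarray, n_levels: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level (n_i, s_i) table and the number of valid pixels.

    Valid pixels are in-mask pixels with at least one in-mask 8-neighbour;
    s_i accumulates |level - mean neighbour level| over valid pixels of level
    i.
    """
    arr = np.asarray(arr, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    h, w = arr.shape
    nb_sum = np.zeros(arr.shape)
    nb_cnt = np.zeros(arr.shape)
    a = np.where(mask, arr, 0.0)
    for dy, dx in _EIGHT_NEIGHBOURS:
        ys = slice(max(dy, 0), h + min(dy, 0))
        xs = slice(max(dx, 0), w + min(dx, 0))
        ys2 = slice(max(-dy, 0), h + min(-dy, 0))
        xs2 = slice(max(-dx, 0), w + min(-dx, 0))
        nb_sum[ys, xs] += a[ys2, xs2] * mask[ys2, xs2]
        nb_cnt[ys, xs] += mask[ys2, xs2]
    valid = mask & (nb_cnt > 0)
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    if valid.any():
        levels = arr[valid].astype(int)
        diffs = np.abs(arr[valid] - nb_sum[valid] / nb_cnt[valid])
        np.add.at(n_i, levels - 1, 1.0)
        np.add.at(s_i, levels - 1, diffs)
    return n_i, s_i, int(valid.sum())


def ngtdm_features(
    arr: np.ndarray, mask: np.ndarray, n_levels: int
) -> dict[str, float]:
    n_i, s_i, nvp = ngtdm_table(arr, mask, n_levels)
    if nvp == 0:
        return _nan_dict(NGTDM_FEATURES)
    p_i = n_i / nvp
    iv = np.arange(1, n_levels + 1, dtype=float)
    act = p_i > 0
    ngp = int(act.sum())
    ps = float(np.sum(p_i * s_i))

    coarseness = 1.0 / ps if ps > 0 else 1e6

    if ngp > 1:
        pij = np.outer(p_i[act], p_i[act])
        dij2 = (iv[act][:, None] - iv[act][None, :]) ** 2
        contrast = float(np.sum(pij * dij2)) / (ngp * (ngp - 1)) * float(s_i.sum()) / nvp
    else:
        contrast = 0.0

    ipi = iv * p_i
    denom_busy = float(np.sum(np.abs(ipi[act][:, None] - ipi[act][None, :])))
    busyness = ps / denom_busy if denom_busy > 0 else 0.0

    if ngp > 0:
        pi_a = p_i[act]
        si_a = s_i[act]
        iv_a = iv[act]
        absd = np.abs(iv_a[:, None] - iv_a[None, :])
        num = pi_a[:, None] * si_a[:, None] + pi_a[None, :] * si_a[None, :]
        den = pi_a[:, None] + pi_a[None, :]
        complexity = float(np.sum(absd * num / den)) / nvp
        strength_num = float(
            np.sum(den * (iv_a[:, None] - iv_a[None, :]) ** 2)
        )
    else:
        complexity = 0.0
        strength_num = 0.0
    s_sum = float(s_i.sum())
    strength = strength_num / s_sum if s_sum > 0 else 0.0

    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }


def texture_features(
    arr: np.ndarray, mask: np.ndarray, n_levels: int
) -> dict[str, float]:
    """All 73 texture features of a discretised ROI, canonically named.

    Keys are ``<class>_<Feature>`` with classes glcm (22), gldm (14),
    glrlm (16), glszm (16) and ngtdm (5).
    """
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    out: dict[str, float] = {}
    for cls, fn in (
        ("glcm", glcm_features),
        ("gldm", gldm_features),
        ("glrlm", glrlm_features),
        ("glszm", glszm_features),
        ("ngtdm", ngtdm_features),
    ):
        for name, val in fn(arr, mask, n_levels).items():
            out[f"{cls}_{name}"] = val
    return out
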