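"""Brute-force reference implementations used as independent test oracles.

Everything here is written with explicit Python loops and elementary
formulas, deliberately avoiding the vectorised code paths of the package, so
that agreement between the two routes is meaningful.
"""

from __future__ import annotations

import math

import numpy as np

EIGHT = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
DIRECTIONS = [(0, 1), (1, 1), (1, 0), (1, -1)]


def _inmask(mask, y, x):
    return 0 <= y < mask.shape[0] and 0 <= x < mask.shape[1] and mask[y, x]


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def oracle_glcm_matrix(arr, mask, n_levels, direction):
    c = np.zeros((n_levels, n_levels))
    dy, dx = direction
    for y in range(arr.shape[0]):
        for x in range(arr.shape[1]):
            if not mask[y, x]:
                continue
            y2, x2 = y + dy, x + dx
            if _inmask(mask, y2, x2):
                c[arr[y, x] - 1, arr[y2, x2] - 1] += 1
                c[arr[y2, x2] - 1, arr[y, x] - 1] += 1  # symmetric
    return c


def oracle_glcm_features(arr, mask, n_levels):
    per_dir = []
    for d in DIRECTIONS:
        c = oracle_glcm_matrix(arr, mask, n_levels, d)
        tot = c.sum()
        if tot == 0:
            continue
        p = c / tot
        ng = n_levels
        px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
        py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
        ux = sum((i + 1) * px[i] for i in range(ng))
        uy = sum((j + 1) * py[j] for j in range(ng))
        sx = math.sqrt(sum((i + 1 - ux) ** 2 * px[i] for i in range(ng)))
        sy = math.sqrt(sum((j + 1 - uy) ** 2 * py[j] for j in range(ng)))
        pdiff = {}
        psum = {}
        for i in range(ng):
            for j in range(ng):
                pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + p[i][j]
                psum[i + j + 2] = psum.get(i + j + 2, 0.0) + p[i][j]
        hxy = -sum(v * math.log2(v) for row in p for v in row if v > 0)
        hx = -sum(v * math.log2(v) for v in px if v > 0)
        hy = -sum(v * math.log2(v) for v in py if v > 0)
        eps = np.finfo(float).eps
        hxy1 = -sum(
            p[i][j] * math.log2(px[i] * py[j] + eps)
            for i in range(ng)
            for j in range(ng)
            if p[i][j] > 0
        )
        hxy2 = -sum(
            px[i] * py[j] * math.log2(px[i] * py[j])
            for i in range(ng)
            for j in range(ng)
            if px[i] * py[j] > 0
        )
        da = sum(k * v for k, v in pdiff.items())
        f = {}
        f["Autocorrelation"] = sum(
            (i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng)
        )
        f["JointAverage"] = ux
        for name, power in (("ClusterProminence", 4), ("ClusterShade", 3), ("ClusterTendency", 2)):
            f[name] = sum(
                (i + 1 + j + 1 - ux - uy) ** power * p[i][j]
                for i in range(ng)
                for j in range(ng)
            )
        f["Contrast"] = sum(
            (i - j) ** 2 * p[i][j] for i in range(ng) for j in range(ng)
        )
        if sx > 0 and sy > 0:
            f["Correlation"] = (f["Autocorrelation"] - ux * uy) / (sx * sy)
        else:
            f["Correlation"] = 1.0
        f["DifferenceAverage"] = da
        f["DifferenceEntropy"] = -sum(
            v * math.log2(v) for v in pdiff.values() if v > 0
        )
        f["DifferenceVariance"] = sum(
            (k - da) ** 2 * v for k, v in pdiff.items()
        )
        f["JointEnergy"] = sum(v * v for row in p for v in row)
        f["JointEntropy"] = hxy
        f["Imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
        f["Imc2"] = math.sqrt(max(1.0 - math.exp(-2.0 * (hxy2 - hxy)), 0.0))
        f["Idm"] = sum(
            p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)
        )
        f["Idmn"] = sum(
            p[i][j] / (1 + ((i - j) / ng) ** 2) for i in range(ng) for j in range(ng)
        )
        f["Id"] = sum(
            p[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)
        )
        f["Idn"] = sum(
            p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
        )
        f["InverseVariance"] = sum(
            p[i][j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
        )
        f["MaximumProbability"] = max(v for row in p for v in row)
        f["SumEntropy"] = -sum(v * math.log2(v) for v in psum.values() if v > 0)
        f["SumSquares"] = sum(
            (i + 1 - ux) ** 2 * p[i][j] for i in range(ng) for j in range(ng)
        )
        per_dir.append(f)
    if not per_dir:
        return None
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# run/zone/dependence helpers
# ---------------------------------------------------------------------------

def _oracle_runs(arr, mask, direction):
    """(gray, length) runs along a direction, by walking each line."""
    h, w = arr.shape
    dy, dx = direction
    starts = []
    if direction == (0, 1):
        starts = [(y, 0) for y in range(h)]
    elif direction == (1, 0):
        starts = [(0, x) for x in range(w)]
    elif direction == (1, 1):
        starts = [(0, x) for x in range(w)] + [(y, 0) for y in range(1, h)]
    elif direction == (1, -1):
        starts = [(0, x) for x in range(w)] + [(y, w - 1) for y in range(1, h)]
    runs = []
    for y0, x0 in starts:
        y, x = y0, x0
        cur, length = None, 0
        while 0 <= y < h and 0 <= x < w:
            v = arr[y, x] if mask[y, x] else None
            if v is not None and v == cur:
                length += 1
            else:
                if cur is not None:
                    runs.append((cur, length))
                cur, length = v, 1 if v is not None else 0
            y += dy
            x += dx
        if cur is not None:
            runs.append((cur, length))
    return runs


def _oracle_sizezone_features(pairs, n_levels, n_pixels):
    """Common gray x size statistics for run/zone/dependence matrices."""
    n = len(pairs)
    pg = {}
    ps = {}
    pij = {}
    for g, s in pairs:
        pg[g] = pg.get(g, 0) + 1
        ps[s] = ps.get(s, 0) + 1
        pij[(g, s)] = pij.get((g, s), 0) + 1
    mu_i = sum(g * c for g, c in pg.items()) / n
    mu_j = sum(s * c for s, c in ps.items()) / n
    return {
        "small": sum(c / s**2 for s, c in ps.items()) / n,
        "large": sum(c * s**2 for s, c in ps.items()) / n,
        "gln": sum(c**2 for c in pg.values()) / n,
        "glnn": sum(c**2 for c in pg.values()) / n**2,
        "sn": sum(c**2 for c in ps.values()) / n,
        "snn": sum(c**2 for c in ps.values()) / n**2,
        "pct": n / n_pixels,
        "glv": sum((g - mu_i) ** 2 * c for g, c in pg.items()) / n,
        "sv": sum((s - mu_j) ** 2 * c for s, c in ps.items()) / n,
        "entropy": -sum(
            (c / n) * math.log2(c / n) for c in pij.values()
        ),
        "lgl": sum(c / g**2 for g, c in pg.items()) / n,
        "hgl": sum(c * g**2 for g, c in pg.items()) / n,
        "s_lgl": sum(c / (g**2 * s**2) for (g, s), c in pij.items()) / n,
        "s_hgl": sum(c * g**2 / s**2 for (g, s), c in pij.items()) / n,
        "l_lgl": sum(c * s**2 / g**2 for (g, s), c in pij.items()) / n,
        "l_hgl": sum(c * g**2 * s**2 for (g, s), c in pij.items()) / n,
    }


_GLRLM_KEYS = {
    "ShortRunEmphasis": "small",
    "LongRunEmphasis": "large",
    "GrayLevelNonUniformity": "gln",
    "GrayLevelNonUniformityNormalized": "glnn",
    "RunLengthNonUniformity": "sn",
    "RunLengthNonUniformityNormalized": "snn",
    "RunPercentage": "pct",
    "GrayLevelVariance": "glv",
    "RunVariance": "sv",
    "RunEntropy": "entropy",
    "LowGrayLevelRunEmphasis": "lgl",
    "HighGrayLevelRunEmphasis": "hgl",
    "ShortRunLowGrayLevelEmphasis": "s_lgl",
    "ShortRunHighGrayLevelEmphasis": "s_hgl",
    "LongRunLowGrayLevelEmphasis": "l_lgl",
    "LongRunHighGrayLevelEmphasis": "l_hgl",
}

_GLSZM_KEYS = {
    "SmallAreaEmphasis": "small",
    "LargeAreaEmphasis": "large",
    "GrayLevelNonUniformity": "gln",
    "GrayLevelNonUniformityNormalized": "glnn",
    "SizeZoneNonUniformity": "sn",
    "SizeZoneNonUniformityNormalized": "snn",
    "ZonePercentage": "pct",
    "GrayLevelVariance": "glv",
    "ZoneVariance": "sv",
    "ZoneEntropy": "entropy",
    "LowGrayLevelZoneEmphasis": "lgl",
    "HighGrayLevelZoneEmphasis": "hgl",
    "SmallAreaLowGrayLevelEmphasis": "s_lgl",
    "SmallAreaHighGrayLevelEmphasis": "s_hgl",
    "LargeAreaLowGrayLevelEmphasis": "l_lgl",
    "LargeAreaHighGrayLevelEmphasis": "l_hgl",
}

_GLDM_KEYS = {
    "SmallDependenceEmphasis": "small",
    "LargeDependenceEmphasis": "large",
    "GrayLevelNonUniformity": "gln",
    "DependenceNonUniformity": "sn",
    "DependenceNonUniformityNormalized": "snn",
    "GrayLevelVariance": "glv",
    "DependenceVariance": "sv",
    "DependenceEntropy": "entropy",
    "LowGrayLevelEmphasis": "lgl",
    "HighGrayLevelEmphasis": "hgl",
    "SmallDependenceLowGrayLevelEmphasis": "s_lgl",
    "SmallDependenceHighGrayLevelEmphasis": "s_hgl",
    "LargeDependenceLowGrayLevelEmphasis": "l_lgl",
    "LargeDependenceHighGrayLevelEmphasis": "l_hgl",
}


def oracle_glrlm_features(arr, mask, n_levels):
    n_pixels = int(mask.sum())
    per_dir = []
    for d in DIRECTIONS:
        runs = _oracle_runs(arr, mask, d)
        if not runs:
            continue
        r = _oracle_sizezone_features(runs, n_levels, n_pixels)
        per_dir.append({k: r[v] for k, v in _GLRLM_KEYS.items()})
    if not per_dir:
        return None
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


def oracle_glszm_features(arr, mask, n_levels):
    h, w = arr.shape
    seen = np.zeros_like(mask, dtype=bool)
    zones = []
    for y in range(h):
        for x in range(w):
            if mask[y, x] and not seen[y, x]:
                g = arr[y, x]
                stack = [(y, x)]
                seen[y, x] = True
                size = 0
                while stack:
                    cy, cx = stack.pop()
                    size += 1
                    for dy, dx in EIGHT:
                        ny, nx = cy + dy, cx + dx
                        if (
                            _inmask(mask, ny, nx)
                            and not seen[ny, nx]
                            and arr[ny, nx] == g
                        ):
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                zones.append((int(g), size))
    if not zones:
        return None
    r = _oracle_sizezone_features(zones, n_levels, int(mask.sum()))
    return {k: r[v] for k, v in _GLSZM_KEYS.items()}


def oracle_gldm_features(arr, mask, n_levels):
    pairs = []
    for y in range(arr.shape[0]):
        for x in range(arr.shape[1]):
            if not mask[y, x]:
                continue
            dep = 0
            for dy, dx in EIGHT:
                if _inmask(mask, y + dy, x + dx) and arr[y + dy, x + dx] == arr[y, x]:
                    dep += 1
            pairs.append((int(arr[y, x]), dep + 1))
    if not pairs:
        return None
    r = _oracle_sizezone_features(pairs, n_levels, int(mask.sum()))
    return {k: r[v] for k, v in _GLDM_KEYS.items()}


def oracle_ngtdm_features(arr, mask, n_levels):
    n_i = [0.0] * (n_levels + 1)
    s_i = [0.0] * (n_levels + 1)
    nvp = 0
    for y in range(arr.shape[0]):
        for x in range(arr.shape[1]):
            if not mask[y, x]:
                continue
            nb = [
                arr[y + dy, x + dx]
                for dy, dx in EIGHT
                if _inmask(mask, y + dy, x + dx)
            ]
            if not nb:
                continue
            nvp += 1
            g = int(arr[y, x])
            n_i[g] += 1
            s_i[g] += abs(arr[y, x] - sum(nb) / len(nb))
    if nvp == 0:
        return None
    p_i = [n / nvp for n in n_i]
    act = [g for g in range(1, n_levels + 1) if p_i[g] > 0]
    ngp = len(act)
    ps = sum(p_i[g] * s_i[g] for g in act)
    coarse = 1.0 / ps if ps > 0 else 1e6
    if ngp > 1:
        contrast = (
            sum(p_i[a] * p_i[b] * (a - b) ** 2 for a in act for b in act)
            / (ngp * (ngp - 1))
            * sum(s_i)
            / nvp
        )
    else:
        contrast = 0.0
    denom = sum(abs(a * p_i[a] - b * p_i[b]) for a in act for b in act)
    busy = ps / denom if denom > 0 else 0.0
    compl = (
        sum(
            abs(a - b) * (p_i[a] * s_i[a] + p_i[b] * s_i[b]) / (p_i[a] + p_i[b])
            for a in act
            for b in act
        )
        / nvp
    )
    s_tot = sum(s_i)
    strength = (
        sum((p_i[a] + p_i[b]) * (a - b) ** 2 for a in act for b in act) / s_tot
        if s_tot > 0
        else 0.0
    )
    return {
        "Coarseness": coarse,
        "Contrast": contrast,
        "Busyness": busy,
        "Complexity": compl,
        "Strength": strength,
    }


def oracle_texture_features(arr, mask, n_levels):
    """All 73 features with the package's naming, NaN where undefined."""
    out = {}
    for cls, fn, names in (
        ("glcm", oracle_glcm_features, None),
        ("gldm", oracle_gldm_features, None),
        ("glrlm", oracle_glrlm_features, None),
        ("glszm", oracle_glszm_features, None),
        ("ngtdm", oracle_ngtdm_features, None),
    ):
        res = fn(arr, mask, n_levels)
        if res is None:
            continue
        for k, v in res.items():
            out[f"{cls}_{k}"] = v
    return out


# ---------------------------------------------------------------------------
# marching squares (mesh area / perimeter) oracle
# ---------------------------------------------------------------------------

def oracle_mesh_area_perimeter(mask, spacing=1.0):
    """Half-level iso-contour area and perimeter by per-cell marching squares.

    Walks every 2x2 pixel cell of the padded mask, accumulating the polygon
    area via the shoelace contribution of each cell's contour segments and
    the perimeter via segment lengths.  Vertices sit at midpoints between
    pixel centers (linear interpolation between 0 and 1 at level 0.5).
    """
    m = np.pad(np.asarray(mask, dtype=float), 1)
    area = 0.0
    per = 0.0
    h, w = m.shape
    for y in range(h - 1):
        for x in range(w - 1):
            tl, tr = m[y, x], m[y, x + 1]
            bl, br = m[y + 1, x], m[y + 1, x + 1]
            idx = int(tl) * 8 + int(tr) * 4 + int(br) * 2 + int(bl)
            if idx in (0, 15):
                if idx == 15:
                    area += 1.0
                continue
            # edge midpoints in (y, x)
            top = (y, x + 0.5)
            bottom = (y + 1, x + 0.5)
            left = (y + 0.5, x)
            right = (y + 0.5, x + 1)
            corners = {"tl": (y, x), "tr": (y, x + 1), "bl": (y + 1, x), "br": (y + 1, x + 1)}
            # polygon of the inside region within this cell
            polys = {
                1: [[left, bottom, corners["bl"]]],
                2: [[bottom, right, corners["br"]]],
                3: [[left, right, corners["br"], corners["bl"]]],
                4: [[top, corners["tr"], right]],
                5: [[left, bottom, corners["bl"]], [top, corners["tr"], right]],
                6: [[top, corners["tr"], corners["br"], bottom]],
                7: [[left, top, corners["tr"], corners["br"], corners["bl"]]],
                8: [[corners["tl"], top, left]],
                9: [[corners["tl"], top, bottom, corners["bl"]]],
                10: [[corners["tl"], top, left], [bottom, right, corners["br"]]],
                11: [[corners["tl"], top, right, corners["br"], corners["bl"]]],
                12: [[corners["tl"], corners["tr"], right, left]],
                13: [[corners["tl"], corners["tr"], right, bottom, corners["bl"]]],
                14: [[corners["tl"], corners["tr"], corners["br"], bottom, left]],
            }[idx]
            for poly in polys:
                a = 0.0
                for i in range(len(poly)):
                    y1, x1 = poly[i]
                    y2, x2 = poly[(i + 1) % len(poly)]
                    a += x1 * y2 - x2 * y1
                area += abs(a) / 2.0
                # perimeter: only segments between two edge midpoints count
                pts = {top, bottom, left, right}
                for i in range(len(poly)):
                    p1 = poly[i]
                    p2 = poly[(i + 1) % len(poly)]
                    if p1 in pts and p2 in pts:
                        per += math.hypot(p1[0] - p2[0], p1[1] - p2[1])
    return area * spacing * spacing, per * spacing


# ---------------------------------------------------------------------------
# Hausdorff-95 oracle
# ---------------------------------------------------------------------------

def oracle_hd95(mask_a, mask_b, spacing=1.0):
    """Exhaustive symmetric 95th-percentile boundary distance."""

    def boundary(m):
        pts = []
        for y in range(m.shape[0]):
            for x in range(m.shape[1]):
                if not m[y, x]:
                    continue
                edge = False
                for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    ny, nx = y + dy, x + dx
                    if not (0 <= ny < m.shape[0] and 0 <= nx < m.shape[1]) or not m[ny, nx]:
                        edge = True
                if edge:
                    pts.append((y, x))
        return pts

    pa = boundary(np.asarray(mask_a, dtype=bool))
    pb = boundary(np.asarray(mask_b, dtype=bool))
    d = []
    for p in pa:
        d.append(min(math.hypot(p[0] - q[0], p[1] - q[1]) for q in pb))
    for q in pb:
        d.append(min(math.hypot(p[0] - q[0], p[1] - q[1]) for p in pa))
    return float(np.percentile(np.array(d) * spacing, 95))


# ---------------------------------------------------------------------------
# ICC(A,1) closed-form oracle
# ---------------------------------------------------------------------------

def oracle_icc_a1(x, y):
    """Two-way absolute-agreement single-measurement ICC via explicit ANOVA."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    k = 2
    grand = (sum(x) + sum(y)) / (n * k)
    row_means = [(a + b) / 2 for a, b in zip(x, y)]
    col_means = [sum(x) / n, sum(y) / n]
    msr = k * sum((r - grand) ** 2 for r in row_means) / (n - 1)
    msc = n * sum((c - grand) ** 2 for c in col_means) / (k - 1)
    sst = sum((v - grand) ** 2 for v in x + y)
    sse = sst - k * sum((r - grand) ** 2 for r in row_means) - n * sum(
        (c - grand) ** 2 for c in col_means
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
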