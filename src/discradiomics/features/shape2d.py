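"""2D shape features from binary masks.

Mesh surface area and perimeter are measured on the half-level iso-contour of
the mask (linear interpolation at 0.5 between pixel centers), which is the
standard sub-pixel convention for 2D shape radiomics; axis lengths come from
the second central moments of the in-mask pixel centers (length = 4 sqrt of
the principal eigenvalue, so a disk of radius r has axis length 2r).
Sphericity is the circularity ratio 2 sqrt(pi A) / P, maximal (1) for a disk.
All lengths are in mm, areas in mm^2.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

__all__ = ["shape2d_features", "SHAPE2D_FEATURES"]

SHAPE2D_FEATURES = (
    "MeshSurface",
    "PixelSurface",
    "Perimeter",
    "PerimeterSurfaceRatio",
    "Sphericity",
    "MaximumDiameter",
    "MajorAxisLength",
    "MinorAxisLength",
    "Elongation",
)


def _contours(mask: np.ndarray) -> list[np.ndarray]:
    padded = np.pad(mask.astype(float), 1)
    cs = measure.find_contours(padded, 0.5)
    return [c - 1.0 for c in cs]  # undo the padding offset


def _polygon_area(poly: np.ndarray) -> float:
    y, x = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _polyline_length(poly: np.ndarray) -> float:
    d = np.diff(np.vstack([poly, poly[:1]]), axis=0)
    return float(np.sqrt((d**2).sum(axis=1)).sum())


def shape2d_features(mask: np.ndarray, spacing: float) -> dict[str, float]:
    """Compute the 9 shape features of a 2D binary mask.

    Degenerate masks (< 4 pixels) return NaN for the contour-derived features
    and carry a NaN Sphericity; callers flag and exclude such cases.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    npx = int(mask.sum())
    pixel_surface = npx * spacing * spacing

    if npx < 4:
        return {
            "MeshSurface": float("nan"),
            "PixelSurface": pixel_surface,
            "Perimeter": float("nan"),
            "PerimeterSurfaceRatio": float("nan"),
            "Sphericity": float("nan"),
            "MaximumDiameter": float("nan"),
            "MajorAxisLength": float("nan"),
            "MinorAxisLength": float("nan"),
            "Elongation": float("nan"),
        }

    contours = _contours(mask)
    # signed areas: outer contours and holes have opposite orientation
    mesh_area = abs(sum(_polygon_area(c) for c in contours)) * spacing * spacing
    perimeter = sum(_polyline_length(c) for c in contours) * spacing

    verts = np.vstack(contours) * spacing
    if len(verts) > 3:
        try:
            hull = ConvexHull(verts)
            verts = verts[hull.vertices]
        except Exception:  # collinear degenerate hull
            pass
    max_diam = float(pdist(verts).max()) if len(verts) >= 2 else float("nan")

    coords = np.argwhere(mask).astype(float) * spacing
    cov = np.cov(coords, rowvar=False, bias=False)
    eigvals = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    major = 4.0 * np.sqrt(eigvals[0])
    minor = 4.0 * np.sqrt(eigvals[1]) if eigvals.size > 1 else 0.0
    elong = float(np.sqrt(eigvals[1] / eigvals[0])) if eigvals[0] > 0 else float("nan")

    sphericity = (
        2.0 * np.sqrt(np.pi * mesh_area) / perimeter if perimeter > 0 else float("nan")
    )
    return {
        "MeshSurface": mesh_area,
        "PixelSurface": pixel_surface,
        "Perimeter": perimeter,
        "PerimeterSurfaceRatio": perimeter / mesh_area if mesh_area > 0 else float("nan"),
        "Sphericity": float(sphericity),
        "MaximumDiameter": max_diam,
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "Elongation": elong,
    }
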