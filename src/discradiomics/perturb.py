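"""Image/mask perturbation operators for feature-robustness probing.

Six operator kinds: morphological dilation and erosion with a 2x2 square
structuring element (mask only), per-boundary-pixel contour randomization
(mask only), random integer translation of 1-10 pixels per axis and random
rotation of 1-360 degrees (image + mask), and additive Gaussian image noise
with SD 8 clipped to [0, 255] (image only).

The 2x2 structuring element has no center pixel, so an anchor convention is
required; the top-left element is the anchor here.  Under that convention
``dilate(m)[i, j] = m[i, j] | m[i-1, j] | m[i, j-1] | m[i-1, j-1]`` and
erosion is its dual (the mask survives at (i, j) only if the 2x2 block
anchored there is fully inside).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PerturbationSpec",
    "PERTURBATION_KINDS",
    "dilate",
    "erode",
    "randomize_contour",
    "draw_shift",
    "translate",
    "rotate",
    "add_noise",
    "build_perturbation_suite",
    "apply_perturbation",
]

PERTURBATION_KINDS = (
    "dilation",
    "erosion",
    "contour_randomization",
    "translation",
    "rotation",
    "gaussian_noise",
)

_TARGETS = {
    "dilation": "mask",
    "erosion": "mask",
    "contour_randomization": "mask",
    "translation": "image+mask",
    "rotation": "image+mask",
    "gaussian_noise": "image",
}

_STOCHASTIC = ("contour_randomization", "translation", "rotation", "gaussian_noise")


@dataclass(frozen=True)
class PerturbationSpec:
    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")

    @property
    def target(self) -> str:
        return _TARGETS[self.kind]

    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": dict(self.params), "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "PerturbationSpec":
        return cls(kind=d["kind"], params=dict(d.get("params", {})), seed=int(d.get("seed", 0)))


def _shifted(m: np.ndarray, dy: int, dx: int, fill: bool) -> np.ndarray:
    """Mask shifted by (dy, dx), out-of-frame filled with ``fill``."""
    out = np.full(m.shape, fill, dtype=bool)
    h, w = m.shape
    ys = slice(max(dy, 0), h + min(dy, 0))
    xs = slice(max(dx, 0), w + min(dx, 0))
    ys2 = slice(max(-dy, 0), h + min(-dy, 0))
    xs2 = slice(max(-dx, 0), w + min(-dx, 0))
    out[ys, xs] = m[ys2, xs2]
    return out


def dilate(mask: np.ndarray) -> np.ndarray:
    """2x2 square dilation, top-left anchor; output is a superset."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return (
        mask
        | _shifted(mask, 1, 0, False)
        | _shifted(mask, 0, 1, False)
        | _shifted(mask, 1, 1, False)
    )


def erode(mask: np.ndarray) -> np.ndarray:
    """2x2 square erosion, top-left anchor (dual of :func:`dilate`)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return (
        mask
        & _shifted(mask, -1, 0, False)
        & _shifted(mask, 0, -1, False)
        & _shifted(mask, -1, -1, False)
    )


def randomize_contour(
    mask: np.ndarray, rng: np.random.Generator, p_dilate: float = 0.5
) -> np.ndarray:
    """Randomly erode or dilate each boundary neighbourhood of the mask.

    Each boundary pixel draws Bernoulli(``p_dilate``): chosen pixels locally
    dilate (their 2x2 dilation footprint is added), the rest locally erode
    (the pixel is removed).  The interior is preserved.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    boundary = mask & ~ndimage.binary_erosion(mask)
    choose = rng.random(mask.shape) < p_dilate
    grow_seed = boundary & choose
    grow = (
        grow_seed
        | _shifted(grow_seed, 1, 0, False)
        | _shifted(grow_seed, 0, 1, False)
        | _shifted(grow_seed, 1, 1, False)
    )
    shrink = boundary & ~choose
    return (mask | grow) & ~shrink


def draw_shift(rng: np.random.Generator, max_shift: int = 10) -> tuple[int, int]:
    """Draw a translation: magnitude uniform in 1..max_shift, random sign, per axis."""
    mag = rng.integers(1, max_shift + 1, size=2)
    sign = rng.choice((-1, 1), size=2)
    return int(mag[0] * sign[0]), int(mag[1] * sign[1])


def translate(
    image: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator | None = None,
    max_shift: int = 10,
    shift: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integer shift of both image and mask; out-of-frame pixels filled with 0.

    Without an explicit ``shift`` the magnitude is uniform in 1..``max_shift``
    per axis with random sign.
    """
    if shift is None:
        if rng is None:
            raise ValueError("either rng or shift is required")
        dy, dx = draw_shift(rng, max_shift)
    else:
        dy, dx = int(shift[0]), int(shift[1])
    img = np.asarray(image, dtype=float)
    out_img = np.zeros_like(img)
    h, w = img.shape
    ys = slice(max(dy, 0), h + min(dy, 0))
    xs = slice(max(dx, 0), w + min(dx, 0))
    ys2 = slice(max(-dy, 0), h + min(-dy, 0))
    xs2 = slice(max(-dx, 0), w + min(-dx, 0))
    out_img[ys, xs] = img[ys2, xs2]
    out_mask = _shifted(np.asarray(mask, dtype=bool), dy, dx, False)
    return out_img, out_mask


def rotate(
    image: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator | None = None,
    angle: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rotation about the image center, random in 1-360 degrees by default.

    Image interpolation is bilinear; the mask uses nearest-neighbour and is
    re-binarized at 0.5.  Out-of-frame regions are filled with 0.
    """
    if angle is None:
        if rng is None:
            raise ValueError("either rng or angle is required")
        angle = float(rng.uniform(1.0, 360.0))
    img = ndimage.rotate(
        np.asarray(image, dtype=float), angle, reshape=False, order=1, cval=0.0
    )
    m = ndimage.rotate(
        np.asarray(mask, dtype=float), angle, reshape=False, order=0, cval=0.0
    )
    return img, m > 0.5


def add_noise(
    image: np.ndarray, rng: np.random.Generator, sd: float = 8.0
) -> np.ndarray:
    """Per-pixel Gaussian noise (mean 0, SD ``sd``), clipped to [0, 255]."""
    img = np.asarray(image, dtype=float)
    noisy = img + rng.normal(0.0, sd, img.shape)
    return np.clip(noisy, 0.0, 255.0)


def build_perturbation_suite(
    replicates: int = 1, seed: int = 0
) -> list[PerturbationSpec]:
    """Default robustness suite: the six operators with per-spec seeds.

    ``replicates > 1`` adds extra seeded replicates of the stochastic
    operators (contour randomization, translation, rotation, noise), so the
    suite can be grown to 9+ matched sets.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    specs = [
        PerturbationSpec("dilation", seed=seed),
        PerturbationSpec("erosion", seed=seed),
    ]
    for r in range(replicates):
        for kind in _STOCHASTIC:
            specs.append(PerturbationSpec(kind, seed=seed + 1000 * r + hash(kind) % 997))
    return specs


def apply_perturbation(
    spec: PerturbationSpec,
    image: np.ndarray,
    mask: np.ndarray,
    extra_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Apply one spec to an (image, mask) pair.

    Returns ``(image, mask, ok)``; ``ok`` is False when the perturbation
    emptied the mask (the replicate is flagged for exclusion, never silently
    dropped).  ``extra_seed`` decorrelates draws across discs/slices while
    keeping the suite reproducible.
    """
    rng = np.random.default_rng((spec.seed, extra_seed))
    img = np.asarray(image, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if spec.kind == "dilation":
        m = dilate(m)
    elif spec.kind == "erosion":
        m = erode(m)
    elif spec.kind == "contour_randomization":
        m = randomize_contour(m, rng, spec.params.get("p_dilate", 0.5))
    elif spec.kind == "translation":
        img, m = translate(img, m, rng, spec.params.get("max_shift", 10))
    elif spec.kind == "rotation":
        img, m = rotate(img, m, rng)
    elif spec.kind == "gaussian_noise":
        img = add_noise(img, rng, spec.params.get("sd", 8.0))
    return img, m, bool(m.any())
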