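"""Synthetic sagittal spine phantoms with known grade-dependent structure.

Each :class:`DiscSample` is a small multi-slice sagittal crop holding one
intervertebral disc (IVD) between its two adjacent vertebral bodies, a bright
cerebrospinal-fluid (CSF) band posterior to the disc column, and per-slice
binary masks for each structure.  Degeneration is encoded on the ordinal
Pfirrmann scale (grades 2–5; grades 1 and 2 pooled): higher grades render a
flatter disc (lower disc-height / vertebral-height ratio), a dimmer and more
homogeneous nucleus (lower nucleus–annulus contrast and heterogeneity), and a
higher chance of osteophyte-like mask protrusions.  These monotone encodings
are the ground truth the downstream radiomics pipeline must recover: mean
disc-mask sphericity and disc-intensity interquartile range both decrease
with grade by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "AcquisitionGeometry",
    "DiscPhenotype",
    "DiscSample",
    "DiscSlice",
    "SyntheticCohort",
    "make_geometry",
    "sample_phenotype",
    "render_disc",
    "make_cohort",
    "make_dl_like_mask",
    "GRADES",
    "GRADE_PREVALENCE",
]

GRADES = (2, 3, 4, 5)

#: Default grade mix: population prevalence of Pfirrmann grades 2-5 in a
#: middle-aged birth-cohort sample (46.6 / 31.7 / 16.4 / 5.3 %).
GRADE_PREVALENCE = (0.466, 0.317, 0.164, 0.053)

#: Grade-conditional phenotype means for grades 2..5.
HEIGHT_RATIO_MEANS = {2: 0.40, 3: 0.33, 4: 0.25, 5: 0.15}
NP_AF_CONTRAST_MEANS = {2: 90.0, 3: 55.0, 4: 25.0, 5: 8.0}
HETEROGENEITY_SD_MEANS = {2: 25.0, 3: 30.0, 4: 20.0, 5: 10.0}
OSTEOPHYTE_PROB = {2: 0.05, 3: 0.15, 4: 0.35, 5: 0.5}

#: Probability of focal high-intensity zones (fluid signal in annular
#: fissures) by grade.  These small bright foci in otherwise dim degenerated
#: discs make histogram-peak indices unreliable while leaving quartile-based
#: dispersion features untouched; they peak in moderate degeneration, where a
#: partially preserved disc can still carry bright fluid signal.
FOCAL_HIZ_PROB = {2: 0.02, 3: 0.10, 4: 0.15, 5: 0.05}

#: Additive Gaussian pixel-noise SD (gray levels), clipped to [0, 255].
PIXEL_NOISE_SD = 6.0

LEVELS = ("L1/L2", "L2/L3", "L3/L4", "L4/L5", "L5/S1")

#: Caudally increasing structure size: lower lumbar discs and vertebrae are
#: wider than upper ones.  Size variation (level trend + individual spread)
#: decorrelates size-driven features (areas, axis lengths) from compactness
#: features (sphericity, elongation), as in real cohorts.
LEVEL_SIZE_FACTOR = {
    "L1/L2": 0.90,
    "L2/L3": 0.95,
    "L3/L4": 1.00,
    "L4/L5": 1.06,
    "L5/S1": 1.12,
}


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Scan geometry of the sagittal T2-weighted acquisition."""

    in_plane_spacing: float  # mm / pixel
    slice_thickness: float = 3.0  # mm
    slice_gap: float = 1.0  # mm
    image_size: int = 512  # square, pixels
    n_slices_per_disc: int = 4

    def __post_init__(self) -> None:
        if self.in_plane_spacing <= 0:
            raise ValueError("in_plane_spacing must be positive")
        if self.image_size < 128:
            raise ValueError("image_size must be >= 128")
        if self.n_slices_per_disc not in (4, 5):
            raise ValueError("n_slices_per_disc must be 4 or 5")


@dataclass(frozen=True)
class DiscPhenotype:
    """Grade-conditional generative parameters of a single disc."""

    grade: int
    height_ratio: float  # disc height / vertebral body height
    np_mean_intensity: float  # nucleus mean gray level, 0-255
    np_af_contrast: float  # nucleus - annulus gray-level difference, >= 0
    heterogeneity_sd: float  # within-nucleus texture SD, gray levels
    osteophyte_flag: bool


@dataclass
class DiscSlice:
    """One sagittal slice of a disc sample."""

    image: np.ndarray  # uint8, 0-255
    disc_mask: np.ndarray  # bool
    sup_vb_mask: np.ndarray  # bool
    inf_vb_mask: np.ndarray  # bool
    csf_center: tuple[int, int]  # (row, col)


@dataclass
class DiscSample:
    subject_id: str
    level: str
    slices: list[DiscSlice]
    grade: int
    geometry: AcquisitionGeometry


@dataclass
class SyntheticCohort:
    subjects: list[str]
    discs: list[DiscSample]
    grade_distribution: tuple[float, ...]
    seed: int

    def __len__(self) -> int:
        return len(self.discs)


def make_geometry(
    fov_mm: float,
    matrix_size: int,
    thickness_mm: float = 3.0,
    gap_mm: float = 1.0,
    n_slices: int = 4,
) -> AcquisitionGeometry:
    """Build an :class:`AcquisitionGeometry` from field of view and matrix size.

    In-plane spacing is ``fov_mm / matrix_size`` (e.g. a 280 mm field of view
    on a 512 matrix gives 0.546875 mm/pixel).
    """
    if fov_mm <= 0 or matrix_size <= 0:
        raise ValueError("fov_mm and matrix_size must be positive")
    if thickness_mm <= 0:
        raise ValueError("thickness_mm must be positive")
    return AcquisitionGeometry(
        in_plane_spacing=fov_mm / matrix_size,
        slice_thickness=thickness_mm,
        slice_gap=gap_mm,
        image_size=int(matrix_size),
        n_slices_per_disc=n_slices,
    )


def sample_phenotype(grade: int, rng: np.random.Generator) -> DiscPhenotype:
    """Draw grade-conditional disc phenotype parameters.

    Means by grade 2..5: height ratio {0.40, 0.33, 0.25, 0.15}, nucleus-annulus
    contrast {90, 55, 25, 8} gray levels, heterogeneity SD {25, 30, 20, 10},
    osteophyte probability {0.05, 0.15, 0.35, 0.5}.  Height ratio and contrast
    are strictly decreasing in expectation with grade.
    """
    if grade not in GRADES:
        raise ValueError(f"grade must be one of {GRADES}, got {grade!r}")
    # spreads are wide: disc geometry varies a lot between individuals at the
    # same degeneration stage, which is why height-based indices correlate
    # only moderately with grade in population cohorts
    height_ratio = float(
        np.clip(rng.normal(HEIGHT_RATIO_MEANS[grade], 0.08), 0.05, 0.55)
    )
    contrast = float(np.clip(rng.normal(NP_AF_CONTRAST_MEANS[grade], 10.0), 0.0, 160.0))
    het = float(np.clip(rng.normal(HETEROGENEITY_SD_MEANS[grade], 3.0), 1.0, 60.0))
    np_mean = float(np.clip(40.0 + contrast + rng.normal(0.0, 5.0), 30.0, 230.0))
    osteo = bool(rng.random() < OSTEOPHYTE_PROB[grade])
    return DiscPhenotype(
        grade=grade,
        height_ratio=height_ratio,
        np_mean_intensity=np_mean,
        np_af_contrast=contrast,
        heterogeneity_sd=het,
        osteophyte_flag=osteo,
    )


def _ellipse_mask(
    shape: tuple[int, int], center: tuple[float, float], semi: tuple[float, float]
) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    cy, cx = center
    ay, ax = semi
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _rounded_rect_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    half: tuple[float, float],
    corner: float,
) -> np.ndarray:
    """Axis-aligned rounded rectangle (rounded-corner radius ``corner`` px)."""
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    cy, cx = center
    hy, hx = half
    dy = np.abs(yy - cy) - (hy - corner)
    dx = np.abs(xx - cx) - (hx - corner)
    dy = np.maximum(dy, 0.0)
    dx = np.maximum(dx, 0.0)
    return dy**2 + dx**2 <= corner**2


def _smooth_noise(
    shape: tuple[int, int], sd: float, rng: np.random.Generator, corr_px: float = 1.5
) -> np.ndarray:
    """Spatially correlated zero-mean Gaussian field with pointwise SD ``sd``."""
    raw = rng.normal(0.0, 1.0, shape)
    sm = ndimage.gaussian_filter(raw, corr_px)
    s = sm.std()
    if s == 0:
        return np.zeros(shape)
    return sm / s * sd


def render_disc(
    phenotype: DiscPhenotype,
    geometry: AcquisitionGeometry,
    rng: np.random.Generator,
    *,
    subject_id: str = "S0000",
    level: str = "L4/L5",
    noise_sd: float = PIXEL_NOISE_SD,
) -> DiscSample:
    """Render a multi-slice disc phantom from a phenotype.

    The disc is a (possibly flattened, possibly osteophyte-notched) ellipse
    with a bright nucleus and darker annulus rim; vertebral bodies are rounded
    rectangles above and below; CSF is a bright vertical band posterior to the
    disc column.  Per-slice masks match the rendered supports exactly and are
    mutually disjoint.  Additive Gaussian noise (SD ``noise_sd``) is clipped
    to [0, 255].
    """
    n = geometry.image_size
    sp = geometry.in_plane_spacing
    shape = (n, n)
    cy, cx = n / 2.0, n * 0.42  # disc center, anterior of image midline

    # Structure sizes in mm, converted to pixels; caudal levels are larger
    size_f = LEVEL_SIZE_FACTOR.get(level, 1.0)
    vb_height_mm = (24.0 + rng.normal(0.0, 2.0)) * size_f
    vb_height = max(vb_height_mm / sp, 12.0)
    disc_width = max((34.0 + rng.normal(0.0, 3.5)) * size_f / sp, 10.0)
    disc_height = max(phenotype.height_ratio * vb_height, 2.5)
    vb_width = disc_width * 1.02
    gap = max(1.5 / sp, 2.0)  # disc-vertebra gap (cartilage endplate)

    csf_x0 = cx + disc_width / 2 + max(4.0 / sp, 4.0)
    csf_w = max(5.0 / sp, 4.0)

    af_base = 38.0 + rng.normal(0.0, 3.0)
    vb_value = 95.0 + rng.normal(0.0, 4.0)
    csf_value = 235.0
    bg_value = 12.0

    # focal high-intensity zones: small bright foci, mostly in degenerated
    # discs; drawn once per disc so they persist across slices
    foci: list[tuple[float, float, float, float]] = []
    if rng.random() < FOCAL_HIZ_PROB[phenotype.grade]:
        for _ in range(int(rng.integers(1, 3))):
            foci.append(
                (
                    rng.uniform(-0.5, 0.5),  # fractional offset of semi-axes
                    rng.uniform(-0.6, 0.6),
                    max(1.2 / sp, 1.2) * rng.uniform(0.8, 1.2),  # radius px
                    rng.uniform(160.0, 210.0),  # gray value
                )
            )

    slices: list[DiscSlice] = []
    k = geometry.n_slices_per_disc
    for s in range(k):
        # mild through-plane tapering: outer slices slightly smaller
        t = abs(s - (k - 1) / 2.0) / max(k / 2.0, 1.0)
        scale = 1.0 - 0.08 * t**2
        a_x = disc_width / 2 * scale
        a_y = disc_height / 2 * scale

        disc = _ellipse_mask(shape, (cy, cx), (a_y, a_x))
        nucleus = _ellipse_mask(shape, (cy, cx), (max(a_y * 0.62, 1.0), a_x * 0.62))

        if phenotype.osteophyte_flag:
            # anterior osteophyte: small protrusion at the disc's anterior edge
            oy = cy + rng.normal(0.0, a_y * 0.2)
            ox = cx - a_x
            r = max(2.2, a_y * 0.5)
            disc |= _ellipse_mask(shape, (oy, ox), (r, r))

        vb_half = (vb_height / 2.0, vb_width / 2.0)
        sup_c = (cy - a_y - gap - vb_half[0], cx)
        inf_c = (cy + a_y + gap + vb_half[0], cx)
        corner = max(2.0 / sp, 2.0)
        sup = _rounded_rect_mask(shape, sup_c, vb_half, corner)
        inf = _rounded_rect_mask(shape, inf_c, vb_half, corner)
        sup &= ~disc
        inf &= ~disc & ~sup

        csf = np.zeros(shape, dtype=bool)
        x0, x1 = int(round(csf_x0)), int(round(csf_x0 + csf_w))
        csf[:, max(x0, 0) : min(x1, n)] = True
        csf &= ~(disc | sup | inf)

        img = np.full(shape, bg_value, dtype=float)
        img[sup] = vb_value
        img[inf] = vb_value
        img[csf] = csf_value
        img[disc] = af_base
        nucleus &= disc
        img[nucleus] = phenotype.np_mean_intensity
        if nucleus.any():
            het = _smooth_noise(shape, phenotype.heterogeneity_sd, rng)
            img[nucleus] += het[nucleus]
        for fy, fx, r, val in foci:
            spot = _ellipse_mask(shape, (cy + fy * a_y, cx + fx * a_x), (r, r))
            spot &= disc
            img[spot] = val
        if noise_sd > 0:
            img += rng.normal(0.0, noise_sd, shape)
        img = np.clip(img, 0, 255).astype(np.uint8)

        csf_center = (int(round(cy)), int(round((x0 + x1) / 2)))
        slices.append(
            DiscSlice(
                image=img,
                disc_mask=disc,
                sup_vb_mask=sup,
                inf_vb_mask=inf,
                csf_center=csf_center,
            )
        )
    return DiscSample(
        subject_id=subject_id,
        level=level,
        slices=slices,
        grade=phenotype.grade,
        geometry=geometry,
    )


def make_cohort(
    n_subjects: int,
    grade_distribution: tuple[float, ...] = GRADE_PREVALENCE,
    geometry: AcquisitionGeometry | None = None,
    seed: int = 0,
    render: bool = True,
) -> SyntheticCohort:
    """Generate a cohort of ``n_subjects`` subjects with 5 discs each.

    Grades are drawn i.i.d. per disc from ``grade_distribution`` (defaults to
    the population prevalence of grades 2-5).  Fully reproducible under
    ``seed``.  With ``render=False`` the discs carry their subject, level and
    grade but no rendered slices — useful for cohort-level arithmetic
    (splitting, prevalence checks) at sizes where holding every pixel in
    memory is pointless.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    gd = np.asarray(grade_distribution, dtype=float)
    if gd.shape != (4,):
        raise ValueError("grade_distribution must have 4 entries (grades 2-5)")
    if abs(gd.sum() - 1.0) > 1e-9:
        raise ValueError("grade_distribution must sum to 1")
    if geometry is None:
        geometry = make_geometry(280.0, 512)
    rng = np.random.default_rng(seed)
    subjects = [f"S{i:04d}" for i in range(n_subjects)]
    discs: list[DiscSample] = []
    for sid in subjects:
        grades = rng.choice(GRADES, size=len(LEVELS), p=gd)
        for level, g in zip(LEVELS, grades):
            pheno = sample_phenotype(int(g), rng)
            if render:
                discs.append(
                    render_disc(pheno, geometry, rng, subject_id=sid, level=level)
                )
            else:
                discs.append(
                    DiscSample(
                        subject_id=sid, level=level, slices=[],
                        grade=pheno.grade, geometry=geometry,
                    )
                )
    return SyntheticCohort(
        subjects=subjects,
        discs=discs,
        grade_distribution=tuple(float(v) for v in gd),
        seed=seed,
    )


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return float(inter) / float(union) if union else float("nan")


def make_dl_like_mask(
    truth_mask: np.ndarray,
    rng: np.random.Generator,
    jaccard_band: tuple[float, float] = (0.75, 0.90),
    max_tries: int = 25,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Emulate an imperfect automatic segmentation of ``truth_mask``.

    Applies a small random translation plus independent boundary jitter
    (per-boundary-pixel erode/dilate), then retries with re-scaled jitter until
    the Jaccard index against truth falls inside ``jaccard_band``.  With
    ``amplitude`` 0 the truth mask is returned unchanged (Jaccard 1).  Raises
    if the mask is too small for a meaningful perturbation (< 4 pixels).
    """
    truth_mask = np.asarray(truth_mask, dtype=bool)
    if truth_mask.sum() == 0:
        raise ValueError("truth mask is empty")
    if truth_mask.sum() < 4:
        raise ValueError("truth mask too small to perturb meaningfully")
    if amplitude == 0:
        return truth_mask.copy()
    lo, hi = jaccard_band
    if not (0 < lo < hi <= 1):
        raise ValueError("invalid jaccard band")

    amp = float(amplitude)
    best = None
    for _ in range(max_tries):
        m = truth_mask.copy()
        # sub-structuring translation of up to round(amp) pixels per axis
        shift = rng.integers(-max(int(round(amp)), 1), max(int(round(amp)), 1) + 1, 2)
        m = np.roll(m, tuple(shift), axis=(0, 1))
        # boundary jitter: randomly erode/dilate boundary neighbourhoods
        n_iter = max(int(round(amp)), 1)
        for _ in range(n_iter):
            boundary = m ^ ndimage.binary_erosion(m)
            noise = rng.random(m.shape) < 0.5
            grow = ndimage.binary_dilation(boundary & noise)
            shrink = boundary & ~noise
            m = (m | grow) & ~shrink
        # automatic segmentations have smooth contours: low-pass the jittered
        # mask so the boundary is displaced but not pixel-rough
        m = ndimage.gaussian_filter(m.astype(float), 0.9) > 0.5
        # keep the largest connected component to stay mask-like
        lab, nlab = ndimage.label(m)
        if nlab > 1:
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, range(1, nlab + 1))
            m = lab == (1 + int(np.argmax(sizes)))
        j = _jaccard(m, truth_mask)
        if m.any() and lo <= j <= hi:
            return m
        if best is None or abs(j - (lo + hi) / 2) < best[0]:
            best = (abs(j - (lo + hi) / 2), m)
        amp = amp * 1.3 if j > hi else max(amp / 1.3, 0.5)
    return best[1]
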