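"""Cohort writers: PNG slices and masks, CSV manifest, YAML sidecar, NIfTI."""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

__all__ = ["write_cohort", "write_disc_nifti", "write_perturbed_pair"]


def _save_png(path: Path, arr: np.ndarray) -> None:
    Image.fromarray(np.asarray(arr, dtype=np.uint8)).save(path)


def write_cohort(cohort, outdir, write_nifti: bool = False) -> pd.DataFrame:
    """Write per-slice 8-bit PNG images/masks plus a manifest CSV and YAML sidecar.

    Returns the manifest (subject_id, level, grade, per-slice file paths).
    Masks are stored as 0/255 PNGs; an optional NIfTI volume per disc carries
    the acquisition spacing metadata.
    """
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for d, disc in enumerate(cohort.discs):
        stem = f"{disc.subject_id}_{disc.level.replace('/', '-')}"
        paths = []
        for k, sl in enumerate(disc.slices):
            img_p = outdir / "images" / f"{stem}_s{k}.png"
            _save_png(img_p, sl.image)
            _save_png(outdir / "images" / f"{stem}_s{k}_disc.png", sl.disc_mask * 255)
            _save_png(outdir / "images" / f"{stem}_s{k}_supvb.png", sl.sup_vb_mask * 255)
            _save_png(outdir / "images" / f"{stem}_s{k}_infvb.png", sl.inf_vb_mask * 255)
            paths.append(os.fspath(img_p.relative_to(outdir)))
        if write_nifti:
            write_disc_nifti(disc, outdir / "images" / f"{stem}.nii")
        rows.append(
            {
                "subject_id": disc.subject_id,
                "level": disc.level,
                "grade": disc.grade,
                "n_slices": len(disc.slices),
                "image_paths": ";".join(paths),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    geom = cohort.discs[0].geometry
    sidecar = {
        "seed": cohort.seed,
        "n_subjects": len(cohort.subjects),
        "grade_distribution": list(cohort.grade_distribution),
        "geometry": {
            "in_plane_spacing": geom.in_plane_spacing,
            "slice_thickness": geom.slice_thickness,
            "slice_gap": geom.slice_gap,
            "image_size": geom.image_size,
            "n_slices_per_disc": geom.n_slices_per_disc,
        },
    }
    with open(outdir / "cohort.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh)
    return manifest


def write_perturbed_pair(outdir, stem: str, spec, image, mask) -> tuple[Path, Path]:
    """Write a perturbed (image, mask) pair with the ``_pert-<kind>-<seed>`` suffix."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = f"_pert-{spec.kind}-{spec.seed}"
    img_p = outdir / f"{stem}{suffix}.png"
    mask_p = outdir / f"{stem}{suffix}_mask.png"
    _save_png(img_p, np.clip(image, 0, 255))
    _save_png(mask_p, np.asarray(mask, dtype=np.uint8) * 255)
    return img_p, mask_p


def write_disc_nifti(disc, path) -> None:
    """Write the disc's image stack as a NIfTI volume with spacing metadata."""
    import nibabel as nib

    geom = disc.geometry
    vol = np.stack([sl.image for sl in disc.slices], axis=-1).astype(np.uint8)
    affine = np.diag(
        [
            geom.in_plane_spacing,
            geom.in_plane_spacing,
            geom.slice_thickness + geom.slice_gap,
            1.0,
        ]
    )
    nib.save(nib.Nifti1Image(vol, affine), os.fspath(path))
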