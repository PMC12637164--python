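"""End-to-end experiment orchestration and the participant-stratified split.

:func:`run_experiment` executes the study stages on synthetic data —
phantom generation, feature extraction, perturbation robustness, the
selection cascade, model training and test-set evaluation — and returns an
:class:`ExperimentResults` bundle with a ``summary()`` table covering the
four model variants (conventional-index SVM, best-two-radiomics SVM,
texture-only sparse PLS-DA, all-features sparse PLS-DA).  Stages write their
artifacts under the configured output directory keyed by a config hash, so a
rerun with the same configuration and seed reproduces the bundle and
completed stages can be reloaded instead of recomputed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import bootstrap_ci, classification_metrics
from .features import extract_cohort_features, extract_disc_features
from .indices import indices_for_disc
from .perturb import apply_perturbation, build_perturbation_suite
from .preprocess import PreprocessConfig
from .robustness import compute_robustness_table, selection_cascade
from .splsda import SPLSDA, svm_baseline, tune_splsda
from .synth import make_cohort, make_dl_like_mask, make_geometry

__all__ = ["PipelineConfig", "SplitSpec", "split_cohort", "run_experiment", "ExperimentResults"]

log = logging.getLogger("discradiomics")

_TEXTURE_CLASSES = ("glcm", "gldm", "glrlm", "glszm", "ngtdm")


@dataclass(frozen=True)
class SplitSpec:
    dev_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.dev_fraction < 1:
            raise ValueError("dev_fraction must be in (0, 1)")


@dataclass
class PipelineConfig:
    """Serializable configuration of the whole experiment."""

    seed: int = 0
    outdir: str = "experiment_out"
    # geometry
    fov_mm: float = 280.0
    matrix_size: int = 512
    slice_thickness_mm: float = 3.0
    slice_gap_mm: float = 1.0
    n_slices: int = 4
    # synth
    n_subjects: int = 50
    grade_distribution: tuple[float, ...] = (0.466, 0.317, 0.164, 0.053)
    # preprocess
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    # segmentation source for the main feature table: emulated imperfect
    # (DL-like) masks, as in a deployed automatic pipeline; truth masks are
    # the robustness reference
    use_dl_masks: bool = True
    # perturbations
    perturbation_replicates: int = 1
    n_robust_discs: int = 60
    # selection
    relevance_alpha: float = 0.05
    redundancy_threshold: float = 0.90
    area_threshold: float = 0.90
    # split
    split: SplitSpec = field(default_factory=SplitSpec)
    # models
    component_grid: tuple[int, ...] = (1, 2, 3)
    keepx_grid: tuple = (2, 5, 10, None)
    cv_repeats: int = 2
    cv_folds: int = 5
    # evaluation
    n_boot: int = 200

    def to_dict(self) -> dict:
        d = asdict(self)
        d["preprocess"] = self.preprocess.to_dict()
        d["split"] = {"dev_fraction": self.split.dev_fraction}
        d["grade_distribution"] = [float(v) for v in self.grade_distribution]
        d["component_grid"] = [int(v) for v in self.component_grid]
        d["keepx_grid"] = [None if v is None else int(v) for v in self.keepx_grid]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "preprocess" in d:
            d["preprocess"] = PreprocessConfig.from_dict(d["preprocess"])
        if "split" in d:
            d["split"] = SplitSpec(**d["split"])
        for key in ("grade_distribution", "component_grid", "keepx_grid"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def split_cohort(cohort, spec: SplitSpec, seed: int = 0) -> tuple[list[int], list[int]]:
    """Participant-stratified development/test split, returning disc indices.

    Participants are assigned wholly to one partition.  Stratification keys
    are the participants' sorted grade multisets, so the grade mix is matched
    between partitions to the granularity participant-level assignment
    allows; partition sizes land within one participant of the target
    fraction.
    """
    if len(cohort.discs) == 0:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(seed)
    by_subject: dict[str, list[int]] = {}
    key: dict[str, tuple] = {}
    for i, disc in enumerate(cohort.discs):
        by_subject.setdefault(disc.subject_id, []).append(i)
        key.setdefault(disc.subject_id, tuple())
    for sid, idxs in by_subject.items():
        key[sid] = tuple(sorted(cohort.discs[i].grade for i in idxs))

    strata: dict[tuple, list[str]] = {}
    for sid, k in key.items():
        strata.setdefault(k, []).append(sid)
    singletons = [s for s, members in strata.items() if len(members) < 2]
    if singletons:
        warnings.warn(
            f"{len(singletons)} grade-profile strata have a single participant; "
            "best-effort stratification"
        )

    test_frac = 1.0 - spec.dev_fraction
    n_target = int(round(test_frac * len(by_subject)))
    test_subjects: list[str] = []
    carry = 0.0
    for k in sorted(strata):
        members = sorted(strata[k])
        rng.shuffle(members)
        want = test_frac * len(members) + carry
        take = int(round(want))
        take = min(take, len(members))
        carry = want - take
        test_subjects.extend(members[:take])
    # final nudge to the global target, ±1 participant
    while len(test_subjects) > n_target + 1:
        test_subjects.pop(rng.integers(0, len(test_subjects)))
    dev_idx, test_idx = [], []
    test_set = set(test_subjects)
    for sid, idxs in by_subject.items():
        (test_idx if sid in test_set else dev_idx).extend(idxs)
    return sorted(dev_idx), sorted(test_idx)


@dataclass
class ExperimentResults:
    """Bundle of the experiment's tables, models and reports."""

    config: PipelineConfig
    features: pd.DataFrame
    dev_index: list[int]
    test_index: list[int]
    robustness: object
    ledger: object
    selected_features: list[str]
    tuning: object
    reports: dict[str, dict]
    top_two: tuple[str, str]

    def summary(self) -> str:
        lines = [
            "Synthetic disc-degeneration grading experiment",
            "==============================================",
            f"discs: {len(self.features)}  (dev {len(self.dev_index)}, test {len(self.test_index)})",
            f"features surviving screening: {len(self.selected_features)}",
            f"top-two radiomic features: {self.top_two[0]}, {self.top_two[1]}",
            "",
            f"{'model':<28}{'BA':>8}{'kappa':>8}{'QW kappa':>10}",
        ]
        for name, rep in self.reports.items():
            lines.append(
                f"{name:<28}{rep['balanced_accuracy']:>8.3f}"
                f"{rep['cohen_kappa']:>8.3f}{rep['quadratic_weighted_kappa']:>10.3f}"
            )
        return "\n".join(lines)


def _feature_cols(df: pd.DataFrame) -> list[str]:
    meta = {"subject_id", "level", "grade", "degenerate", "convidx_DHI", "convidx_PSID"}
    return [c for c in df.columns if c not in meta]


def _evaluate(y_true, y_pred, y_scores, labels, n_boot, seed) -> dict:
    rep = classification_metrics(y_true, y_pred, y_scores, labels=labels)
    out = rep.to_dict()
    if n_boot >= 100:
        from sklearn.metrics import balanced_accuracy_score, cohen_kappa_score

        out["ci"] = {
            "balanced_accuracy": list(
                bootstrap_ci(balanced_accuracy_score, y_true, y_pred, n_boot, seed)
            ),
            "cohen_kappa": list(
                bootstrap_ci(cohen_kappa_score, y_true, y_pred, n_boot, seed + 1)
            ),
        }
    return out


def run_experiment(config: PipelineConfig, resume: bool = True) -> ExperimentResults:
    """Execute the full synthetic study: phantoms through evaluated models."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = config.hash()
    config.to_yaml(outdir / "config.yaml")

    geometry = make_geometry(
        config.fov_mm,
        config.matrix_size,
        config.slice_thickness_mm,
        config.slice_gap_mm,
        config.n_slices,
    )

    log.info("stage synth: %d subjects", config.n_subjects)
    cohort = make_cohort(
        config.n_subjects, tuple(config.grade_distribution), geometry, seed=config.seed
    )
    dev_idx, test_idx = split_cohort(cohort, config.split, seed=config.seed)

    # --- extraction (resumable) ---
    feat_path = outdir / f"features_{tag}.csv"
    if resume and feat_path.exists():
        log.info("stage extract: reusing %s", feat_path)
        features = pd.read_csv(feat_path)
    else:
        log.info("stage extract: %d discs", len(cohort.discs))
        if config.use_dl_masks:
            rng_dl = np.random.default_rng(config.seed + 2)
            records = []
            for disc in cohort.discs:
                dm = [make_dl_like_mask(sl.disc_mask, rng_dl) for sl in disc.slices]
                feats = extract_disc_features(disc, config.preprocess, masks=dm)
                pair = indices_for_disc(disc, disc_masks=dm)
                rec = {
                    "subject_id": disc.subject_id,
                    "level": disc.level,
                    "grade": disc.grade,
                }
                rec.update(feats)
                rec["degenerate"] = any(np.isnan(v) for v in feats.values())
                rec["convidx_DHI"] = pair.disc_height_index
                rec["convidx_PSID"] = pair.peak_signal_intensity_difference
                records.append(rec)
            features = pd.DataFrame.from_records(records)
        else:
            features = extract_cohort_features(cohort, config.preprocess)
            idx_rows = [indices_for_disc(d) for d in cohort.discs]
            features["convidx_DHI"] = [r.disc_height_index for r in idx_rows]
            features["convidx_PSID"] = [
                r.peak_signal_intensity_difference for r in idx_rows
            ]
        features.to_csv(feat_path, index=False)

    fcols = _feature_cols(features)

    # --- perturbation robustness (resumable) ---
    rob_path = outdir / f"robustness_{tag}.csv"
    suite = build_perturbation_suite(config.perturbation_replicates, seed=config.seed)
    rob_discs = [cohort.discs[i] for i in dev_idx[: config.n_robust_discs]]
    if resume and rob_path.exists():
        log.info("stage robustness: reusing %s", rob_path)
        icc_df = pd.read_csv(rob_path, index_col=0)
        from .robustness import RobustnessTable

        robustness = RobustnessTable(
            icc=icc_df, ci_low=icc_df * np.nan, ci_high=icc_df * np.nan,
            n_discs=len(rob_discs),
        )
    else:
        log.info("stage robustness: %d discs x %d perturbations", len(rob_discs), len(suite))
        rng = np.random.default_rng(config.seed + 1)
        ref_rows, pert_rows = [], {f"{s.kind}-{s.seed}": [] for s in suite}
        for di, disc in enumerate(rob_discs):
            ref_rows.append(extract_disc_features(disc, config.preprocess))
            dl_masks = [
                make_dl_like_mask(sl.disc_mask, rng) for sl in disc.slices
            ]
            for s in suite:
                imgs, msks = [], []
                for k, sl in enumerate(disc.slices):
                    img, m, ok = apply_perturbation(s, sl.image, dl_masks[k], extra_seed=di * 16 + k)
                    imgs.append(img)
                    msks.append(m if ok else None)
                pert_rows[f"{s.kind}-{s.seed}"].append(
                    extract_disc_features(disc, config.preprocess, masks=msks, images=imgs)
                )
        reference = pd.DataFrame(ref_rows)
        perturbed = {k: pd.DataFrame(v) for k, v in pert_rows.items()}
        robustness = compute_robustness_table(reference, perturbed)
        robustness.icc.to_csv(rob_path)

    # --- selection cascade on development data ---
    dev = features.iloc[dev_idx].reset_index(drop=True)
    test = features.iloc[test_idx].reset_index(drop=True)
    areas = dev["original_shape2D_MeshSurface"].to_numpy()
    selected_df, ledger, area_model = selection_cascade(
        dev[fcols],
        dev["grade"].to_numpy(),
        robustness,
        areas=areas,
        alpha=config.relevance_alpha,
        redundancy_threshold=config.redundancy_threshold,
        area_threshold=config.area_threshold,
    )
    selected = list(selected_df.columns)
    log.info("stage select: %d features survive", len(selected))
    with open(outdir / f"ledger_{tag}.json", "w") as fh:
        json.dump(ledger.stages, fh, indent=1, default=str)

    test_sel = test[selected]
    if area_model is not None:
        test_sel = area_model.apply(
            test_sel, test["original_shape2D_MeshSurface"].to_numpy()
        )

    y_dev = dev["grade"].to_numpy()
    y_test = test["grade"].to_numpy()
    g_dev = dev["subject_id"].to_numpy()
    labels = sorted(np.unique(features["grade"]).tolist())

    # --- models ---
    log.info("stage train: tuning sparse PLS-DA on %d features", len(selected))
    tuning = tune_splsda(
        selected_df.to_numpy(),
        y_dev,
        groups=g_dev,
        component_grid=config.component_grid,
        keepx_grid=config.keepx_grid,
        n_folds=config.cv_folds,
        n_repeats=config.cv_repeats,
        seed=config.seed,
        feature_names=selected,
    )
    full_model = SPLSDA(
        selected_df.to_numpy(), y_dev,
        n_components=tuning.best_n_components, keep_x=tuning.best_keep_x,
    ).fit()

    # texture-only variant: drop shape and first-order features
    tex_cols = [
        c for c in selected if any(f"_{cls}_" in c for cls in _TEXTURE_CLASSES)
    ]
    reports: dict[str, dict] = {}
    seed_eval = config.seed + 9
    yhat = full_model.predict(test_sel.to_numpy())
    scores = full_model.predict_dummy(test_sel.to_numpy())
    reports["splsda_all_features"] = _evaluate(
        y_test, yhat, scores, labels, config.n_boot, seed_eval
    )

    if tex_cols:
        tex_tuning = tune_splsda(
            selected_df[tex_cols].to_numpy(), y_dev, groups=g_dev,
            component_grid=config.component_grid, keepx_grid=config.keepx_grid,
            n_folds=config.cv_folds, n_repeats=config.cv_repeats,
            seed=config.seed + 3, feature_names=tex_cols,
        )
        tex_model = SPLSDA(
            selected_df[tex_cols].to_numpy(), y_dev,
            n_components=tex_tuning.best_n_components, keep_x=tex_tuning.best_keep_x,
        ).fit()
        yhat = tex_model.predict(test_sel[tex_cols].to_numpy())
        reports["splsda_texture_only"] = _evaluate(
            y_test, yhat, tex_model.predict_dummy(test_sel[tex_cols].to_numpy()),
            labels, config.n_boot, seed_eval + 1,
        )

    # conventional-index SVM
    conv_cols = ["convidx_DHI", "convidx_PSID"]
    conv_model, _ = svm_baseline(
        dev[conv_cols].to_numpy(), y_dev, groups=g_dev, seed=config.seed + 5,
        n_repeats=min(config.cv_repeats, 3),
    )
    yhat = conv_model.predict(test[conv_cols].to_numpy())
    reports["svm_conventional"] = _evaluate(
        y_test, yhat, conv_model.decision_function(test[conv_cols].to_numpy()),
        labels, config.n_boot, seed_eval + 2,
    )

    # best-two radiomics SVM: the two most stable distinct sPLSDA features
    stab = tuning.stability.max(axis=1).sort_values(ascending=False)
    top_two = tuple(stab.index[:2])
    t2_dev = selected_df[list(top_two)].to_numpy()
    t2_model, _ = svm_baseline(
        t2_dev, y_dev, groups=g_dev, seed=config.seed + 6,
        n_repeats=min(config.cv_repeats, 3),
    )
    yhat = t2_model.predict(test_sel[list(top_two)].to_numpy())
    reports["svm_top2_radiomics"] = _evaluate(
        y_test, yhat, t2_model.decision_function(test_sel[list(top_two)].to_numpy()),
        labels, config.n_boot, seed_eval + 3,
    )

    with open(outdir / f"report_{tag}.json", "w") as fh:
        json.dump(reports, fh, indent=1, default=str)
    tuning.grid.to_csv(outdir / f"tuning_grid_{tag}.csv", index=False)
    (outdir / f"model_splsda_{tag}.json").write_text(full_model.to_json())
    for name, rep in reports.items():
        pd.DataFrame(rep["confusion"], index=labels, columns=labels).to_csv(
            outdir / f"confusion_{name}_{tag}.csv"
        )

    return ExperimentResults(
        config=config,
        features=features,
        dev_index=dev_idx,
        test_index=test_idx,
        robustness=robustness,
        ledger=ledger,
        selected_features=selected,
        tuning=tuning,
        reports=reports,
        top_two=top_two,
    )
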