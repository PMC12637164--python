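"""Classification and segmentation-agreement metrics with bootstrap CIs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from sklearn import metrics as skm

__all__ = [
    "ClassReport",
    "SegReport",
    "classification_metrics",
    "bootstrap_ci",
    "segmentation_metrics",
    "lin_ccc",
]


@dataclass
class ClassReport:
    accuracy: float
    balanced_accuracy: float
    macro_f1: float
    macro_auc: float
    cohen_kappa: float
    quadratic_weighted_kappa: float
    lin_ccc: float
    confusion: np.ndarray
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "macro_f1": self.macro_f1,
            "macro_auc": self.macro_auc,
            "cohen_kappa": self.cohen_kappa,
            "quadratic_weighted_kappa": self.quadratic_weighted_kappa,
            "lin_ccc": self.lin_ccc,
            "confusion": self.confusion.tolist(),
        }
        if self.ci:
            d["ci"] = {k: list(v) for k, v in self.ci.items()}
        return d


@dataclass
class SegReport:
    dice: float
    jaccard: float
    hausdorff95_mm: float


def lin_ccc(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Lin's concordance correlation coefficient on (ordinal) labels."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    mx, my = y_true.mean(), y_pred.mean()
    vx, vy = y_true.var(), y_pred.var()
    cov = np.mean((y_true - mx) * (y_pred - my))
    denom = vx + vy + (mx - my) ** 2
    return float(2.0 * cov / denom) if denom > 0 else float("nan")


def classification_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    y_scores: np.ndarray | None = None,
    labels: list[int] | None = None,
) -> ClassReport:
    """Compute the ordinal-grade classification report.

    Balanced accuracy is the mean per-class recall; kappas are Cohen's
    unweighted and quadratic-weighted; Lin's concordance treats the grades as
    numeric.  Macro AUC is one-vs-rest from ``y_scores`` (class-probability
    columns in ``labels`` order) and NaN when scores are absent.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    if labels is None:
        labels = sorted(np.unique(np.concatenate([y_true, y_pred])).tolist())
    if y_scores is not None and len(set(y_true)) > 1:
        try:
            scores = np.asarray(y_scores, dtype=float)
            if len(labels) == 2 and scores.ndim == 2:
                scores = scores[:, 1]
            auc = float(
                skm.roc_auc_score(
                    y_true, scores, multi_class="ovr", average="macro", labels=labels
                )
            )
        except ValueError:
            auc = float("nan")
    else:
        auc = float("nan")
    return ClassReport(
        accuracy=float(skm.accuracy_score(y_true, y_pred)),
        balanced_accuracy=float(skm.balanced_accuracy_score(y_true, y_pred)),
        macro_f1=float(skm.f1_score(y_true, y_pred, labels=labels, average="macro")),
        macro_auc=auc,
        cohen_kappa=float(skm.cohen_kappa_score(y_true, y_pred, labels=labels)),
        quadratic_weighted_kappa=float(
            skm.cohen_kappa_score(y_true, y_pred, labels=labels, weights="quadratic")
        ),
        lin_ccc=lin_ccc(y_true, y_pred),
        confusion=skm.confusion_matrix(y_true, y_pred, labels=labels),
    )


def bootstrap_ci(
    metric_fn,
    y_true: np.ndarray,
    y_pred_or_scores: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI over resampled test rows (disc level)."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    y_true = np.asarray(y_true)
    other = np.asarray(y_pred_or_scores)
    rng = np.random.default_rng(seed)
    n = len(y_true)
    stats = []
    n_nan = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            v = float(metric_fn(y_true[idx], other[idx]))
        except ValueError:
            v = float("nan")
        if np.isnan(v):
            n_nan += 1
        else:
            stats.append(v)
    if n_nan > n_boot / 2:
        raise ValueError("metric undefined in more than half of the resamples")
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def _boundary(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask)


def segmentation_metrics(
    mask_a: np.ndarray, mask_b: np.ndarray, spacing: float = 1.0
) -> SegReport:
    """Dice, Jaccard and 95th-percentile symmetric Hausdorff distance (mm).

    HD95 is the 95th percentile of the pooled boundary-to-boundary nearest
    distances in both directions.  Raises on an empty mask (distances
    undefined).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share shape")
    if not a.any() or not b.any():
        raise ValueError("empty mask: segmentation metrics undefined")
    inter = np.logical_and(a, b).sum()
    dice = 2.0 * inter / (a.sum() + b.sum())
    jacc = inter / np.logical_or(a, b).sum()

    pa = np.argwhere(_boundary(a)).astype(float) * spacing
    pb = np.argwhere(_boundary(b)).astype(float) * spacing
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    hd95 = float(np.percentile(np.concatenate([d_ab, d_ba]), 95))
    return SegReport(dice=float(dice), jaccard=float(jacc), hausdorff95_mm=hd95)
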