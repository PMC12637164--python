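"""Feature screening: relevance, perturbation ICC, clustering, redundancy, area.

The cascade runs in a fixed order on development data: (1) drop features
whose Spearman correlation with grade is not significant; (2) compute, for
every surviving feature and every perturbation, the two-way absolute-
agreement single-measurement intraclass correlation ICC(A,1) between
reference-mask and perturbed-mask feature values; (3) Ward-cluster the
per-feature ICC vectors (k = 2) and keep the cluster with the highest mean
ICC; (4) among feature pairs with |Spearman rho| > 0.90 drop the
lower-variance member; (5) fit per-feature linear adjustments for features
highly correlated with 2D disc surface area, and apply the stored (never
refitted) coefficients to any later data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import f as f_dist
from sklearn.cluster import AgglomerativeClustering

__all__ = [
    "RobustnessTable",
    "SelectionLedger",
    "AreaAdjustmentModel",
    "relevance_filter",
    "icc_two_way",
    "compute_robustness_table",
    "select_robust_cluster",
    "redundancy_filter",
    "fit_area_adjustment",
    "selection_cascade",
]


@dataclass
class RobustnessTable:
    """feature x perturbation ICC matrix with 95% CIs."""

    icc: pd.DataFrame  # rows: features, columns: perturbation names
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    n_discs: int

    @property
    def mean_icc(self) -> pd.Series:
        return self.icc.mean(axis=1)


@dataclass
class SelectionLedger:
    """Ordered record of removals per cascade stage."""

    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, removed: list[str], surviving: list[str], **params):
        self.stages.append(
            {
                "stage": stage,
                "removed": list(removed),
                "n_removed": len(removed),
                "surviving": list(surviving),
                "n_surviving": len(surviving),
                "params": params,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s["stage"],
                    "n_removed": s["n_removed"],
                    "n_surviving": s["n_surviving"],
                    "params": s["params"],
                }
                for s in self.stages
            ]
        )


def relevance_filter(
    features: pd.DataFrame, grades: np.ndarray, alpha: float = 0.05
) -> tuple[list[str], dict[str, str]]:
    """Keep features whose Spearman correlation with grade has p <= alpha.

    Returns (surviving names, removal reasons).  Constant features have an
    undefined p-value and are removed with reason "constant"; NaN-containing
    features are removed with reason "degenerate".
    """
    if len(features) < 3:
        raise ValueError("need at least 3 discs")
    grades = np.asarray(grades)
    surviving: list[str] = []
    removed: dict[str, str] = {}
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        if np.isnan(x).any():
            removed[col] = "degenerate"
            continue
        if np.ptp(x) == 0:
            removed[col] = "constant"
            continue
        rho, p = stats.spearmanr(x, grades)
        if np.isnan(p) or p > alpha:
            removed[col] = "low_relevance"
        else:
            surviving.append(col)
    return surviving, removed


def icc_two_way(
    reference_values: np.ndarray,
    perturbed_values: np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float]]:
    """ICC(A,1): two-way, absolute agreement, single measurement, with CI.

    The point estimate is (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE)/n)
    from the two-way ANOVA mean squares; the 95% CI uses the F-based
    approximation with Satterthwaite degrees of freedom.  Zero variance in
    both measurements is undefined and returns NaN.
    """
    x = np.asarray(reference_values, dtype=float)
    y = np.asarray(perturbed_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    data = np.column_stack([x, y])
    if np.ptp(data) == 0:
        return float("nan"), (float("nan"), float("nan"))
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sst = np.sum((data - grand) ** 2)
    sse = sst - k * np.sum((row_means - grand) ** 2) - n * np.sum((col_means - grand) ** 2)
    mse = max(sse / ((n - 1) * (k - 1)), 0.0)

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return float("nan"), (float("nan"), float("nan"))
    icc = (msr - mse) / denom

    # Satterthwaite-approximate F interval (McGraw-Wong form for A,1)
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a):
        return float(icc), (float(icc), float(icc))
    vn = (k - 1) * (n - 1) * (
        (k * icc * msc + n * (1 + (k - 1) * icc) * mse - k * icc * mse) ** 2
    )
    vd = (n - 1) * (k**2) * (icc**2) * (msc**2) + (
        (n * (1 + (k - 1) * icc) - k * icc) ** 2
    ) * (mse**2)
    if vd <= 0:
        return float(icc), (float("nan"), float("nan"))
    v = vn / vd
    f2u = f_dist.ppf(1 - alpha / 2, n - 1, v)
    f2l = f_dist.ppf(1 - alpha / 2, v, n - 1)
    lb = n * (msr - f2u * mse) / (
        f2u * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    ub = n * (f2l * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2l * msr
    )
    return float(icc), (float(lb), float(ub))


def compute_robustness_table(
    reference: pd.DataFrame,
    perturbed: dict[str, pd.DataFrame],
    features: list[str] | None = None,
) -> RobustnessTable:
    """ICC of every feature under every perturbation against the reference.

    ``reference`` and each entry of ``perturbed`` must be row-aligned feature
    tables over the same discs.
    """
    features = list(features) if features is not None else list(reference.columns)
    icc = {}
    lo = {}
    hi = {}
    for pname, table in perturbed.items():
        if len(table) != len(reference):
            raise ValueError(f"perturbation {pname!r} not row-aligned with reference")
        col_icc, col_lo, col_hi = [], [], []
        for f in features:
            i, (l, h) = icc_two_way(
                reference[f].to_numpy(), table[f].to_numpy()
            )
            col_icc.append(i)
            col_lo.append(l)
            col_hi.append(h)
        icc[pname] = col_icc
        lo[pname] = col_lo
        hi[pname] = col_hi
    return RobustnessTable(
        icc=pd.DataFrame(icc, index=features),
        ci_low=pd.DataFrame(lo, index=features),
        ci_high=pd.DataFrame(hi, index=features),
        n_discs=len(reference),
    )


def select_robust_cluster(table: RobustnessTable, n_clusters: int = 2) -> list[str]:
    """Members of the Ward cluster with the highest mean ICC.

    Features with any NaN ICC are treated as non-robust and excluded before
    clustering.  Deterministic given the table.
    """
    icc = table.icc.dropna(axis=0, how="any")
    if len(icc) < 2:
        return list(icc.index)
    if n_clusters == 1:
        return list(icc.index)
    model = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward")
    labels = model.fit_predict(icc.to_numpy())
    means = [icc.to_numpy()[labels == c].mean() for c in range(n_clusters)]
    best = int(np.argmax(means))
    return list(icc.index[labels == best])


def redundancy_filter(features: pd.DataFrame, threshold: float = 0.90) -> list[str]:
    """Drop the lower-variance member of each highly correlated pair.

    Pairs with |Spearman rho| > ``threshold`` are processed in descending
    |rho| order; a pair is acted on only if both members still survive, so at
    least one member of any correlated group always remains.
    """
    cols = list(features.columns)
    if len(cols) < 2:
        return cols
    rho = features.corr(method="spearman").to_numpy()
    var = features.var().to_numpy()
    pairs = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = abs(rho[i, j])
            if r > threshold:
                pairs.append((r, i, j))
    pairs.sort(reverse=True)
    alive = np.ones(len(cols), dtype=bool)
    for r, i, j in pairs:
        if alive[i] and alive[j]:
            drop = i if var[i] <= var[j] else j
            alive[drop] = False
    return [c for c, a in zip(cols, alive) if a]


@dataclass
class AreaAdjustmentModel:
    """Per-feature linear de-trending against 2D disc surface area.

    Fitted on development data only; ``apply`` always uses the stored
    coefficients.  Adjusted value = residual + development grand mean.
    """

    coefficients: dict[str, tuple[float, float]]  # feature -> (intercept, slope)
    grand_means: dict[str, float]
    adjusted_features: list[str]
    threshold: float

    def apply(self, features: pd.DataFrame, areas: np.ndarray) -> pd.DataFrame:
        out = features.copy()
        areas = np.asarray(areas, dtype=float)
        for f in self.adjusted_features:
            if f not in out.columns:
                continue
            b0, b1 = self.coefficients[f]
            out[f] = features[f].to_numpy() - (b0 + b1 * areas) + self.grand_means[f]
        return out


def fit_area_adjustment(
    features: pd.DataFrame, areas: np.ndarray, threshold: float = 0.90
) -> AreaAdjustmentModel:
    """Flag features with |Spearman(feature, area)| >= threshold and fit lines."""
    areas = np.asarray(areas, dtype=float)
    if np.ptp(areas) == 0:
        raise ValueError("zero-variance area")
    coeffs: dict[str, tuple[float, float]] = {}
    gmeans: dict[str, float] = {}
    flagged: list[str] = []
    for f in features.columns:
        x = features[f].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.isnan(x).any():
            continue
        rho, _ = stats.spearmanr(x, areas)
        if np.isnan(rho) or abs(rho) < threshold:
            continue
        b1, b0 = np.polyfit(areas, x, 1)
        coeffs[f] = (float(b0), float(b1))
        gmeans[f] = float(x.mean())
        flagged.append(f)
    return AreaAdjustmentModel(
        coefficients=coeffs,
        grand_means=gmeans,
        adjusted_features=flagged,
        threshold=threshold,
    )


def selection_cascade(
    features: pd.DataFrame,
    grades: np.ndarray,
    robustness: RobustnessTable | None,
    areas: np.ndarray | None = None,
    alpha: float = 0.05,
    redundancy_threshold: float = 0.90,
    area_threshold: float = 0.90,
) -> tuple[pd.DataFrame, SelectionLedger, AreaAdjustmentModel | None]:
    """Run the full screening cascade in its fixed order.

    Returns the surviving (possibly area-adjusted) development feature table,
    the per-stage removal ledger, and the fitted area-adjustment model (None
    when ``areas`` is not given).
    """
    ledger = SelectionLedger()
    surviving, removed = relevance_filter(features, grades, alpha)
    ledger.record(
        "relevance", sorted(removed), surviving, alpha=alpha,
        reasons={k: v for k, v in removed.items()},
    )
    X = features[surviving]

    if robustness is not None:
        avail = [f for f in surviving if f in robustness.icc.index]
        sub = RobustnessTable(
            icc=robustness.icc.loc[avail],
            ci_low=robustness.ci_low.loc[avail],
            ci_high=robustness.ci_high.loc[avail],
            n_discs=robustness.n_discs,
        )
        robust = select_robust_cluster(sub)
        ledger.record(
            "robust_cluster", sorted(set(surviving) - set(robust)), robust,
            n_clusters=2, linkage="ward",
        )
        X = X[robust]

    kept = redundancy_filter(X, redundancy_threshold)
    ledger.record(
        "redundancy", sorted(set(X.columns) - set(kept)), kept,
        threshold=redundancy_threshold,
    )
    X = X[kept]

    area_model = None
    if areas is not None:
        area_model = fit_area_adjustment(X, areas, area_threshold)
        ledger.record(
            "area_adjustment", [], list(X.columns),
            adjusted=list(area_model.adjusted_features), threshold=area_threshold,
        )
        X = area_model.apply(X, areas)
    return X, ledger, area_model
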