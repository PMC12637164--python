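"""Sparse partial least squares discriminant analysis and baseline classifiers.

:class:`SPLSDA` is a statsmodels-style model object: construct it from a
feature matrix and class labels, call :meth:`SPLSDA.fit` and receive an
:class:`SPLSDAResults` carrying the sparse loadings, scores, prediction rule
and a ``summary()`` table.

The estimator extracts latent components by NIPALS on the column-centered,
unit-variance-scaled X against the centered/scaled one-hot class matrix Y.
Sparsity is enforced per component by soft-thresholding the X-weight vector
so that at most ``keep_x[h]`` entries are nonzero (the threshold is the
(keepX+1)-th largest weight magnitude); both X and Y are deflated with the
X-score regression.  With ``keep_x`` equal to the number of features no
thresholding is active and the model coincides with dense PLS-DA (PLS2
regression on the dummy matrix).  Class prediction uses the
maximum-predicted-dummy rule.

:func:`tune_splsda` performs the repeated, subject-grouped, class-stratified
5-fold cross-validation used to choose the number of components and the
per-component sparsity by balanced error rate (BER = 1 - balanced accuracy),
and reports per-feature stability (selection frequency across folds).
:func:`svm_baseline` is the two-feature RBF support-vector baseline used for
the conventional-index and top-two-radiomics models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["SPLSDA", "SPLSDAResults", "TuningResult", "tune_splsda", "svm_baseline", "ber"]


def ber(y_true, y_pred) -> float:
    """Balanced error rate: 1 minus mean per-class recall."""
    return 1.0 - float(balanced_accuracy_score(y_true, y_pred))


def _soft_threshold_keep(g: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold ``g`` so at most ``keep`` entries stay nonzero."""
    if keep >= len(g):
        return g.copy()
    mags = np.abs(g)
    lam = np.sort(mags)[::-1][keep]  # (keep+1)-th largest magnitude
    out = np.sign(g) * np.maximum(mags - lam, 0.0)
    return out


class SPLSDA:
    """Sparse PLS-DA model for ordinal/nominal class labels.

    Parameters
    ----------
    X : array-like (n, p)
        Feature matrix (centered/scaled internally on the training data).
    y : array-like (n,)
        Class labels (at least 2 distinct values).
    n_components : int
        Number of latent components.
    keep_x : int | sequence of int | None
        Nonzeros retained per component; None keeps all (dense PLS-DA).
    """

    def __init__(self, X, y, n_components: int = 2, keep_x=None, scale: bool = True):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be (n, p) with matching y length")
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        self.X = X
        self.y = y
        self.n_components = int(n_components)
        p = X.shape[1]
        if keep_x is None:
            keep = [p] * n_components
        elif np.isscalar(keep_x):
            keep = [int(keep_x)] * n_components
        else:
            keep = [int(k) for k in keep_x]
            if len(keep) < n_components:
                keep = keep + [keep[-1]] * (n_components - len(keep))
        clipped = [min(max(k, 1), p) for k in keep]
        if any(c != k for c, k in zip(clipped, keep)):
            warnings.warn("keep_x clipped to [1, n_features]")
        self.keep_x = clipped[: self.n_components]
        self.scale = scale

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, feature_cols, label_col: str, **kwargs
    ) -> "SPLSDA":
        return cls(df[list(feature_cols)].to_numpy(), df[label_col].to_numpy(), **kwargs)

    def _dummy(self, y: np.ndarray) -> np.ndarray:
        return (y[:, None] == self.classes_[None, :]).astype(float)

    def fit(self, max_iter: int = 500, tol: float = 1e-9) -> "SPLSDAResults":
        X = self.X.copy()
        Y = self._dummy(self.y)
        n, p = X.shape
        g = Y.shape[1]

        self.x_mean_ = X.mean(axis=0)
        self.x_std_ = X.std(axis=0, ddof=1)
        self.x_std_[self.x_std_ == 0] = 1.0
        self.y_mean_ = Y.mean(axis=0)
        self.y_std_ = Y.std(axis=0, ddof=1)
        self.y_std_[self.y_std_ == 0] = 1.0
        Xc = (X - self.x_mean_) / (self.x_std_ if self.scale else 1.0)
        Yc = (Y - self.y_mean_) / (self.y_std_ if self.scale else 1.0)

        H = self.n_components
        W = np.zeros((p, H))  # sparse X weights
        T = np.zeros((n, H))  # X scores
        C = np.zeros((p, H))  # X loadings (deflation)
        D = np.zeros((g, H))  # Y loadings
        Xh, Yh = Xc.copy(), Yc.copy()
        for h in range(H):
            M = Xh.T @ Yh
            if not np.any(M):
                H = h
                W, T, C, D = W[:, :H], T[:, :H], C[:, :H], D[:, :H]
                warnings.warn("X-Y covariance exhausted; fewer components extracted")
                break
            # initialise v with the dominant right singular vector of M
            _, _, vt = np.linalg.svd(M, full_matrices=False)
            v = vt[0]
            u = np.zeros(p)
            for _ in range(max_iter):
                u_new = _soft_threshold_keep(M @ v, self.keep_x[h])
                nrm = np.linalg.norm(u_new)
                if nrm == 0:  # threshold removed everything; keep best single
                    u_new = np.zeros(p)
                    u_new[np.argmax(np.abs(M @ v))] = 1.0
                    nrm = 1.0
                u_new /= nrm
                v_new = M.T @ u_new
                v_nrm = np.linalg.norm(v_new)
                if v_nrm > 0:
                    v_new /= v_nrm
                if np.linalg.norm(u_new - u) < tol:
                    u, v = u_new, v_new
                    break
                u, v = u_new, v_new
            t = Xh @ u
            tt = float(t @ t)
            if tt == 0:
                H = h
                W, T, C, D = W[:, :H], T[:, :H], C[:, :H], D[:, :H]
                break
            c = Xh.T @ t / tt
            d = Yh.T @ t / tt
            W[:, h], T[:, h], C[:, h], D[:, h] = u, t, c, d
            Xh = Xh - np.outer(t, c)
            Yh = Yh - np.outer(t, d)

        # regression coefficients on the scaled spaces: B = W (C'W)^-1 D'
        cw = C.T @ W
        try:
            rot = W @ np.linalg.inv(cw)
        except np.linalg.LinAlgError:
            rot = W @ np.linalg.pinv(cw)
        coef = rot @ D.T
        return SPLSDAResults(model=self, x_weights=W, x_scores=T, x_loadings=C,
                             y_loadings=D, coef=coef, n_components=W.shape[1])


@dataclass
class SPLSDAResults:
    """Fitted sparse PLS-DA: loadings, scores and the prediction rule."""

    model: SPLSDA
    x_weights: np.ndarray  # (p, H) sparse, unit-norm columns
    x_scores: np.ndarray  # (n, H)
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    coef: np.ndarray  # (p, G) on scaled spaces
    n_components: int

    @property
    def classes_(self) -> np.ndarray:
        return self.model.classes_

    def selected_features(self, component: int) -> np.ndarray:
        """Indices of features with nonzero weight on ``component`` (0-based)."""
        return np.flatnonzero(self.x_weights[:, component])

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xc = (X - self.model.x_mean_) / (self.model.x_std_ if self.model.scale else 1.0)
        cw = self.x_loadings.T @ self.x_weights
        rot = self.x_weights @ np.linalg.pinv(cw)
        return Xc @ rot

    def predict_dummy(self, X) -> np.ndarray:
        """Predicted (unscaled) class-indicator values, used as scores."""
        X = np.asarray(X, dtype=float)
        Xc = (X - self.model.x_mean_) / (self.model.x_std_ if self.model.scale else 1.0)
        Yhat = Xc @ self.coef
        return Yhat * (self.model.y_std_ if self.model.scale else 1.0) + self.model.y_mean_

    def predict(self, X) -> np.ndarray:
        """Class labels by the maximum-predicted-dummy rule."""
        return self.classes_[np.argmax(self.predict_dummy(X), axis=1)]

    def to_json(self) -> str:
        """Serialize loadings, scaling vectors and the prediction rule."""
        import json

        return json.dumps(
            {
                "classes": self.classes_.tolist(),
                "n_components": int(self.n_components),
                "keep_x": [int(k) for k in self.model.keep_x],
                "prediction_rule": "max_predicted_dummy",
                "x_mean": self.model.x_mean_.tolist(),
                "x_std": self.model.x_std_.tolist(),
                "y_mean": self.model.y_mean_.tolist(),
                "y_std": self.model.y_std_.tolist(),
                "scale": bool(self.model.scale),
                "x_weights": self.x_weights.tolist(),
                "x_loadings": self.x_loadings.tolist(),
                "y_loadings": self.y_loadings.tolist(),
                "coef": self.coef.tolist(),
            }
        )

    @staticmethod
    def predict_from_json(payload: str, X) -> np.ndarray:
        """Predict classes with a serialized model (no refit)."""
        import json

        d = json.loads(payload)
        X = np.asarray(X, dtype=float)
        xm = np.asarray(d["x_mean"])
        xs = np.asarray(d["x_std"]) if d["scale"] else 1.0
        yhat = ((X - xm) / xs) @ np.asarray(d["coef"])
        yhat = yhat * (np.asarray(d["y_std"]) if d["scale"] else 1.0) + np.asarray(
            d["y_mean"]
        )
        return np.asarray(d["classes"])[np.argmax(yhat, axis=1)]

    def summary(self) -> str:
        lines = [
            "Sparse PLS-DA results",
            "=====================",
            f"n obs:          {len(self.model.y)}",
            f"n features:     {self.model.X.shape[1]}",
            f"components:     {self.n_components}",
            f"keepX:          {self.model.keep_x}",
            f"classes:        {list(self.classes_)}",
        ]
        for h in range(self.n_components):
            sel = self.selected_features(h)
            lines.append(f"component {h + 1}: {len(sel)} active features")
        return "\n".join(lines)


@dataclass
class TuningResult:
    grid: pd.DataFrame  # columns: n_components, keep_x, ber
    best_n_components: int
    best_keep_x: list[int]
    best_ber: float
    stability: pd.DataFrame  # feature x component selection frequency
    ber_per_component: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def _grouped_folds(y, groups, n_folds, rng_seed, max_tries=10):
    """Stratified, subject-grouped folds; re-drawn if a fold misses a class."""
    y = np.asarray(y)
    for t in range(max_tries):
        if groups is not None:
            cv = StratifiedGroupKFold(n_splits=n_folds, shuffle=True,
                                      random_state=rng_seed + t)
            splits = list(cv.split(np.zeros(len(y)), y, groups))
        else:
            cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rng_seed + t)
            splits = list(cv.split(np.zeros(len(y)), y))
        ok = all(len(np.unique(y[tr])) == len(np.unique(y)) for tr, _ in splits)
        if ok:
            return splits
    warnings.warn("could not stratify all classes into every fold; best effort used")
    return splits


def tune_splsda(
    X,
    y,
    groups=None,
    component_grid=None,
    keepx_grid=(1, 2, 5, 10, 25, 50, 100, None),
    n_folds: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
    feature_names=None,
) -> TuningResult:
    """Greedy component-by-component sparsity tuning by repeated grouped CV.

    For each component in turn, every candidate keepX is evaluated by the
    mean BER across ``n_repeats`` x ``n_folds`` subject-grouped stratified
    folds, holding previously chosen keepX values fixed; the component count
    is then chosen as the BER-minimal prefix.  ``None`` in ``keepx_grid``
    means all features.  Stability is the per-feature selection frequency
    across all folds of the winning configuration.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    p = X.shape[1]
    if component_grid is None:
        component_grid = range(1, min(6, p) + 1)
    component_grid = list(component_grid)
    keepx_values = [p if k is None else min(int(k), p) for k in keepx_grid]
    keepx_values = sorted(set(keepx_values))

    all_splits = [
        _grouped_folds(y, groups, n_folds, seed + 7919 * r) for r in range(n_repeats)
    ]

    chosen: list[int] = []
    rows = []
    ber_per_component = {}
    for h in component_grid:
        best_k, best_b = None, np.inf
        for k in keepx_values:
            keep = chosen + [k]
            bers = []
            for splits in all_splits:
                for tr, va in splits:
                    res = SPLSDA(X[tr], y[tr], n_components=h, keep_x=keep).fit()
                    bers.append(ber(y[va], res.predict(X[va])))
            mb = float(np.mean(bers))
            rows.append({"n_components": h, "keep_x": k, "ber": mb})
            if mb < best_b:
                best_k, best_b = k, mb
        chosen.append(best_k)
        ber_per_component[h] = best_b

    ber_series = pd.Series(ber_per_component)
    best_h = int(ber_series.idxmin())
    best_keep = chosen[: best_h - component_grid[0] + 1] if component_grid[0] == 1 else chosen[: component_grid.index(best_h) + 1]

    # stability of the winning configuration across folds
    names = list(feature_names) if feature_names is not None else [f"x{i}" for i in range(p)]
    counts = np.zeros((p, best_h))
    total = 0
    for splits in all_splits:
        for tr, _ in splits:
            res = SPLSDA(X[tr], y[tr], n_components=best_h, keep_x=best_keep).fit()
            for c in range(res.n_components):
                counts[res.selected_features(c), c] += 1
            total += 1
    stability = pd.DataFrame(
        counts / max(total, 1), index=names,
        columns=[f"comp{c + 1}" for c in range(best_h)],
    )
    return TuningResult(
        grid=pd.DataFrame(rows),
        best_n_components=best_h,
        best_keep_x=[int(k) for k in best_keep],
        best_ber=float(ber_series.min()),
        stability=stability,
        ber_per_component=ber_series,
    )


def svm_baseline(
    X,
    y,
    groups=None,
    c_grid=(0.1, 1.0, 10.0, 100.0),
    gamma_grid=("scale", 0.01, 0.1, 1.0),
    n_folds: int = 5,
    n_repeats: int = 3,
    seed: int = 0,
):
    """RBF support-vector classifier for a low-dimensional feature pair.

    Hyperparameters are chosen by repeated subject-grouped stratified CV on
    balanced accuracy; classes are inverse-frequency weighted.  Returns the
    refitted pipeline and the CV results table.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    rows = []
    best = (None, -np.inf)
    splits_all = [
        _grouped_folds(y, groups, n_folds, seed + 104729 * r) for r in range(n_repeats)
    ]
    for C in c_grid:
        for gamma in gamma_grid:
            accs = []
            for splits in splits_all:
                for tr, va in splits:
                    pipe = Pipeline(
                        [
                            ("scale", StandardScaler()),
                            ("svc", SVC(kernel="rbf", C=C, gamma=gamma,
                                        class_weight="balanced")),
                        ]
                    )
                    pipe.fit(X[tr], y[tr])
                    accs.append(balanced_accuracy_score(y[va], pipe.predict(X[va])))
            m = float(np.mean(accs))
            rows.append({"C": C, "gamma": gamma, "balanced_accuracy": m})
            if m > best[1]:
                best = ((C, gamma), m)
    C, gamma = best[0]
    final = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svc", SVC(kernel="rbf", C=C, gamma=gamma, class_weight="balanced",
                        decision_function_shape="ovr")),
        ]
    )
    final.fit(X, y)
    return final, pd.DataFrame(rows)
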