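"""Selection cascade: relevance, ICC, robust clustering, redundancy, area."""

import numpy as np
import pandas as pd
import pytest

from discradiomics.robustness import (
    RobustnessTable,
    compute_robustness_table,
    fit_area_adjustment,
    icc_two_way,
    redundancy_filter,
    relevance_filter,
    select_robust_cluster,
    selection_cascade,
)
from oracles import oracle_icc_a1


class TestRelevanceFilter:
    def test_perfect_monotone_kept(self):
        rng = np.random.default_rng(0)
        grades = rng.integers(2, 6, 100)
        df = pd.DataFrame({"exact": grades.astype(float)})
        kept, removed = relevance_filter(df, grades)
        assert kept == ["exact"]

    def test_noise_mostly_removed(self):
        rng = np.random.default_rng(1)
        grades = rng.integers(2, 6, 300)
        n_removed = 0
        for s in range(40):
            df = pd.DataFrame({"noise": np.random.default_rng(s).normal(size=300)})
            _, removed = relevance_filter(df, grades)
            n_removed += "noise" in removed
        assert n_removed >= 33  # ~95% type-I control at alpha 0.05

    def test_alpha_one_keeps_all_nonconstant(self):
        rng = np.random.default_rng(2)
        grades = rng.integers(2, 6, 50)
        df = pd.DataFrame({"a": rng.normal(size=50), "c": np.ones(50)})
        kept, removed = relevance_filter(df, grades, alpha=1.0)
        assert kept == ["a"]
        assert removed["c"] == "constant"

    def test_too_few_discs(self):
        with pytest.raises(ValueError):
            relevance_filter(pd.DataFrame({"a": [1.0, 2.0]}), np.array([2, 3]))


class TestICC:
    def test_identity_is_one(self):
        x = np.arange(10.0)
        icc, _ = icc_two_way(x, x)
        assert icc == pytest.approx(1.0)

    def test_mean_shift_closed_form(self):
        x = np.arange(10.0)
        y = x + 5.0
        icc, _ = icc_two_way(x, y)
        assert icc == pytest.approx(oracle_icc_a1(x, y), abs=1e-12)
        assert icc < 0.6  # absolute agreement punishes the offset

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        x = rng.normal(size=25)
        y = x + rng.normal(0, 0.4, 25) + 0.3
        icc, (lo, hi) = icc_two_way(x, y)
        df = pd.DataFrame(
            {
                "t": np.r_[np.arange(25), np.arange(25)],
                "r": ["a"] * 25 + ["b"] * 25,
                "v": np.r_[x, y],
            }
        )
        row = pg.intraclass_corr(df, "t", "r", "v").set_index("Type").loc["ICC(A,1)"]
        assert icc == pytest.approx(row["ICC"], abs=1e-9)
        assert (lo, hi) == pytest.approx(tuple(row["CI95"]), abs=5e-3)

    def test_independent_normals_near_zero(self):
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            icc, _ = icc_two_way(rng.normal(size=300), rng.normal(size=300))
            hits += abs(icc) < 0.15
        assert hits >= 90

    def test_degenerate_flagged(self):
        icc, ci = icc_two_way(np.zeros(5), np.zeros(5))
        assert np.isnan(icc)


class TestRobustCluster:
    def _table(self, icc_matrix, names):
        df = pd.DataFrame(icc_matrix, index=names)
        return RobustnessTable(icc=df, ci_low=df, ci_high=df, n_discs=50)

    def test_planted_partition_recovered_exactly(self):
        rng = np.random.default_rng(0)
        high = 0.95 + rng.normal(0, 0.02, (10, 6))
        low = 0.40 + rng.normal(0, 0.02, (10, 6))
        names = [f"h{i}" for i in range(10)] + [f"l{i}" for i in range(10)]
        table = self._table(np.vstack([high, low]), names)
        got = select_robust_cluster(table)
        assert sorted(got) == [f"h{i}" for i in range(10)]

    def test_k1_identity(self):
        rng = np.random.default_rng(1)
        table = self._table(rng.random((5, 3)), list("abcde"))
        assert select_robust_cluster(table, n_clusters=1) == list("abcde")

    def test_nan_rows_excluded(self):
        m = np.array([[0.9, 0.9], [np.nan, 0.9], [0.2, 0.3]])
        table = self._table(m, ["a", "b", "c"])
        got = select_robust_cluster(table)
        assert "b" not in got

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        table = self._table(rng.random((8, 4)), list("abcdefgh"))
        assert select_robust_cluster(table) == select_robust_cluster(table)


class TestRedundancy:
    def test_lower_variance_dropped(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        df = pd.DataFrame({"x": x, "x2": 2 * x})
        assert redundancy_filter(df) == ["x2"]

    def test_correlated_group_keeps_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": x * 1.5, "c": x * 2.0 + 1e-6 * rng.normal(size=200)})
        kept = redundancy_filter(df)
        assert len(kept) >= 1

    def test_independent_all_kept(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(300, 5)), columns=list("abcde"))
        assert redundancy_filter(df) == list("abcde")


class TestAreaAdjustment:
    def test_area_driven_feature_detrended(self):
        rng = np.random.default_rng(0)
        areas = rng.uniform(50, 300, 400)
        df = pd.DataFrame(
            {
                "dep": 3 * areas + rng.normal(0, 5, 400),
                "indep": rng.normal(size=400),
            }
        )
        model = fit_area_adjustment(df, areas)
        assert model.adjusted_features == ["dep"]
        adj = model.apply(df, areas)
        from scipy.stats import spearmanr

        assert abs(spearmanr(adj["dep"], areas)[0]) < 0.2
        np.testing.assert_array_equal(adj["indep"], df["indep"])

    def test_apply_uses_stored_coefficients(self):
        rng = np.random.default_rng(1)
        areas = rng.uniform(10, 100, 200)
        df = pd.DataFrame({"dep": 2 * areas})
        model = fit_area_adjustment(df, areas)
        coefs = dict(model.coefficients)
        new_areas = rng.uniform(10, 100, 50)
        new_df = pd.DataFrame({"dep": 2 * new_areas + 10})
        model.apply(new_df, new_areas)
        assert model.coefficients == coefs  # never refit

    def test_constant_area_rejected(self):
        with pytest.raises(ValueError):
            fit_area_adjustment(pd.DataFrame({"a": [1.0, 2.0]}), np.array([5.0, 5.0]))


class TestCascade:
    def test_ledger_stages_nested(self):
        rng = np.random.default_rng(0)
        n = 200
        grades = rng.integers(2, 6, n)
        informative = -1.0 * grades + rng.normal(0, 0.5, n)
        features = pd.DataFrame(
            {
                "good": informative,
                "good_copy": informative * 2.0 + rng.normal(0, 0.01, n),
                "noise": rng.normal(size=n),
                "constant": np.ones(n),
            }
        )
        # synthetic robustness: 'good*' robust, others fragile
        jitter = pd.DataFrame(
            rng.normal(0, 0.05, features.shape) * features.std().to_numpy(),
            columns=features.columns,
        )
        perturbed = {"p1": features + jitter}
        table = compute_robustness_table(features, perturbed)
        selected, ledger, _ = selection_cascade(
            features, grades, table, areas=None
        )
        sizes = [s["n_surviving"] for s in ledger.stages]
        assert sizes == sorted(sizes, reverse=True)  # strictly nested stages
        assert "good" in selected.columns or "good_copy" in selected.columns
        assert "constant" not in selected.columns
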