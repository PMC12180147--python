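"""Evaluation harness: AUC vs the pair-counting oracle, split and
grouping arithmetic, task construction, repeated holdout, model search,
permutation importance."""

import numpy as np
import pandas as pd
import pytest
from helpers import mann_whitney_auc
from hypothesis import given, settings, strategies as st
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from cslv import bench
from cslv.bench import (
    TaskSpec,
    auc_roc,
    build_task,
    grouped_mean_curve,
    model_search,
    permutation_importance,
    repeated_holdout,
    split_counts,
)


class TestAucRoc:
    def test_perfect_separation(self):
        assert auc_roc([0.9, 0.8], [1, 0]).auc == 1.0

    def test_all_ties_is_half(self):
        assert auc_roc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]).auc == pytest.approx(0.5)

    def test_hand_counted_example(self):
        # of the 4 pos-neg pairs, 3 are correctly ordered -> 0.75
        assert auc_roc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]).auc == pytest.approx(0.75)

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError, match="two classes"):
            auc_roc([0.1, 0.2], [1, 1])

    def test_curve_shape_contract(self):
        rng = np.random.default_rng(1)
        roc = auc_roc(rng.normal(size=40), rng.integers(0, 2, size=40))
        assert roc.fpr[0] == 0.0 and roc.tpr[0] == 0.0
        assert roc.fpr[-1] == 1.0 and roc.tpr[-1] == 1.0
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()
        assert roc.auc == pytest.approx(np.trapezoid(roc.tpr, roc.fpr), abs=1e-15)

    def test_matches_pair_counting_oracle_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            labels = np.zeros(n, dtype=int)
            labels[: max(1, n // 3)] = 1
            rng.shuffle(labels)
            scores = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
            assert auc_roc(scores, labels).auc == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-12
            )


class TestSplitCounts:
    @pytest.mark.parametrize(
        "n,frac,expected",
        [
            (161_820, 0.8, (129_456, 32_364)),  # exact product
            (10, 0.8, (8, 2)),
            (11, 0.8, (8, 3)),  # floor of 8.8
            (5, 0.5, (2, 3)),
        ],
    )
    def test_cases(self, n, frac, expected):
        assert split_counts(n, frac) == expected

    def test_errors(self):
        with pytest.raises(ValueError):
            split_counts(1, 0.8)
        with pytest.raises(ValueError):
            split_counts(10, 1.0)


class TestGroupedMeanCurve:
    def test_sorted_identity(self):
        values = np.arange(1, 101, dtype=float)
        curve = grouped_mean_curve(values, values, n_groups=50)
        means = curve.table["mean_actual"].to_numpy()
        assert np.allclose(means, np.arange(1.5, 100, 2.0))
        assert (np.diff(means) > 0).all()

    def test_ranking_uses_predicted_order(self):
        predicted = np.arange(10, 0, -1, dtype=float)  # reverse order
        actual = np.arange(10, dtype=float)
        curve = grouped_mean_curve(predicted, actual, n_groups=5)
        first = curve.table.iloc[0]
        # the first group holds the two smallest *predicted* values,
        # which sit at the end of the input
        assert first["mean_predicted"] == pytest.approx(1.5)
        assert first["mean_actual"] == pytest.approx(8.5)

    @given(n=st.integers(1, 500), g=st.integers(1, 60))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_group_sizes_partition_n(self, n, g):
        if n < g:
            return
        rng = np.random.default_rng(0)
        curve = grouped_mean_curve(rng.normal(size=n), rng.normal(size=n), g)
        sizes = curve.table["size"].to_numpy()
        assert sizes.sum() == n
        assert sizes.max() - sizes.min() <= 1
        assert (sizes == sorted(sizes, reverse=True)).all()

    def test_uninformative_predictions_give_flat_curve(self):
        # group means of actual fluctuate within a CLT band around the
        # grand mean when predictions carry no information
        rng = np.random.default_rng(3)
        n = 5000
        actual = rng.normal(size=n)
        predicted = rng.normal(size=n)
        curve = grouped_mean_curve(predicted, actual, n_groups=50)
        means = curve.table["mean_actual"].to_numpy()
        bound = 4 * actual.std() / np.sqrt(n / 50)
        assert np.max(np.abs(means - actual.mean())) <= bound

    def test_errors(self):
        with pytest.raises(ValueError):
            grouped_mean_curve([1.0, 2.0], [1.0, 2.0], n_groups=0)
        with pytest.raises(ValueError):
            grouped_mean_curve([1.0, 2.0], [1.0, 2.0], n_groups=3)


def _features(n, labels, seed=0):
    rng = np.random.default_rng(seed)
    idx = [f"s{i}" for i in range(n)]
    feats = pd.DataFrame(rng.normal(size=(n, 3)),
                         columns=["chr1_1", "chr1_2", "chr2_1"], index=idx)
    feats.index.name = "sample_id"
    pheno = pd.DataFrame({
        "sample_id": idx,
        "sex": rng.choice(["male", "female"], size=n),
        "group_label": labels,
        "age": rng.uniform(15, 80, size=n),
        "height": rng.normal(168, 8, size=n),
    })
    return feats, pheno


class TestBuildTask:
    def test_pair_filter_drops_other_labels(self):
        feats, pheno = _features(30, ["A", "B", "C"] * 10)
        spec = TaskSpec(mode=bench.CLASSIFICATION, positive="A", negative="B")
        table = build_task(feats, pheno, spec)
        assert len(table) == 20
        assert set(table["label"]) == {0, 1}
        kept = pheno.set_index("sample_id").loc[table.index, "group_label"]
        assert set(kept) == {"A", "B"}

    def test_regression_filters_minors_and_has_only_age_plus_features(self):
        feats, pheno = _features(40, ["A"] * 40, seed=1)
        pheno.loc[0, "age"] = 20.0  # under the adult cutoff
        pheno.loc[1, "height"] = np.nan
        spec = TaskSpec(mode=bench.REGRESSION)
        table = build_task(feats, pheno, spec)
        assert "s0" not in table.index and "s1" not in table.index
        assert list(table.columns) == ["height", "age", "chr1_1", "chr1_2", "chr2_1"]
        assert (pheno.set_index("sample_id").loc[table.index, "age"] >= 21).all()

    def test_too_few_per_class_is_an_error(self):
        feats, pheno = _features(10, ["A"] * 9 + ["B"])
        spec = TaskSpec(mode=bench.CLASSIFICATION, positive="A", negative="B")
        with pytest.raises(ValueError, match="per class"):
            build_task(feats, pheno, spec)


def _separable_table(n=200, gap=6.0, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    X = rng.normal(size=(n, 2)) + gap * y[:, None]
    table = pd.DataFrame(X, columns=["f1", "f2"],
                         index=[f"s{i}" for i in range(n)])
    table.insert(0, "label", y)
    return table


class TestRepeatedHoldout:
    RECIPE = make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000))

    def test_separable_data_scores_one(self):
        spec = TaskSpec(mode=bench.CLASSIFICATION, positive="x", negative="y",
                        n_repeats=3, seed=0)
        res = repeated_holdout(_separable_table(), self.RECIPE, spec)
        assert res.mean == 1.0 and res.sd == 0.0

    def test_same_seed_reproduces_per_repeat_aucs(self):
        table = _separable_table(gap=1.0, seed=2)
        spec = TaskSpec(mode=bench.CLASSIFICATION, positive="x", negative="y",
                        n_repeats=4, seed=7)
        a = repeated_holdout(table, self.RECIPE, spec)
        b = repeated_holdout(table, self.RECIPE, spec)
        assert a.aucs == b.aucs
        assert a.mean == pytest.approx(np.mean(a.aucs))
        assert a.sd == pytest.approx(np.std(a.aucs, ddof=1))

    def test_null_labels_score_near_half(self):
        table = _separable_table(n=1000, gap=0.0, seed=3)
        spec = TaskSpec(mode=bench.CLASSIFICATION, positive="x", negative="y",
                        n_repeats=5, seed=3)
        res = repeated_holdout(table, self.RECIPE, spec)
        assert 0.45 <= res.mean <= 0.55


class TestModelSearch:
    def test_separable_data_reaches_high_cv_auc(self):
        spec = TaskSpec(mode=bench.CLASSIFICATION, positive="x", negative="y",
                        cv_folds=5, trial_budget=4, seed=0)
        board, best = model_search(_separable_table(n=200), spec)
        assert board.table.iloc[0]["metric"] >= 0.99
        scores = best.predict_proba(_separable_table(n=60, seed=9).drop(columns="label"))
        assert scores.shape == (60, 2)

    def test_leaderboard_is_sorted_with_contiguous_ranks(self):
        spec = TaskSpec(mode=bench.CLASSIFICATION, positive="x", negative="y",
                        cv_folds=4, trial_budget=4, seed=1)
        board, _ = model_search(_separable_table(n=120, gap=1.0, seed=4), spec)
        metrics = board.table["metric"].to_numpy()
        assert (np.diff(metrics) <= 1e-12).all()  # non-increasing for AUC
        assert board.table["rank"].tolist() == list(range(1, len(board.table) + 1))
        assert {"StackedEnsemble_AllModels", "StackedEnsemble_BestOfFamily"} <= set(
            board.table["model_id"])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ensembles_beat_the_worst_base_model(self, seed):
        spec = TaskSpec(mode=bench.CLASSIFICATION, positive="x", negative="y",
                        cv_folds=4, trial_budget=4, seed=seed)
        board, _ = model_search(_separable_table(n=120, gap=0.8, seed=seed), spec)
        t = board.table
        worst_base = t.loc[t["family"] != "ensemble", "metric"].min()
        for ens in ("StackedEnsemble_AllModels", "StackedEnsemble_BestOfFamily"):
            assert t.loc[t["model_id"] == ens, "metric"].iloc[0] >= worst_base - 1e-9

    def test_regression_leaderboard_ascends_in_rmse(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(150, 3))
        y = 2.0 * X[:, 0] + rng.normal(scale=0.5, size=150)
        table = pd.DataFrame(X, columns=["a", "b", "c"])
        table.insert(0, "height", y)
        spec = TaskSpec(mode=bench.REGRESSION, cv_folds=4, trial_budget=4, seed=5)
        board, best = model_search(table, spec)
        metrics = board.table["metric"].to_numpy()
        assert (np.diff(metrics) >= -1e-12).all()  # non-decreasing RMSE
        assert board.metric == "rmse"
        assert np.isfinite(best.predict(table.drop(columns="height"))).all()

    def test_budget_below_family_count_is_an_error(self):
        spec = TaskSpec(mode=bench.CLASSIFICATION, positive="x", negative="y",
                        trial_budget=3)
        with pytest.raises(ValueError, match="trial_budget"):
            model_search(_separable_table(), spec)


class TestPermutationImportance:
    def test_constant_predictor_has_zero_importances(self):
        class Constant:
            def predict(self, X):
                return np.full(len(X), 0.5)

        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "c"])
        y = rng.normal(size=50)
        report = permutation_importance(Constant(), X, y, metric="rmse",
                                        n_repeats=3, seed=0)
        assert (report.table["importance_mean"] == 0.0).all()

    def test_single_informative_feature_dominates(self):
        rng = np.random.default_rng(7)
        n = 800
        y = rng.integers(0, 2, size=n)
        X = pd.DataFrame(rng.normal(size=(n, 6)),
                         columns=[f"f{i}" for i in range(6)])
        X["f0"] = X["f0"] + 2.0 * y
        model = make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000))
        model.fit(X, y)
        report = permutation_importance(model, X, y, metric="auc",
                                        n_repeats=5, seed=1)
        t = report.table.set_index("feature")
        assert t["importance_mean"].idxmax() == "f0"
        # a pure-noise feature sits within 2 sd of zero importance
        noise = t.loc["f3"]
        assert abs(noise["importance_mean"]) <= 2 * noise["importance_sd"] + 1e-3

    def test_agrees_with_sklearn_reference(self):
        from sklearn.inspection import permutation_importance as sk_pi

        rng = np.random.default_rng(8)
        n = 400
        y = rng.integers(0, 2, size=n)
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        X["a"] = X["a"] + 1.5 * y
        model = LogisticRegression(max_iter=1000).fit(X, y)
        ours = permutation_importance(model, X, y, metric="auc",
                                      n_repeats=20, seed=2)
        ref = sk_pi(model, X, y, scoring="roc_auc", n_repeats=20, random_state=2)
        assert np.allclose(
            ours.table["importance_mean"].to_numpy(), ref.importances_mean, atol=0.03
        )
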