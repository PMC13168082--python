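"""Stratified folds, composite metric, and the four selection strategies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sexpanel.config import MetricWeights, SelectorConfig
from sexpanel.select import (
    RankedPanel,
    composite_score,
    rfe_schedule,
    select_dgea,
    select_logreg_l1,
    select_opt_rf,
    select_svm_rfe,
    stratified_kfold,
    tune_hyperparameters,
)


class TestStratifiedKfold:
    def test_rare_class_spread_over_folds(self):
        labels = pd.Series(["pos"] * 8 + ["neg"] * 2, index=[f"s{i}" for i in range(10)])
        scheme = stratified_kfold(labels, k=5, seed=0)
        sizes = scheme.assignment.value_counts()
        assert sorted(sizes) == [2, 2, 2, 2, 2]
        folds_with_neg = scheme.assignment[labels == "neg"].nunique()
        assert folds_with_neg == 2

    def test_balanced_classes_split_evenly(self):
        labels = pd.Series(["a"] * 10 + ["b"] * 10, index=[f"s{i}" for i in range(20)])
        scheme = stratified_kfold(labels, k=5, seed=1)
        for f in range(5):
            fold_labels = labels[scheme.assignment == f]
            assert fold_labels.value_counts().tolist() == [2, 2]

    def test_deterministic_under_seed(self):
        labels = pd.Series(["a"] * 13 + ["b"] * 7, index=[f"s{i}" for i in range(20)])
        a = stratified_kfold(labels, k=5, seed=42)
        b = stratified_kfold(labels, k=5, seed=42)
        assert a.assignment.equals(b.assignment)
        c = stratified_kfold(labels, k=5, seed=43)
        assert not a.assignment.equals(c.assignment)

    @settings(max_examples=40, deadline=None)
    @given(
        st.integers(6, 40), st.integers(1, 40), st.integers(2, 6), st.integers(0, 10_000)
    )
    def test_class_counts_within_one_of_proportional(self, n_a, n_b, k, seed):
        labels = pd.Series(
            ["a"] * n_a + ["b"] * n_b, index=[f"s{i}" for i in range(n_a + n_b)]
        )
        scheme = stratified_kfold(labels, k=k, seed=seed)
        for cls, n_cls in (("a", n_a), ("b", n_b)):
            per_fold = (
                scheme.assignment[labels == cls].value_counts().reindex(range(k), fill_value=0)
            )
            assert per_fold.max() - per_fold.min() <= 1
            assert abs(per_fold.max() - n_cls / k) <= 1


class TestCompositeScore:
    @pytest.mark.parametrize(
        "f1,auroc,bal,expected",
        [
            (0.917, 0.923, 0.896, 0.915),
            (0.878, 0.914, 0.750, 0.863),
            (0.853, 0.734, 0.689, 0.784),
            (1.0, 1.0, 1.0, 1.0),
        ],
    )
    def test_published_worked_examples(self, f1, auroc, bal, expected):
        assert round(composite_score(f1, auroc, bal), 3) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="auroc"):
            composite_score(0.5, 1.2, 0.5)

    def test_custom_weights(self):
        w = MetricWeights(f1=1.0, auroc=0.0, balanced_accuracy=0.0)
        assert composite_score(0.7, 0.1, 0.2, w) == pytest.approx(0.7)


class TestRfeSchedule:
    def test_thousand_features_take_700_iterations(self):
        drops = rfe_schedule(1000, 0.001, 300)
        assert len(drops) == 700
        assert all(d == 1 for d in drops)

    def test_start_equals_stop_no_iterations(self):
        assert rfe_schedule(300, 0.001, 300) == []

    def test_large_pool_uses_fractional_steps_and_lands_exactly(self):
        drops = rfe_schedule(5000, 0.01, 300)
        assert sum(drops) == 4700
        assert drops[0] == 50
        assert min(drops) >= 1


def _panel_data(n_informative, n_noise, n_samples=60, seed=0, effect=3.0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n_samples // 2))
    names = [f"inf{i}" for i in range(n_informative)] + [f"n{i:03d}" for i in range(n_noise)]
    X = rng.normal(size=(n_samples, n_informative + n_noise))
    X[:, :n_informative] += effect * y[:, None]
    return pd.DataFrame(X, columns=names), y


FAST = SelectorConfig(
    rf_iterations=10,
    rf_grid={"n_estimators": [100], "max_depth": [None]},
    svm_grid={"C": [0.1, 1.0]},
    logreg_grid={"C": [0.1, 1.0]},
    inner_cv_k=3,
    top_k=300,
)


class TestOptRF:
    def test_informative_features_rank_top(self):
        X, y = _panel_data(2, 200, seed=1)
        panel = select_opt_rf(X, y, FAST, seed=0)
        assert {"inf0", "inf1"} <= set(panel.genes[:5])

    def test_single_iteration_equals_one_forest_ranking(self):
        from sklearn.ensemble import RandomForestClassifier

        X, y = _panel_data(2, 50, seed=2)
        cfg = SelectorConfig(**{**FAST.__dict__, "rf_iterations": 1})
        panel = select_opt_rf(X, y, cfg, seed=7)
        rf = RandomForestClassifier(
            n_estimators=100, max_depth=None, random_state=7, n_jobs=1
        ).fit(X.to_numpy(), y)
        imp = pd.Series(rf.feature_importances_, index=X.columns)
        expected = imp.sort_values(ascending=False, kind="stable").index[: len(panel)]
        assert panel.genes[:10] == list(expected[:10])

    def test_summed_importances_bounded_by_iterations(self):
        X, y = _panel_data(2, 30, seed=3)
        panel = select_opt_rf(X, y, FAST, seed=0)
        assert (np.asarray(panel.scores) >= 0).all()
        assert np.asarray(panel.scores).sum() <= FAST.rf_iterations + 1e-9


class TestSvmRfe:
    def test_ranking_only_when_pool_at_stop_size(self):
        X, y = _panel_data(1, 49, seed=4)
        cfg = SelectorConfig(**{**FAST.__dict__, "rfe_stop": 50})
        panel = select_svm_rfe(X, y, cfg, seed=0)
        assert set(panel.genes) == set(X.columns)
        assert panel.genes[0] == "inf0"

    def test_perfect_separator_survives_elimination(self):
        X, y = _panel_data(1, 319, seed=5, effect=8.0)
        cfg = SelectorConfig(**{**FAST.__dict__, "rfe_stop": 300})
        panel = select_svm_rfe(X, y, cfg, seed=0)
        assert "inf0" in panel.genes
        assert len(panel) == 300


class TestLogregL1:
    def test_strong_predictor_ranked_first(self):
        X, y = _panel_data(1, 100, seed=6)
        panel = select_logreg_l1(X, y, FAST, seed=0)
        assert panel.genes[0] == "inf0"

    def test_sparsity_monotone_in_penalty(self):
        from sklearn.linear_model import LogisticRegression
        from sklearn.preprocessing import StandardScaler

        X, y = _panel_data(3, 80, seed=7, effect=1.0)
        Xs = StandardScaler().fit_transform(X)
        nonzero = []
        for C in (0.01, 0.1, 1.0):
            lr = LogisticRegression(penalty="l1", solver="liblinear", C=C).fit(Xs, y)
            nonzero.append(int((lr.coef_ != 0).sum()))
        assert nonzero == sorted(nonzero)


class TestSelectDgea:
    def _result(self):
        return pd.DataFrame(
            {
                "log2fc": [2.0, -1.5, 0.5, 1.2, -2.5],
                "padj": [0.001, 0.001, 0.0001, 0.01, 0.02],
            },
            index=["a", "b", "c", "d", "e"],
        )

    def test_small_pool_returned_whole(self):
        panel = select_dgea(self._result(), top_k=300)
        assert len(panel) == 4  # "c" fails the fold-change filter

    def test_subthreshold_fold_change_excluded(self):
        panel = select_dgea(self._result(), top_k=300)
        assert "c" not in panel.genes

    def test_padj_ties_broken_by_abs_lfc(self):
        panel = select_dgea(self._result(), top_k=2)
        assert panel.genes == ["a", "b"]  # tie at padj 0.001 -> |lfc| 2.0 before 1.5


class TestTuning:
    def test_single_point_space_returned(self):
        from sklearn.linear_model import LogisticRegression

        X, y = _panel_data(1, 5, seed=8)
        best, score = tune_hyperparameters(
            LogisticRegression(max_iter=500), {"C": [0.5]}, X, y, inner_k=3, seed=0
        )
        assert best == {"C": 0.5}
        assert 0 <= score <= 1

    def test_dominated_point_never_wins(self):
        from sklearn.linear_model import LogisticRegression

        X, y = _panel_data(2, 10, seed=9)
        best_small, _ = tune_hyperparameters(
            LogisticRegression(max_iter=500), {"C": [1.0]}, X, y, inner_k=3, seed=0
        )
        best_more, _ = tune_hyperparameters(
            LogisticRegression(max_iter=500, penalty="l1", solver="liblinear"),
            {"C": [1.0, 1e-4]},  # C=1e-4 shrinks every coefficient to zero
            X, y, inner_k=3, seed=0,
        )
        assert best_more["C"] == 1.0
        assert best_small["C"] == 1.0

    def test_random_search_deterministic_under_seed(self):
        from sklearn.ensemble import RandomForestClassifier

        X, y = _panel_data(1, 10, seed=10)
        space = {"n_estimators": [10, 20], "max_depth": [1, 2, None]}
        kw = dict(weights=MetricWeights(), inner_k=2, method="random", n_iter=3)
        a, _ = tune_hyperparameters(RandomForestClassifier(random_state=0), space, X, y, seed=5, **kw)
        b, _ = tune_hyperparameters(RandomForestClassifier(random_state=0), space, X, y, seed=5, **kw)
        assert a == b

    def test_empty_space_rejected(self):
        from sklearn.linear_model import LogisticRegression

        X, y = _panel_data(1, 3, seed=11)
        with pytest.raises(ValueError, match="empty"):
            tune_hyperparameters(LogisticRegression(), {"C": []}, X, y)


def test_ranked_panel_rejects_duplicates():
    with pytest.raises(ValueError, match="duplicate"):
        RankedPanel(genes=["a", "a"], scores=np.array([1.0, 0.5]), method="opt_rf")
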