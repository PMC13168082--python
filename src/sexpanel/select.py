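"""Stratified cross-validation and the four feature-selection strategies.

Per classification task and fold, four top-K gene panels are produced:

* ``opt_rf``    -- a grid-tuned random forest grown ``rf_iterations`` times
  with consecutive seeds; each forest adds the importances of its own top
  ``rf_track_top`` genes to a running sum, and genes are ranked by the sum.
* ``svm_rfe``   -- recursive feature elimination with a linear max-margin
  classifier, removing max(1, round(0.001 * current)) features per iteration
  until ``rfe_stop`` remain; survivors are ranked by final |coefficient|.
* ``logreg_l1`` -- an L1-penalised logistic model at a tuned regularisation
  strength; genes ranked by |coefficient|.
* ``dgea_p``    -- the differential-expression ranking: |log2FC| > 1 genes
  ordered by adjusted p-value.

Hyperparameters are tuned by the composite metric on inner stratified folds
drawn from the training data only; standardisation for the distance-based
models is fitted inside each inner training fold to avoid leakage.
Tie-breaking is score desc -> |effect| desc -> gene id, everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import ParameterGrid, ParameterSampler
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .config import DEGThresholds, MetricWeights, SelectorConfig

METHODS = ("opt_rf", "svm_rfe", "logreg_l1", "dgea_p")


# ---------------------------------------------------------------------------
# folds

@dataclass(frozen=True)
class FoldScheme:
    """Partition of samples into k stratified folds."""

    assignment: pd.Series  # sample id -> fold index
    k: int
    task: str = ""
    seed: int = 0

    def test_ids(self, fold: int) -> list[str]:
        return list(self.assignment.index[self.assignment == fold])

    def train_ids(self, fold: int) -> list[str]:
        return list(self.assignment.index[self.assignment != fold])


def stratified_kfold(labels: pd.Series, k: int = 5, seed: int = 0, task: str = "") -> FoldScheme:
    """Deterministic stratified k-fold assignment.

    Classes are processed largest-first; each class is shuffled under the seed
    and dealt to the currently smallest fold, which keeps per-fold class
    counts within one of the proportional share and keeps fold sizes balanced
    even for classes smaller than k (rare strata are spread across folds
    rather than rejected).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = pd.Series(labels)
    counts = labels.value_counts()
    if (counts < 1).any() or len(counts) < 2:
        raise ValueError("need at least two non-empty classes")
    rng = np.random.default_rng(seed)
    fold_sizes = np.zeros(k, dtype=int)
    assignment = pd.Series(-1, index=labels.index, dtype=int)
    for cls in counts.sort_values(ascending=False).index:
        members = list(labels.index[labels == cls])
        rng.shuffle(members)
        for m in members:
            f = int(np.argmin(fold_sizes))  # ties -> lowest fold index
            assignment.loc[m] = f
            fold_sizes[f] += 1
    return FoldScheme(assignment=assignment, k=k, task=task, seed=seed)


# ---------------------------------------------------------------------------
# composite metric

def composite_score(
    f1: float,
    auroc: float,
    balanced_accuracy: float,
    weights: MetricWeights = MetricWeights(),
) -> float:
    """Imbalance-aware model-selection score: weighted sum of F1, AUROC, and
    balanced accuracy (defaults 0.5 / 0.3 / 0.2)."""
    for name, v in (("f1", f1), ("auroc", auroc), ("balanced_accuracy", balanced_accuracy)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return weights.f1 * f1 + weights.auroc * auroc + weights.balanced_accuracy * balanced_accuracy


def decision_scores(estimator, X) -> np.ndarray:
    """Probability-like scores for ranking metrics, whatever the model exposes."""
    if hasattr(estimator, "predict_proba"):
        return np.asarray(estimator.predict_proba(X))[:, 1]
    return np.asarray(estimator.decision_function(X))


def composite_from_predictions(
    y_true, y_pred, y_score, weights: MetricWeights = MetricWeights()
) -> float:
    y_true = np.asarray(y_true)
    f1 = f1_score(y_true, y_pred, zero_division=0)
    bal = balanced_accuracy_score(y_true, y_pred)
    # a degenerate single-class validation fold carries no ranking information
    auroc = 0.5 if len(np.unique(y_true)) < 2 else roc_auc_score(y_true, y_score)
    return composite_score(f1, auroc, bal, weights)


def _cv_splits(y: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    labels = pd.Series(y, index=pd.RangeIndex(len(y)))
    scheme = stratified_kfold(labels, k=k, seed=seed)
    splits = []
    for f in range(k):
        test = np.asarray(scheme.test_ids(f), dtype=int)
        train = np.asarray(scheme.train_ids(f), dtype=int)
        splits.append((train, test))
    return splits


def tune_hyperparameters(
    estimator,
    search_space,
    X,
    y,
    *,
    weights: MetricWeights = MetricWeights(),
    inner_k: int = 5,
    seed: int = 0,
    method: str = "grid",
    n_iter: int = 50,
) -> tuple[dict, float]:
    """Maximise the mean inner-fold composite score over a parameter space.

    ``method='grid'`` enumerates :class:`ParameterGrid` order; ``'random'``
    draws ``n_iter`` points with :class:`ParameterSampler` under the seed.
    Ties are broken by the first-encountered candidate, so the search is
    deterministic end to end.
    """
    if method == "grid":
        candidates = list(ParameterGrid(search_space))
    elif method == "random":
        total = 1
        for v in search_space.values():
            total *= len(v)
        candidates = list(
            ParameterSampler(search_space, n_iter=min(n_iter, total), random_state=seed)
        )
    else:
        raise ValueError(f"unknown search method {method!r}")
    if not candidates:
        raise ValueError("empty hyperparameter search space")

    X = np.asarray(X, float)
    y = np.asarray(y)
    k = min(inner_k, int(pd.Series(y).value_counts().min()), len(y) // 2)
    k = max(k, 2)
    splits = _cv_splits(y, k, seed)

    best_params: dict | None = None
    best_score = -np.inf
    for params in candidates:
        scores = []
        for train, test in splits:
            est = clone(estimator).set_params(**params)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(X[train], y[train])
                pred = est.predict(X[test])
                score = decision_scores(est, X[test])
            scores.append(composite_from_predictions(y[test], pred, score, weights))
        mean = float(np.mean(scores))
        if mean > best_score:
            best_score = mean
            best_params = dict(params)
    assert best_params is not None
    return best_params, best_score


# ---------------------------------------------------------------------------
# ranked panels

@dataclass
class RankedPanel:
    """Ordered gene list with per-gene scores from one selector run."""

    genes: list[str]
    scores: np.ndarray
    method: str
    fold: int | None = None
    task: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("panel contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def top(self, n: int) -> "RankedPanel":
        n = max(int(n), 0)
        return RankedPanel(
            genes=self.genes[:n],
            scores=np.asarray(self.scores)[:n],
            method=self.method,
            fold=self.fold,
            task=self.task,
        )


def _ranked(genes: np.ndarray, scores: np.ndarray, effects: np.ndarray | None,
            method: str, top_k: int, fold, task, ascending: bool = False) -> RankedPanel:
    """Order by score (desc unless ascending), tie-break |effect| desc then gene id."""
    primary = scores if ascending else -scores
    eff = np.zeros_like(scores) if effects is None else -np.abs(effects)
    order = np.lexsort((genes, eff, primary))
    order = order[: min(top_k, len(genes))]
    return RankedPanel(
        genes=[str(g) for g in genes[order]],
        scores=np.asarray(scores)[order],
        method=method,
        fold=fold,
        task=task,
    )


def select_opt_rf(
    X: pd.DataFrame,
    y,
    config: SelectorConfig = SelectorConfig(),
    *,
    weights: MetricWeights = MetricWeights(),
    seed: int = 0,
    fold: int | None = None,
    task: str = "",
) -> RankedPanel:
    """Optimized-RF tallying: tune once, then sum each iteration's top
    ``rf_track_top`` importances across ``rf_iterations`` reseeded forests."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("optimized RF needs two classes in the training fold")
    base = RandomForestClassifier(random_state=seed, n_jobs=1)
    best, _ = tune_hyperparameters(
        base, config.rf_grid, X, y,
        weights=weights, inner_k=config.inner_cv_k, seed=seed, method="grid",
    )
    genes = np.asarray(X.columns, dtype=object)
    track = min(config.rf_track_top, len(genes))
    sums = np.zeros(len(genes))
    Xv = X.to_numpy(float)
    for i in range(config.rf_iterations):
        rf = RandomForestClassifier(**best, random_state=seed + i, n_jobs=1)
        rf.fit(Xv, y)
        imp = rf.feature_importances_
        top = np.lexsort((genes, -imp))[:track]
        sums[top] += imp[top]
    return _ranked(genes, sums, None, "opt_rf", config.top_k, fold, task)


def rfe_schedule(n_start: int, step_fraction: float, n_stop: int) -> list[int]:
    """Number of features removed at each RFE iteration until ``n_stop`` remain.

    Each entry is max(1, round(step_fraction * current)), clipped so the last
    iteration lands exactly on ``n_stop``.  With the 0.1% step and the
    max(1, .) floor, 1,000 starting features take exactly 700 iterations.
    """
    drops = []
    current = n_start
    while current > n_stop:
        d = max(1, round(step_fraction * current))
        d = min(d, current - n_stop)
        drops.append(d)
        current -= d
    return drops


def select_svm_rfe(
    X: pd.DataFrame,
    y,
    config: SelectorConfig = SelectorConfig(),
    *,
    weights: MetricWeights = MetricWeights(),
    seed: int = 0,
    fold: int | None = None,
    task: str = "",
) -> RankedPanel:
    """Linear-kernel SVM recursive feature elimination down to ``rfe_stop``."""
    y = np.asarray(y)
    genes = np.asarray(X.columns, dtype=object)
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svm", LinearSVC(random_state=seed, max_iter=20000)),
    ])
    space = {f"svm__{k}": v for k, v in config.svm_grid.items()}
    best, _ = tune_hyperparameters(
        pipe, space, X, y,
        weights=weights, inner_k=config.inner_cv_k, seed=seed, method="grid",
    )
    C = best["svm__C"]
    Xs = StandardScaler().fit_transform(X.to_numpy(float))

    def fit_svm(cols: np.ndarray) -> np.ndarray:
        svm = LinearSVC(C=C, random_state=seed, max_iter=20000)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            svm.fit(Xs[:, cols], y)
        for w in caught:
            if "ConvergenceWarning" in type(w.message).__name__:
                raise RuntimeError(
                    "linear SVM failed to converge during RFE; "
                    "increase regularization (smaller C) or max_iter"
                )
        return np.abs(svm.coef_.ravel())

    remaining = np.arange(len(genes))
    for n_drop in rfe_schedule(len(genes), config.rfe_step_fraction, config.rfe_stop):
        coefs = fit_svm(remaining)
        # drop the lowest-|coefficient| features; ties drop later gene ids first
        order = np.lexsort((genes[remaining], coefs))
        remaining = np.delete(remaining, order[:n_drop])
    coefs = fit_svm(remaining)
    return _ranked(genes[remaining], coefs, coefs, "svm_rfe", config.top_k, fold, task)


def select_logreg_l1(
    X: pd.DataFrame,
    y,
    config: SelectorConfig = SelectorConfig(),
    *,
    weights: MetricWeights = MetricWeights(),
    seed: int = 0,
    fold: int | None = None,
    task: str = "",
) -> RankedPanel:
    """L1-penalised logistic regression at a tuned strength; rank by |coef|."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("logistic selection needs two classes in the training fold")
    lr = LogisticRegression(penalty="l1", solver="liblinear", max_iter=2000, random_state=seed)
    pipe = Pipeline([("scale", StandardScaler()), ("lr", lr)])
    space = {f"lr__{k}": v for k, v in config.logreg_grid.items()}
    best, _ = tune_hyperparameters(
        pipe, space, X, y,
        weights=weights, inner_k=config.inner_cv_k, seed=seed, method="grid",
    )
    final = clone(pipe).set_params(**best)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", FutureWarning)
        final.fit(X.to_numpy(float), y)
    if final.named_steps["lr"].n_iter_.max() >= 2000:
        raise RuntimeError("L1 logistic fit hit the iteration cap (2000) without converging")
    coefs = np.abs(final.named_steps["lr"].coef_.ravel())
    genes = np.asarray(X.columns, dtype=object)
    return _ranked(genes, coefs, coefs, "logreg_l1", config.top_k, fold, task)


def select_dgea(
    dge_result: pd.DataFrame,
    thresholds: DEGThresholds = DEGThresholds(),
    top_k: int = 300,
    *,
    fold: int | None = None,
    task: str = "",
) -> RankedPanel:
    """Top genes by adjusted p-value among those with |log2FC| above threshold.

    Ties in padj break by |log2FC| descending, then gene id.
    """
    sub = dge_result.loc[dge_result["log2fc"].abs() > thresholds.abs_log2fc_min]
    genes = np.asarray(sub.index, dtype=object)
    return _ranked(
        genes,
        sub["padj"].to_numpy(float),
        sub["log2fc"].to_numpy(float),
        "dgea_p",
        top_k,
        fold,
        task,
        ascending=True,
    )
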