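"""Panel evaluation: four classifier families, composite metric, bootstrap CIs.

Evaluation models are random forest, linear-kernel SVM, k-nearest neighbours,
and gradient-boosted trees; the distance-based families are pipelined with a
standardisation step so scaling statistics never leak across CV folds.
Hyperparameters are tuned on the training data by inner stratified CV with
the composite metric (exhaustive search for the small SVM/KNN spaces,
randomised search for the larger forest/boosting spaces), the tuned model is
refitted on the full training data and scored on the test set, and every
metric gets a 95% percentile bootstrap confidence interval over resamples of
the test samples.  F1 and balanced accuracy use hard labels at the 0.5
probability threshold; AUROC and PR-AUC use the model's continuous scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    average_precision_score,
    balanced_accuracy_score,
    f1_score,
    roc_auc_score,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .config import BootstrapConfig, DEFAULT_KNN_GRID, DEFAULT_RF_GRID, DEFAULT_SVM_GRID, \
    DEFAULT_XGB_SPACE, MetricWeights
from .select import FoldScheme, RankedPanel, composite_score, decision_scores, \
    tune_hyperparameters

MODEL_FAMILIES = ("rf", "svm", "knn", "xgb")
METRIC_NAMES = ("balanced_accuracy", "f1", "auroc", "pr_auc", "composite")


def make_model(family: str, seed: int = 0):
    """Estimator, search space, and search method for one evaluation family."""
    if family == "rf":
        return (
            RandomForestClassifier(random_state=seed, n_jobs=1),
            dict(DEFAULT_RF_GRID),
            "random",
        )
    if family == "svm":
        est = Pipeline([
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="linear", random_state=seed)),
        ])
        return est, {f"svm__{k}": v for k, v in DEFAULT_SVM_GRID.items()}, "grid"
    if family == "knn":
        est = Pipeline([("scale", StandardScaler()), ("knn", KNeighborsClassifier())])
        return est, {f"knn__{k}": v for k, v in DEFAULT_KNN_GRID.items()}, "grid"
    if family == "xgb":
        est = XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss", verbosity=0
        )
        return est, dict(DEFAULT_XGB_SPACE), "random"
    raise ValueError(f"unknown model family {family!r}; expected one of {MODEL_FAMILIES}")


def subset_panel(panel, n: int):
    """First min(n, length) genes, order preserved (prefix property)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(panel, RankedPanel):
        return panel.top(n)
    return list(panel)[:n]


@dataclass
class Metric:
    point: float | None
    lo: float | None = None
    hi: float | None = None
    note: str = ""


@dataclass
class MetricsReport:
    metrics: dict[str, Metric]
    model: str = ""
    panel_method: str = ""
    n_genes: int = 0
    task: str = ""
    dataset: str = ""

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "panel_method": self.panel_method,
            "n_genes": self.n_genes,
            "task": self.task,
            "dataset": self.dataset,
            "metrics": {
                k: {"point": m.point, "lo": m.lo, "hi": m.hi, "note": m.note}
                for k, m in self.metrics.items()
            },
        }


def _metric_values(y_true, y_pred, y_score, weights: MetricWeights) -> dict[str, float | None]:
    y_true = np.asarray(y_true)
    out: dict[str, float | None] = {
        "balanced_accuracy": balanced_accuracy_score(y_true, y_pred),
        "f1": f1_score(y_true, y_pred, zero_division=0),
    }
    if len(np.unique(y_true)) < 2:
        out["auroc"] = None
        out["pr_auc"] = None
        out["composite"] = None
    else:
        out["auroc"] = roc_auc_score(y_true, y_score)
        out["pr_auc"] = average_precision_score(y_true, y_score)
        out["composite"] = composite_score(
            out["f1"], out["auroc"], out["balanced_accuracy"], weights
        )
    return out


def bootstrap_ci(
    y_true,
    y_out,
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    config: BootstrapConfig = BootstrapConfig(),
    *,
    needs_both_classes: bool = True,
) -> tuple[float, float, int] | None:
    """Percentile bootstrap CI of one metric over resampled test samples.

    Returns (lo, hi, n_skipped); resamples lacking both classes are skipped
    for class-dependent metrics.  Returns None when every resample was
    degenerate.
    """
    y_true = np.asarray(y_true)
    y_out = np.asarray(y_out)
    if len(y_true) < 2:
        raise ValueError("need at least two test samples to bootstrap")
    rng = np.random.default_rng(config.seed)
    values = []
    skipped = 0
    for _ in range(config.n_resamples):
        idx = rng.integers(0, len(y_true), len(y_true))
        yt = y_true[idx]
        if needs_both_classes and len(np.unique(yt)) < 2:
            skipped += 1
            continue
        values.append(metric_fn(yt, y_out[idx]))
    if not values:
        return None
    q = (1.0 - config.ci_level) / 2.0
    lo, hi = np.quantile(values, [q, 1.0 - q])
    return float(lo), float(hi), skipped


def _bootstrap_report(
    y_true, y_pred, y_score, weights: MetricWeights, config: BootstrapConfig
) -> dict[str, Metric]:
    """All five metrics with CIs sharing one stream of resamples."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    y_score = np.asarray(y_score)
    points = _metric_values(y_true, y_pred, y_score, weights)
    rng = np.random.default_rng(config.seed)
    samples: dict[str, list[float]] = {k: [] for k in METRIC_NAMES}
    skipped = 0
    for _ in range(config.n_resamples):
        idx = rng.integers(0, len(y_true), len(y_true))
        if len(np.unique(y_true[idx])) < 2:
            skipped += 1
            continue
        vals = _metric_values(y_true[idx], y_pred[idx], y_score[idx], weights)
        for k in METRIC_NAMES:
            samples[k].append(vals[k])
    q = (1.0 - config.ci_level) / 2.0
    out: dict[str, Metric] = {}
    note = f"{skipped} degenerate resamples skipped" if skipped else ""
    for k in METRIC_NAMES:
        if points[k] is None:
            out[k] = Metric(None, note="single-class test set; metric undefined")
        elif samples[k]:
            lo, hi = np.quantile(samples[k], [q, 1.0 - q])
            out[k] = Metric(points[k], float(lo), float(hi), note)
        else:
            out[k] = Metric(points[k], note="all bootstrap resamples degenerate")
    return out


def evaluate_panel(
    train_X: pd.DataFrame,
    y_train,
    test_X: pd.DataFrame,
    y_test,
    panel,
    model_family: str,
    *,
    weights: MetricWeights = MetricWeights(),
    bootstrap: BootstrapConfig | None = None,
    seed: int = 0,
    inner_k: int = 5,
    n_iter: int = 200,
    dataset: str = "",
    task: str = "",
) -> MetricsReport:
    """Tune on training data, fit, score one panel on one test cohort."""
    genes = list(panel.genes) if isinstance(panel, RankedPanel) else [str(g) for g in panel]
    present = [g for g in genes if g in train_X.columns and g in test_X.columns]
    missing = sorted(set(genes) - set(present))
    if missing:
        warnings.warn(
            f"{len(missing)} panel genes absent from train/test and dropped: "
            f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
        )
    if not present:
        raise ValueError("no panel genes present in both matrices")

    est, space, method = make_model(model_family, seed)
    Xtr = train_X.loc[:, present]
    Xte = test_X.loc[:, present]
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    best, _ = tune_hyperparameters(
        est, space, Xtr, y_train,
        weights=weights, inner_k=inner_k, seed=seed, method=method, n_iter=n_iter,
    )
    final = est.set_params(**best)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(Xtr.to_numpy(float), y_train)
        y_pred = final.predict(Xte.to_numpy(float))
        y_score = decision_scores(final, Xte.to_numpy(float))

    if bootstrap is not None:
        metrics = _bootstrap_report(y_test, y_pred, y_score, weights, bootstrap)
    else:
        metrics = {
            k: Metric(v) if v is not None else Metric(None, note="single-class test set")
            for k, v in _metric_values(y_test, y_pred, y_score, weights).items()
        }
    method_name = panel.method if isinstance(panel, RankedPanel) else ""
    return MetricsReport(
        metrics=metrics,
        model=model_family,
        panel_method=method_name,
        n_genes=len(present),
        task=task,
        dataset=dataset,
    )


def internal_validate(
    X: pd.DataFrame,
    y: pd.Series,
    fold_scheme: FoldScheme,
    panels: Sequence[RankedPanel],
    model_families: Sequence[str] = ("rf",),
    *,
    weights: MetricWeights = MetricWeights(),
    seed: int = 0,
    inner_k: int = 5,
    n_iter: int = 50,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Average each per-fold panel's metrics over its own held-out fold.

    Panels must carry the fold they were derived in (fold f's panel is scored
    only on fold f); cross-fold aggregated panels are rejected here because
    they were assembled outside the cross-validation scheme.
    """
    rows = []
    for panel in panels:
        if panel.fold is None:
            raise ValueError(
                "aggregated (cross-fold) panels cannot enter internal validation"
            )
        if panel.fold not in range(fold_scheme.k):
            raise ValueError(f"panel fold {panel.fold} outside scheme with k={fold_scheme.k}")
    for family in model_families:
        per_method: dict[str, list[dict[str, float | None]]] = {}
        for panel in panels:
            use = panel if top_n is None else panel.top(top_n)
            train_ids = fold_scheme.train_ids(panel.fold)
            test_ids = fold_scheme.test_ids(panel.fold)
            report = evaluate_panel(
                X.loc[train_ids], y.loc[train_ids],
                X.loc[test_ids], y.loc[test_ids],
                use, family,
                weights=weights, seed=seed, inner_k=inner_k, n_iter=n_iter,
                dataset="internal", task=panel.task,
            )
            per_method.setdefault(panel.method, []).append(
                {k: m.point for k, m in report.metrics.items()}
            )
        for method_name, fold_metrics in per_method.items():
            row: dict = {"model": family, "method": method_name, "n_folds": len(fold_metrics)}
            for k in METRIC_NAMES:
                vals = [m[k] for m in fold_metrics if m[k] is not None]
                row[k] = float(np.mean(vals)) if vals else None
            rows.append(row)
    return pd.DataFrame(rows)
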