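"""Fixed constants and tunable configuration blocks shared across the pipeline.

The defaults here are the study conditions: DEG thresholds (BH-adjusted
p < 0.05, |log2FC| > 1), the imbalance-aware composite model-selection
metric 0.5*F1 + 0.3*AUROC + 0.2*balanced accuracy, top-300 panels, 1,000
optimized-RF iterations, the 0.1% SVM-RFE elimination step, and 500-resample
95% percentile bootstrap intervals.  Every block is overridable so the full
pipeline also runs at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

TASKS = ("male_dev", "female_dev", "tumor_sex")


@dataclass(frozen=True)
class DEGThresholds:
    """Differential-expression calls use strict inequalities, exactly as printed."""

    padj_max: float = 0.05
    abs_log2fc_min: float = 1.0

    def violations(self) -> list[str]:
        out = []
        if not 0 < self.padj_max <= 1:
            out.append(f"padj_max must lie in (0, 1], got {self.padj_max}")
        if self.abs_log2fc_min < 0:
            out.append(f"abs_log2fc_min must be >= 0, got {self.abs_log2fc_min}")
        return out


@dataclass(frozen=True)
class MetricWeights:
    """Weights of the composite metric; F1 is weighted most heavily because of
    its sensitivity to the true-positive rate on imbalanced cohorts."""

    f1: float = 0.5
    auroc: float = 0.3
    balanced_accuracy: float = 0.2

    def violations(self) -> list[str]:
        total = self.f1 + self.auroc + self.balanced_accuracy
        out = []
        if abs(total - 1.0) > 1e-9:
            out.append(f"metric weights must sum to 1, got {total}")
        if min(self.f1, self.auroc, self.balanced_accuracy) < 0:
            out.append("metric weights must be non-negative")
        return out


#: default hyperparameter search spaces; the source study does not publish its
#: grids, so these are modest fixed spaces recorded in the run manifest.
DEFAULT_RF_GRID: Mapping[str, list[Any]] = {
    "n_estimators": [100],
    "max_depth": [None, 10],
    "min_samples_split": [2, 5],
    "max_features": ["sqrt"],
}
DEFAULT_SVM_GRID: Mapping[str, list[Any]] = {"C": [0.01, 0.1, 1.0, 10.0]}
DEFAULT_LOGREG_GRID: Mapping[str, list[Any]] = {"C": [0.01, 0.1, 1.0, 10.0]}
DEFAULT_KNN_GRID: Mapping[str, list[Any]] = {
    "n_neighbors": [3, 5, 7],
    "weights": ["uniform", "distance"],
}
DEFAULT_XGB_SPACE: Mapping[str, list[Any]] = {
    "n_estimators": [50, 100, 200],
    "max_depth": [2, 3, 4, 6],
    "learning_rate": [0.05, 0.1, 0.3],
    "subsample": [0.7, 1.0],
}


@dataclass(frozen=True)
class SelectorConfig:
    """Knobs of the four feature-selection strategies.

    ``rf_iterations`` forests are grown with consecutive seeds; each forest
    contributes the importances of its own top ``rf_track_top`` genes to a
    running sum.  SVM-RFE removes ``max(1, round(rfe_step_fraction * current))``
    features per iteration until ``rfe_stop`` remain.  All panels are truncated
    to ``top_k`` genes.
    """

    rf_iterations: int = 1000
    rf_track_top: int = 300
    rfe_step_fraction: float = 0.001
    rfe_stop: int = 300
    top_k: int = 300
    inner_cv_k: int = 5
    rf_grid: Mapping[str, list[Any]] = field(default_factory=lambda: dict(DEFAULT_RF_GRID))
    svm_grid: Mapping[str, list[Any]] = field(default_factory=lambda: dict(DEFAULT_SVM_GRID))
    logreg_grid: Mapping[str, list[Any]] = field(default_factory=lambda: dict(DEFAULT_LOGREG_GRID))
    seed: int = 0

    def violations(self) -> list[str]:
        out = []
        for name in ("rf_iterations", "rf_track_top", "rfe_stop", "top_k", "inner_cv_k"):
            if getattr(self, name) < 1:
                out.append(f"{name} must be a positive integer")
        if not 0 < self.rfe_step_fraction < 1:
            out.append("rfe_step_fraction must lie in (0, 1)")
        return out


@dataclass(frozen=True)
class BootstrapConfig:
    n_resamples: int = 500
    ci_level: float = 0.95
    seed: int = 0

    def violations(self) -> list[str]:
        out = []
        if self.n_resamples < 1:
            out.append("n_resamples must be >= 1")
        if not 0 < self.ci_level < 1:
            out.append("ci_level must lie in (0, 1)")
        return out


#: feature-count ladder used when subsetting a top-300 panel for evaluation
DEFAULT_TOP_N_LADDER = (300, 250, 200, 150, 100, 50, 25, 10)
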