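"""Batch-aware negative-binomial differential expression on raw counts.

Per gene, counts are modelled as NB(mu, alpha) with log link,

    log mu = log(size factor) + intercept + batch indicators + condition,

fitted by iteratively reweighted least squares, vectorised across genes.
Size factors use the median-of-ratios convention; the per-gene dispersion
alpha is a Pearson-residual moment estimate with a floor, refined once by
refitting.  The condition coefficient's Wald statistic yields a two-sided
normal p-value; Benjamini-Hochberg adjustment runs across all tested genes.
The contract is calibrated type-I error on a null simulation, not numeric
identity with any particular reference implementation (whose dispersion
shrinkage and outlier handling are deliberately out of scope here).

DEG filtering uses the strict thresholds padj < 0.05 and |log2FC| > 1.0, and
the cross-stratum exclusion rule removes genes differentially expressed in
the same direction in the companion contrast, retaining oppositely regulated
genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import DEGThresholds

LN2 = np.log(2.0)
_MIN_ALPHA = 1e-8
_MAX_ALPHA = 20.0


class ConfoundedDesignError(ValueError):
    """Condition is not estimable given the batch structure."""


def estimate_size_factors(counts: pd.DataFrame, method: str = "all-positive") -> pd.Series:
    """Median-of-ratios size factors.

    ``all-positive`` (the standard convention) uses only genes with positive
    counts in every sample and raises if none exist, suggesting the
    ``poscounts`` fallback, which takes per-gene ratios over the samples where
    the gene is expressed.
    """
    x = counts.to_numpy(float)
    if x.shape[1] == 0:
        raise ValueError("no samples")
    with np.errstate(divide="ignore"):
        logx = np.log(x)
    if method == "all-positive":
        allpos = (x > 0).all(axis=1)
        if not allpos.any():
            raise ValueError(
                "no gene has positive counts in every sample; "
                "use method='poscounts' as a fallback"
            )
        loggeo = logx[allpos].mean(axis=1)
        ratios = logx[allpos] - loggeo[:, None]
        sf = np.exp(np.median(ratios, axis=0))
    elif method == "poscounts":
        pos = x > 0
        with np.errstate(invalid="ignore"):
            loggeo = np.where(pos, logx, 0.0).sum(axis=1) / np.maximum(pos.sum(axis=1), 1)
        keep = pos.sum(axis=1) > 0
        ratios = np.where(pos, logx - loggeo[:, None], np.nan)[keep]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sf = np.exp(np.nanmedian(ratios, axis=0))
    else:
        raise ValueError(f"unknown method {method!r}")
    if not np.all(np.isfinite(sf)) or (sf <= 0).any():
        raise ValueError("size-factor estimation produced non-positive factors")
    return pd.Series(sf, index=counts.columns, name="size_factor")


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up with monotonicity enforcement, capped at 1."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _design(condition: np.ndarray, batch: np.ndarray | None) -> tuple[np.ndarray, list[str]]:
    n = condition.shape[0]
    cols = [np.ones(n)]
    names = ["intercept"]
    if batch is not None:
        levels = sorted(pd.unique(batch))
        for lev in levels[1:]:
            cols.append((batch == lev).astype(float))
            names.append(f"batch[{lev}]")
    cols.append(condition.astype(float))
    names.append("condition")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ConfoundedDesignError(
            "design matrix is rank-deficient: condition is confounded with batch"
        )
    return X, names


def _irls(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    n_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched NB IRLS over genes.  Returns (beta, se, mu).

    The linear predictor is clipped to keep exp() finite for separated genes
    (e.g. a group with all-zero counts); their coefficients saturate at the
    clip and their Wald statistics remain finite and extreme.
    """
    G, n = y.shape
    p = X.shape[1]
    pinv = np.linalg.pinv(X)
    with np.errstate(divide="ignore"):
        beta = (np.log(y + 0.5) - offset) @ pinv.T
    XtWX = None
    for _ in range(n_iter):
        eta = np.clip(beta @ X.T + offset, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset) + (y - mu) / mu
        XtWX = np.einsum("gn,ni,nj->gij", W, X, X)
        XtWX += 1e-10 * np.eye(p)
        XtWz = np.einsum("gn,ni,gn->gi", W, X, z)
        new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        step = np.max(np.abs(new - beta))
        beta = new
        if step < tol:
            break
    eta = np.clip(beta @ X.T + offset, -30.0, 30.0)
    mu = np.exp(eta)
    cov = np.linalg.inv(XtWX)
    se = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))
    return beta, se, mu


def _moment_dispersion(y: np.ndarray, mu: np.ndarray, p: int) -> np.ndarray:
    """Pearson-residual moment estimator of NB alpha with floor and ceiling."""
    n = y.shape[1]
    mu_safe = np.maximum(mu, 1e-8)
    contrib = ((y - mu) ** 2 - mu) / mu_safe**2
    alpha = contrib.sum(axis=1) / max(n - p, 1)
    return np.clip(alpha, _MIN_ALPHA, _MAX_ALPHA)


def nb_wald_test(
    counts: pd.DataFrame,
    condition_labels,
    batch_labels=None,
    *,
    positive=None,
    size_factors: pd.Series | None = None,
    dispersion: float | np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test of ``condition`` with optional batch covariates.

    ``positive`` names the condition level whose effect is reported (log2FC of
    positive vs the other level); by default the lexicographically larger
    level.  All-zero genes are excluded from testing and listed in
    ``result.attrs['excluded']``.
    """
    cond = pd.Series(condition_labels, index=counts.columns) if not isinstance(
        condition_labels, pd.Series
    ) else condition_labels.loc[counts.columns]
    levels = sorted(pd.unique(cond))
    if len(levels) != 2:
        raise ValueError(f"condition must have exactly two levels, got {levels}")
    if positive is None:
        positive = levels[1]
    if positive not in levels:
        raise ValueError(f"positive level {positive!r} not among {levels}")
    ind = (cond == positive).to_numpy()

    batch = None
    if batch_labels is not None:
        b = pd.Series(batch_labels, index=counts.columns) if not isinstance(
            batch_labels, pd.Series
        ) else batch_labels.loc[counts.columns]
        if b.nunique() > 1:
            batch = b.to_numpy()

    X, _ = _design(ind, batch)
    y_all = counts.to_numpy(float)
    nonzero = y_all.sum(axis=1) > 0
    excluded = [str(g) for g in counts.index[~nonzero]]
    y = y_all[nonzero]
    if y.shape[0] == 0:
        raise ValueError("all genes have zero counts")

    if size_factors is None:
        try:
            sf = estimate_size_factors(counts)
        except ValueError:
            sf = estimate_size_factors(counts, method="poscounts")
    else:
        sf = size_factors.loc[counts.columns]
    offset = np.log(sf.to_numpy(float))

    p = X.shape[1]
    if dispersion is None:
        zeros = np.zeros(y.shape[0])
        _, _, mu0 = _irls(y, X, offset, zeros, n_iter=25)
        alpha = _moment_dispersion(y, mu0, p)
        _, _, mu1 = _irls(y, X, offset, alpha, n_iter=25)
        alpha = _moment_dispersion(y, mu1, p)
    elif np.isscalar(dispersion):
        alpha = np.full(y.shape[0], float(dispersion))
        alpha = np.clip(alpha, _MIN_ALPHA, _MAX_ALPHA)
    else:
        alpha = np.clip(np.asarray(dispersion, float)[nonzero], _MIN_ALPHA, _MAX_ALPHA)

    beta, se, _ = _irls(y, X, offset, alpha)
    b_cond = beta[:, -1]
    se_cond = np.maximum(se[:, -1], 1e-12)
    wald = b_cond / se_cond
    pval = 2.0 * stats.norm.sf(np.abs(wald))
    padj = bh_adjust(pval)
    base_mean = (y / sf.to_numpy(float)[None, :]).mean(axis=1)

    result = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": b_cond / LN2,
            "lfc_se": se_cond / LN2,
            "stat": wald,
            "pvalue": pval,
            "padj": padj,
            "dispersion": alpha,
        },
        index=counts.index[nonzero],
    )
    result.attrs["excluded"] = excluded
    result.attrs["positive"] = positive
    result.attrs["reference"] = [l for l in levels if l != positive][0]
    return result


@dataclass(frozen=True)
class DEGSet:
    """Genes passing both DEG thresholds, with their direction of regulation."""

    directions: dict[str, int] = field(default_factory=dict)  # gene -> +1 (up) / -1 (down)
    contrast: str = ""

    def genes(self) -> set[str]:
        return set(self.directions)

    def __len__(self) -> int:
        return len(self.directions)


def filter_degs(result: pd.DataFrame, thresholds: DEGThresholds = DEGThresholds(),
                contrast: str = "") -> DEGSet:
    """Strict thresholds exactly as printed: padj < 0.05 and |log2FC| > 1.0."""
    mask = (result["padj"] < thresholds.padj_max) & (
        result["log2fc"].abs() > thresholds.abs_log2fc_min
    )
    sub = result.loc[mask]
    directions = {str(g): (1 if l > 0 else -1) for g, l in sub["log2fc"].items()}
    return DEGSet(directions=directions, contrast=contrast)


def exclude_shared_degs(target: DEGSet, other: DEGSet) -> DEGSet:
    """Drop genes regulated in the same direction in both contrasts; genes
    absent from ``other`` or oppositely regulated are retained."""
    kept = {
        g: d
        for g, d in target.directions.items()
        if other.directions.get(g) != d
    }
    return DEGSet(directions=kept, contrast=target.contrast)
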