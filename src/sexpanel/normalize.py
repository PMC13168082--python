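"""Normalization chain: counts -> TPM -> log2(x+1) -> per-dataset z-score -> merge.

Each matrix carries an explicit ``stage`` label and every operation checks it,
so the chain can only be applied in order.  Datasets are z-scored
independently (gene-wise mean 0, sd 1 within each batch, sample-sd
convention with the n-1 denominator) before concatenation on common genes;
this is the batch-correction step of the pipeline, and external test sets are
always z-scored with their own statistics, never the training statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

STAGES = ("counts", "tpm", "log2tpm", "zscored")


class StageError(ValueError):
    """An operation was applied to a matrix at the wrong pipeline stage."""


@dataclass
class ExpressionMatrix:
    """Gene x sample grid with a pipeline-stage label and optional metadata."""

    values: pd.DataFrame
    stage: str = "counts"
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}; expected one of {STAGES}")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    def _require(self, *stages: str) -> None:
        if self.stage not in stages:
            raise StageError(
                f"operation requires stage in {stages}, matrix is at {self.stage!r}"
            )


def collapse_duplicates(matrix: ExpressionMatrix, mode: str) -> ExpressionMatrix:
    """Collapse duplicate gene IDs: ``sum`` on raw counts (training sets) or
    arithmetic ``mean`` on TPM-scale values (external sets)."""
    if mode == "sum":
        matrix._require("counts")
    elif mode == "mean":
        matrix._require("tpm", "log2tpm")
    else:
        raise ValueError(f"mode must be 'sum' or 'mean', got {mode!r}")
    if matrix.values.index.is_unique:
        return replace(matrix, values=matrix.values.copy())
    grouped = matrix.values.groupby(level=0, sort=False)
    values = grouped.sum() if mode == "sum" else grouped.mean()
    # groupby(sort=False) keeps first-occurrence order of gene IDs
    return replace(matrix, values=values)


def counts_to_tpm(counts: ExpressionMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """tpm_ij = (c_ij / len_i) / sum_k (c_kj / len_k) * 1e6; all-zero samples stay zero."""
    counts._require("counts")
    missing = [g for g in counts.gene_ids if g not in lengths.index]
    if missing:
        raise KeyError(f"gene length missing for {missing[:5]}"
                       + ("..." if len(missing) > 5 else ""))
    lens = lengths.loc[counts.values.index].astype(float)
    if (lens <= 0).any():
        bad = lens.index[lens <= 0][0]
        raise ValueError(f"non-positive gene length for {bad!r}")
    rate = counts.values.div(lens, axis=0)
    colsum = rate.sum(axis=0)
    tpm = rate.div(colsum.where(colsum > 0, 1.0), axis=1) * 1e6
    return replace(counts, values=tpm, stage="tpm")


def log2_pseudocount(matrix: ExpressionMatrix) -> ExpressionMatrix:
    matrix._require("tpm")
    if (matrix.values.to_numpy() < 0).any():
        raise ValueError("log2 transform requires non-negative values")
    return replace(matrix, values=np.log2(matrix.values + 1.0), stage="log2tpm")


def zscore_per_dataset(matrix: ExpressionMatrix, batch_labels: pd.Series) -> ExpressionMatrix:
    """Within each batch, bring every gene to mean 0 / sd 1 (sample sd, n-1).

    Genes with zero within-batch variance are set to zero in that batch so
    gene sets stay aligned across batches instead of being dropped.
    """
    matrix._require("log2tpm")
    batch_labels = batch_labels.loc[matrix.values.columns]
    out = matrix.values.copy().astype(float)
    for batch, cols in matrix.values.T.groupby(batch_labels, sort=False):
        block = cols.T  # genes x samples of this batch
        if block.shape[1] < 2:
            raise ValueError(
                f"batch {batch!r} has a single sample; gene-wise sd is undefined"
            )
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        z = block.sub(mean, axis=0).div(sd.where(sd > 0, 1.0), axis=0)
        z[sd == 0] = 0.0
        out.loc[:, block.columns] = z
    return replace(matrix, values=out, stage="zscored")


def merge_on_common_genes(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Concatenate samples over the gene intersection; genes not present in
    every matrix are excluded.  Per-sample batch provenance lives in metadata."""
    if not matrices:
        raise ValueError("nothing to merge")
    stages = {m.stage for m in matrices}
    if len(stages) > 1:
        raise StageError(f"cannot merge matrices at mixed stages {sorted(stages)}")
    common = matrices[0].values.index
    for m in matrices[1:]:
        common = common.intersection(m.values.index, sort=False)
    if len(common) == 0:
        raise ValueError("empty gene intersection across matrices")
    values = pd.concat([m.values.loc[common] for m in matrices], axis=1)
    metas = [m.metadata for m in matrices]
    metadata = pd.concat(metas) if all(m is not None for m in metas) else None
    return ExpressionMatrix(values=values, stage=matrices[0].stage, metadata=metadata)


def normalize_counts(
    counts: pd.DataFrame,
    lengths: pd.Series,
    *,
    collapse: str | None = "sum",
    metadata: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Convenience chain counts -> (collapse) -> TPM -> log2(x+1) for one dataset."""
    m = ExpressionMatrix(values=counts, stage="counts", metadata=metadata)
    if collapse is not None:
        m = collapse_duplicates(m, collapse)
    return log2_pseudocount(counts_to_tpm(m, lengths))
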