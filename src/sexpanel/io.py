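"""Tab-delimited readers/writers for every artifact the pipeline exchanges.

Gene IDs are opaque strings (Ensembl-style in real data).  All tables are
plain TSV so that a fixture written by the simulator round-trips through the
same readers the real-data path would use.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .sim import GENE_CLASSES, PlantedTruth, SimResult


def write_matrix(df: pd.DataFrame, path: Path | str, index_label: str = "gene_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_fixture(sim: SimResult, directory: Path | str) -> list[Path]:
    """One counts table per batch, plus metadata, gene lengths, and truth.

    Returns the list of files written.  Everything is round-trippable via
    :func:`read_fixture`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for batch, mat in sim.counts.items():
        p = directory / f"counts_{batch}.tsv"
        write_matrix(mat, p)
        written.append(p)
    p = directory / "metadata.tsv"
    sim.metadata.to_csv(p, sep="\t", index_label="sample_id")
    written.append(p)
    p = directory / "gene_lengths.tsv"
    sim.gene_lengths.rename("length_bp").to_csv(p, sep="\t", index_label="gene_id")
    written.append(p)
    p = directory / "truth.tsv"
    sim.truth_table().to_csv(p, sep="\t")
    written.append(p)
    return written


def _truth_from_table(table: pd.DataFrame) -> PlantedTruth:
    by_class: dict[str, dict[str, float]] = {c: {} for c in GENE_CLASSES if c != "null"}
    for gene, row in table.iterrows():
        if row["class"] != "null":
            by_class[row["class"]][str(gene)] = float(row["log2fc"])
    return PlantedTruth(
        male_specific=by_class["male_specific"],
        female_specific=by_class["female_specific"],
        shared_same=by_class["shared_same"],
        shared_opposite=by_class["shared_opposite"],
        sex_dimorphic=by_class["sex_dimorphic"],
    )


def read_fixture(directory: Path | str) -> SimResult:
    directory = Path(directory)
    metadata = pd.read_csv(directory / "metadata.tsv", sep="\t", index_col="sample_id")
    lengths = pd.read_csv(directory / "gene_lengths.tsv", sep="\t", index_col="gene_id")[
        "length_bp"
    ]
    # keep_default_na: the literal class label "null" must stay a string
    truth_table = pd.read_csv(
        directory / "truth.tsv", sep="\t", index_col="gene_id", keep_default_na=False
    )
    counts = {}
    for path in sorted(directory.glob("counts_*.tsv")):
        batch = path.stem[len("counts_"):]
        counts[batch] = read_matrix(path)
    if not counts:
        raise FileNotFoundError(f"no counts_<batch>.tsv files under {directory}")
    return SimResult(
        counts=counts,
        metadata=metadata,
        gene_lengths=lengths,
        truth=_truth_from_table(truth_table),
    )


def write_panel(panel, path: Path | str) -> None:
    """RankedPanel -> TSV (rank, gene_id, score, method, fold, task)."""
    rows = pd.DataFrame(
        {
            "rank": range(1, len(panel.genes) + 1),
            "gene_id": panel.genes,
            "score": panel.scores,
            "method": panel.method,
            "fold": "" if panel.fold is None else panel.fold,
            "task": panel.task,
        }
    )
    rows.to_csv(path, sep="\t", index=False)


def read_panel(path: Path | str):
    from .select import RankedPanel

    rows = pd.read_csv(path, sep="\t", keep_default_na=False)
    fold = rows["fold"].iloc[0]
    fold = None if fold == "" else int(fold)
    return RankedPanel(
        genes=[str(g) for g in rows["gene_id"]],
        scores=rows["score"].to_numpy(float),
        method=str(rows["method"].iloc[0]),
        fold=fold,
        task=str(rows["task"].iloc[0]),
    )


def write_dge(result: pd.DataFrame, path: Path | str) -> None:
    result.to_csv(path, sep="\t", index_label="gene_id")


def read_dge(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
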