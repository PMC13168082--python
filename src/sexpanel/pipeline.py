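"""Orchestration of the full per-task analysis, file-based and resumable.

A run works inside one workspace directory::

    workdir/
      inputs/                simulated or user-supplied counts/metadata/lengths
      normalized/            per-task normalised training + external matrices
      folds_primary.tsv      stratified 5-fold assignment of the task subset
      folds_exclusion.tsv    fold assignment of the companion subset (dev tasks)
      dge/                   per-fold DGE tables and DEG pools
      panels/                per-fold per-method ranked panels (k x 4 files)
      aggregate/             RRA aggregated + per-method consensus + overlaps
      internal_validation.tsv
      metrics.json           external evaluation with bootstrap CIs
      manifest.json

The three classification tasks mirror the study design: ``male_dev`` and
``female_dev`` contrast tumor vs non-tumor within one sex on the z-score
merged multi-batch cohort; ``tumor_sex`` contrasts male vs female tumors on a
single cohort, with the non-tumor male-vs-female contrast run once outside
the fold scheme purely to exclude sex-shifted genes unrelated to disease.
Stage seeds are split deterministically from one master seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io
from .config import (
    BootstrapConfig,
    DEFAULT_TOP_N_LADDER,
    DEGThresholds,
    MetricWeights,
    SelectorConfig,
    TASKS,
)
from .dge import DEGSet, exclude_shared_degs, filter_degs, nb_wald_test
from .evaluate import MODEL_FAMILIES, evaluate_panel, internal_validate
from .normalize import merge_on_common_genes, normalize_counts, zscore_per_dataset
from .rra import consensus_per_method, panel_overlap, rra_scores
from .select import (
    METHODS,
    FoldScheme,
    RankedPanel,
    select_dgea,
    select_logreg_l1,
    select_opt_rf,
    select_svm_rfe,
    stratified_kfold,
)
from .sim import ConfigurationError, SimConfig, SimResult, simulate_cohorts

__version__ = "0.1.0"


@dataclass(frozen=True)
class RunConfig:
    task: str
    workdir: Path
    sim: SimConfig | None = None
    thresholds: DEGThresholds = DEGThresholds()
    selector: SelectorConfig = SelectorConfig()
    weights: MetricWeights = MetricWeights()
    bootstrap: BootstrapConfig = BootstrapConfig()
    eval_models: tuple[str, ...] = MODEL_FAMILIES
    internal_models: tuple[str, ...] = ("rf",)
    top_n_ladder: tuple[int, ...] = DEFAULT_TOP_N_LADDER
    k_folds: int = 5
    tumor_task_batch: str = "cohortA"
    run_internal_validation: bool = True
    eval_inner_k: int = 5
    eval_n_iter: int = 200
    seed: int = 0


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict[str, int]
    version: str
    stages: dict[str, list[str]] = field(default_factory=dict)

    def files(self) -> list[str]:
        return [f for fs in self.stages.values() for f in fs]


def validate_config(cfg: RunConfig) -> list[str]:
    """Collect every violation instead of stopping at the first."""
    out: list[str] = []
    if cfg.task not in TASKS:
        out.append(f"unknown task {cfg.task!r}; expected one of {TASKS}")
    out += cfg.thresholds.violations()
    out += cfg.weights.violations()
    out += cfg.selector.violations()
    out += cfg.bootstrap.violations()
    if cfg.k_folds < 2:
        out.append("k_folds must be >= 2")
    for fam in tuple(cfg.eval_models) + tuple(cfg.internal_models):
        if fam not in MODEL_FAMILIES:
            out.append(f"unknown evaluation model family {fam!r}")
    if any(n < 1 for n in cfg.top_n_ladder):
        out.append("top_n_ladder entries must be >= 1")
    if not isinstance(cfg.seed, (int, np.integer)):
        out.append("seed must be an integer")
    if cfg.sim is not None and cfg.task in TASKS:
        meta_counts: dict[tuple[str, str], int] = {}
        for spec in cfg.sim.batch_specs:
            if spec.role != "training":
                continue
            for cell, n in spec.cells.items():
                meta_counts[cell] = meta_counts.get(cell, 0) + n
        if cfg.task == "male_dev":
            classes = [meta_counts.get(("male", "tumor"), 0), meta_counts.get(("male", "non-tumor"), 0)]
        elif cfg.task == "female_dev":
            classes = [meta_counts.get(("female", "tumor"), 0), meta_counts.get(("female", "non-tumor"), 0)]
        else:
            classes = [meta_counts.get(("male", "tumor"), 0), meta_counts.get(("female", "tumor"), 0)]
        if min(classes) < 1:
            out.append(f"task {cfg.task}: an empty class makes {cfg.k_folds}-fold CV infeasible")
        elif sum(classes) < 2 * cfg.k_folds:
            out.append(
                f"task {cfg.task}: only {sum(classes)} samples for {cfg.k_folds}-fold CV"
            )
    return out


def stage_seeds(seed: int) -> dict[str, int]:
    names = ("sim", "folds", "select", "internal", "evaluate", "bootstrap")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % 2**31) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# task geometry

def task_subsets(metadata: pd.DataFrame, task: str, tumor_task_batch: str) -> dict:
    """Sample subsets, contrast labels, and exclusion mode for one task."""
    train = metadata[metadata["role"] == "training"]
    if task == "male_dev":
        primary = train[train["sex"] == "male"]
        excl = train[train["sex"] == "female"]
        return {
            "primary_ids": list(primary.index), "label_col": "status", "positive": "tumor",
            "excl_ids": list(excl.index), "excl_label_col": "status",
            "excl_positive": "tumor", "excl_mode": "per-fold",
        }
    if task == "female_dev":
        primary = train[train["sex"] == "female"]
        excl = train[train["sex"] == "male"]
        return {
            "primary_ids": list(primary.index), "label_col": "status", "positive": "tumor",
            "excl_ids": list(excl.index), "excl_label_col": "status",
            "excl_positive": "tumor", "excl_mode": "per-fold",
        }
    if task == "tumor_sex":
        primary = train[(train["status"] == "tumor") & (train["batch"] == tumor_task_batch)]
        excl = train[train["status"] == "non-tumor"]
        return {
            "primary_ids": list(primary.index), "label_col": "sex", "positive": "male",
            "excl_ids": list(excl.index), "excl_label_col": "sex",
            "excl_positive": "male", "excl_mode": "once",
        }
    raise ValueError(f"unknown task {task!r}")


def _merged_training_counts(sim: SimResult, batches: Sequence[str]) -> pd.DataFrame:
    frames = [sim.counts[b] for b in batches]
    common = frames[0].index
    for f in frames[1:]:
        common = common.intersection(f.index, sort=False)
    if len(common) == 0:
        raise ValueError("no common genes across training batches")
    return pd.concat([f.loc[common] for f in frames], axis=1)


# ---------------------------------------------------------------------------
# stages (each reads/writes the workspace and returns written files)

def _paths(cfg: RunConfig) -> dict[str, Path]:
    w = Path(cfg.workdir)
    return {
        "inputs": w / "inputs",
        "normalized": w / "normalized",
        "dge": w / "dge",
        "panels": w / "panels",
        "aggregate": w / "aggregate",
        "folds_primary": w / "folds_primary.tsv",
        "folds_exclusion": w / "folds_exclusion.tsv",
        "internal": w / "internal_validation.tsv",
        "metrics": w / "metrics.json",
        "manifest": w / "manifest.json",
    }


def stage_simulate(cfg: RunConfig) -> list[Path]:
    p = _paths(cfg)
    if cfg.sim is None:
        if not (p["inputs"] / "metadata.tsv").exists():
            raise FileNotFoundError(
                f"no simulation config and no fixture under {p['inputs']}"
            )
        return []
    # all stage seeds, including the simulator's, derive from the master seed
    seeds = stage_seeds(cfg.seed)
    fields = {f: getattr(cfg.sim, f) for f in cfg.sim.__dataclass_fields__}
    sim = simulate_cohorts(SimConfig(**{**fields, "seed": seeds["sim"]}))
    return io.write_fixture(sim, p["inputs"])


def _load(cfg: RunConfig) -> SimResult:
    return io.read_fixture(_paths(cfg)["inputs"])


def stage_normalize(cfg: RunConfig) -> list[Path]:
    """Per-task normalisation: dev tasks z-score each training batch
    independently and merge on common genes; the single-cohort tumor task
    stays on the log2(TPM+1) scale.  External cohorts always use their own
    statistics."""
    sim = _load(cfg)
    p = _paths(cfg)
    p["normalized"].mkdir(parents=True, exist_ok=True)
    written = []
    zscore = cfg.task in ("male_dev", "female_dev")

    if zscore:
        per_batch = []
        for b in sim.training_batches():
            meta = sim.metadata[sim.metadata["batch"] == b]
            m = normalize_counts(sim.counts[b], sim.gene_lengths, collapse="sum", metadata=meta)
            m = zscore_per_dataset(m, pd.Series(b, index=m.values.columns))
            per_batch.append(m)
        train = merge_on_common_genes(per_batch)
    else:
        b = cfg.tumor_task_batch
        meta = sim.metadata[sim.metadata["batch"] == b]
        train = normalize_counts(sim.counts[b], sim.gene_lengths, collapse="sum", metadata=meta)
    path = p["normalized"] / "train.tsv"
    io.write_matrix(train.values, path)
    written.append(path)

    for b in sim.external_batches():
        # external sets arrive on the TPM scale; duplicates averaged there
        m = normalize_counts(sim.counts[b], sim.gene_lengths, collapse=None)
        if zscore:
            m = zscore_per_dataset(m, pd.Series(b, index=m.values.columns))
        path = p["normalized"] / f"external_{b}.tsv"
        io.write_matrix(m.values, path)
        written.append(path)
    return written


def stage_folds(cfg: RunConfig) -> list[Path]:
    sim = _load(cfg)
    p = _paths(cfg)
    seeds = stage_seeds(cfg.seed)
    sub = task_subsets(sim.metadata, cfg.task, cfg.tumor_task_batch)
    labels = sim.metadata.loc[sub["primary_ids"], sub["label_col"]]
    scheme = stratified_kfold(labels, k=cfg.k_folds, seed=seeds["folds"], task=cfg.task)
    scheme.assignment.rename("fold").to_csv(p["folds_primary"], sep="\t", index_label="sample_id")
    written = [p["folds_primary"]]
    if sub["excl_mode"] == "per-fold":
        excl_labels = sim.metadata.loc[sub["excl_ids"], sub["excl_label_col"]]
        excl_scheme = stratified_kfold(
            excl_labels, k=cfg.k_folds, seed=seeds["folds"] + 1, task=cfg.task + "_excl"
        )
        excl_scheme.assignment.rename("fold").to_csv(
            p["folds_exclusion"], sep="\t", index_label="sample_id"
        )
        written.append(p["folds_exclusion"])
    return written


def _read_folds(path: Path, k: int, task: str = "") -> FoldScheme:
    s = pd.read_csv(path, sep="\t", index_col="sample_id")["fold"]
    return FoldScheme(assignment=s, k=k, task=task)


def stage_dge(cfg: RunConfig) -> list[Path]:
    """Per-fold batch-aware DGE on raw counts plus the exclusion contrast,
    then the task DEG pools."""
    sim = _load(cfg)
    p = _paths(cfg)
    p["dge"].mkdir(parents=True, exist_ok=True)
    sub = task_subsets(sim.metadata, cfg.task, cfg.tumor_task_batch)
    if cfg.task == "tumor_sex":
        counts = sim.counts[cfg.tumor_task_batch]
    else:
        counts = _merged_training_counts(sim, sim.training_batches())
    written: list[Path] = []

    primary = _read_folds(p["folds_primary"], cfg.k_folds, cfg.task)

    def run_contrast(
        ids: list[str], label_col: str, positive: str, table: pd.DataFrame = None
    ) -> pd.DataFrame:
        table = counts if table is None else table
        cols = [i for i in ids if i in table.columns]
        sub_counts = table.loc[:, cols]
        labels = sim.metadata.loc[cols, label_col]
        batches = sim.metadata.loc[cols, "batch"]
        return nb_wald_test(sub_counts, labels, batches, positive=positive)

    excl_sets: dict[int, DEGSet] = {}
    if sub["excl_mode"] == "once":
        # non-tumor male-vs-female contrast runs once, outside the fold scheme
        merged = _merged_training_counts(sim, sim.training_batches())
        res = run_contrast(
            sub["excl_ids"], sub["excl_label_col"], sub["excl_positive"], table=merged
        )
        path = p["dge"] / "exclusion_once.tsv"
        io.write_dge(res, path)
        written.append(path)
        excl_once = filter_degs(res, cfg.thresholds, contrast="nontumor-sex")
        excl_sets = {f: excl_once for f in range(cfg.k_folds)}
    else:
        excl_scheme = _read_folds(p["folds_exclusion"], cfg.k_folds)
        for f in range(cfg.k_folds):
            res = run_contrast(
                excl_scheme.train_ids(f), sub["excl_label_col"], sub["excl_positive"]
            )
            path = p["dge"] / f"fold{f}_exclusion.tsv"
            io.write_dge(res, path)
            written.append(path)
            excl_sets[f] = filter_degs(res, cfg.thresholds, contrast="exclusion")

    for f in range(cfg.k_folds):
        res = run_contrast(primary.train_ids(f), sub["label_col"], sub["positive"])
        path = p["dge"] / f"fold{f}_primary.tsv"
        io.write_dge(res, path)
        written.append(path)
        degs = filter_degs(res, cfg.thresholds, contrast=cfg.task)
        pool = exclude_shared_degs(degs, excl_sets[f])
        pool_df = pd.DataFrame(
            sorted(pool.directions.items()), columns=["gene_id", "direction"]
        )
        path = p["dge"] / f"fold{f}_pool.tsv"
        pool_df.to_csv(path, sep="\t", index=False)
        written.append(path)
    return written


def stage_select(cfg: RunConfig) -> list[Path]:
    """Four ranked panels per fold from the fold's DEG pool."""
    sim = _load(cfg)
    p = _paths(cfg)
    p["panels"].mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg.seed)
    sub = task_subsets(sim.metadata, cfg.task, cfg.tumor_task_batch)
    train = io.read_matrix(p["normalized"] / "train.tsv")
    primary = _read_folds(p["folds_primary"], cfg.k_folds, cfg.task)
    labels = sim.metadata.loc[primary.assignment.index, sub["label_col"]]
    y_all = (labels == sub["positive"]).astype(int)

    written = []
    for f in range(cfg.k_folds):
        pool = pd.read_csv(p["dge"] / f"fold{f}_pool.tsv", sep="\t")["gene_id"].astype(str)
        pool = [g for g in pool if g in train.index]
        if not pool:
            raise RuntimeError(f"fold {f}: empty DEG pool, nothing to select from")
        train_ids = [i for i in primary.train_ids(f) if i in train.columns]
        X = train.loc[pool, train_ids].T
        y = y_all.loc[train_ids].to_numpy()
        fold_seed = seeds["select"] + 1000 * f
        dge_table = io.read_dge(p["dge"] / f"fold{f}_primary.tsv").loc[pool]
        panels = [
            select_opt_rf(X, y, cfg.selector, weights=cfg.weights,
                          seed=fold_seed, fold=f, task=cfg.task),
            select_svm_rfe(X, y, cfg.selector, weights=cfg.weights,
                           seed=fold_seed + 1, fold=f, task=cfg.task),
            select_logreg_l1(X, y, cfg.selector, weights=cfg.weights,
                             seed=fold_seed + 2, fold=f, task=cfg.task),
            select_dgea(dge_table, cfg.thresholds, cfg.selector.top_k,
                        fold=f, task=cfg.task),
        ]
        for panel in panels:
            path = p["panels"] / f"fold{f}_{panel.method}.tsv"
            io.write_panel(panel, path)
            written.append(path)
    return written


def _load_panels(cfg: RunConfig) -> list[RankedPanel]:
    p = _paths(cfg)
    panels = []
    for f in range(cfg.k_folds):
        for m in METHODS:
            panels.append(io.read_panel(p["panels"] / f"fold{f}_{m}.tsv"))
    return panels


def stage_aggregate(cfg: RunConfig) -> list[Path]:
    """RRA over all fold x method rankings, per-method consensus, overlaps."""
    p = _paths(cfg)
    p["aggregate"].mkdir(parents=True, exist_ok=True)
    panels = _load_panels(cfg)
    universe = sorted(set().union(*(set(pl.genes) for pl in panels)))
    agg = rra_scores(panels, universe)
    written = []
    path = p["aggregate"] / "aggregated.tsv"
    agg.table.head(cfg.selector.top_k).to_csv(path, sep="\t")
    written.append(path)

    consensus = {}
    for m in METHODS:
        cons = consensus_per_method(
            [pl for pl in panels if pl.method == m], k=cfg.selector.top_k
        )
        consensus[m] = cons
        path = p["aggregate"] / f"consensus_{m}.tsv"
        io.write_panel(cons, path)
        written.append(path)

    overlap = panel_overlap(list(consensus.values()), names=list(consensus))
    rows = [
        {"panels": "&".join(sorted(k)), "exclusive_count": v}
        for k, v in sorted(overlap.items(), key=lambda kv: ("&".join(sorted(kv[0]))))
    ]
    path = p["aggregate"] / "overlap.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    written.append(path)
    return written


def stage_internal_validation(cfg: RunConfig) -> list[Path]:
    sim = _load(cfg)
    p = _paths(cfg)
    seeds = stage_seeds(cfg.seed)
    sub = task_subsets(sim.metadata, cfg.task, cfg.tumor_task_batch)
    train = io.read_matrix(p["normalized"] / "train.tsv")
    scheme = _read_folds(p["folds_primary"], cfg.k_folds, cfg.task)
    ids = [i for i in scheme.assignment.index if i in train.columns]
    scheme = FoldScheme(scheme.assignment.loc[ids], cfg.k_folds, cfg.task)
    X = train.loc[:, ids].T
    y = (sim.metadata.loc[ids, sub["label_col"]] == sub["positive"]).astype(int)
    table = internal_validate(
        X, y, scheme, _load_panels(cfg), cfg.internal_models,
        weights=cfg.weights, seed=seeds["internal"],
        inner_k=cfg.eval_inner_k, n_iter=cfg.eval_n_iter,
    )
    table.to_csv(p["internal"], sep="\t", index=False)
    return [p["internal"]]


def stage_evaluate(cfg: RunConfig) -> list[Path]:
    """External evaluation of the aggregated and consensus panels across the
    top-N ladder, every model family, and every external cohort."""
    sim = _load(cfg)
    p = _paths(cfg)
    seeds = stage_seeds(cfg.seed)
    sub = task_subsets(sim.metadata, cfg.task, cfg.tumor_task_batch)
    train = io.read_matrix(p["normalized"] / "train.tsv")
    ids = [i for i in sub["primary_ids"] if i in train.columns]
    X_train = train.loc[:, ids].T
    y_train = (sim.metadata.loc[ids, sub["label_col"]] == sub["positive"]).astype(int).to_numpy()

    externals = {}
    for b in sim.external_batches():
        mat = io.read_matrix(p["normalized"] / f"external_{b}.tsv")
        meta = sim.metadata[sim.metadata["batch"] == b]
        if cfg.task == "male_dev":
            keep = meta[meta["sex"] == "male"]
        elif cfg.task == "female_dev":
            keep = meta[meta["sex"] == "female"]
        else:
            keep = meta[meta["status"] == "tumor"]
        cols = [i for i in keep.index if i in mat.columns]
        externals[b] = (
            mat.loc[:, cols].T,
            (sim.metadata.loc[cols, sub["label_col"]] == sub["positive"]).astype(int).to_numpy(),
        )

    agg_table = pd.read_csv(p["aggregate"] / "aggregated.tsv", sep="\t", index_col="gene_id")
    panels: dict[str, RankedPanel] = {
        "aggregated": RankedPanel(
            genes=[str(g) for g in agg_table.index],
            scores=agg_table["rho"].to_numpy(float),
            method="aggregated", fold=None, task=cfg.task,
        )
    }
    for m in METHODS:
        panels[m] = io.read_panel(p["aggregate"] / f"consensus_{m}.tsv")

    reports = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pname, panel in panels.items():
            ladder = sorted({min(n, len(panel)) for n in cfg.top_n_ladder if n >= 1})
            for n in ladder:
                use = panel.top(n)
                for fam in cfg.eval_models:
                    per_ext = {}
                    for b, (X_ext, y_ext) in externals.items():
                        rep = evaluate_panel(
                            X_train, y_train, X_ext, y_ext, use, fam,
                            weights=cfg.weights,
                            bootstrap=BootstrapConfig(
                                cfg.bootstrap.n_resamples, cfg.bootstrap.ci_level,
                                seeds["bootstrap"],
                            ),
                            seed=seeds["evaluate"], inner_k=cfg.eval_inner_k,
                            n_iter=cfg.eval_n_iter, dataset=b, task=cfg.task,
                        )
                        d = rep.to_dict()
                        d["panel"] = pname
                        per_ext[b] = d
                        reports.append(d)
                    avg = {"panel": pname, "panel_method": panel.method, "n_genes": n,
                           "model": fam, "task": cfg.task, "dataset": "external_average",
                           "metrics": {}}
                    for metric in per_ext[next(iter(per_ext))]["metrics"]:
                        pts = [d["metrics"][metric]["point"] for d in per_ext.values()]
                        pts = [v for v in pts if v is not None]
                        avg["metrics"][metric] = {
                            "point": float(np.mean(pts)) if pts else None,
                            "lo": None, "hi": None, "note": "mean over external cohorts",
                        }
                    reports.append(avg)
    path = p["metrics"]
    path.write_text(json.dumps(reports, indent=1))
    return [path]


# ---------------------------------------------------------------------------

STAGE_ORDER = (
    ("simulate", stage_simulate),
    ("normalize", stage_normalize),
    ("folds", stage_folds),
    ("dge", stage_dge),
    ("select", stage_select),
    ("aggregate", stage_aggregate),
    ("internal_validation", stage_internal_validation),
    ("evaluate", stage_evaluate),
)


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(repr(cfg).encode()).hexdigest()[:16]


def run_task(cfg: RunConfig) -> RunManifest:
    """Execute every stage in order and write the manifest."""
    problems = validate_config(cfg)
    if problems:
        raise ConfigurationError("invalid run configuration:\n- " + "\n- ".join(problems))
    Path(cfg.workdir).mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config_hash(cfg), seeds=stage_seeds(cfg.seed), version=__version__
    )
    for name, fn in STAGE_ORDER:
        if name == "internal_validation" and not cfg.run_internal_validation:
            continue
        try:
            files = fn(cfg)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest.stages[name] = [str(Path(f).relative_to(cfg.workdir)) for f in files]
    p = _paths(cfg)["manifest"]
    p.write_text(
        json.dumps(
            {
                "config_hash": manifest.config_hash,
                "seeds": manifest.seeds,
                "version": manifest.version,
                "stages": manifest.stages,
            },
            indent=1,
        )
    )
    return manifest
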