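"""Synthetic multi-batch bulk RNA-seq cohorts with planted sex-specific tumor signal.

The generator emulates the structure of a multi-cohort bladder-cancer design:
several training batches plus external test batches, strong male/female class
imbalance, negative-binomial gene counts with gene-specific multiplicative
batch effects and log-normal library-size variation, and five planted gene
classes with known log2 fold changes:

* ``male_specific``     -- tumor vs non-tumor effect in males only
* ``female_specific``   -- tumor vs non-tumor effect in females only
* ``shared_same``       -- one tumor effect applied identically in both sexes
* ``shared_opposite``   -- tumor effect with opposite sign per sex
* ``sex_dimorphic``     -- male-tumor vs female-tumor difference, realised as a
  symmetric +/- lfc/2 split so the recorded log2FC is the male-vs-female
  contrast within tumors

Everything downstream of the generator therefore has ground truth, and the
whole pipeline is testable without downloading any cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

SEXES = ("male", "female")
STATUSES = ("non-tumor", "tumor")
GENE_CLASSES = (
    "male_specific",
    "female_specific",
    "shared_same",
    "shared_opposite",
    "sex_dimorphic",
    "null",
)


class ConfigurationError(ValueError):
    """Raised for inconsistent simulation configurations."""


def gene_ids(n_genes: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n_genes)]


@dataclass(frozen=True)
class PlantedTruth:
    """Planted gene classes, each a mapping gene id -> log2 fold change.

    ``shared_opposite`` entries record the male-side sign (the female tumor
    effect is the negation).  ``sex_dimorphic`` entries record the full
    male-tumor vs female-tumor log2FC; half the effect is applied to each sex
    with opposite signs.
    """

    male_specific: Mapping[str, float] = field(default_factory=dict)
    female_specific: Mapping[str, float] = field(default_factory=dict)
    shared_same: Mapping[str, float] = field(default_factory=dict)
    shared_opposite: Mapping[str, float] = field(default_factory=dict)
    sex_dimorphic: Mapping[str, float] = field(default_factory=dict)

    def classes(self) -> dict[str, dict[str, float]]:
        return {
            "male_specific": dict(self.male_specific),
            "female_specific": dict(self.female_specific),
            "shared_same": dict(self.shared_same),
            "shared_opposite": dict(self.shared_opposite),
            "sex_dimorphic": dict(self.sex_dimorphic),
        }

    def class_of(self) -> dict[str, str]:
        """Gene id -> class name for every planted gene; raises on overlap."""
        out: dict[str, str] = {}
        for name, genes in self.classes().items():
            for g in genes:
                if g in out:
                    raise ConfigurationError(
                        f"gene {g!r} planted in both {out[g]!r} and {name!r};"
                        " planted classes must be disjoint"
                    )
                out[g] = name
        return out

    def all_planted(self) -> set[str]:
        return set(self.class_of())

    def validate(self) -> None:
        self.class_of()

    @staticmethod
    def default(
        n_male: int = 40,
        n_female: int = 40,
        n_shared_same: int = 30,
        n_shared_opposite: int = 20,
        n_dimorphic: int = 20,
        lfc: float = 2.0,
        dimorphic_lfc: float = 1.6,
    ) -> "PlantedTruth":
        """Planted classes on the first genes of the universe, alternating
        up/down regulation.  The dimorphic magnitude defaults below 2x the DEG
        threshold so its per-sex half-effect (0.8) stays sub-threshold and the
        sex-specific pools remain clean."""
        ids = iter(gene_ids(n_male + n_female + n_shared_same + n_shared_opposite + n_dimorphic))

        def take(n: int, size: float) -> dict[str, float]:
            return {next(ids): (size if i % 2 == 0 else -size) for i in range(n)}

        return PlantedTruth(
            male_specific=take(n_male, lfc),
            female_specific=take(n_female, lfc),
            shared_same=take(n_shared_same, lfc),
            shared_opposite=take(n_shared_opposite, lfc),
            sex_dimorphic=take(n_dimorphic, dimorphic_lfc),
        )


@dataclass(frozen=True)
class BatchSpec:
    """One sequencing batch: sample counts per (sex, status) cell."""

    batch_id: str
    cells: Mapping[tuple[str, str], int]
    role: str = "training"  # "training" or "external"

    def n_samples(self) -> int:
        return sum(self.cells.values())


@dataclass(frozen=True)
class SimConfig:
    """Full description of a simulated multi-batch cohort.

    Gene baseline means are log-normal (natural-log location/spread); batch
    effects are gene-specific multiplicative log-normal factors shared by all
    samples of a batch; library sizes vary log-normally per sample.  The seed
    fully determines the output.
    """

    n_genes: int = 2000
    batch_specs: tuple[BatchSpec, ...] = ()
    baseline_log_mean_mu: float = 3.5
    baseline_log_mean_sigma: float = 1.5
    dispersion: float = 0.1
    batch_effect_sigma: float = 0.4
    library_size_sigma: float = 0.3
    planted: PlantedTruth = field(default_factory=PlantedTruth)
    length_range: tuple[int, int] = (200, 10_000)
    gene_dropout: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0


def default_config(seed: int = 0, n_genes: int = 2000) -> SimConfig:
    """Desk-scale analogue of the study's cohorts.

    Three training batches (one tumor-heavy, one non-tumor-only, one small
    mixed) and two external batches, preserving the strong male/female
    imbalance of the real class-distribution table at roughly one fifth to one
    half of the original sample counts.
    """
    specs = (
        BatchSpec(
            "cohortA",
            {
                ("male", "tumor"): 60,
                ("female", "tumor"): 20,
                ("male", "non-tumor"): 4,
                ("female", "non-tumor"): 4,
            },
        ),
        BatchSpec(
            "cohortB",
            {("male", "non-tumor"): 24, ("female", "non-tumor"): 14},
        ),
        BatchSpec(
            "cohortC",
            {
                ("male", "tumor"): 14,
                ("female", "tumor"): 4,
                ("male", "non-tumor"): 12,
                ("female", "non-tumor"): 4,
            },
        ),
        BatchSpec(
            "externalD",
            {
                ("male", "tumor"): 14,
                ("female", "tumor"): 4,
                ("male", "non-tumor"): 8,
                ("female", "non-tumor"): 4,
            },
            role="external",
        ),
        BatchSpec(
            "externalE",
            {
                ("male", "tumor"): 22,
                ("female", "tumor"): 6,
                ("male", "non-tumor"): 6,
                ("female", "non-tumor"): 2,
            },
            role="external",
        ),
    )
    return SimConfig(
        n_genes=n_genes,
        batch_specs=specs,
        planted=PlantedTruth.default(),
        seed=seed,
    )


@dataclass
class SimResult:
    """Counts per batch plus sample metadata, gene lengths, and the truth."""

    counts: dict[str, pd.DataFrame]  # batch id -> genes x samples
    metadata: pd.DataFrame  # index sample_id; columns batch, sex, status, role
    gene_lengths: pd.Series  # gene id -> length in bases
    truth: PlantedTruth
    config: SimConfig | None = None

    def truth_table(self) -> pd.DataFrame:
        """One row per gene of the universe: class label and planted log2FC."""
        class_of = self.truth.class_of()
        lfc_of: dict[str, float] = {}
        for genes in self.truth.classes().values():
            lfc_of.update(genes)
        genes = list(self.gene_lengths.index)
        return pd.DataFrame(
            {
                "gene_id": genes,
                "class": [class_of.get(g, "null") for g in genes],
                "log2fc": [lfc_of.get(g, 0.0) for g in genes],
            }
        ).set_index("gene_id")

    def training_batches(self) -> list[str]:
        return sorted(self.metadata.loc[self.metadata["role"] == "training", "batch"].unique())

    def external_batches(self) -> list[str]:
        return sorted(self.metadata.loc[self.metadata["role"] == "external", "batch"].unique())


def _validate(config: SimConfig) -> None:
    truth = config.planted
    truth.validate()
    universe = set(gene_ids(config.n_genes))
    stray = truth.all_planted() - universe
    if stray:
        raise ConfigurationError(
            f"planted genes outside the {config.n_genes}-gene universe: {sorted(stray)[:5]}"
        )
    if not config.batch_specs:
        raise ConfigurationError("at least one batch must be specified")
    for spec in config.batch_specs:
        for cell, n in spec.cells.items():
            if n < 0:
                raise ConfigurationError(f"negative cell size {n} in batch {spec.batch_id}")
            if cell[0] not in SEXES or cell[1] not in STATUSES:
                raise ConfigurationError(f"unknown cell {cell} in batch {spec.batch_id}")
    totals: dict[tuple[str, str], int] = {}
    for spec in config.batch_specs:
        if spec.role != "training":
            continue
        for cell, n in spec.cells.items():
            totals[cell] = totals.get(cell, 0) + n
    required: list[tuple[str, str]] = []
    if truth.male_specific or truth.shared_same or truth.shared_opposite:
        required += [("male", "tumor"), ("male", "non-tumor")]
    if truth.female_specific or truth.shared_same or truth.shared_opposite:
        required += [("female", "tumor"), ("female", "non-tumor")]
    if truth.sex_dimorphic:
        required += [("male", "tumor"), ("female", "tumor")]
    for cell in required:
        if totals.get(cell, 0) == 0:
            raise ConfigurationError(
                f"planted classes require training samples in stratum {cell}, but it is empty"
            )


def _condition_log2_effects(config: SimConfig) -> dict[tuple[str, str], np.ndarray]:
    """Per-(sex, status) log2 multiplier vector over the gene universe."""
    index = {g: i for i, g in enumerate(gene_ids(config.n_genes))}
    eff = {
        (sex, status): np.zeros(config.n_genes) for sex in SEXES for status in STATUSES
    }
    t = config.planted
    for g, l in t.male_specific.items():
        eff[("male", "tumor")][index[g]] += l
    for g, l in t.female_specific.items():
        eff[("female", "tumor")][index[g]] += l
    for g, l in t.shared_same.items():
        eff[("male", "tumor")][index[g]] += l
        eff[("female", "tumor")][index[g]] += l
    for g, l in t.shared_opposite.items():
        eff[("male", "tumor")][index[g]] += l
        eff[("female", "tumor")][index[g]] -= l
    for g, l in t.sex_dimorphic.items():
        eff[("male", "tumor")][index[g]] += l / 2.0
        eff[("female", "tumor")][index[g]] -= l / 2.0
    return eff


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, alpha) with var = mean + alpha * mean^2, via gamma-Poisson."""
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def simulate_cohorts(config: SimConfig) -> SimResult:
    """Draw every batch of the configured cohort; deterministic under the seed."""
    _validate(config)
    rng = np.random.default_rng(config.seed)
    genes = pd.Index(gene_ids(config.n_genes), name="gene_id")

    log_base = rng.normal(config.baseline_log_mean_mu, config.baseline_log_mean_sigma, config.n_genes)
    lo, hi = config.length_range
    lengths = pd.Series(rng.integers(lo, hi + 1, config.n_genes), index=genes, name="length_bp")
    cond_eff = _condition_log2_effects(config)

    counts: dict[str, pd.DataFrame] = {}
    meta_rows = []
    for spec in config.batch_specs:
        batch_eff = rng.normal(0.0, 1.0, config.n_genes) * config.batch_effect_sigma
        base = np.exp(log_base + batch_eff)
        cols: list[np.ndarray] = []
        names: list[str] = []
        for (sex, status) in sorted(spec.cells):
            n = spec.cells[(sex, status)]
            if n == 0:
                continue
            lib = np.exp(rng.normal(0.0, config.library_size_sigma, n))
            mean = base[:, None] * lib[None, :] * 2.0 ** cond_eff[(sex, status)][:, None]
            cols.append(_nb_draw(rng, mean, config.dispersion))
            tag = f"{sex[0]}{'t' if status == 'tumor' else 'n'}"
            start = len(names)
            for i in range(n):
                name = f"{spec.batch_id}_{tag}{i:03d}"
                names.append(name)
                meta_rows.append((name, spec.batch_id, sex, status, spec.role))
            assert len(names) == start + n
        mat = pd.DataFrame(
            np.hstack(cols) if cols else np.zeros((config.n_genes, 0), dtype=int),
            index=genes,
            columns=names,
        )
        frac = config.gene_dropout.get(spec.batch_id, 0.0)
        if frac > 0:
            keep = rng.random(config.n_genes) >= frac
            mat = mat.loc[np.asarray(genes)[keep]]
        counts[spec.batch_id] = mat

    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "batch", "sex", "status", "role"]
    ).set_index("sample_id")
    return SimResult(counts=counts, metadata=metadata, gene_lengths=lengths,
                     truth=config.planted, config=config)
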