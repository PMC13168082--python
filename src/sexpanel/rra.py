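"""Robust rank aggregation via Beta order statistics.

Each gene's positions across n ranked lists are normalised by the universe
size N (rank/N); a gene absent from a list contributes the worst-case
normalised rank 1, the standard treatment of partial top-K lists.  With the
sorted normalised ranks r_(1) <= ... <= r_(n), the rho score is

    rho = min_k  P(Beta(k, n - k + 1) <= r_(k)),

the smallest tail probability that the k-th best rank is this good under the
null of n independent uniform rankings.  The multiplicity-corrected score is
the Bonferroni bound min(1, N * rho).  Lower is better; a gene ranked first
in every list attains the minimum.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .select import RankedPanel


def _gene_lists(lists: Sequence) -> list[list[str]]:
    out = []
    for lst in lists:
        genes = list(lst.genes) if isinstance(lst, RankedPanel) else [str(g) for g in lst]
        if len(genes) != len(set(genes)):
            raise ValueError("a ranked list contains duplicate genes")
        out.append(genes)
    return out


@dataclass
class AggregatedPanel:
    """RRA consensus: genes sorted by rho ascending, with corrected scores."""

    table: pd.DataFrame  # index gene_id; columns rho, corrected
    n_lists: int
    universe_size: int

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.table.index]

    def top(self, n: int) -> list[str]:
        return self.genes[: max(int(n), 0)]

    def to_ranked_panel(self, k: int | None = None, method: str = "rra",
                        task: str = "") -> RankedPanel:
        k = len(self.table) if k is None else k
        sub = self.table.iloc[:k]
        return RankedPanel(
            genes=[str(g) for g in sub.index],
            scores=sub["rho"].to_numpy(float),
            method=method,
            fold=None,
            task=task,
        )


def rho_score(normalized_ranks: Iterable[float], n_lists: int | None = None) -> float:
    """rho of one gene given its observed normalised ranks (unobserved = 1)."""
    r = np.sort(np.asarray(list(normalized_ranks), float))
    n = len(r) if n_lists is None else n_lists
    if n < len(r):
        raise ValueError("more observed ranks than lists")
    r = np.concatenate([r, np.ones(n - len(r))])
    k = np.arange(1, n + 1)
    return float(np.min(beta_dist.cdf(r, k, n - k + 1)))


def rra_scores(lists: Sequence, universe: Iterable[str]) -> AggregatedPanel:
    """Score every universe gene across the given ranked (possibly partial) lists."""
    gene_lists = _gene_lists(lists)
    if not gene_lists:
        raise ValueError("need at least one ranked list")
    universe = [str(g) for g in universe]
    uset = set(universe)
    if len(universe) != len(uset):
        raise ValueError("universe contains duplicate genes")
    for genes in gene_lists:
        stray = set(genes) - uset
        if stray:
            raise ValueError(f"listed genes outside the universe: {sorted(stray)[:5]}")

    N = len(universe)
    n = len(gene_lists)
    index = {g: i for i, g in enumerate(universe)}
    r = np.ones((N, n))
    for j, genes in enumerate(gene_lists):
        for pos, g in enumerate(genes):
            r[index[g], j] = (pos + 1) / N
    r.sort(axis=1)
    k = np.arange(1, n + 1)
    cdf = beta_dist.cdf(r, k[None, :], (n - k + 1)[None, :])
    rho = cdf.min(axis=1)
    corrected = np.minimum(1.0, N * rho)
    order = np.lexsort((np.asarray(universe, dtype=object), rho))
    table = pd.DataFrame(
        {"rho": rho[order], "corrected": corrected[order]},
        index=pd.Index(np.asarray(universe, dtype=object)[order], name="gene_id"),
    )
    return AggregatedPanel(table=table, n_lists=n, universe_size=N)


def consensus_per_method(
    panels: Sequence[RankedPanel],
    k: int | None = None,
    universe: Iterable[str] | None = None,
) -> RankedPanel:
    """Aggregate one selector's per-fold rankings into a cross-fold consensus."""
    methods = {p.method for p in panels}
    tasks = {p.task for p in panels}
    if len(methods) != 1 or len(tasks) != 1:
        raise ValueError(f"panels mix methods/tasks: {sorted(methods)}, {sorted(tasks)}")
    if universe is None:
        universe = sorted(set().union(*(p.genes for p in panels)))
    agg = rra_scores(panels, universe)
    k = max(len(p) for p in panels) if k is None else k
    return agg.to_ranked_panel(k=k, method=next(iter(methods)), task=next(iter(tasks)))


def panel_overlap(panels: Sequence, names: Sequence[str] | None = None) -> dict[frozenset, int]:
    """Exact Venn-region membership counts for 2-4 panels.

    Keys are frozensets of panel names; the value counts genes belonging to
    exactly that subset of panels.  Region counts sum to the union size.
    """
    gene_lists = _gene_lists(panels)
    if names is None:
        names = []
        for i, p in enumerate(panels):
            label = p.method if isinstance(p, RankedPanel) and p.method else f"panel{i}"
            names.append(label)
    if len(set(names)) != len(names):
        names = [f"{nm}_{i}" for i, nm in enumerate(names)]
    if not 2 <= len(gene_lists) <= 4:
        raise ValueError("Venn overlap supports 2-4 panels")
    membership = Counter()
    sets = dict(zip(names, map(set, gene_lists)))
    for g in set().union(*sets.values()):
        membership[frozenset(nm for nm, s in sets.items() if g in s)] += 1
    regions: dict[frozenset, int] = {}
    for size in range(1, len(names) + 1):
        for combo in combinations(names, size):
            regions[frozenset(combo)] = membership.get(frozenset(combo), 0)
    return regions
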