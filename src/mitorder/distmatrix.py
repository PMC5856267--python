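"""Pairwise exact distance matrices over a taxon dataset.

Each unordered pair of gene orders is first reduced to its common genes
(removals are reported as gain/loss annotations, never as path steps) and
the exact rearrangement distance of the reduced pair is computed.  Cells
whose distance exceeds the search budget are marked as lower bounds and are
excluded from tree building.

Random gene orders of mitochondrial size are nearly always 6 or more steps
apart, so large distances carry little signal; the fast-evolver rule flags
taxa farther than a threshold from almost all others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._kernel import kernel_distance
from .genome import Genome, GenomeError, encode, restrict_to_common
from .pathsearch import SearchBudgetExceeded, distance as reference_distance

__all__ = ["DistanceMatrix", "build_matrix", "flag_fast_evolving"]

logger = logging.getLogger("mitorder")


@dataclass
class DistanceMatrix:
    """Symmetric exact distances between the distinct genomes of a dataset.

    ``values[i, j]`` holds the exact distance when ``exact[i, j]`` is true;
    otherwise the true distance is known to exceed ``k_max`` and
    ``values[i, j] == k_max + 1`` is a lower bound.
    """

    taxa: tuple[str, ...]
    values: np.ndarray
    exact: np.ndarray
    k_max: int
    removals: dict[tuple[str, str], tuple[tuple[str, ...], tuple[str, ...]]] = field(
        default_factory=dict
    )
    merged: dict[str, str] = field(default_factory=dict)

    def index(self, taxon: str) -> int:
        return self.taxa.index(taxon)

    def get(self, a: str, b: str) -> int:
        return int(self.values[self.index(a), self.index(b)])

    def is_exact(self, a: str, b: str) -> bool:
        return bool(self.exact[self.index(a), self.index(b)])

    @property
    def all_exact(self) -> bool:
        return bool(self.exact.all())

    def removed_genes_by_taxon(self) -> dict[str, frozenset[str]]:
        """Union of genes removed per taxon across its pairwise reductions."""
        out: dict[str, set[str]] = {t: set() for t in self.taxa}
        for (a, b), (rem_a, rem_b) in self.removals.items():
            out[a].update(rem_a)
            out[b].update(rem_b)
        return {t: frozenset(s) for t, s in out.items()}


def _pair_distance(a: Genome, b: Genome, k_max: int, engine: str) -> int:
    """Exact distance of a common-gene pair, or -1 beyond the budget."""
    order = sorted(a.gene_set)
    if engine == "kernel":
        return kernel_distance(encode(a, order), encode(b, order), k_max)
    try:
        return reference_distance(a, b, k_max=k_max)
    except SearchBudgetExceeded:
        return -1


def build_matrix(
    dataset: list[tuple[str, Genome]],
    k_max: int = 8,
    engine: str = "kernel",
) -> DistanceMatrix:
    """Distance matrix over a dataset of named circular genomes.

    Taxa with genomes equal to an earlier taxon's are merged into that taxon
    (the mapping is recorded and logged): the analysis is defined over
    distinct gene orders.  Every pair must share at least 3 genes.

    ``engine`` selects the accelerated kernel (default) or the reference
    search; both produce identical distances.
    """
    if len(dataset) < 2:
        raise GenomeError("a distance matrix needs at least 2 taxa")
    if engine not in ("kernel", "reference"):
        raise ValueError(f"unknown engine {engine!r}")
    names = [t for t, _ in dataset]
    if len(set(names)) != len(names):
        raise GenomeError("duplicate taxon names in dataset")

    kept: list[tuple[str, Genome]] = []
    merged: dict[str, str] = {}
    for name, g in dataset:
        if not g.circular:
            raise GenomeError("distance matrices are defined for circular genomes")
        rep = next((kn for kn, kg in kept if kg.gene_set == g.gene_set and kg == g), None)
        if rep is not None:
            merged[name] = rep
            logger.warning("taxon %r has the same gene order as %r; merged", name, rep)
        else:
            kept.append((name, g))

    taxa = tuple(t for t, _ in kept)
    m = len(taxa)
    values = np.zeros((m, m), dtype=int)
    exact = np.ones((m, m), dtype=bool)
    removals: dict[tuple[str, str], tuple[tuple[str, ...], tuple[str, ...]]] = {}
    for i in range(m):
        for j in range(i + 1, m):
            a, b = kept[i][1], kept[j][1]
            a2, b2, rem_a, rem_b = restrict_to_common(a, b)
            if rem_a or rem_b:
                removals[(taxa[i], taxa[j])] = (rem_a, rem_b)
            d = 0 if a2 == b2 else _pair_distance(a2, b2, k_max, engine)
            if d < 0:
                values[i, j] = values[j, i] = k_max + 1
                exact[i, j] = exact[j, i] = False
            else:
                values[i, j] = values[j, i] = d
    return DistanceMatrix(taxa, values, exact, k_max, removals, merged)


def flag_fast_evolving(
    matrix: DistanceMatrix,
    dist_threshold: int = 5,
    frac_threshold: float = 0.95,
) -> list[str]:
    """Taxa at distance > ``dist_threshold`` from strictly more than
    ``frac_threshold`` of the other taxa.

    Lower-bound cells count as exceeding the threshold when the bound does.
    The defaults implement the removal rule for shuffled mitochondrial
    genomes (distance above 5 from more than 95% of the dataset).
    """
    m = len(matrix.taxa)
    if m < 3:
        raise GenomeError("fast-evolver flagging needs at least 3 taxa")
    flagged = []
    for i, taxon in enumerate(matrix.taxa):
        over = sum(
            1
            for j in range(m)
            if j != i and matrix.values[i, j] > dist_threshold
        )
        if over > frac_threshold * (m - 1):
            flagged.append(taxon)
    return flagged
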