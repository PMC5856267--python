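"""Shared fixtures and independent oracles.

The oracles deliberately avoid the code paths they check: neighborhoods come
from a parameter sweep over the public ``apply`` operation, and small-n
distances from breadth-first search over those neighborhoods.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations, product

import numpy as np
import pytest

from mitorder.genome import Genome, canonical_array, decode, parse_genome
from mitorder.rearrangements import Rearrangement, apply


def brute_neighbors(g: Genome) -> set[Genome]:
    """Every genome reachable by one rearrangement, via exhaustive sweep of
    operation parameters through the public ``apply``."""
    out: set[Genome] = set()
    n = g.n
    starts = range(n) if g.circular else range(n)
    for start in starts:
        for length in range(1, n):
            if not g.circular and start + length > n:
                continue
            try:
                out.add(apply(g, Rearrangement("inversion", start, length)))
            except Exception:
                pass
            inserts = range(n) if g.circular else range(n + 1)
            for ins in inserts:
                for kind in ("transposition", "reverse_transposition"):
                    try:
                        out.add(apply(g, Rearrangement(kind, start, length, ins)))
                    except Exception:
                        pass
    out.discard(g)
    return out


@lru_cache(maxsize=None)
def class_representatives(n: int) -> tuple[Genome, ...]:
    """One representative per circular-genome equivalence class on n genes."""
    labels = [str(i) for i in range(1, n + 1)]
    seen: dict[bytes, Genome] = {}
    for perm in permutations(range(1, n + 1)):
        for signs in product((1, -1), repeat=n):
            arr = np.array([p * s for p, s in zip(perm, signs)], dtype=np.int64)
            key = canonical_array(arr, True).tobytes()
            if key not in seen:
                seen[key] = decode(arr, labels)
    return tuple(seen[k] for k in sorted(seen))


@lru_cache(maxsize=None)
def bfs_distance_oracle(n: int) -> dict[Genome, int]:
    """Exact distance from the identity genome to every class, by BFS over
    the brute-force neighborhoods."""
    ident = decode(np.arange(1, n + 1, dtype=np.int64), [str(i) for i in range(1, n + 1)])
    dist = {ident: 0}
    frontier = [ident]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for g in frontier:
            for h in brute_neighbors(g):
                if h not in dist:
                    dist[h] = d
                    nxt.append(h)
        frontier = nxt
    return dist


def make_matrix(taxa: list[str], dvals: dict[tuple[str, str], int], k_max: int = 8):
    """Hand-built exact distance matrix for tree tests."""
    from mitorder.distmatrix import DistanceMatrix

    m = len(taxa)
    values = np.zeros((m, m), dtype=int)
    for (a, b), d in dvals.items():
        i, j = taxa.index(a), taxa.index(b)
        values[i, j] = values[j, i] = d
    return DistanceMatrix(tuple(taxa), values, np.ones((m, m), dtype=bool), k_max)


@pytest.fixture
def toy_pair():
    """The worked circular example: distance 2, eight minimal paths."""
    return parse_genome("1 -2 -3 -5 -4"), parse_genome("1 2 3 4 5")


@pytest.fixture
def toy_pair_linear():
    return (
        parse_genome("1 -2 -3 -5 -4", circular=False),
        parse_genome("1 2 3 4 5", circular=False),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


# genome triple whose pairwise 2-path midpoint sets are pairwise disjoint
# (found by brute-force screening; forces a P6 failure on the star tree)
DISJOINT_MIDPOINT_TRIPLE = (
    "-3 -1 4 -5 2",
    "-2 4 5 -3 1",
    "5 4 -1 2 3",
)
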