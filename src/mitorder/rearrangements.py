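"""The three elementary rearrangements and derived pairwise quantities.

Modelled operations: inversion (a block is replaced in place by its
reversal-with-negation), transposition (a block moves between two other
successive genes) and reverse transposition (the block moves and flips).
Gain and loss are handled upstream as gene-content reduction, never as
path steps.

Because the genomes are circular, distinct parameter choices can produce
the same resulting genome (three transpositions, or two inversions, always
collapse pairwise); neighbor enumeration therefore deduplicates by the
resulting genome, not by operation parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .genome import Genome, GenomeError, canonical_array, decode, encode

__all__ = [
    "Rearrangement",
    "apply",
    "enumerate_neighbors",
    "nb_breakpoints",
    "shared_blocks",
]

KINDS = ("inversion", "transposition", "reverse_transposition")


@dataclass(frozen=True)
class Rearrangement:
    """One elementary rearrangement, parameterised on a genome's own token order.

    ``start``/``length`` select the moved block (circular indices allowed for
    circular genomes); ``insert`` is the token index before which the block is
    re-inserted (unused for inversions).
    """

    kind: str
    start: int
    length: int
    insert: int | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown rearrangement kind: {self.kind!r}")


def _check_block(g: Genome, r: Rearrangement) -> None:
    n = g.n
    if not (1 <= r.length <= n - 1):
        raise GenomeError(f"block length must be in [1, {n - 1}], got {r.length}")
    if g.circular:
        if not (0 <= r.start < n):
            raise GenomeError(f"block start out of range: {r.start}")
    else:
        if not (0 <= r.start and r.start + r.length <= n):
            raise GenomeError("block exceeds linear genome bounds")


def apply(g: Genome, r: Rearrangement) -> Genome:
    """Apply one rearrangement; no-op parameter choices are rejected."""
    _check_block(g, r)
    toks = list(zip(g.labels, g.signs))
    n = g.n

    def inv(block):
        return [(lab, -s) for lab, s in reversed(block)]

    if r.kind == "inversion":
        if r.insert is not None:
            raise GenomeError("inversion takes no insertion point")
        if g.circular:
            block = [toks[(r.start + i) % n] for i in range(r.length)]
            out = list(toks)
            for i, tok in enumerate(inv(block)):
                out[(r.start + i) % n] = tok
        else:
            out = (
                toks[: r.start]
                + inv(toks[r.start : r.start + r.length])
                + toks[r.start + r.length :]
            )
        return Genome(out, circular=g.circular)

    if r.insert is None:
        raise GenomeError(f"{r.kind} requires an insertion point")
    flip = r.kind == "reverse_transposition"

    if g.circular:
        rot = toks[r.start:] + toks[: r.start]
        i_rot = (r.insert - r.start) % n
        # i_rot == 0 or == length re-insert the block where it came from (a
        # no-op for a transposition, a plain inversion for a reverse one);
        # 0 < i_rot < length falls inside the block.  All are invalid.
        if not (r.length < i_rot <= n - 1):
            raise GenomeError("insertion point inside the block or a no-op")
        block, rest = rot[: r.length], rot[r.length :]
        j = i_rot - r.length
        out = rest[:j] + (inv(block) if flip else block) + rest[j:]
        return Genome(out, circular=g.circular)

    # linear
    i = r.insert
    if not (0 <= i <= n):
        raise GenomeError(f"insertion point out of range: {i}")
    if r.start <= i <= r.start + r.length:
        raise GenomeError("insertion point inside the block or a no-op")
    block = toks[r.start : r.start + r.length]
    rest = toks[: r.start] + toks[r.start + r.length :]
    j = i if i < r.start else i - r.length
    out = rest[:j] + (inv(block) if flip else block) + rest[j:]
    return Genome(out, circular=g.circular)


# -- fast array-level neighbor generation ---------------------------------


def _neighbor_arrays(arr: np.ndarray, circular: bool):
    """Yield ``(child_array, severed_adjacency_indices)`` for every structural
    one-rearrangement neighbor.

    For circular genomes each inversion corresponds to one cut pair and each
    (reverse) transposition to one cut triple, so intra-kind duplicates are
    avoided by construction; remaining collisions are removed by the caller.
    Adjacency index ``i`` denotes the join between positions ``i`` and
    ``i+1`` (mod n for circular genomes).
    """
    n = len(arr)
    if circular:
        for p, q in combinations(range(n), 2):
            child = arr.copy()
            child[p:q] = -arr[p:q][::-1]
            yield child, ((p - 1) % n, (q - 1) % n)
        for p, q, r in combinations(range(n), 3):
            # cut points p, q, r split the circle into blocks B=[p,q),
            # C=[q,r) and the wrapping block D+A; one transposition class and
            # three reverse transpositions (either of the three blocks moves
            # inverted into the opposite gap) exist per triple
            cuts = ((p - 1) % n, (q - 1) % n, (r - 1) % n)
            a, b, c, d = arr[:p], arr[p:q], arr[q:r], arr[r:]
            yield np.concatenate([a, c, b, d]), cuts
            yield np.concatenate([a, -c[::-1], b, d]), cuts
            yield np.concatenate([a, c, -b[::-1], d]), cuts
            yield np.concatenate([b, -a[::-1], -d[::-1], c]), cuts
    else:
        for p, q in combinations(range(n + 1), 2):
            if p == 0 and q == n:
                continue  # a whole genome is not a block
            child = arr.copy()
            child[p:q] = -arr[p:q][::-1]
            yield child, tuple(i - 1 for i in (p, q) if 0 < i < n)
        for p in range(n):
            for q in range(p + 1, n + 1):
                if q - p == n:
                    continue
                block = arr[p:q]
                rest = np.concatenate([arr[:p], arr[q:]])
                for i in list(range(0, p)) + list(range(q + 1, n + 1)):
                    j = i if i < p else i - (q - p)
                    cuts = tuple(
                        k - 1 for k in (p, q, i) if 0 < k < n
                    )
                    yield np.concatenate([rest[:j], block, rest[j:]]), cuts
                    yield np.concatenate([rest[:j], -block[::-1], rest[j:]]), cuts


def enumerate_neighbors(g: Genome) -> list[Genome]:
    """All genomes one rearrangement away, deduplicated by genome identity.

    The genome itself is excluded; iteration order is deterministic
    (sorted canonical keys).
    """
    if g.n < 3:
        raise GenomeError("neighbor enumeration needs at least 3 genes")
    order = sorted(g.gene_set)
    arr = encode(g, order)
    self_key = canonical_array(arr, g.circular).tobytes()
    seen = {}
    for child, _cuts in _neighbor_arrays(arr, g.circular):
        key = canonical_array(child, g.circular).tobytes()
        if key != self_key and key not in seen:
            seen[key] = np.frombuffer(key, dtype=np.int64)
    return [
        decode(seen[k], order, g.circular) for k in sorted(seen)
    ]


# -- breakpoints and shared blocks ----------------------------------------


def _adjacencies(g: Genome) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    toks = list(zip(g.labels, g.signs))
    pairs = list(zip(toks, toks[1:]))
    if g.circular:
        pairs.append((toks[-1], toks[0]))
    return pairs


def _adjacency_set(g: Genome) -> set:
    """Adjacency set closed under reversal-with-negation: if y follows x,
    then -x follows -y."""
    s = set()
    for (la, sa), (lb, sb) in _adjacencies(g):
        s.add(((la, sa), (lb, sb)))
        s.add(((lb, -sb), (la, -sa)))
    return s


def nb_breakpoints(a: Genome, b: Genome) -> int:
    """Number of successive gene pairs of ``a`` that are not successive in ``b``.

    Symmetric in its arguments for genomes over the same gene set.
    """
    if a.gene_set != b.gene_set:
        raise GenomeError("breakpoints are defined for identical gene sets only")
    if a.circular != b.circular:
        raise GenomeError("cannot mix topologies")
    bset = _adjacency_set(b)
    return sum(1 for adj in _adjacencies(a) if adj not in bset)


def shared_blocks(a: Genome, b: Genome) -> list[tuple[str, ...]]:
    """Maximal blocks (length >= 2) present in both genomes, reported in
    ``a``'s reading direction.

    A block counts as present when it or its inversion occurs; blocks of a
    single gene are always shared and are excluded.  Identical genomes are
    rejected (every block would be shared while a whole genome is not a
    block); callers treat that case upstream.
    """
    if a.gene_set != b.gene_set:
        raise GenomeError("shared blocks are defined for identical gene sets only")
    if a == b:
        raise GenomeError("shared blocks of identical genomes are undefined")
    toks = list(zip(a.labels, a.signs))
    n = a.n
    bset = _adjacency_set(b)
    adjs = _adjacencies(a)
    shared = [adj in bset for adj in adjs]
    m = len(adjs)
    blocks = []
    i = 0
    visited = [False] * m
    for i in range(m):
        if visited[i] or not shared[i]:
            continue
        # walk back to the start of this maximal run (circular genomes)
        s = i
        while a.circular and shared[(s - 1) % m] and (s - 1) % m != i:
            s = (s - 1) % m
        # walk forward
        length = 0
        j = s
        while shared[j % m] and length < m:
            visited[j % m] = True
            length += 1
            j += 1
            if not a.circular and j >= m:
                break
        block = [toks[(s + k) % n] for k in range(length + 1)]
        blocks.append(tuple(lab if sg > 0 else "-" + lab for lab, sg in block))
    return sorted(set(blocks))
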