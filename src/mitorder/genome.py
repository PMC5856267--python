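"""Signed circular (and linear) genome representation.

A genome is an ordered sequence of signed genes.  Two circular genomes are
equal when one can be turned into the other by rotation or by reading the
circle in the opposite direction with all signs flipped (reversal-with-
negation); a circular genome of ``n`` genes therefore has exactly ``2n``
representations, a linear genome exactly 2.

Gene identity is by label only: orientation is state, not identity, so the
gene content of ``[1 2 -3]`` and ``[1 -2 3]`` is the same.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Genome",
    "GenomeError",
    "parse_genome",
    "genomes_equal",
    "restrict_to_common",
    "encode",
    "decode",
]

_TOKEN_RE = re.compile(r"^-?[A-Za-z0-9_.+']+$")


class GenomeError(ValueError):
    """Raised for malformed or degenerate gene-order input."""


def _parse_token(tok: str) -> tuple[str, int]:
    if not _TOKEN_RE.match(tok):
        raise GenomeError(f"unparsable gene token: {tok!r}")
    if tok.startswith("-"):
        label = tok[1:]
        sign = -1
    else:
        label, sign = tok, 1
    if not label:
        raise GenomeError(f"unparsable gene token: {tok!r}")
    return label, sign


class Genome:
    """An immutable signed gene order, circular by default.

    Parameters
    ----------
    tokens:
        Iterable of ``(label, sign)`` pairs with ``sign`` in ``{+1, -1}``.
    circular:
        Topology flag; the analysis pipeline assumes circular genomes, the
        linear case is supported for path searches only.
    """

    __slots__ = ("labels", "signs", "circular", "_canon")

    def __init__(self, tokens: Iterable[tuple[str, int]], circular: bool = True):
        toks = list(tokens)
        if len(toks) < 2:
            raise GenomeError("a genome needs at least 2 genes")
        labels = tuple(t[0] for t in toks)
        signs = tuple(int(t[1]) for t in toks)
        if any(s not in (1, -1) for s in signs):
            raise GenomeError("signs must be +1 or -1")
        seen = set()
        for lab in labels:
            if lab in seen:
                raise GenomeError(f"duplicate gene label: {lab!r}")
            seen.add(lab)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "signs", signs)
        object.__setattr__(self, "circular", bool(circular))
        object.__setattr__(self, "_canon", None)

    def __setattr__(self, *a):  # immutability guard
        raise AttributeError("Genome is immutable")

    # -- basic views ------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.labels)

    def tokens(self) -> tuple[str, ...]:
        return tuple(
            (lab if s > 0 else "-" + lab) for lab, s in zip(self.labels, self.signs)
        )

    def __str__(self) -> str:
        return " ".join(self.tokens())

    def __repr__(self) -> str:
        topo = "circular" if self.circular else "linear"
        return f"Genome({' '.join(self.tokens())!r}, {topo})"

    # -- representations --------------------------------------------------

    def representations(self) -> list[tuple[str, ...]]:
        """All distinct token sequences representing this genome.

        ``2n`` sequences for a circular genome (n rotations of the sequence
        and n rotations of its reversal-with-negation), 2 for a linear one.
        """
        fwd = list(zip(self.labels, self.signs))
        rev = [(lab, -s) for lab, s in reversed(fwd)]
        if not self.circular:
            reps = [fwd, rev]
        else:
            reps = [fwd[i:] + fwd[:i] for i in range(self.n)]
            reps += [rev[i:] + rev[:i] for i in range(self.n)]
        return [
            tuple((lab if s > 0 else "-" + lab) for lab, s in r) for r in reps
        ]

    def canonical_key(self, label_order: Sequence[str] | None = None) -> tuple[str, ...]:
        """Deterministic representative token sequence.

        The lexicographically least representation under a total order on
        signed tokens: labels ordered by ``label_order`` (sorted label order
        when not given, e.g. outside a dataset context), ``+`` before ``-``.
        Equal genomes yield identical keys for the same order.
        """
        if label_order is None:
            if self._canon is not None:
                return self._canon
            order = sorted(self.gene_set)
        else:
            order = list(label_order)
            missing = self.gene_set.difference(order)
            if missing:
                raise GenomeError(f"label order missing genes: {sorted(missing)}")
        arr = encode(self, order)
        best = canonical_array(arr, self.circular)
        key = decode(best, order, self.circular).tokens()
        if label_order is None:
            object.__setattr__(self, "_canon", key)
        return key

    # -- equality ---------------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        if self.circular != other.circular or self.gene_set != other.gene_set:
            return False
        return self.canonical_key() == other.canonical_key()

    def __hash__(self) -> int:
        return hash((self.circular, self.canonical_key()))


def parse_genome(text: str, circular: bool = True) -> Genome:
    """Parse whitespace-separated signed tokens, e.g. ``"cox1 -nad6 cob"``."""
    toks = text.split()
    if not toks:
        raise GenomeError("empty genome input")
    return Genome([_parse_token(t) for t in toks], circular=circular)


def genomes_equal(a: Genome, b: Genome) -> bool:
    """True iff ``b`` occurs among the representations of ``a``.

    Genomes over different gene sets are unequal, not an error.
    """
    if a.circular != b.circular:
        raise GenomeError("cannot compare genomes of different topology")
    return a == b


def restrict_to_common(
    a: Genome, b: Genome
) -> tuple[Genome, Genome, tuple[str, ...], tuple[str, ...]]:
    """Reduce two genomes to their common genes (label-wise, sign-free).

    Returns the two reduced genomes (original relative order and orientation
    preserved) plus the removed labels per input, reported as gain/loss
    annotations.  At least 3 shared genes are required for the rearrangement
    model to be meaningful.
    """
    common = a.gene_set & b.gene_set
    if len(common) < 3:
        raise GenomeError(
            f"genomes share only {len(common)} genes; at least 3 are required"
        )

    def reduce(g: Genome) -> tuple[Genome, tuple[str, ...]]:
        kept = [(lab, s) for lab, s in zip(g.labels, g.signs) if lab in common]
        removed = tuple(lab for lab in g.labels if lab not in common)
        return Genome(kept, circular=g.circular), removed

    a2, rem_a = reduce(a)
    b2, rem_b = reduce(b)
    return a2, b2, rem_a, rem_b


def clr(g: Genome, anchor: str = "cox1") -> tuple[str, ...]:
    """Canonical linear representation: the unique representation starting
    at the anchor gene in forward (+) orientation.

    Mitochondrial maps are conventionally written anchored at cox1.
    """
    if anchor not in g.gene_set:
        raise GenomeError(f"anchor gene {anchor!r} not in genome")
    for rep in g.representations():
        if rep[0] == anchor:
            return rep
    raise AssertionError("unreachable: every gene heads some representation")


# -- integer encoding used by the search engines --------------------------


def encode(g: Genome, label_order: Sequence[str]) -> np.ndarray:
    """Encode as a signed int array: gene ``label_order[i]`` becomes ``±(i+1)``."""
    idx = {lab: i + 1 for i, lab in enumerate(label_order)}
    return np.array(
        [s * idx[lab] for lab, s in zip(g.labels, g.signs)], dtype=np.int64
    )


def decode(arr: np.ndarray, label_order: Sequence[str], circular: bool = True) -> Genome:
    return Genome(
        [(label_order[abs(int(v)) - 1], 1 if v > 0 else -1) for v in arr],
        circular=circular,
    )


def canonical_array(arr: np.ndarray, circular: bool = True) -> np.ndarray:
    """Lexicographically least representation of an encoded genome."""
    n = len(arr)
    rev = -arr[::-1]
    if not circular:
        cands = [arr, rev]
    else:
        cands = [np.roll(arr, -i) for i in range(n)]
        cands += [np.roll(rev, -i) for i in range(n)]
    # sign ordering: +g before -g, labels ascending -> order key (abs, sign<0)
    best = min(cands, key=lambda c: [(abs(int(v)), int(v) < 0) for v in c])
    return best.copy()
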