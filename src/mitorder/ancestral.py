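"""Ancestral gene-order inference and tree validation (property P6).

For a candidate tree, every pair of OTUs whose connecting path runs only
through hypothetical ancestors constrains those ancestors: all rearrangement
paths of exactly the tree-path length between the two observed gene orders
are re-enumerated (with shared-block pruning disabled, so the enumeration is
exhaustive), and a hypothetical ancestor may only carry gene orders that
occur at its position along such paths.

An ancestor sitting on the single branch leading to one pendant OTU is
constrained by paths that all share that OTU: its possible gene orders are
the union of what those paths propose.  An ancestor at or between branching
points must be consistent with every pair crossing it: its gene orders are
the intersection.  An empty set anywhere invalidates the tree and yields a
minimal forbidden subtree reusable as an exclusion constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import Genome
from .pathsearch import SearchBudgetExceeded, distance, enumerate_k_paths
from .treesearch import ExclusionConstraint, HTU_PREFIX, PhyloTree, is_htu

__all__ = [
    "HTUAssignment",
    "P6Result",
    "AncestralBudgetExceeded",
    "constraining_pairs",
    "candidate_orders",
    "validate_P6",
]


class AncestralBudgetExceeded(RuntimeError):
    """Path re-enumeration exceeded the configured budget; reported
    distinctly from tree invalidity."""


@dataclass
class HTUAssignment:
    """Per-ancestor candidate gene orders and the supporting pair data."""

    candidates: dict[str, tuple[Genome, ...]] = field(default_factory=dict)
    pair_positions: dict[tuple[str, str], dict[str, frozenset[Genome]]] = field(
        default_factory=dict
    )

    def is_complete(self) -> bool:
        return all(len(c) > 0 for c in self.candidates.values())


@dataclass
class P6Result:
    valid: bool
    assignment: HTUAssignment | None = None
    failing_htu: str | None = None
    exclusion: ExclusionConstraint | None = None


def constraining_pairs(tree: PhyloTree) -> list[tuple[str, str, tuple[str, ...]]]:
    """OTU pairs whose tree path passes only through HTUs, with the path.

    Pairs separated by an intermediate OTU are not returned: the intermediate
    gene order is observed and breaks the constraint into smaller ones.
    """
    otus = sorted(tree.otus)
    out = []
    for i, a in enumerate(otus):
        for b in otus[i + 1 :]:
            path = tree.path(a, b)
            if all(is_htu(x) for x in path[1:-1]):
                out.append((a, b, path))
    return out


def _pair_position_sets(
    a: Genome,
    b: Genome,
    path: tuple[str, ...],
    k_max: int,
    slack: int,
) -> dict[str, frozenset[Genome]] | None:
    """Genomes occurring at each intermediate position over all paths of the
    tree-path length; None when no such path exists (invalid tree)."""
    k = len(path) - 1
    try:
        d = distance(a, b, k_max=k_max, use_ht1=True, use_ht2=True)
    except SearchBudgetExceeded as exc:
        raise AncestralBudgetExceeded(
            f"distance between {path[0]!r} and {path[-1]!r} exceeds k_max={k_max}"
        ) from exc
    if k > d + slack:
        raise AncestralBudgetExceeded(
            f"tree path of length {k} between {path[0]!r} and {path[-1]!r} "
            f"exceeds the enumeration budget (distance {d} + slack {slack})"
        )
    paths = enumerate_k_paths(a, b, k, use_ht1=False, use_ht2=True)
    if not paths:
        return None
    out: dict[str, set[Genome]] = {h: set() for h in path[1:-1]}
    for p in paths:
        for idx, h in enumerate(path[1:-1], start=1):
            out[h].add(p[idx])
    return {h: frozenset(s) for h, s in out.items()}


def _minimal_exclusion(
    tree: PhyloTree,
    htu: str,
    pairs: list[tuple[str, str, tuple[str, ...]]],
    position_sets: list[frozenset[Genome]],
) -> ExclusionConstraint:
    """Smallest subset of constraining pairs keeping the intersection empty
    (greedy, deterministic order); the pattern is the union of their paths."""
    keep = list(range(len(pairs)))

    def empty(idxs) -> bool:
        inter = None
        for i in idxs:
            inter = position_sets[i] if inter is None else inter & position_sets[i]
        return inter is not None and not inter

    for i in sorted(range(len(pairs)), key=lambda i: (pairs[i][0], pairs[i][1])):
        if len(keep) <= 2 or i not in keep:
            continue
        trial = [j for j in keep if j != i]
        endpoints = [set(pairs[j][:2]) for j in trial]
        if empty(trial) and not set.intersection(*endpoints):
            keep = trial
    nodes: set[str] = set()
    edges: set[frozenset[str]] = set()
    for i in keep:
        path = pairs[i][2]
        nodes.update(path)
        edges.update(frozenset(e) for e in zip(path, path[1:]))
    # anonymize HTUs with fresh consecutive names
    ren = {}
    for x in sorted(n for n in nodes if is_htu(n)):
        ren[x] = f"{HTU_PREFIX}{len(ren) + 1}"
    pat = PhyloTree(
        tuple(sorted(ren.get(x, x) for x in nodes)),
        frozenset(frozenset(ren.get(x, x) for x in e) for e in edges),
    )
    reason = (
        f"no common gene order at ancestor {htu!r} for pairs "
        + ", ".join(f"{pairs[i][0]}-{pairs[i][1]}" for i in keep)
    )
    return ExclusionConstraint(pat, reason)


def _single_path_exclusion(pair: tuple[str, str, tuple[str, ...]]) -> ExclusionConstraint:
    a, b, path = pair
    ren = {x: f"{HTU_PREFIX}{i + 1}" for i, x in enumerate(p for p in path if is_htu(p))}
    pat = PhyloTree(
        tuple(sorted(ren.get(x, x) for x in path)),
        frozenset(frozenset((ren.get(x, x), ren.get(y, y))) for x, y in zip(path, path[1:])),
    )
    return ExclusionConstraint(
        pat, f"no rearrangement path of length {len(path) - 1} between {a!r} and {b!r}"
    )


def candidate_orders(
    tree: PhyloTree,
    leaf_genomes: dict[str, Genome],
    k_max: int = 8,
    slack: int = 2,
) -> HTUAssignment:
    """All possible gene orders for every HTU of the tree.

    Candidate sets may be empty; use :func:`validate_P6` to turn emptiness
    into a tree rejection with a forbidden-subtree witness.
    """
    assignment = HTUAssignment()
    pairs = constraining_pairs(tree)
    for a, b, path in pairs:
        if len(path) <= 2:
            continue
        pos = _pair_position_sets(leaf_genomes[a], leaf_genomes[b], path, k_max, slack)
        assignment.pair_positions[(a, b)] = (
            {h: frozenset() for h in path[1:-1]} if pos is None else pos
        )
    for h in tree.htus:
        covering = [
            (key, posmap[h])
            for key, posmap in assignment.pair_positions.items()
            if h in posmap
        ]
        if not covering:
            assignment.candidates[h] = ()
            continue
        shared_otu = set.intersection(*(set(key) for key, _ in covering))
        sets = [s for _, s in covering]
        if shared_otu and len(covering) > 1:
            # pendant-branch ancestor: every constraint runs through one OTU
            merged = frozenset().union(*sets)
        else:
            merged = sets[0]
            for s in sets[1:]:
                merged = merged & s
        assignment.candidates[h] = tuple(
            sorted(merged, key=lambda g: g.canonical_key())
        )
    return assignment


def validate_P6(
    tree: PhyloTree,
    leaf_genomes: dict[str, Genome],
    k_max: int = 8,
    slack: int = 2,
) -> P6Result:
    """Accept the tree with its full ancestral assignment, or reject it with
    a minimal forbidden subtree."""
    assignment = candidate_orders(tree, leaf_genomes, k_max=k_max, slack=slack)
    # a pair with no path of its tree length invalidates the tree outright
    pairs = constraining_pairs(tree)
    for a, b, path in pairs:
        if len(path) > 2 and not any(assignment.pair_positions[(a, b)].values()):
            return P6Result(
                valid=False,
                failing_htu=path[1],
                exclusion=_single_path_exclusion((a, b, path)),
            )
    for h in sorted(tree.htus):
        if assignment.candidates.get(h):
            continue
        covering = [
            (a, b, path)
            for a, b, path in pairs
            if h in path[1:-1]
        ]
        if not covering:
            continue  # unconstrained HTU cannot occur (degree-1 HTUs are barred)
        sets = [frozenset(assignment.pair_positions[(a, b)][h]) for a, b, path in covering]
        return P6Result(
            valid=False,
            failing_htu=h,
            exclusion=_minimal_exclusion(tree, h, covering, sets),
        )
    return P6Result(valid=True, assignment=assignment)
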