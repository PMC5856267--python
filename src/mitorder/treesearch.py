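"""Complete enumeration of minimum-size rearrangement trees.

A candidate phylogeny is an unrooted tree whose nodes are the dataset's
distinct gene orders (OTUs, which may sit at internal positions) plus
anonymous hypothetical ancestors (HTUs); every edge stands for exactly one
rearrangement.  A tree is admissible when it

* is simple, undirected, connected and acyclic (P1-P3),
* respects the distance matrix: the tree path between two OTUs is never
  shorter than their exact pairwise distance (P4),
* realizes every imposed monophyly constraint relative to a root taxon (P5),
* contains no forbidden subtree accumulated from failed ancestral-state
  checks.

Parsimony means the smallest node count V = N + M admitting an admissible
tree; the enumeration at each V is complete (every labeled tree on V nodes
is generated and filtered, duplicates modulo HTU renaming removed), so the
returned set is exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations, product

from .genome import GenomeError

__all__ = [
    "PhyloTree",
    "PPH",
    "ExclusionConstraint",
    "check_monophyly",
    "verify_P1_to_P5",
    "enumerate_trees_at",
    "enumerate_parsimonious_trees",
    "contains_pattern",
    "TreeSearchError",
]

HTU_PREFIX = "HTU#"


class TreeSearchError(RuntimeError):
    pass


def is_htu(node: str) -> bool:
    return node.startswith(HTU_PREFIX)


@dataclass(frozen=True)
class PhyloTree:
    """Unrooted tree over OTU names and anonymous ``HTU#k`` nodes."""

    nodes: tuple[str, ...]
    edges: frozenset[frozenset[str]]

    def __post_init__(self):
        for e in self.edges:
            if len(e) != 2:
                raise TreeSearchError("edges must join two distinct nodes")
            if not e.issubset(self.nodes):
                raise TreeSearchError("edge endpoint outside node set")

    @property
    def otus(self) -> tuple[str, ...]:
        return tuple(x for x in self.nodes if not is_htu(x))

    @property
    def htus(self) -> tuple[str, ...]:
        return tuple(x for x in self.nodes if is_htu(x))

    def adjacency(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {x: [] for x in self.nodes}
        for e in self.edges:
            a, b = sorted(e)
            adj[a].append(b)
            adj[b].append(a)
        for x in adj:
            adj[x].sort()
        return adj

    def degree(self, node: str) -> int:
        return sum(1 for e in self.edges if node in e)

    def is_tree(self) -> bool:
        if len(self.edges) != len(self.nodes) - 1:
            return False
        return len(self._component(self.nodes[0])) == len(self.nodes)

    def _component(self, start: str, blocked_edge: frozenset[str] | None = None) -> set[str]:
        adj = self.adjacency()
        seen = {start}
        stack = [start]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if blocked_edge is not None and frozenset((x, y)) == blocked_edge:
                    continue
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return seen

    def path(self, a: str, b: str) -> tuple[str, ...]:
        """The unique simple path from a to b (inclusive)."""
        adj = self.adjacency()
        prev = {a: None}
        stack = [a]
        while stack:
            x = stack.pop()
            if x == b:
                break
            for y in adj[x]:
                if y not in prev:
                    prev[y] = x
                    stack.append(y)
        if b not in prev:
            raise TreeSearchError(f"no path between {a!r} and {b!r}")
        out = [b]
        while out[-1] != a:
            out.append(prev[out[-1]])
        return tuple(reversed(out))

    def path_length(self, a: str, b: str) -> int:
        return len(self.path(a, b)) - 1

    def clades(self, root: str) -> set[frozenset[str]]:
        """All OTU sets lying on the non-root side of some edge."""
        out = set()
        for e in self.edges:
            a, b = tuple(e)
            side = self._component(a, blocked_edge=e)
            far = side if root not in side else set(self.nodes) - side
            otus = frozenset(x for x in far if not is_htu(x))
            if otus:
                out.add(otus)
        return out

    def canonical_signature(self) -> tuple:
        """Edge multiset, minimized over renamings of the anonymous HTUs;
        equal signatures mean equal trees up to HTU relabeling."""
        htus = sorted(self.htus)
        best = None
        for perm in permutations(htus):
            ren = dict(zip(htus, perm))
            sig = tuple(
                sorted(tuple(sorted(ren.get(x, x) for x in e)) for e in self.edges)
            )
            if best is None or sig < best:
                best = sig
        return best

    def newick(self, root: str | None = None) -> str:
        """Newick string with unit branch lengths; internal nodes keep their
        OTU or HTU#k labels."""
        if root is None:
            root = sorted(self.otus)[0] if self.otus else self.nodes[0]
        adj = self.adjacency()

        def sub(node: str, parent: str | None) -> str:
            kids = [y for y in adj[node] if y != parent]
            inner = ",".join(sub(y, node) for y in kids)
            label = node
            body = f"({inner}){label}" if kids else label
            return body if parent is None else body + ":1"

        return sub(root, None) + ";"


@dataclass(frozen=True)
class PPH:
    """Primary phylogenetic hypothesis: a named monophyly constraint."""

    name: str
    taxa: frozenset[str]

    def __post_init__(self):
        if len(self.taxa) < 2:
            raise TreeSearchError("a PPH needs at least 2 taxa")


@dataclass(frozen=True)
class ExclusionConstraint:
    """A forbidden subtree fragment (OTU labels fixed, HTUs anonymous)."""

    pattern: PhyloTree
    reason: str = ""


def check_monophyly(tree: PhyloTree, root: str, taxa_set: frozenset[str]) -> bool:
    """True iff removing some edge separates exactly ``taxa_set`` (plus any
    HTUs) from the side containing ``root``."""
    if root in taxa_set:
        raise TreeSearchError("the root taxon cannot be part of a clade constraint")
    if is_htu(root) or root not in tree.nodes:
        raise TreeSearchError(f"root must be an OTU of the tree, got {root!r}")
    return frozenset(taxa_set) in tree.clades(root)


def verify_P1_to_P5(
    tree: PhyloTree,
    matrix,
    pphs=(),
    root: str | None = None,
) -> tuple[bool, str | None]:
    """Check the tree axioms in order; returns (ok, first violated property).

    P1 simple, P2 undirected, P3 tree, P4 path lengths respect the distance
    matrix, P5 monophyly constraints hold relative to the root taxon.
    """
    for e in tree.edges:
        if len(e) != 2:
            return False, "P1"
    # P2 is structural: edges are unordered pairs.
    if not tree.is_tree():
        return False, "P3"
    taxa = [t for t in matrix.taxa if t in tree.nodes]
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            if not matrix.is_exact(a, b):
                continue
            if tree.path_length(a, b) < matrix.get(a, b):
                return False, "P4"
    if pphs:
        if root is None:
            raise TreeSearchError("monophyly constraints require a root taxon")
        for pph in pphs:
            if not check_monophyly(tree, root, pph.taxa):
                return False, "P5"
    return True, None


# -- pattern containment ---------------------------------------------------


def contains_pattern(tree: PhyloTree, pattern: PhyloTree) -> bool:
    """Injective embedding of ``pattern`` into ``tree`` preserving edges,
    OTU labels, and HTU degrees (an anonymous pattern node must map to an
    HTU of identical degree)."""
    p_adj = pattern.adjacency()
    t_adj = tree.adjacency()
    p_nodes = sorted(pattern.nodes, key=lambda x: (is_htu(x), x))
    assignment: dict[str, str] = {}
    used: set[str] = set()

    def candidates(p: str):
        if not is_htu(p):
            return [p] if p in tree.nodes else []
        return [
            t
            for t in tree.htus
            if t not in used and tree.degree(t) == pattern.degree(p)
        ]

    def ok_with(p: str, t: str) -> bool:
        for q in p_adj[p]:
            if q in assignment and frozenset((t, assignment[q])) not in tree.edges:
                return False
        return True

    def rec(i: int) -> bool:
        if i == len(p_nodes):
            return True
        p = p_nodes[i]
        for t in candidates(p):
            if t in used or not ok_with(p, t):
                continue
            assignment[p] = t
            used.add(t)
            if rec(i + 1):
                return True
            del assignment[p]
            used.discard(t)
        return False

    return rec(0)


# -- complete enumeration --------------------------------------------------


def _prufer_trees(nodes: list[str]):
    """All labeled trees on the given nodes (Prüfer bijection)."""
    v = len(nodes)
    if v == 1:
        yield frozenset()
        return
    if v == 2:
        yield frozenset({frozenset(nodes)})
        return
    import heapq

    for seq in product(range(v), repeat=v - 2):
        deg = [1] * v
        for s in seq:
            deg[s] += 1
        leaves = [i for i in range(v) if deg[i] == 1]
        heapq.heapify(leaves)
        edges = []
        for s in seq:
            leaf = heapq.heappop(leaves)
            edges.append(frozenset((nodes[leaf], nodes[s])))
            deg[s] -= 1
            if deg[s] == 1:
                heapq.heappush(leaves, s)
        u = heapq.heappop(leaves)
        w = heapq.heappop(leaves)
        edges.append(frozenset((nodes[u], nodes[w])))
        yield frozenset(edges)


def enumerate_trees_at(
    n_nodes: int,
    matrix,
    pphs=(),
    root: str | None = None,
    exclusions=(),
) -> list[PhyloTree]:
    """All admissible trees on exactly ``n_nodes`` nodes, complete and
    deduplicated up to HTU renaming.

    HTUs of degree 1 are rejected: a pendant hypothetical ancestor explains
    nothing and deleting it yields an equally admissible smaller tree, so it
    can never occur at the minimal node count.
    """
    taxa = list(matrix.taxa)
    n = len(taxa)
    if n_nodes < n:
        raise TreeSearchError("cannot use fewer nodes than taxa")
    htus = [f"{HTU_PREFIX}{i + 1}" for i in range(n_nodes - n)]
    nodes = taxa + htus
    found: dict[tuple, PhyloTree] = {}
    for edges in _prufer_trees(nodes):
        tree = PhyloTree(tuple(nodes), edges)
        if any(tree.degree(h) <= 1 for h in htus):
            continue
        ok, _ = verify_P1_to_P5(tree, matrix, pphs, root)
        if not ok:
            continue
        if any(contains_pattern(tree, ex.pattern) for ex in exclusions):
            continue
        sig = tree.canonical_signature()
        if sig not in found:
            found[sig] = tree
    return [found[s] for s in sorted(found)]


def enumerate_parsimonious_trees(
    matrix,
    pphs=(),
    root: str | None = None,
    exclusions=(),
    max_htus: int | None = None,
) -> tuple[list[PhyloTree], int]:
    """All admissible trees on the smallest possible node count.

    Returns ``(trees, V)``.  Raises :class:`TreeSearchError` when no tree
    exists below the HTU ceiling (default: number of taxa + 4).
    """
    if not matrix.all_exact:
        raise TreeSearchError(
            "tree enumeration needs exact distances; inexact cells present"
        )
    n = len(matrix.taxa)
    if max_htus is None:
        max_htus = n + 4
    for v in range(n, n + max_htus + 1):
        trees = enumerate_trees_at(v, matrix, pphs, root, exclusions)
        if trees:
            return trees, v
    raise TreeSearchError(
        f"no admissible tree with at most {max_htus} hypothetical ancestors"
    )
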