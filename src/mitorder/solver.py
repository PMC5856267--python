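"""Complete solution sets: tree enumeration alternating with ancestral
validation, plus extraction of logical consequences.

The solver enumerates every admissible tree on the smallest node count,
validates each by ancestral-state inference, and turns every failure into a
forbidden-subtree constraint.  When a node count admits trees but none
survives validation, the search escalates to the next node count: parsimony
asks for the smallest domain on which a fully consistent scenario exists.
The final set is complete — every returned tree passes all checks and no
passing tree is missing — which is what makes statements true across the
whole set ("logical consequences") robust results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .ancestral import HTUAssignment, validate_P6
from .distmatrix import DistanceMatrix, build_matrix
from .genome import Genome, GenomeError
from .treesearch import (
    ExclusionConstraint,
    PhyloTree,
    TreeSearchError,
    contains_pattern,
    enumerate_trees_at,
    is_htu,
)

logger = logging.getLogger("mitorder")

__all__ = ["Solution", "SolutionSet", "Fact", "solve", "logical_consequences"]


@dataclass
class Solution:
    tree: PhyloTree
    assignment: HTUAssignment


@dataclass
class SolutionSet:
    solutions: list[Solution]
    n_nodes: int
    exclusions: list[ExclusionConstraint]
    matrix: DistanceMatrix
    root: str | None
    complete: bool
    leaf_genomes: dict[str, Genome] = field(default_factory=dict)
    rounds: list[dict] = field(default_factory=list)


@dataclass(frozen=True)
class Fact:
    """A statement true in every solution of a complete set."""

    kind: str  # "monophyly" | "edge" | "ur_identity"
    description: str
    data: tuple


def solve(
    dataset: list[tuple[str, Genome]],
    pphs=(),
    root: str | None = None,
    k_max: int = 8,
    slack: int = 2,
    max_htus: int | None = None,
) -> SolutionSet:
    """All most-parsimonious trees passing the full axiom set P1-P6.

    The distance matrix is built with pairwise common-gene reduction; the
    ancestral inference runs on the gene orders reduced to the genes shared
    by the whole dataset, so candidate ancestors live on one gene universe.
    """
    if len(dataset) < 2:
        raise GenomeError("the solver needs at least 2 taxa")
    matrix = build_matrix(dataset, k_max=k_max)
    if not matrix.all_exact:
        raise TreeSearchError(
            "some pairwise distances exceed the budget; solver requires exact cells"
        )
    by_name = dict(dataset)
    common = frozenset.intersection(*(g.gene_set for _, g in dataset))
    if len(common) < 3:
        raise GenomeError("dataset shares fewer than 3 genes overall")
    leaf_genomes: dict[str, Genome] = {}
    for t in matrix.taxa:
        g = by_name[t]
        kept = [
            (lab, s) for lab, s in zip(g.labels, g.signs) if lab in common
        ]
        leaf_genomes[t] = Genome(kept, circular=True)

    n = len(matrix.taxa)
    if max_htus is None:
        max_htus = n + 4
    exclusions: list[ExclusionConstraint] = []
    rounds: list[dict] = []
    for v in range(n, n + max_htus + 1):
        while True:
            trees = enumerate_trees_at(v, matrix, pphs, root, exclusions)
            valid: list[Solution] = []
            new_exclusions = 0
            for tree in trees:
                res = validate_P6(tree, leaf_genomes, k_max=k_max, slack=slack)
                if res.valid:
                    valid.append(Solution(tree, res.assignment))
                elif res.exclusion is not None:
                    if not any(
                        res.exclusion.pattern.canonical_signature()
                        == ex.pattern.canonical_signature()
                        for ex in exclusions
                    ):
                        exclusions.append(res.exclusion)
                        new_exclusions += 1
            round_info = {
                "n_nodes": v,
                "trees_enumerated": len(trees),
                "valid": len(valid),
                "new_exclusions": new_exclusions,
            }
            rounds.append(round_info)
            logger.info("solver round %s", json.dumps(round_info))
            if valid:
                return SolutionSet(
                    valid, v, exclusions, matrix, root, True, leaf_genomes, rounds
                )
            if new_exclusions == 0:
                break  # nothing left to learn at this node count: escalate
    raise TreeSearchError(
        f"no fully consistent tree with at most {max_htus} hypothetical ancestors"
    )


def logical_consequences(solset: SolutionSet) -> list[Fact]:
    """Statements verified by every solution.

    Emitted facts: clades monophyletic in all trees, edges present in all
    trees, and ancestral identities — a clade whose basal gene order equals
    one OTU's genome in every solution represents that clade's ground
    pattern ("Ur-" identity).
    """
    if not solset.solutions:
        raise ValueError("logical consequences need a nonempty solution set")
    if not solset.complete:
        raise ValueError("logical consequences are defined on complete sets only")
    sols = solset.solutions
    root = solset.root
    facts: list[Fact] = []

    if root is not None:
        clade_sets = [s.tree.clades(root) for s in sols]
        common_clades = set.intersection(*clade_sets)
        for clade in sorted(common_clades, key=lambda c: (len(c), sorted(c))):
            if len(clade) < 2:
                continue
            facts.append(
                Fact(
                    "monophyly",
                    "monophyly of {" + ", ".join(sorted(clade)) + "} holds in all solutions",
                    tuple(sorted(clade)),
                )
            )

    edge_sets = [frozenset(s.tree.edges) for s in sols]
    for e in sorted(frozenset.intersection(*edge_sets), key=lambda e: sorted(e)):
        a, b = sorted(e)
        if is_htu(a) or is_htu(b):
            continue  # HTU identities are not comparable across trees
        facts.append(
            Fact("edge", f"{a} and {b} are linked by one rearrangement in all solutions", (a, b))
        )

    if root is not None:
        facts.extend(_ur_identities(solset))
    return facts


def _basal_node(tree: PhyloTree, root: str, clade: frozenset[str]) -> str | None:
    """Node on the clade side of the edge separating the clade from the root."""
    for e in tree.edges:
        a, b = tuple(e)
        side = tree._component(a, blocked_edge=e)
        if root in side:
            side = set(tree.nodes) - side
            top = a if a in side else b
        else:
            top = a
        if frozenset(x for x in side if not is_htu(x)) == clade:
            return top
    return None


def _ur_identities(solset: SolutionSet) -> list[Fact]:
    sols = solset.solutions
    root = solset.root
    common_clades = set.intersection(*(s.tree.clades(root) for s in sols))
    facts = []
    for clade in sorted(common_clades, key=lambda c: (len(c), sorted(c))):
        if len(clade) < 2:
            continue
        reps: set[str] = set()
        ok = True
        for s in sols:
            node = _basal_node(s.tree, root, clade)
            if node is None:
                ok = False
                break
            if not is_htu(node):
                reps.add(node)
            else:
                cands = s.assignment.candidates.get(node, ())
                named = {
                    t
                    for t in clade
                    if t in solset.leaf_genomes
                    and any(g == solset.leaf_genomes[t] for g in cands)
                }
                if len(cands) == 1 and named:
                    reps.update(named)
                else:
                    ok = False
                    break
        if ok and len(reps) == 1:
            (taxon,) = reps
            facts.append(
                Fact(
                    "ur_identity",
                    f"{taxon} carries the ancestral gene order of "
                    "{" + ", ".join(sorted(clade)) + "} in all solutions",
                    (taxon, tuple(sorted(clade))),
                )
            )
    return facts

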