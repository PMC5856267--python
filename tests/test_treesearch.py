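"""Tree axioms, monophyly, complete enumeration, pattern exclusion."""

from itertools import combinations

import pytest

from conftest import make_matrix
from mitorder.treesearch import (
    PPH,
    ExclusionConstraint,
    PhyloTree,
    TreeSearchError,
    check_monophyly,
    contains_pattern,
    enumerate_parsimonious_trees,
    enumerate_trees_at,
    is_htu,
    verify_P1_to_P5,
)


def T(*edges):
    nodes = tuple(sorted({x for e in edges for x in e}))
    return PhyloTree(nodes, frozenset(frozenset(e) for e in edges))


CHAIN = T(("A", "B"), ("B", "C"))
STAR = T(("A", "HTU#1"), ("B", "HTU#1"), ("C", "HTU#1"))


class TestMonophyly:
    def test_chain_tail_clade(self):
        assert check_monophyly(CHAIN, "A", frozenset({"B", "C"}))

    def test_chain_split_clade_fails(self):
        assert not check_monophyly(CHAIN, "B", frozenset({"A", "C"}))

    def test_star_clade_through_hub(self):
        # cutting the A-hub edge leaves {B, C} as the non-root OTU set
        assert check_monophyly(STAR, "A", frozenset({"B", "C"}))

    def test_root_inside_clade_rejected(self):
        with pytest.raises(TreeSearchError):
            check_monophyly(CHAIN, "A", frozenset({"A", "B"}))


class TestVerifyAxioms:
    def test_direct_edge_violates_distance(self):
        m = make_matrix(["A", "B"], {("A", "B"): 2})
        ok, prop = verify_P1_to_P5(T(("A", "B")), m)
        assert not ok and prop == "P4"

    def test_intermediate_htu_satisfies(self):
        m = make_matrix(["A", "B"], {("A", "B"): 2})
        ok, _ = verify_P1_to_P5(T(("A", "HTU#1"), ("HTU#1", "B")), m)
        assert ok

    def test_cycle_violates_tree_axiom(self):
        m = make_matrix(["A", "B", "C"], {})
        cyc = PhyloTree(
            ("A", "B", "C"),
            frozenset(
                {frozenset(("A", "B")), frozenset(("B", "C")), frozenset(("A", "C"))}
            ),
        )
        ok, prop = verify_P1_to_P5(cyc, m)
        assert not ok and prop == "P3"

    def test_pph_violation_reported(self):
        m = make_matrix(["A", "B", "C"], {("A", "B"): 1, ("B", "C"): 1, ("A", "C"): 1})
        ok, prop = verify_P1_to_P5(
            T(("A", "C"), ("C", "B")), m, [PPH("ab", frozenset({"A", "B"}))], root="C"
        )
        assert not ok and prop == "P5"


class TestEnumeration:
    def test_two_otus_at_distance_two(self):
        m = make_matrix(["A", "B"], {("A", "B"): 2})
        trees, v = enumerate_parsimonious_trees(m)
        assert v == 3 and len(trees) == 1
        assert trees[0].edges == frozenset(
            {frozenset(("A", "HTU#1")), frozenset(("HTU#1", "B"))}
        )

    def test_three_otus_all_neighbors_gives_three_chains(self):
        m = make_matrix(["A", "B", "C"], {("A", "B"): 1, ("A", "C"): 1, ("B", "C"): 1})
        trees, v = enumerate_parsimonious_trees(m)
        assert v == 3 and len(trees) == 3
        internals = sorted(
            next(x for x in t.nodes if t.degree(x) == 2) for t in trees
        )
        assert internals == ["A", "B", "C"]

    def test_pph_restricts_to_two_chains(self):
        m = make_matrix(["A", "B", "C"], {("A", "B"): 1, ("A", "C"): 1, ("B", "C"): 1})
        trees, _ = enumerate_parsimonious_trees(
            m, [PPH("ab", frozenset({"A", "B"}))], root="C"
        )
        assert len(trees) == 2
        assert all(t.degree("C") == 1 for t in trees)

    def test_monotone_under_constraints(self):
        m = make_matrix(
            ["A", "B", "C", "D"],
            {(a, b): 2 for a, b in combinations("ABCD", 2)},
        )
        base = enumerate_trees_at(6, m)
        with_pph = enumerate_trees_at(
            6, m, [PPH("ab", frozenset({"A", "B"}))], root="D"
        )
        assert len(with_pph) <= len(base)
        if base:
            ex = ExclusionConstraint(base[0])
            excl = enumerate_trees_at(6, m, exclusions=[ex])
            assert len(excl) <= len(base)

    def test_ceiling_failure_is_explicit(self):
        m = make_matrix(["A", "B"], {("A", "B"): 8})
        with pytest.raises(TreeSearchError):
            enumerate_parsimonious_trees(m, max_htus=2)


class TestBruteForceCompleteness:
    """The enumeration must agree with an independent generator that builds
    every edge subset of the complete graph and filters."""

    def brute(self, n_nodes, matrix, pphs=(), root=None):
        taxa = list(matrix.taxa)
        htus = [f"HTU#{i + 1}" for i in range(n_nodes - len(taxa))]
        nodes = taxa + htus
        all_edges = [frozenset(e) for e in combinations(nodes, 2)]
        sigs = set()
        for edges in combinations(all_edges, n_nodes - 1):
            t = PhyloTree(tuple(nodes), frozenset(edges))
            if not t.is_tree():
                continue
            if any(t.degree(h) <= 1 for h in htus):
                continue
            ok, _ = verify_P1_to_P5(t, matrix, pphs, root)
            if ok:
                sigs.add(t.canonical_signature())
        return sigs

    @pytest.mark.parametrize(
        "dists,extra",
        [
            ({("A", "B"): 2, ("A", "C"): 2, ("B", "C"): 2}, 1),
            ({("A", "B"): 1, ("A", "C"): 2, ("B", "C"): 1}, 1),
            ({("A", "B"): 2, ("A", "C"): 3, ("B", "C"): 1}, 2),
        ],
    )
    def test_matches_edge_subset_generator(self, dists, extra):
        taxa = sorted({x for pair in dists for x in pair})
        m = make_matrix(taxa, dists)
        v = len(taxa) + extra
        ours = {t.canonical_signature() for t in enumerate_trees_at(v, m)}
        assert ours == self.brute(v, m)

    def test_matches_with_four_taxa(self):
        dists = {(a, b): 2 for a, b in combinations("ABCD", 2)}
        m = make_matrix(list("ABCD"), dists)
        for v in (5, 6):
            ours = {t.canonical_signature() for t in enumerate_trees_at(v, m)}
            assert ours == self.brute(v, m)


class TestPatternContainment:
    def test_star_pattern_found(self):
        tree = T(("A", "HTU#1"), ("B", "HTU#1"), ("C", "HTU#1"), ("C", "D"))
        pat = T(("A", "HTU#1"), ("B", "HTU#1"), ("C", "HTU#1"))
        assert contains_pattern(tree, pat)

    def test_htu_degree_must_match(self):
        tree = T(("A", "HTU#1"), ("B", "HTU#1"), ("C", "HTU#1"), ("D", "HTU#1"))
        pat = T(("A", "HTU#1"), ("B", "HTU#1"), ("C", "HTU#1"))
        assert not contains_pattern(tree, pat)  # hub degree 4 != 3

    def test_otu_labels_preserved(self):
        tree = T(("A", "HTU#1"), ("B", "HTU#1"), ("C", "HTU#1"))
        pat = T(("A", "HTU#1"), ("D", "HTU#1"), ("C", "HTU#1"))
        assert not contains_pattern(tree, pat)

    def test_path_pattern_embeds_anywhere(self):
        tree = T(("A", "HTU#1"), ("HTU#1", "HTU#2"), ("HTU#2", "B"), ("HTU#1", "C"))
        pat = T(("A", "HTU#9"), ("HTU#9", "C"))
        # HTU#1 has degree 3 in the tree but 2 in the pattern
        assert not contains_pattern(tree, pat)
        pat2 = T(("B", "HTU#9"), ("HTU#9", "HTU#8"), ("HTU#8", "A"), ("HTU#8", "C"))
        assert contains_pattern(tree, pat2)
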