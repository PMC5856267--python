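"""Elementary rearrangements, neighborhoods, breakpoints, shared blocks."""

import pytest

from conftest import brute_neighbors, class_representatives
from mitorder.genome import GenomeError, parse_genome
from mitorder.rearrangements import (
    Rearrangement,
    apply,
    enumerate_neighbors,
    nb_breakpoints,
    shared_blocks,
)


class TestApply:
    def test_transposition_moves_block(self):
        g = parse_genome("A B C")
        moved = apply(g, Rearrangement("transposition", 1, 1, 0))  # B before A
        assert moved == parse_genome("B A C")

    def test_equivalent_transpositions_collapse(self):
        # circularity: transposing A, B or C gives the same gene order
        g = parse_genome("A B C")
        target = parse_genome("B A C")
        assert target == parse_genome("A C B") == parse_genome("C B A")

    def test_equivalent_inversions_collapse(self):
        g = parse_genome("A B")
        inv_a = apply(g, Rearrangement("inversion", 0, 1))
        inv_b = apply(g, Rearrangement("inversion", 1, 1))
        assert inv_a == parse_genome("-A B")
        assert inv_b == parse_genome("A -B")
        assert inv_a == inv_b

    def test_inversion_is_involution(self):
        g = parse_genome("1 2 -3 4 5")
        r = Rearrangement("inversion", 1, 3)
        assert apply(apply(g, r), r) == g

    def test_wrapping_block_inversion(self):
        g = parse_genome("1 2 3 4")
        out = apply(g, Rearrangement("inversion", 3, 2))  # block [4 1]
        assert out == parse_genome("-1 -4 2 3")

    @pytest.mark.parametrize(
        "r",
        [
            Rearrangement("inversion", 0, 5),  # whole genome is not a block
            Rearrangement("transposition", 0, 2, 2),  # re-insert in place
            Rearrangement("transposition", 0, 2, 1),  # inside the block
            Rearrangement("reverse_transposition", 0, 2, 0),  # same position
        ],
    )
    def test_invalid_parameters(self, r):
        with pytest.raises(GenomeError):
            apply(parse_genome("1 2 3 4 5"), r)


class TestNeighbors:
    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_matches_brute_force_oracle(self, n):
        for g in class_representatives(n):
            assert set(enumerate_neighbors(g)) == brute_neighbors(g)

    def test_self_excluded_and_deterministic(self):
        g = parse_genome("1 -2 3 4")
        nb = enumerate_neighbors(g)
        assert g not in nb
        assert nb == enumerate_neighbors(g)
        assert len(nb) == len(set(nb))

    def test_symmetry(self):
        for g in class_representatives(4):
            for h in enumerate_neighbors(g):
                assert g in enumerate_neighbors(h)


class TestBreakpoints:
    def test_zero_iff_equal(self):
        g = parse_genome("1 -2 3 4")
        assert nb_breakpoints(g, g) == 0
        assert nb_breakpoints(g, parse_genome("3 4 1 -2")) == 0

    def test_worked_pair_has_four(self):
        # oracle: check each of the 5 circular adjacencies of the identity
        # against all representations of the other genome
        a = parse_genome("1 2 3 4 5")
        b = parse_genome("1 -2 -3 -5 -4")
        reps = set(b.representations())
        toks = a.tokens()
        shared = 0
        for i in range(5):
            x, y = toks[i], toks[(i + 1) % 5]
            if any(
                r[j] == x and r[(j + 1) % 5] == y for r in reps for j in range(5)
            ):
                shared += 1
        assert 5 - shared == 4
        assert nb_breakpoints(a, b) == 4
        assert nb_breakpoints(b, a) == 4

    def test_symmetric_on_random_pairs(self, rng):
        from mitorder.simulate import random_genome

        for _ in range(20):
            a, b = random_genome(6, rng), random_genome(6, rng)
            assert nb_breakpoints(a, b) == nb_breakpoints(b, a)

    def test_one_rearrangement_makes_at_most_three(self):
        for g in class_representatives(5)[:40]:
            for h in enumerate_neighbors(g):
                assert nb_breakpoints(g, h) <= 3

    def test_different_gene_sets_rejected(self):
        with pytest.raises(GenomeError):
            nb_breakpoints(parse_genome("1 2 3"), parse_genome("1 2 4"))


class TestSharedBlocks:
    def test_inverted_block_counts_as_shared(self):
        a = parse_genome("1 2 3 4 5")
        b = parse_genome("1 -2 -3 -5 -4")
        # oracle: [-5 -4] in b is the inversion of [4 5] in a
        assert shared_blocks(a, b) == [("4", "5")]

    def test_transposition_neighbor_shares_the_moved_block(self):
        g = parse_genome("1 2 3 4 5 6")
        h = apply(g, Rearrangement("transposition", 1, 2, 5))  # move [2 3]
        blocks = shared_blocks(g, h)
        assert ("2", "3") in blocks

    def test_block_intersection_oracle(self):
        # enumerate all blocks of both genomes and intersect
        a = parse_genome("1 2 3 4 5")
        b = parse_genome("1 -2 -3 -5 -4")

        def all_blocks(g):
            out = set()
            for rep in g.representations():
                for i in range(g.n):
                    for ln in range(2, g.n):
                        out.add(tuple(rep[(i + k) % g.n] for k in range(ln)))
            return out

        inter = all_blocks(a) & all_blocks(b)
        # maximal shared blocks must appear among the raw intersection
        for blk in shared_blocks(a, b):
            assert blk in inter

    def test_identical_genomes_rejected(self):
        g = parse_genome("1 2 3 4")
        with pytest.raises(GenomeError):
            shared_blocks(g, parse_genome("3 4 1 2"))
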