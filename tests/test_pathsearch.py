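"""The backtracking path search: heuristic test, k-path enumeration,
iterative-deepening distances, cuts."""

import pytest

from conftest import bfs_distance_oracle, class_representatives
from mitorder.genome import GenomeError, parse_genome
from mitorder.pathsearch import TestResult as HeuristicResult
from mitorder.pathsearch import (
    Path,
    SearchBudgetExceeded,
    SearchState,
    distance,
    enumerate_k_paths,
    enumerate_minimal_paths,
    heuristic_test,
    is_path,
    path_has_cut,
)
from mitorder.rearrangements import enumerate_neighbors, nb_breakpoints


class TestHeuristicTest:
    def test_yes_at_target_with_budget_spent(self):
        g = parse_genome("1 2 3")
        st = SearchState(g, parse_genome("2 3 1"), steps_used=2, budget=2)
        assert heuristic_test(st) is HeuristicResult.YES

    def test_no_when_breakpoints_exceed_capacity(self):
        # pair with 10 breakpoints but only 3 steps left: 10 > 9
        a = parse_genome("1 2 3 4 5 6 7 8 9 10")
        b = parse_genome("2 1 4 3 6 5 8 7 10 9")
        assert nb_breakpoints(a, b) == 10
        st = SearchState(a, b, steps_used=0, budget=3)
        assert heuristic_test(st) is HeuristicResult.NO

    def test_no_on_early_target_hit(self):
        g = parse_genome("1 2 3")
        st = SearchState(g, g, steps_used=1, budget=2)
        assert heuristic_test(st) is HeuristicResult.NO

    def test_indeterminate_otherwise(self, toy_pair):
        a, b = toy_pair  # 4 breakpoints, 2 steps left: neither YES nor NO
        st = SearchState(a, b, steps_used=0, budget=2)
        assert heuristic_test(st) is HeuristicResult.INDETERMINATE

    def test_ht2_off_never_fires_breakpoint_rule(self):
        a = parse_genome("1 2 3 4 5 6 7 8 9 10")
        b = parse_genome("2 1 4 3 6 5 8 7 10 9")
        st = SearchState(a, b, steps_used=0, budget=3, use_ht2=False)
        assert heuristic_test(st) is HeuristicResult.INDETERMINATE


class TestToyPair:
    def test_distance_is_two(self, toy_pair):
        a, b = toy_pair
        assert distance(a, b, k_max=4) == 2

    def test_exactly_eight_minimal_paths(self, toy_pair):
        a, b = toy_pair
        paths = enumerate_minimal_paths(a, b, use_ht1=False)
        assert len(paths) == 8
        assert all(p.length == 2 for p in paths)
        printed_middle = parse_genome("1 -2 -3 4 5")
        assert any(p[1] == printed_middle for p in paths)

    def test_all_minimal_paths_cut_free(self, toy_pair):
        a, b = toy_pair
        for p in enumerate_minimal_paths(a, b, use_ht1=False):
            assert not path_has_cut(p)

    def test_no_one_step_path(self, toy_pair):
        a, b = toy_pair
        assert enumerate_k_paths(a, b, 1) == []
        assert b not in enumerate_neighbors(a)

    def test_zero_path_for_identical(self):
        g = parse_genome("1 2 3 4")
        paths = enumerate_k_paths(g, parse_genome("3 4 1 2"), 0)
        assert len(paths) == 1 and paths[0].length == 0

    def test_budget_failure_is_explicit(self, toy_pair):
        a, b = toy_pair
        with pytest.raises(SearchBudgetExceeded):
            distance(a, b, k_max=1)


class TestLinearTopology:
    def test_linear_distance_is_three(self, toy_pair_linear):
        a, b = toy_pair_linear
        assert distance(a, b, k_max=4) == 3

    def test_printed_linear_path_is_valid_and_has_cut(self):
        steps = [
            parse_genome("1 -2 -3 -5 -4", circular=False),
            parse_genome("1 -2 5 3 -4", circular=False),
            parse_genome("1 4 -3 -2 5", circular=False),
            parse_genome("1 2 3 4 5", circular=False),
        ]
        assert is_path(steps)
        assert path_has_cut(Path(tuple(steps)))

    def test_some_circular_minimal_path_is_cut_free(self, toy_pair):
        a, b = toy_pair
        paths = enumerate_minimal_paths(a, b, use_ht1=False)
        assert any(not path_has_cut(p) for p in paths)


class TestDistanceCorrectness:
    @pytest.mark.parametrize("n", [3, 4])
    def test_matches_bfs_oracle_exhaustively(self, n):
        oracle = bfs_distance_oracle(n)
        ident = parse_genome(" ".join(str(i) for i in range(1, n + 1)))
        for g, d_true in oracle.items():
            assert distance(ident, g, k_max=4) == d_true

    def test_single_step_iff_neighbor(self, rng):
        from mitorder.simulate import random_genome

        g = random_genome(5, rng)
        for h in enumerate_neighbors(g)[:15]:
            assert distance(g, h, k_max=2) == 1
        far = random_genome(5, rng)
        if distance(g, far, k_max=4) == 1:
            assert far in enumerate_neighbors(g)

    def test_rejects_different_gene_sets(self):
        with pytest.raises(GenomeError):
            distance(parse_genome("1 2 3"), parse_genome("1 2 4"))


class TestHeuristicConsistency:
    @pytest.mark.parametrize("flags", [(True, True), (True, False), (False, True), (False, False)])
    def test_flags_do_not_change_distance_n4(self, flags):
        ht1, ht2 = flags
        ident = parse_genome("1 2 3 4")
        for g, d_true in bfs_distance_oracle(4).items():
            assert distance(ident, g, k_max=3, use_ht1=ht1, use_ht2=ht2) == d_true

    def test_minimal_path_count_unaffected_by_ht2(self, toy_pair):
        a, b = toy_pair
        with_ht2 = enumerate_k_paths(a, b, 2, use_ht1=False, use_ht2=True)
        without = enumerate_k_paths(a, b, 2, use_ht1=False, use_ht2=False)
        assert {tuple(p.genomes) for p in with_ht2} == {tuple(p.genomes) for p in without}

    def test_ht1_keeps_at_least_one_minimal_path(self, rng):
        from mitorder.simulate import random_genome

        for _ in range(10):
            a, b = random_genome(5, rng), random_genome(5, rng)
            if a == b:
                continue
            full = enumerate_minimal_paths(a, b, use_ht1=False, k_max=4)
            pruned = enumerate_minimal_paths(a, b, use_ht1=True, k_max=4)
            assert pruned
            keys = {tuple(p.genomes) for p in full}
            assert {tuple(p.genomes) for p in pruned} <= keys


class TestMetricAxioms:
    def test_metric_on_random_samples(self, rng):
        from mitorder.simulate import random_genome

        for _ in range(15):
            a, b, c = (random_genome(6, rng) for _ in range(3))
            dab = distance(a, b, k_max=6)
            assert dab == distance(b, a, k_max=6)
            assert (dab == 0) == (a == b)
            assert distance(a, c, k_max=6) <= dab + distance(b, c, k_max=6)
            assert 3 * dab >= nb_breakpoints(a, b)
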