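"""Scheme constructions: worked examples, shapes, and completeness."""

import random

import pytest

from searchschemes import generators as g
from searchschemes.schemes import SchemeError, check_scheme, coverage_set, covers


def triplets(scheme):
    return [s.as_triplet() for s in scheme]


class TestUniformPartition:
    @pytest.mark.parametrize(
        "n,p,sizes",
        [(50, 4, (13, 13, 12, 12)), (8, 3, (3, 3, 2)), (50, 1, (50,)),
         (50, 3, (17, 17, 16)), (6, 6, (1,) * 6)],
    )
    def test_sizes(self, n, p, sizes):
        part = g.uniform_partition(n, p)
        assert part.sizes == sizes
        assert part.query_length == n

    def test_offsets(self):
        assert g.uniform_partition(8, 3).offsets() == (0, 3, 6)

    def test_rejects_too_many_parts(self):
        with pytest.raises(SchemeError):
            g.uniform_partition(3, 4)


class TestPigeonholeFamily:
    def test_plain_k2_matches_figure(self):
        assert triplets(g.pigeonhole(2)) == [
            ((0, 1, 2), (0, 0, 0), (0, 2, 2)),
            ((1, 0, 2), (0, 0, 0), (0, 2, 2)),
            ((2, 1, 0), (0, 0, 0), (0, 2, 2)),
        ]

    def test_plain_k1(self):
        assert triplets(g.pigeonhole(1)) == [
            ((0, 1), (0, 0), (0, 1)),
            ((1, 0), (0, 0), (0, 1)),
        ]

    def test_optimized_k2_matches_figure(self):
        assert triplets(g.pigeonhole_opt(2)) == [
            ((0, 1, 2), (0, 0, 0), (0, 2, 2)),
            ((1, 0, 2), (0, 1, 1), (0, 2, 2)),
            ((2, 1, 0), (0, 1, 2), (0, 1, 2)),
        ]

    def test_optimized_k2_disjoint_k3_redundant(self):
        assert check_scheme(g.pigeonhole_opt(2)).nonredundant
        r3 = check_scheme(g.pigeonhole_opt(3))
        assert r3.complete and not r3.nonredundant


class TestSuffixFilter:
    def test_k2_searches(self):
        assert triplets(g.suffix_filter(2)) == [
            ((0, 1, 2), (0, 0, 0), (0, 1, 2)),
            ((1, 2, 0), (0, 0, 1), (0, 1, 2)),
            ((2, 1, 0), (0, 1, 1), (0, 2, 2)),
        ]

    def test_third_search_coverage_matches_caption(self):
        s2 = g.suffix_filter(2).searches[2]
        assert coverage_set(s2, 2) == {(1, 1, 0), (0, 2, 0), (0, 1, 0)}

    def test_first_search_coverage(self):
        s0 = g.suffix_filter(2).searches[0]
        assert coverage_set(s0, 2) == {
            (0, 0, 0), (0, 0, 1), (0, 1, 0), (0, 1, 1), (0, 0, 2),
        }

    def test_k2_redundant(self):
        r = check_scheme(g.suffix_filter(2))
        assert r.complete and not r.nonredundant


class TestZeroOneStar:
    def test_search_counts(self):
        for k in range(1, 5):
            assert len(g.zero_one_star(k)) == (k + 1) * (k + 2) // 2
            assert len(g.zero_one_star_opt(k)) == k + 1
            assert g.zero_one_star(k).p == k + 2

    def test_block_search_a1_j1(self):
        sch = g.zero_one_star(2)
        assert ((1, 2, 3, 0), (0, 1, 1, 1), (0, 1, 1, 2)) in triplets(sch)

    def test_merged_k2(self):
        assert set(triplets(g.zero_one_star_opt(2))) == {
            ((0, 1, 2, 3), (0, 0, 0, 0), (0, 1, 2, 2)),
            ((1, 2, 3, 0), (0, 0, 0, 0), (0, 1, 2, 2)),
            ((2, 3, 1, 0), (0, 0, 0, 0), (0, 0, 2, 2)),
        }

    def test_merge_widens_coverage(self):
        for k in (1, 2, 3):
            merged = g.zero_one_star_opt(k)
            family = g.zero_one_star(k)
            union = set()
            for s in family:
                union |= coverage_set(s, k)
            merged_union = set()
            for s in merged:
                merged_union |= coverage_set(s, k)
            assert union <= merged_union


class TestHeuristic:
    def test_k2_p4_matches_figure(self):
        assert set(triplets(g.heuristic(2, 4))) == {
            ((2, 3, 1, 0), (0, 0, 0, 0), (0, 0, 2, 2)),
            ((1, 2, 3, 0), (0, 0, 1, 1), (0, 1, 1, 2)),
            ((0, 1, 2, 3), (0, 0, 0, 2), (0, 1, 2, 2)),
        }

    def test_k3_p5_step_by_step(self):
        assert triplets(g.heuristic(3, 5)) == [
            ((0, 1, 2, 3, 4), (0, 0, 0, 0, 3), (0, 2, 2, 3, 3)),
            ((1, 2, 3, 4, 0), (0, 0, 0, 2, 2), (0, 1, 2, 2, 3)),
            ((2, 3, 4, 1, 0), (0, 0, 1, 1, 1), (0, 1, 1, 2, 3)),
            ((3, 4, 2, 1, 0), (0, 0, 0, 0, 0), (0, 0, 3, 3, 3)),
        ]

    def test_k1_p2(self):
        assert triplets(g.heuristic(1, 2)) == [
            ((0, 1), (0, 1), (0, 1)),
            ((1, 0), (0, 0), (0, 1)),
        ]
        r = check_scheme(g.heuristic(1, 2))
        assert r.complete and r.nonredundant

    def test_k0(self):
        sch = g.heuristic(0, 2)
        assert triplets(sch) == [((0, 1), (0, 0), (0, 0))]

    def test_rejects_p_not_larger_than_k(self):
        with pytest.raises(SchemeError):
            g.heuristic(3, 3)

    def test_search_count_is_k_plus_one(self):
        for k in range(1, 7):
            assert len(g.heuristic(k, k + 2)) == k + 1


class TestHeuristicMatrix:
    def test_build_k3_p5(self):
        assert g.build_matrix(3, 5).rows == [
            [0, 2, 1, 3, 3], [1, 0, 2, 2, 2], [2, 1, 0, 1, 1], [3, 3, 3, 0, 0],
        ]

    def test_build_k2_p4_and_k1_p2(self):
        assert g.build_matrix(2, 4).rows == [[0, 1, 2, 2], [1, 0, 1, 1], [2, 2, 0, 0]]
        assert g.build_matrix(1, 2).rows == [[0, 1], [1, 0]]

    def test_adjust_permutes_column_two(self):
        m1 = g.adjust_matrix(g.build_matrix(3, 5))
        assert m1.rows == [
            [0, 2, 2, 3, 3], [1, 0, 1, 2, 2], [2, 1, 0, 1, 1], [3, 3, 3, 0, 0],
        ]

    def test_adjust_leaves_valid_matrix_unchanged(self):
        m = g.build_matrix(2, 4)
        assert g.adjust_matrix(m).rows == m.rows

    def test_adjust_idempotent(self):
        for k, p in [(3, 5), (4, 6), (5, 6), (6, 8)]:
            once = g.adjust_matrix(g.build_matrix(k, p))
            assert g.adjust_matrix(once).rows == once.rows

    def test_terminates_for_large_k(self):
        m = g.adjust_matrix(g.build_matrix(64, 66))
        assert m.row_conditions_ok()

    def test_budget_error_reports(self):
        with pytest.raises(SchemeError, match="budget"):
            g.adjust_matrix(g.build_matrix(8, 10), max_iterations=1)


class TestCompleteness:
    """All generators must produce valid, complete schemes (checked over
    all error distributions with at most k errors)."""

    @pytest.mark.parametrize("k", range(1, 5))
    def test_generators_complete(self, k):
        schemes = [
            g.backtracking(k), g.pigeonhole(k), g.pigeonhole_opt(k),
            g.suffix_filter(k), g.zero_one_star(k), g.zero_one_star_opt(k),
            g.heuristic(k, k + 1), g.heuristic(k, k + 2),
        ]
        for sch in schemes:
            r = check_scheme(sch)
            assert r.valid and r.complete, (sch.name, r.violations)

    def test_heuristic_large_k_sampled(self):
        """Monte-Carlo spot-check of the construction's completeness for
        high error counts (exhaustive enumeration is done separately up
        to k = 8; here random configurations probe k = 9..15)."""
        rng = random.Random(20240101)
        for k in range(9, 16):
            sch = g.heuristic(k, k + 2)
            p = k + 2
            for _ in range(200):
                total = rng.randint(0, k)
                cfg = [0] * p
                for _ in range(total):
                    cfg[rng.randrange(p)] += 1
                assert any(covers(s, tuple(cfg)) for s in sch), (k, cfg)
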