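import random

import pytest

from mcisp import (
    Assignment,
    GenomeDomainError,
    apply_all,
    bfs_exact_distance,
    cap,
    estimate_distance,
    make_genome,
    partition_lower_bound,
    remove_soft_breakpoint,
    sample_assignment,
    sort_by_reversals,
    sort_by_reversals_and_transpositions,
    sort_by_transpositions,
)
from mcisp.operations import apply_transposition
from mcisp.sorting import (
    UnreachableError,
    UnsortableError,
    _direct_cuts,
    sort_under_model,
)

from conftest import random_capped_pair


def _identity(n):
    return Assignment(tuple(range(1, n + 1)))


class TestRemoveSoftBreakpoint:
    def test_single_soft_breakpoint_closed(self):
        g = make_genome("ACBD", [2, 0, 0])
        h = make_genome("ABCD", [0, 0, 2])
        xi = Assignment((1, 3, 2, 4))
        op = remove_soft_breakpoint(g, h, xi)
        out = apply_transposition(g, op)
        before = len(_direct_cuts(g, h, list(xi.mapping)))
        from mcisp.sorting import _permute_assignment

        after = len(_direct_cuts(out, h, _permute_assignment(list(xi.mapping), op)))
        assert after < before

    def test_random_instances_strictly_decrease(self):
        rng = random.Random(5)
        done = 0
        while done < 60:
            g, h = random_capped_pair(rng, rng.randint(2, 5), 2, 3)
            xi = sample_assignment(g, h, None, rng)
            try:
                op = remove_soft_breakpoint(g, h, xi)
            except GenomeDomainError:
                continue
            from mcisp.sorting import _permute_assignment

            out = apply_transposition(g, op)
            before = len(_direct_cuts(g, h, list(xi.mapping)))
            after = len(
                _direct_cuts(out, h, _permute_assignment(list(xi.mapping), op))
            )
            assert after < before
            done += 1

    def test_sorted_pair_rejected(self, ex1):
        g, _ = ex1
        with pytest.raises(GenomeDomainError):
            remove_soft_breakpoint(g, g, _identity(g.n))


class TestSorters:
    def test_equal_genomes_empty(self, ex1):
        g, _ = ex1
        for sorter in (
            sort_by_transpositions,
            sort_by_reversals,
            sort_by_reversals_and_transpositions,
        ):
            res = sorter(g, g, _identity(g.n))
            assert res.operations == ()

    def test_fig_transposition_pair(self, fig4):
        g, h = fig4
        # assignment realized by the printed transposition τ(2,4,6)(2,2,0)
        xi = Assignment((1, 4, 5, 2, 3, 6))
        res = sort_by_transpositions(g, h, xi)
        assert apply_all(g, list(res.operations)) == h
        assert 1 <= len(res.operations) <= res.bound

    def test_fig_reversal_pair(self, fig5):
        g, h = fig5
        xi = Assignment((1, 4, 3, 2, 5, 6))
        res = sort_by_reversals(g, h, xi)
        assert apply_all(g, list(res.operations)) == h
        assert len(res.operations) <= res.bound

    def test_two_hard_breakpoints_two_transpositions(self):
        g = make_genome("ABCD", [2, 0, 0])
        h = make_genome("ABCD", [0, 0, 2])
        res = sort_by_transpositions(g, h, _identity(4))
        assert apply_all(g, list(res.operations)) == h
        assert len(res.operations) == 2 <= res.bound

    def test_too_small_to_sort(self):
        g = make_genome("IAF", [1, 0])
        h = make_genome("IAF", [0, 1])
        with pytest.raises(UnsortableError):
            sort_by_transpositions(g, h, _identity(3))

    def test_mixed_never_longer_than_reversal_only(self):
        rng = random.Random(21)
        for _ in range(40):
            g, h = random_capped_pair(rng, rng.randint(2, 5), 2, 3)
            xi = sample_assignment(g, h, None, rng)
            try:
                rev = sort_by_reversals(g, h, xi)
                mix = sort_by_reversals_and_transpositions(g, h, xi)
            except UnsortableError:
                continue
            assert len(mix.operations) <= len(rev.operations)

    def test_bounds_on_random_instances(self):
        """Soundness and the c+1 / 2c / 1.5c bounds, for every model."""
        rng = random.Random(31)
        for _ in range(80):
            g, h = random_capped_pair(rng, rng.randint(2, 6), 3, 4)
            for model in ("transposition", "reversal", "mixed"):
                xi = sample_assignment(g, h, None, rng)
                try:
                    res = sort_under_model(g, h, xi, model)
                except UnsortableError:
                    continue
                assert apply_all(g, list(res.operations)) == h
                assert len(res.operations) <= res.bound


class TestLowerBoundsAndOracle:
    def test_equal_genomes(self, ex1):
        g, _ = ex1
        assert partition_lower_bound(g, g, "transposition") == 0
        assert bfs_exact_distance(cap(make_genome("A", []), "I", "F", 0, 0),
                                  cap(make_genome("A", []), "I", "F", 0, 0),
                                  "reversal") == 0

    def test_worked_lower_bounds(self, ex1, ex2):
        assert partition_lower_bound(*ex1, "transposition") == 1  # ceil(3/3)
        assert partition_lower_bound(*ex2, "reversal") == 2  # ceil(3/2)

    def test_fig_pairs_distance_one(self, fig4, fig5):
        assert bfs_exact_distance(*fig4, "transposition", max_sum=20) == 1
        assert bfs_exact_distance(*fig5, "reversal", max_sum=20) == 1

    def test_guard(self):
        g = make_genome("ABCDEFG", [9] * 6)
        with pytest.raises(GenomeDomainError):
            bfs_exact_distance(g, g, "transposition")

    def test_unreachable_signalled(self):
        # with n = 4 no reversal can touch the middle region
        g = make_genome("IABF", [0, 1, 0])
        h = make_genome("IABF", [1, 0, 0])
        with pytest.raises(UnreachableError):
            bfs_exact_distance(g, h, "reversal")

    def test_sandwich_on_random_tiny_instances(self):
        """lower bound <= exact distance <= constructed length."""
        rng = random.Random(41)
        done = 0
        while done < 60:
            g, h = random_capped_pair(rng, rng.randint(2, 4), 2, 1)
            if g.intergenic_sum > 6:
                continue
            for model in ("transposition", "reversal", "mixed"):
                xi = sample_assignment(g, h, None, rng)
                try:
                    res = sort_under_model(g, h, xi, model)
                    d = bfs_exact_distance(g, h, model)
                except (UnsortableError, UnreachableError):
                    continue
                lb = partition_lower_bound(g, h, model)
                assert lb <= d
                assert d <= len(res.operations) or not res.operations
            done += 1


class TestEstimateDistance:
    def test_equal_genomes(self, ex1):
        g, _ = ex1
        est = estimate_distance(g, g, "transposition", 3, True, random.Random(0))
        assert est.min_distance == 0 and est.avg_distance == 0.0

    def test_min_le_avg_and_lower_bound(self):
        rng = random.Random(51)
        for _ in range(15):
            g, h = random_capped_pair(rng, 4, 2, 3)
            for model in ("transposition", "reversal", "mixed"):
                try:
                    est = estimate_distance(g, h, model, 5, True, random.Random(3))
                except UnsortableError:
                    continue
                assert est.min_distance <= est.avg_distance
                lb = partition_lower_bound(g, h, model)
                assert est.min_distance >= lb

    def test_partition_assignments_never_worse_in_expectation(self, ex3):
        g, h = ex3
        with_p = estimate_distance(g, h, "transposition", 20, True, random.Random(1))
        without = estimate_distance(g, h, "transposition", 20, False, random.Random(1))
        assert with_p.min_distance <= without.min_distance
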