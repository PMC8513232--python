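import math
import random
from collections import Counter

import pytest

from mcisp import (
    Assignment,
    GenomeDomainError,
    Partition,
    brute_force_min_partition,
    classify_breakpoints,
    compute_tmin_pair,
    induced_partition,
    make_genome,
    max_occ,
    mcisp_partition,
    rmcisp_partition,
    sample_assignment,
    validate_partition,
    weight,
)
from mcisp.partition import InstanceTooLarge, split_blocks

from conftest import capped_pair_family, random_capped_pair


class TestWeight:
    def test_worked_counts(self, ex3):
        g, h = ex3
        assert weight([g], [h], make_genome("CB", [1]), "direct") == 1
        assert weight([g], [h], make_genome("BC", [3]), "direct") == 0

    def test_identical_operands(self, ex3):
        g, _ = ex3
        assert weight([g], [g], make_genome("BA", [3]), "direct") == 0


class TestTmin:
    def test_printed_set(self, ex3):
        g, h = ex3
        got = {
            (e.subgenome.genes, e.subgenome.intergenic)
            for e in compute_tmin_pair(g, h, "direct")
        }
        expected = {
            (("B", "A"), (3,)),
            (("A", "B", "C"), (2, 3)),
            (("C", "B"), (1,)),
            (("I", "B", "C"), (1, 3)),
            (("C", "A"), (0,)),
            (("B", "B"), (4,)),
        }
        assert got == expected

    def test_break_offsets_are_first_region(self, ex3):
        g, h = ex3
        assert {e.break_offset for e in compute_tmin_pair(g, h, "direct")} == {1}

    def test_identical_genomes_empty(self, ex3):
        g, _ = ex3
        assert compute_tmin_pair(g, g, "direct") == set()

    def test_balanced_subgenome_excluded(self, ex3):
        g, h = ex3
        ab = (("A", "B"), (2,))
        assert ab not in {
            (e.subgenome.genes, e.subgenome.intergenic)
            for e in compute_tmin_pair(g, h, "direct")
        }

    def test_unbalanced_rejected(self):
        with pytest.raises(GenomeDomainError):
            compute_tmin_pair(make_genome("AB", [1]), make_genome("AB", [2]))


class TestGreedyPartition:
    def test_printed_trace_endpoint(self, ex3):
        g, h = ex3
        p = mcisp_partition(g, h)
        assert p.cost == 4
        assert [b.genes for b in split_blocks(g, p.source_breakpoints)] == [
            ("I",), ("B",), ("A",), ("B", "C"), ("B", "C", "F"),
        ]
        assert [b.genes for b in split_blocks(h, p.target_breakpoints)] == [
            ("I",), ("B", "C"), ("A",), ("B",), ("B", "C", "F"),
        ]
        assert validate_partition(p, g, h)

    def test_identical_genomes_single_block(self, ex3):
        g, _ = ex3
        assert mcisp_partition(g, g).cost == 0

    def test_printed_bound(self, ex3):
        g, h = ex3
        p = mcisp_partition(g, h)
        k = max_occ(g)
        tmin = compute_tmin_pair(g, h, "direct")
        assert p.cost <= 2 * k * len(tmin) == 36

    def test_reverse_mode_on_reversed_genome(self, ex1):
        g, _ = ex1
        from mcisp import reverse_genome

        assert rmcisp_partition(g, reverse_genome(g)).cost == 0

    def test_reverse_mode_worked_pair(self, ex2):
        g, h = ex2
        p = rmcisp_partition(g, h)
        assert validate_partition(p, g, h)
        assert p.cost >= 3  # brute-force minimum
        k = max_occ(g)
        assert p.cost <= 2 * k * len(compute_tmin_pair(g, h, "reverse"))


class TestValidation:
    def test_printed_direct_partition(self, ex1):
        g, h = ex1
        p = Partition(frozenset({3, 4, 6}), frozenset({1, 3, 6}), "direct")
        assert validate_partition(p, g, h)

    def test_perturbed_sizes_rejected(self, ex1):
        g, h = ex1
        g2 = make_genome(g.genes, (2,) + g.intergenic[1:])
        p = Partition(frozenset({3, 4, 6}), frozenset({1, 3, 6}), "direct")
        assert not validate_partition(p, g2, h)

    def test_printed_reverse_partition_needs_reverse_mode(self, ex2):
        g, h = ex2
        cuts = (frozenset({3, 4, 7}), frozenset({1, 4, 7}))
        assert validate_partition(Partition(*cuts, "reverse"), g, h)
        assert not validate_partition(Partition(*cuts, "direct"), g, h)


class TestInducedPartition:
    def test_fig_assignment_reproduces_partition(self, ex1):
        g, h = ex1
        xi = Assignment((4, 5, 6, 1, 2, 3, 7, 8))
        p = induced_partition(g, h, xi, "direct")
        assert p.source_breakpoints == frozenset({3, 4, 6})
        assert p.target_breakpoints == frozenset({1, 3, 6})
        assert p.cost == 3

    def test_identity_assignment_no_cuts(self, ex1):
        g, _ = ex1
        xi = Assignment(tuple(range(1, g.n + 1)))
        assert induced_partition(g, g, xi, "direct").cost == 0

    def test_size_mismatch_forces_cuts(self):
        g = make_genome("ABC", [0, 2])
        h = make_genome("ABC", [1, 1])
        p = induced_partition(g, h, Assignment((1, 2, 3)), "direct")
        assert p.source_breakpoints == frozenset({1, 2})

    def test_minimality(self, ex1):
        """Merging any two consecutive blocks breaks validity."""
        g, h = ex1
        xi = Assignment((4, 5, 6, 1, 2, 3, 7, 8))
        p = induced_partition(g, h, xi, "direct")
        for c in p.source_breakpoints:
            merged = Partition(
                p.source_breakpoints - {c}, p.target_breakpoints, "direct"
            )
            assert not validate_partition(merged, g, h)


class TestClassifyBreakpoints:
    def test_fig_classification(self, ex1):
        g, h = ex1
        xi = Assignment((4, 5, 6, 1, 2, 3, 7, 8))
        p = induced_partition(g, h, xi, "direct")
        classes = classify_breakpoints(g, h, xi, p)
        by_pos = {c.position: c for c in classes}
        assert by_pos[4].kind == "hard" and by_pos[4].charge == "undercharged"
        assert by_pos[3].kind == "soft" and by_pos[6].kind == "soft"
        assert sum(1 for c in classes if c.kind == "hard") == 1

    def test_over_and_under(self):
        g = make_genome("ABC", [0, 2])
        h = make_genome("ABC", [1, 1])
        xi = Assignment((1, 2, 3))
        p = induced_partition(g, h, xi, "direct")
        classes = {c.position: c.charge for c in classify_breakpoints(g, h, xi, p)}
        assert classes == {1: "undercharged", 2: "overcharged"}

    def test_no_breakpoints(self, ex1):
        g, _ = ex1
        xi = Assignment(tuple(range(1, g.n + 1)))
        p = induced_partition(g, g, xi, "direct")
        assert classify_breakpoints(g, g, xi, p) == []


class TestBruteForce:
    def test_worked_minimums(self, ex1, ex2):
        assert brute_force_min_partition(*ex1, "direct").cost == 3
        assert brute_force_min_partition(*ex2, "reverse").cost == 3

    def test_identical(self, ex1):
        g, _ = ex1
        assert brute_force_min_partition(g, g, "direct").cost == 0

    def test_guard(self):
        g = make_genome("ABCDEFGHIJKLM", [0] * 12)
        with pytest.raises(InstanceTooLarge):
            brute_force_min_partition(g, g, "direct")

    def test_result_validates(self, ex2):
        g, h = ex2
        for mode in ("direct", "reverse"):
            p = brute_force_min_partition(g, h, mode)
            assert validate_partition(p, g, h)


class TestSampleAssignment:
    def test_all_distinct_unique(self):
        g = make_genome("ABC", [1, 2])
        h = make_genome("CAB", [2, 1])
        for seed in range(5):
            xi = sample_assignment(g, h, None, random.Random(seed))
            assert xi.mapping == (2, 3, 1)

    def test_uniform_over_label_bijections(self, ex3):
        """B (x3) and C (x2) give 3!*2! = 12 equally likely assignments."""
        g, h = ex3
        rng = random.Random(12345)
        counts = Counter(
            sample_assignment(g, h, None, rng).mapping for _ in range(12000)
        )
        assert len(counts) == 12
        expect = 12000 / 12
        sd = math.sqrt(12000 * (1 / 12) * (11 / 12))
        for v in counts.values():
            assert abs(v - expect) <= 3 * sd

    def test_partition_consistent_block_matching(self, ex1):
        g, h = ex1
        p = Partition(frozenset({3, 4, 6}), frozenset({1, 3, 6}), "direct")
        seen = set()
        rng = random.Random(7)
        for _ in range(200):
            xi = sample_assignment(g, h, p, rng)
            xi.validate(g, h)
            seen.add(xi.mapping)
            # induced partition of a consistent assignment refines into p
            ip = induced_partition(g, h, xi, "direct")
            assert ip.source_breakpoints <= p.source_breakpoints
        # the two [D E] blocks can map to target blocks 2 and 4 either way
        assert len(seen) == 2


class TestFamilyProperties:
    def test_dual_route_validation_and_bound(self):
        """Greedy partitions validate by both routes and stay within
        2k times the exhaustive optimum over the capped family."""
        n_checked = 0
        for g, h in capped_pair_family(4, "ABC", 3, region_samples=1):
            k = max_occ(g)
            for mode, algo in (("direct", mcisp_partition), ("reverse", rmcisp_partition)):
                p = algo(g, h)
                assert validate_partition(p, g, h)
                opt = brute_force_min_partition(g, h, mode).cost
                assert p.cost <= 2 * k * max(opt, 0)
                assert opt <= p.cost
                assert len(p.source_breakpoints) == len(p.target_breakpoints)
            n_checked += 1
        assert n_checked > 200

    def test_randomized_larger_instances(self):
        rng = random.Random(99)
        for _ in range(120):
            g, h = random_capped_pair(rng, rng.randint(4, 7), 3, 4)
            for mode, algo in (("direct", mcisp_partition), ("reverse", rmcisp_partition)):
                p = algo(g, h)
                assert validate_partition(p, g, h)
                assert p.cost <= 2 * max_occ(g) * len(
                    compute_tmin_pair(g, h, mode)
                ) or p.cost == 0
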