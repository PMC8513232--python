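"""Common intergenic string partitions (MCISP / RMCISP).

A *direct* intergenic partition of two balanced genomes cuts both into
the same multiset of blocks (gene labels AND intergenic sizes must
match); a *reverse* partition additionally allows a block to appear
reversed on the other side.  The cost is the number of cuts, equal on
both sides.  Finding a minimum-cost partition is NP-hard; the
greedy breakpoint-insertion algorithm implemented here achieves a
``2k`` approximation factor, ``k`` being the maximum multiplicity of a
gene label.

The module also provides the assignment-induced minimal partition,
breakpoint classification (soft / hard, over- / undercharged), an
exhaustive small-instance oracle, and uniform sampling of orthologous
assignments.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

from .core import (
    Genome,
    GenomeDomainError,
    combine_all,
    is_balanced,
    max_occ,
    reverse_genome,
    subgenome,
)

PartitionMode = Literal["direct", "reverse"]

# keys used to hash genomes (and their congruence classes)
_Key = tuple[tuple[str, ...], tuple[int, ...]]


def _key(g: Genome) -> _Key:
    return (g.genes, g.intergenic)


def _canon_key(g: Genome, mode: PartitionMode) -> _Key:
    """Hashable identity of ``g``: exact in direct mode, the
    lexicographically smaller of the two orientations in reverse mode."""
    k = _key(g)
    if mode == "direct":
        return k
    rk = _key(reverse_genome(g))
    return min(k, rk)


def _genome_from_key(k: _Key) -> Genome:
    return Genome(k[0], k[1])


# ---------------------------------------------------------------------------
# Assignments


@dataclass(frozen=True)
class Assignment:
    """An orthologous assignment ξ: gene ``i`` of G ↔ gene ``mapping[i-1]``
    of H.  Label-preserving bijection over 1-based positions."""

    mapping: tuple[int, ...]

    def pos(self, i: int) -> int:
        return self.mapping[i - 1]

    def validate(self, g: Genome, h: Genome) -> None:
        n = g.n
        if h.n != n or len(self.mapping) != n:
            raise GenomeDomainError("assignment size does not match the genomes")
        if sorted(self.mapping) != list(range(1, n + 1)):
            raise GenomeDomainError("assignment is not a bijection over positions")
        for i in range(1, n + 1):
            if g.gene(i) != h.gene(self.pos(i)):
                raise GenomeDomainError(
                    f"assignment maps gene {i} ({g.gene(i)}) to a gene with "
                    f"label {h.gene(self.pos(i))}"
                )

    def image_region(self, h: Genome, i: int) -> Optional[int]:
        """ξ(Ŝ_i): the size of the region after gene ξ(S_i) in H (None
        when ξ(S_i) is the last gene)."""
        p = self.pos(i)
        return h.region(p) if p <= h.n - 1 else None


def identity_assignment(n: int) -> Assignment:
    return Assignment(tuple(range(1, n + 1)))


# ---------------------------------------------------------------------------
# Partitions


@dataclass(frozen=True)
class Partition:
    """A matched pair of block decompositions of two genomes.

    ``source_breakpoints`` / ``target_breakpoints`` are the 1-based
    intergenic positions removed from G and H.  ``block_map`` lists, for
    each target block (in order), the matching source-block index and
    whether the match is reversed.
    """

    source_breakpoints: frozenset[int]
    target_breakpoints: frozenset[int]
    mode: PartitionMode
    block_map: Optional[tuple[tuple[int, bool], ...]] = None

    @property
    def cost(self) -> int:
        return len(self.source_breakpoints)


def split_blocks(g: Genome, cuts: frozenset[int] | set[int]) -> list[Genome]:
    """Blocks of ``g`` obtained by removing the intergenic regions in
    ``cuts`` (1-based positions)."""
    for c in cuts:
        if not 1 <= c <= g.n - 1:
            raise GenomeDomainError(f"cut position {c} out of range 1..{g.n - 1}")
    bounds = sorted(cuts)
    blocks = []
    start = 1
    for c in bounds:
        blocks.append(subgenome(g, start, c))
        start = c + 1
    blocks.append(subgenome(g, start, g.n))
    return blocks


def block_ranges(g: Genome, cuts: frozenset[int] | set[int]) -> list[tuple[int, int]]:
    """1-based (start, end) gene ranges of the blocks cut at ``cuts``."""
    bounds = sorted(cuts)
    ranges = []
    start = 1
    for c in bounds:
        ranges.append((start, c))
        start = c + 1
    ranges.append((start, g.n))
    return ranges


def _match_blocks(
    sblocks: Sequence[Genome], pblocks: Sequence[Genome], mode: PartitionMode
) -> Optional[tuple[tuple[int, bool], ...]]:
    """Greedy class matching: returns for each target block the index of
    an equal (or congruent) source block, or None if no bijection exists."""
    pool: dict[_Key, list[int]] = {}
    for idx, blk in enumerate(sblocks):
        pool.setdefault(_canon_key(blk, mode), []).append(idx)
    if len(sblocks) != len(pblocks):
        return None
    out = []
    for blk in pblocks:
        k = _canon_key(blk, mode)
        avail = pool.get(k)
        if not avail:
            return None
        idx = avail.pop()
        reversed_match = sblocks[idx] != blk
        out.append((idx, reversed_match))
    return tuple(out)


# ---------------------------------------------------------------------------
# Occurrence weights and T_min


def weight(
    ss: Sequence[Genome], ps: Sequence[Genome], x: Genome, mode: str = "direct"
) -> int:
    """weight(𝕊, ℙ, X): occurrences of X in the blocks of 𝕊 minus those
    in the blocks of ℙ (congruent windows count in ``congruent`` mode)."""
    from .core import count_occurrences

    return sum(count_occurrences(b, x, mode) for b in ss) - sum(  # type: ignore[arg-type]
        count_occurrences(b, x, mode) for b in ps  # type: ignore[arg-type]
    )


def _window_weights(
    sblocks: Sequence[Genome], pblocks: Sequence[Genome], mode: PartitionMode
) -> dict[_Key, int]:
    """Weights of every size-≥2 subgenome of the current blocks, keyed
    canonically.  Only windows inside a single block are counted."""
    counts: dict[_Key, int] = {}
    for blocks, sign in ((sblocks, 1), (pblocks, -1)):
        for blk in blocks:
            for i in range(1, blk.n):
                for j in range(i + 1, blk.n + 1):
                    k = _canon_key(subgenome(blk, i, j), mode)
                    counts[k] = counts.get(k, 0) + sign
    return {k: w for k, w in counts.items() if w != 0}


def _minimal_keys(nonzero: dict[_Key, int], mode: PartitionMode) -> list[_Key]:
    """Keys of T whose genomes contain no strictly smaller member of T."""
    out = []
    for k in nonzero:
        x = _genome_from_key(k)
        minimal = True
        for i in range(1, x.n):
            for j in range(i + 1, x.n + 1):
                if j - i + 1 == x.n:
                    continue
                if _canon_key(subgenome(x, i, j), mode) in nonzero:
                    minimal = False
                    break
            if not minimal:
                break
        if minimal:
            out.append(k)
    return out


@dataclass(frozen=True)
class TminEntry:
    """A containment-minimal subgenome with unbalanced occurrence counts.

    ``break_offset`` designates the intergenic region of ``subgenome``
    (1-based, within the block) cut whenever the greedy algorithm breaks
    an occurrence of this entry.
    """

    subgenome: Genome
    weight: int
    break_offset: int


def compute_tmin(
    ss: Sequence[Genome], ps: Sequence[Genome], mode: PartitionMode = "direct"
) -> set[TminEntry]:
    """T_min of two block sequences: all subgenomes with non-zero weight
    containing no strictly smaller non-zero-weight subgenome.  The break
    offset of a fresh entry is its first intergenic region."""
    occ_mode = "direct" if mode == "direct" else "congruent"
    del occ_mode  # canonical keys already encode the mode
    nonzero = _window_weights(ss, ps, mode)
    return {
        TminEntry(_genome_from_key(k), nonzero[k], 1)
        for k in _minimal_keys(nonzero, mode)
    }


def compute_tmin_pair(g: Genome, h: Genome, mode: PartitionMode = "direct") -> set[TminEntry]:
    if not is_balanced(g, h):
        raise GenomeDomainError("T_min requires balanced genomes")
    return compute_tmin([g], [h], mode)


# ---------------------------------------------------------------------------
# The greedy 2k-approximation (Algorithm 1 and its reverse adaptation)


def _occurrences_with_orientation(
    g: Genome, x: Genome, mode: PartitionMode
) -> list[tuple[int, bool]]:
    """(start, reversed) windows of ``g`` matching ``x``; the direct
    orientation wins when a palindromic window matches both ways."""
    m = x.n
    rx = reverse_genome(x)
    hits = []
    for i in range(1, g.n - m + 2):
        w = subgenome(g, i, i + m - 1)
        if w == x:
            hits.append((i, False))
        elif mode == "reverse" and w == rx:
            hits.append((i, True))
    return hits


def _entrant_break_offset(
    x: Genome,
    mode: PartitionMode,
    history: list[tuple[str, int]],
    g: Genome,
    h: Genome,
) -> int:
    """Break offset for a subgenome acquiring non-zero weight mid-run:
    the offset (within ``x``) of the chronologically first inserted
    breakpoint that falls inside an occurrence of ``x`` in G or H."""
    m = x.n
    occs = {
        "S": _occurrences_with_orientation(g, x, mode),
        "P": _occurrences_with_orientation(h, x, mode),
    }
    for side, t in history:
        for s, rev in occs[side]:
            if s <= t <= s + m - 2:
                off = t - s + 1
                return m - off if rev else off
    return 1


def greedy_partition(g: Genome, h: Genome, mode: PartitionMode) -> Partition:
    """Greedy breakpoint insertion: repeatedly cut one occurrence of a
    containment-minimal unbalanced subgenome, always at the breakpoint
    associated with that subgenome, until every subgenome has weight
    zero over the current blocks.  Deterministic tie-breaking: the
    smallest entry of T_min (by size, then gene labels, then intergenic
    sizes) is processed first, and the leftmost eligible occurrence on
    the side with excess occurrences is cut.  The number of cuts is at
    most ``2k |T_min(G, H)|`` with ``k = occ(S)``.
    """
    if not is_balanced(g, h):
        raise GenomeDomainError("partition requires balanced genomes")
    cuts_s: set[int] = set()
    cuts_p: set[int] = set()
    history: list[tuple[str, int]] = []
    break_offsets: dict[_Key, int] = {}
    for entry in compute_tmin([g], [h], mode):
        break_offsets[_canon_key(entry.subgenome, mode)] = 1

    max_iter = 2 * (g.n - 1) + 1
    for _ in range(max_iter):
        sblocks = split_blocks(g, cuts_s)
        pblocks = split_blocks(h, cuts_p)
        nonzero = _window_weights(sblocks, pblocks, mode)
        if not nonzero:
            break
        tmin_keys = _minimal_keys(nonzero, mode)
        xk = min(tmin_keys, key=lambda k: (len(k[0]), k[0], k[1]))
        x = _genome_from_key(xk)
        w = nonzero[xk]

        if xk not in break_offsets:
            break_offsets[xk] = _entrant_break_offset(x, mode, history, g, h)
        b = break_offsets[xk]

        side = "S" if w > 0 else "P"
        genome = g if side == "S" else h
        cuts = cuts_s if side == "S" else cuts_p
        ranges = block_ranges(genome, cuts)
        candidates: list[tuple[int, bool, int]] = []  # (start, reversed, cut pos)
        for lo, hi in ranges:
            blk = subgenome(genome, lo, hi)
            for s_local, rev in _occurrences_with_orientation(blk, x, mode):
                s = lo + s_local - 1
                t = s + (x.n - b if rev else b) - 1
                candidates.append((s, rev, t))
        if not candidates:  # pragma: no cover - contradicts Lemma 13
            raise AssertionError(
                f"no occurrence of {x} available to cut on side {side}"
            )
        s, rev, t = min(candidates, key=lambda c: (c[0], c[1]))
        cuts.add(t)
        history.append((side, t))
    else:  # pragma: no cover
        raise AssertionError("breakpoint insertion exceeded its iteration cap")

    sblocks = split_blocks(g, cuts_s)
    pblocks = split_blocks(h, cuts_p)
    bm = _match_blocks(sblocks, pblocks, mode)
    assert bm is not None, "greedy partition failed to produce matching blocks"
    return Partition(frozenset(cuts_s), frozenset(cuts_p), mode, bm)


def mcisp_partition(g: Genome, h: Genome) -> Partition:
    """Direct intergenic partition with cost ≤ 2k·|T_min(G, H)|."""
    return greedy_partition(g, h, "direct")


def rmcisp_partition(g: Genome, h: Genome) -> Partition:
    """Reverse intergenic partition with cost ≤ 2k·|T_min(G, H)| (blocks
    may match up to reversal)."""
    return greedy_partition(g, h, "reverse")


# ---------------------------------------------------------------------------
# Validation


def validate_partition(p: Partition, g: Genome, h: Genome) -> bool:
    """Check the partition conditions by two independent routes.

    Route 1 matches blocks explicitly (a bijection φ with equality, or
    congruence in reverse mode).  Route 2 checks that every subgenome of
    every block has weight zero across the two sides.  The two verdicts
    are asserted to agree.
    """
    try:
        sblocks = split_blocks(g, p.source_breakpoints)
        pblocks = split_blocks(h, p.target_breakpoints)
    except GenomeDomainError:
        return False
    gaps_s = [g.region(c) for c in sorted(p.source_breakpoints)]
    gaps_p = [h.region(c) for c in sorted(p.target_breakpoints)]
    cond12 = combine_all(sblocks, gaps_s) == g and combine_all(pblocks, gaps_p) == h

    by_matching = _match_blocks(sblocks, pblocks, p.mode) is not None
    by_weights = not _window_weights(sblocks, pblocks, p.mode)
    assert by_matching == by_weights, (
        "block-matching and weight-zero validation disagree"
    )
    return cond12 and by_matching


# ---------------------------------------------------------------------------
# Assignment-induced minimal partitions


def induced_partition(
    g: Genome, h: Genome, xi: Assignment, mode: PartitionMode = "direct"
) -> Partition:
    """The unique minimal partition induced by an orthologous assignment.

    In direct mode the region after gene ``i`` survives iff ξ maps
    ``i, i+1`` to consecutive positions of H in the same order and the
    two intergenic sizes agree.  In reverse mode a maximal run of genes
    may instead be consistently reverse-adjacent; a direction flip
    forces a cut.
    """
    xi.validate(g, h)
    if not is_balanced(g, h):
        raise GenomeDomainError("induced partition requires balanced genomes")
    n = g.n
    cuts_s: set[int] = set()
    direction = 0  # +1 forward run, -1 reversed run, 0 undecided
    for i in range(1, n):
        p, q = xi.pos(i), xi.pos(i + 1)
        fwd = q == p + 1 and g.region(i) == h.region(p)
        rev = (
            mode == "reverse"
            and q == p - 1
            and g.region(i) == h.region(q)
        )
        if direction >= 0 and fwd:
            direction = 1
        elif direction <= 0 and rev:
            direction = -1
        else:
            cuts_s.add(i)
            direction = 0

    # target cuts: H regions interior to no block image survive
    keep: set[int] = set()
    for lo, hi in block_ranges(g, cuts_s):
        positions = [xi.pos(i) for i in range(lo, hi + 1)]
        for p in range(min(positions), max(positions)):
            keep.add(p)
    cuts_p = frozenset(set(range(1, n)) - keep)

    sblocks = split_blocks(g, cuts_s)
    pblocks = split_blocks(h, cuts_p)
    bm = _match_blocks(sblocks, pblocks, mode)
    assert bm is not None, "induced partition blocks do not match"
    return Partition(frozenset(cuts_s), cuts_p, mode, bm)


BreakpointKind = Literal["soft", "hard"]
Charge = Literal["overcharged", "undercharged", "none"]


@dataclass(frozen=True)
class BreakpointClass:
    position: int
    kind: BreakpointKind
    charge: Charge


def classify_breakpoints(
    g: Genome, h: Genome, xi: Assignment, p: Partition
) -> list[BreakpointClass]:
    """Classify each source breakpoint of an induced partition.

    A breakpoint after gene ``i`` is *hard* when ξ(S_i) and ξ(S_{i+1})
    are adjacent in H, *soft* otherwise.  A hard breakpoint is
    overcharged when its region holds more nucleotides than ξ(Ŝ_i) and
    undercharged when it holds fewer.
    """
    out = []
    for i in sorted(p.source_breakpoints):
        a, b = xi.pos(i), xi.pos(i + 1)
        hard = abs(a - b) == 1
        charge: Charge = "none"
        if hard:
            target = xi.image_region(h, i)
            if target is not None:
                if g.region(i) > target:
                    charge = "overcharged"
                elif g.region(i) < target:
                    charge = "undercharged"
        out.append(BreakpointClass(i, "hard" if hard else "soft", charge))
    return out


# ---------------------------------------------------------------------------
# Exhaustive small-instance oracle


class InstanceTooLarge(GenomeDomainError):
    pass


def _tile(
    h: Genome,
    start: int,
    pool: dict[_Key, list[int]],
    sblocks: Sequence[Genome],
    mode: PartitionMode,
    acc: list[tuple[int, int, bool]],
) -> Optional[list[tuple[int, int, bool]]]:
    """Backtracking cover of H from gene ``start`` with unused source
    blocks; returns (start, block index, reversed) steps or None."""
    if start == h.n + 1:
        return list(acc)
    for k, idxs in pool.items():
        if not idxs:
            continue
        blk = sblocks[idxs[-1]]
        end = start + blk.n - 1
        if end > h.n:
            continue
        window = subgenome(h, start, end)
        rev_ok = mode == "reverse" and window == reverse_genome(blk)
        if window == blk or rev_ok:
            idx = idxs.pop()
            acc.append((start, idx, window != blk))
            res = _tile(h, end + 1, pool, sblocks, mode, acc)
            if res is not None:
                return res
            acc.pop()
            idxs.append(idx)
    return None


def brute_force_min_partition(
    g: Genome, h: Genome, mode: PartitionMode = "direct", guard: int = 12
) -> Partition:
    """Provably minimum-cost partition by exhaustive search.

    Source cut subsets are enumerated in increasing cardinality; each is
    tested by backtracking-tiling H with the resulting block multiset.
    Exponential — guarded to ``n ≤ guard``.
    """
    from itertools import combinations

    if not is_balanced(g, h):
        raise GenomeDomainError("partition requires balanced genomes")
    n = g.n
    if n > guard:
        raise InstanceTooLarge(
            f"instance too large for exhaustive search (n={n} > {guard})"
        )
    for c in range(n):
        for cut_tuple in combinations(range(1, n), c):
            cuts = frozenset(cut_tuple)
            sblocks = split_blocks(g, cuts)
            pool: dict[_Key, list[int]] = {}
            for idx, blk in enumerate(sblocks):
                pool.setdefault(_canon_key(blk, mode), []).append(idx)
            tiling = _tile(h, 1, pool, sblocks, mode, [])
            if tiling is None:
                continue
            cuts_p = frozenset(
                start - 1 for start, _, _ in tiling if start > 1
            )
            bm = tuple((idx, rev) for _, idx, rev in tiling)
            return Partition(cuts, cuts_p, mode, bm)
    raise AssertionError("unreachable: the trivial full cut always tiles")


# ---------------------------------------------------------------------------
# Assignment sampling


def sample_assignment(
    g: Genome,
    h: Genome,
    p: Optional[Partition],
    rng: random.Random,
) -> Assignment:
    """Uniformly sample an orthologous assignment.

    Without a partition, each gene family is matched by an independent
    uniform random bijection between its positions in G and in H.  With
    a partition, matched block classes are paired by a uniform random
    bijection and genes map positionally inside each matched pair
    (mirrored for a reversed match); palindromic pairs choose an
    orientation uniformly.
    """
    if not is_balanced(g, h):
        raise GenomeDomainError("assignment sampling requires balanced genomes")
    n = g.n
    mapping = [0] * n

    if p is None:
        by_label_h: dict[str, list[int]] = {}
        for j in range(1, n + 1):
            by_label_h.setdefault(h.gene(j), []).append(j)
        by_label_g: dict[str, list[int]] = {}
        for i in range(1, n + 1):
            by_label_g.setdefault(g.gene(i), []).append(i)
        for label in sorted(by_label_g):
            gpos = by_label_g[label]
            hpos = rng.sample(by_label_h[label], len(gpos))
            for i, j in zip(gpos, hpos):
                mapping[i - 1] = j
        return Assignment(tuple(mapping))

    sranges = block_ranges(g, p.source_breakpoints)
    pranges = block_ranges(h, p.target_breakpoints)
    sblocks = split_blocks(g, p.source_breakpoints)
    pblocks = split_blocks(h, p.target_breakpoints)
    classes_s: dict[_Key, list[int]] = {}
    classes_p: dict[_Key, list[int]] = {}
    for idx, blk in enumerate(sblocks):
        classes_s.setdefault(_canon_key(blk, p.mode), []).append(idx)
    for idx, blk in enumerate(pblocks):
        classes_p.setdefault(_canon_key(blk, p.mode), []).append(idx)
    if sorted(classes_s) != sorted(classes_p) or any(
        len(classes_s[k]) != len(classes_p[k]) for k in classes_s
    ):
        raise GenomeDomainError("partition blocks do not match between genomes")

    for k in sorted(classes_s):
        sidx = classes_s[k]
        pidx = rng.sample(classes_p[k], len(sidx))
        for sb, pb in zip(sidx, pidx):
            s_lo, s_hi = sranges[sb]
            p_lo, p_hi = pranges[pb]
            direct_ok = sblocks[sb] == pblocks[pb]
            rev_ok = p.mode == "reverse" and sblocks[sb] == reverse_genome(
                pblocks[pb]
            )
            if direct_ok and rev_ok:
                use_rev = rng.random() < 0.5
            elif direct_ok:
                use_rev = False
            else:
                use_rev = True
            for t in range(s_hi - s_lo + 1):
                mapping[s_lo + t - 1] = (p_hi - t) if use_rev else (p_lo + t)
    xi = Assignment(tuple(mapping))
    xi.validate(g, h)
    return xi


def partition_summary(g: Genome, h: Genome, p: Partition) -> dict[str, int]:
    """One-line summary numbers: cost, k = occ(S), |T_min(G, H)|."""
    return {
        "cost": p.cost,
        "k": max_occ(g),
        "tmin": len(compute_tmin_pair(g, h, p.mode)),
    }
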