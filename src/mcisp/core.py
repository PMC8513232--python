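"""Genome model: gene strings interleaved with intergenic-region sizes.

A genome of size ``n`` is an alternating sequence of ``n`` genes and
``n - 1`` intergenic regions.  Genes are opaque labels (strings compared
by equality); each intergenic region is modeled only by its size in
nucleotides, a non-negative integer.  All public indices are 1-based:
gene ``i`` runs from 1 to ``n`` and intergenic region ``i`` lies between
genes ``i`` and ``i + 1``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterator, Literal, Sequence


class GenomeStructureError(ValueError):
    """Inconsistent gene/intergenic lengths or malformed construction."""


class GenomeDomainError(ValueError):
    """Arguments outside the valid domain (bad index, negative size...)."""


@dataclass(frozen=True)
class Genome:
    """An immutable genome ``(S, Ŝ)``: gene labels plus intergenic sizes."""

    genes: tuple[str, ...]
    intergenic: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.genes) < 1:
            raise GenomeStructureError("a genome must contain at least one gene")
        if len(self.intergenic) != len(self.genes) - 1:
            raise GenomeStructureError(
                f"expected {len(self.genes) - 1} intergenic sizes for "
                f"{len(self.genes)} genes, got {len(self.intergenic)}"
            )
        for v in self.intergenic:
            if v < 0:
                raise GenomeDomainError(f"negative intergenic size {v}")

    @property
    def n(self) -> int:
        return len(self.genes)

    def gene(self, i: int) -> str:
        """Gene at 1-based position ``i``."""
        if not 1 <= i <= self.n:
            raise GenomeDomainError(f"gene index {i} out of range 1..{self.n}")
        return self.genes[i - 1]

    def region(self, i: int) -> int:
        """Size of the intergenic region between genes ``i`` and ``i + 1``."""
        if not 1 <= i <= self.n - 1:
            raise GenomeDomainError(
                f"intergenic index {i} out of range 1..{self.n - 1}"
            )
        return self.intergenic[i - 1]

    @property
    def intergenic_sum(self) -> int:
        return sum(self.intergenic)

    def label_counts(self) -> Counter[str]:
        return Counter(self.genes)

    def __len__(self) -> int:
        return self.n

    def __str__(self) -> str:
        return (
            "([" + " ".join(self.genes) + "],["
            + " ".join(str(v) for v in self.intergenic) + "])"
        )


def make_genome(genes: Sequence[str], intergenic: Sequence[int]) -> Genome:
    """Build an immutable genome from a gene sequence and intergenic sizes."""
    return Genome(tuple(genes), tuple(int(v) for v in intergenic))


def reverse_genome(g: Genome) -> Genome:
    """rev(G): both the gene string and the intergenic list reversed."""
    return Genome(g.genes[::-1], g.intergenic[::-1])


def congruent(g: Genome, h: Genome) -> bool:
    """True iff G = H or G = rev(H), comparing genes and intergenic sizes."""
    return g == h or g == reverse_genome(h)


def subgenome(g: Genome, i: int, j: int) -> Genome:
    """The portion of ``g`` between genes ``i`` and ``j`` (1-based, inclusive)."""
    if not (1 <= i <= j <= g.n):
        raise GenomeDomainError(
            f"invalid subgenome range ({i},{j}) for size {g.n}"
        )
    return Genome(g.genes[i - 1 : j], g.intergenic[i - 1 : j - 1])


def combine(g: Genome, h: Genome, gap: int) -> Genome:
    """Concatenate two genomes, inserting an intergenic region of size ``gap``."""
    if gap < 0:
        raise GenomeDomainError(f"negative combination gap {gap}")
    return Genome(g.genes + h.genes, g.intergenic + (gap,) + h.intergenic)


def combine_all(blocks: Sequence[Genome], gaps: Sequence[int]) -> Genome:
    """Fold ``combine`` over a block sequence with one gap per junction."""
    if len(gaps) != len(blocks) - 1:
        raise GenomeStructureError(
            f"need {len(blocks) - 1} gaps for {len(blocks)} blocks, got {len(gaps)}"
        )
    out = blocks[0]
    for blk, gap in zip(blocks[1:], gaps):
        out = combine(out, blk, gap)
    return out


def is_balanced(g: Genome, h: Genome) -> bool:
    """Same gene-label multiset and equal total intergenic size."""
    return g.label_counts() == h.label_counts() and g.intergenic_sum == h.intergenic_sum


def is_cotailed(g: Genome, h: Genome) -> bool:
    """Same first and last gene (guaranteed by capping both with one pair)."""
    return g.genes[0] == h.genes[0] and g.genes[-1] == h.genes[-1]


def max_occ(g: Genome) -> int:
    """occ(S): the maximum multiplicity of any gene label."""
    return max(g.label_counts().values())


Mode = Literal["direct", "congruent"]


def occurrence_positions(g: Genome, x: Genome, mode: Mode = "direct") -> list[int]:
    """1-based start positions of subgenomes of ``g`` matching ``x``.

    In ``direct`` mode a window matches iff it equals ``x``; in
    ``congruent`` mode iff it equals ``x`` or ``rev(x)``.  A window is
    counted once even when ``x`` is a palindrome.
    """
    m = x.n
    rx = reverse_genome(x)
    hits = []
    for i in range(1, g.n - m + 2):
        w = subgenome(g, i, i + m - 1)
        if w == x or (mode == "congruent" and w == rx):
            hits.append(i)
    return hits


def count_occurrences(g: Genome, x: Genome, mode: Mode = "direct") -> int:
    """subgen(G, X): number of windows of ``g`` equal (or congruent) to ``x``."""
    return len(occurrence_positions(g, x, mode))


def iter_subgenomes(g: Genome, min_size: int = 1) -> Iterator[Genome]:
    """All subgenomes of ``g`` (with repetition by position)."""
    for i in range(1, g.n + 1):
        for j in range(i + min_size - 1, g.n + 1):
            yield subgenome(g, i, j)


def cap(
    g: Genome,
    start_label: str,
    end_label: str,
    start_gap: int = 0,
    end_gap: int = 0,
) -> Genome:
    """Extend a genome with artificial first/last genes (capping).

    Capping two genomes of a pair with the SAME label pair makes them
    co-tailed, which the sorting procedures require.
    """
    if start_gap < 0 or end_gap < 0:
        raise GenomeDomainError("cap gaps must be non-negative")
    return Genome(
        (start_label,) + g.genes + (end_label,),
        (start_gap,) + g.intergenic + (end_gap,),
    )
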