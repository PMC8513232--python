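"""Intergenic rearrangement events: transpositions and reversals.

Both events are *conservative*: they permute genes and redistribute
intergenic nucleotides but never create or destroy either.  An event
record stores only its parameters; application is a pure function on
genomes.

The transposition ``τ(i,j,k)(x,y,z)`` (with ``2 ≤ i < j < k ≤ n``)
exchanges the consecutive gene segments ``S_i..S_{j-1}`` and
``S_j..S_{k-1}``; the cut values ``x, y, z`` say how many nucleotides of
the three affected intergenic regions ``Ŝ_{i-1}, Ŝ_{j-1}, Ŝ_{k-1}``
stay on their left side.  The reversal ``ρ(i,j)(x,y)`` (with
``2 ≤ i < j ≤ n-1``) reverses the segment ``S_i..S_j`` together with its
internal intergenic regions; ``x`` and ``y`` cut the two flanking
regions ``Ŝ_{i-1}`` and ``Ŝ_j``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

from .core import Genome, GenomeDomainError


class OperationError(GenomeDomainError):
    """An event's parameters violate its validity bounds for a genome."""


@dataclass(frozen=True)
class Transposition:
    i: int
    j: int
    k: int
    x: int
    y: int
    z: int

    def validate(self, g: Genome) -> None:
        n = g.n
        if not (2 <= self.i < self.j < self.k <= n):
            raise OperationError(
                f"transposition indices must satisfy 2 <= i < j < k <= n; "
                f"got (i,j,k)=({self.i},{self.j},{self.k}) with n={n}"
            )
        for cut, region, name in (
            (self.x, self.i - 1, "x"),
            (self.y, self.j - 1, "y"),
            (self.z, self.k - 1, "z"),
        ):
            cap_ = g.region(region)
            if not 0 <= cut <= cap_:
                raise OperationError(
                    f"{name} = {cut} outside [0, Ŝ_{region}] = [0, {cap_}]"
                )

    def __str__(self) -> str:
        return f"T {self.i} {self.j} {self.k} {self.x} {self.y} {self.z}"


@dataclass(frozen=True)
class Reversal:
    i: int
    j: int
    x: int
    y: int

    def validate(self, g: Genome) -> None:
        n = g.n
        if not (2 <= self.i < self.j <= n - 1):
            raise OperationError(
                f"reversal indices must satisfy 2 <= i < j <= n-1; "
                f"got (i,j)=({self.i},{self.j}) with n={n}"
            )
        if not 0 <= self.x <= g.region(self.i - 1):
            raise OperationError(
                f"x = {self.x} outside [0, Ŝ_{self.i - 1}] = "
                f"[0, {g.region(self.i - 1)}]"
            )
        if not 0 <= self.y <= g.region(self.j):
            raise OperationError(
                f"y = {self.y} outside [0, Ŝ_{self.j}] = [0, {g.region(self.j)}]"
            )

    def __str__(self) -> str:
        return f"R {self.i} {self.j} {self.x} {self.y}"


Operation = Union[Transposition, Reversal]


def apply_transposition(g: Genome, t: Transposition) -> Genome:
    t.validate(g)
    i, j, k = t.i, t.j, t.k
    S = g.genes
    B = g.intergenic
    xp = g.region(i - 1) - t.x
    yp = g.region(j - 1) - t.y
    zp = g.region(k - 1) - t.z
    genes = S[: i - 1] + S[j - 1 : k - 1] + S[i - 1 : j - 1] + S[k - 1 :]
    inter = (
        B[: i - 2]
        + (t.x + yp,)
        + B[j - 1 : k - 2]
        + (t.z + xp,)
        + B[i - 1 : j - 2]
        + (t.y + zp,)
        + B[k - 1 :]
    )
    return Genome(genes, inter)


def apply_reversal(g: Genome, r: Reversal) -> Genome:
    r.validate(g)
    i, j = r.i, r.j
    S = g.genes
    B = g.intergenic
    xp = g.region(i - 1) - r.x
    yp = g.region(j) - r.y
    genes = S[: i - 1] + S[i - 1 : j][::-1] + S[j:]
    inter = (
        B[: i - 2]
        + (r.x + r.y,)
        + B[i - 1 : j - 1][::-1]
        + (xp + yp,)
        + B[j:]
    )
    return Genome(genes, inter)


def apply_operation(g: Genome, op: Operation) -> Genome:
    if isinstance(op, Transposition):
        return apply_transposition(g, op)
    return apply_reversal(g, op)


def apply_all(g: Genome, ops: list[Operation] | tuple[Operation, ...]) -> Genome:
    for op in ops:
        g = apply_operation(g, op)
    return g


def inverse_reversal(g: Genome, r: Reversal) -> Reversal:
    """The reversal on the same span that undoes ``r`` applied to ``g``.

    After ``ρ(i,j)(x,y)`` the two flanking regions hold ``x+y`` and
    ``x'+y'`` nucleotides; cutting them again at ``(x, x')`` restores the
    original left region ``x + x'`` and, by conservation, the right one.
    """
    r.validate(g)
    xp = g.region(r.i - 1) - r.x
    return Reversal(r.i, r.j, r.x, xp)


def redistribute_three(
    g: Genome, p: int, q: int, r: int, targets: tuple[int, int, int]
) -> list[Transposition]:
    """Redistribute nucleotides among intergenic regions ``p < q < r``.

    Returns at most two transpositions — ``τ(p+1,q+1,r+1)`` followed by
    ``τ(p+1,p+r-q+1,r+1)`` — whose application leaves the gene order
    unchanged and sets the three regions to ``targets``.  Any target
    triple with the same total as the current sizes is reachable: the
    first transposition moves the regions to an intermediate triple
    (A, B, C) bounded by ``A ≤ min(a+b, ta+tb)`` (and symmetrically),
    and those bounds always sum to at least the conserved total.
    """
    if not (1 <= p < q < r <= g.n - 1):
        raise OperationError(
            f"need 1 <= p < q < r <= n-1; got ({p},{q},{r}) with n={g.n}"
        )
    a, b, c = g.region(p), g.region(q), g.region(r)
    ta, tb, tc = targets
    if min(ta, tb, tc) < 0:
        raise OperationError(f"negative target sizes {targets}")
    total = a + b + c
    if ta + tb + tc != total:
        raise OperationError(
            f"targets {targets} sum to {ta + tb + tc}, regions hold {total}"
        )
    if (ta, tb, tc) == (a, b, c):
        return []

    # Intermediate triple reachable from (a,b,c) by the first transposition
    # and from which the second reaches (ta,tb,tc).
    cap_a = min(a + b, ta + tb)
    cap_b = min(a + c, ta + tc)
    A = min(cap_a, total)
    B = min(cap_b, total - A)
    C = total - A - B

    # First transposition: regions (a,b,c) at (p, q, r) -> (A,B,C) at
    # (p, p+r-q, r).  x1 is pinned by interval intersection; y1, z1 follow.
    x1 = max(0, a - B, A - b)
    y1 = x1 + b - A
    z1 = B - a + x1
    t1 = Transposition(p + 1, q + 1, r + 1, x1, y1, z1)

    # Second transposition swaps the segments back and lands on targets.
    x2 = max(0, A - tb, ta - B)
    y2 = x2 + B - ta
    z2 = tb - A + x2
    t2 = Transposition(p + 1, p + r - q + 1, r + 1, x2, y2, z2)

    out = apply_transposition(apply_transposition(g, t1), t2)
    assert out.genes == g.genes, "redistribution altered the gene order"
    assert (out.region(p), out.region(q), out.region(r)) == (ta, tb, tc)
    return [t1, t2]
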