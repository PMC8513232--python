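"""Shared fixtures: worked-example genomes and instance families."""

from __future__ import annotations

import itertools
import random
from pathlib import Path

import pytest

from mcisp import Genome, cap, make_genome
from mcisp.io import read_genome

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def fig1() -> Genome:
    return read_genome(DATA / "fig1.txt")


@pytest.fixture(scope="session")
def fig2():
    return (
        read_genome(DATA / "fig2_G.txt"),
        read_genome(DATA / "fig2_H.txt"),
        read_genome(DATA / "fig2_K.txt"),
    )


@pytest.fixture(scope="session")
def fig4():
    return read_genome(DATA / "fig4_G.txt"), read_genome(DATA / "fig4_result.txt")


@pytest.fixture(scope="session")
def fig5():
    return read_genome(DATA / "fig4_G.txt"), read_genome(DATA / "fig5_result.txt")


@pytest.fixture(scope="session")
def ex1():
    return read_genome(DATA / "ex1_G.txt"), read_genome(DATA / "ex1_H.txt")


@pytest.fixture(scope="session")
def ex2():
    return read_genome(DATA / "ex2_G.txt"), read_genome(DATA / "ex2_H.txt")


@pytest.fixture(scope="session")
def ex3():
    return read_genome(DATA / "ex3_G.txt"), read_genome(DATA / "ex3_H.txt")


# ---------------------------------------------------------------------------
# instance families


def compositions(total: int, parts: int) -> list[tuple[int, ...]]:
    """All non-negative integer vectors of given length and sum."""
    if parts == 0:
        return [()] if total == 0 else []
    out = []
    for first in range(total + 1):
        for rest in compositions(total - first, parts - 1):
            out.append((first,) + rest)
    return out


def _canonical(labels: tuple[str, ...]) -> bool:
    """Keep one representative per label-renaming class (labels must
    appear in first-occurrence order A, B, C...)."""
    seen: dict[str, int] = {}
    for lab in labels:
        if lab not in seen:
            seen[lab] = len(seen)
            if ["A", "B", "C"][seen[lab]] != lab:
                return False
    return True


def capped_pair_family(
    max_core: int,
    labels: str,
    max_sum: int,
    region_samples: int,
    seed: int = 20240,
):
    """Capped balanced co-tailed pairs: every canonical core gene-string
    pair, with the all-zero intergenic assignment plus a seeded sample
    of intergenic vectors for each positive total up to ``max_sum``."""
    rng = random.Random(seed)
    for nc in range(0, max_core + 1):
        for core in itertools.product(labels, repeat=nc):
            if not _canonical(core):
                continue
            perms = sorted(set(itertools.permutations(core)))
            for target in perms:
                n = nc + 2
                vec_pairs = [((0,) * (n - 1), (0,) * (n - 1))]
                for s in range(1, max_sum + 1):
                    vecs = compositions(s, n - 1)
                    for _ in range(region_samples):
                        vec_pairs.append((rng.choice(vecs), rng.choice(vecs)))
                for sv, tv in vec_pairs:
                    yield (
                        Genome(("I",) + core + ("F",), sv),
                        Genome(("I",) + target + ("F",), tv),
                    )


def random_capped_pair(rng: random.Random, n_core: int, n_labels: int, max_region: int):
    """One random balanced co-tailed capped pair."""
    alphabet = [chr(ord("A") + i) for i in range(n_labels)]
    core = [rng.choice(alphabet) for _ in range(n_core)]
    target = core[:]
    rng.shuffle(target)
    total = sum(rng.randint(0, max_region) for _ in range(n_core + 1))
    def vec(k: int) -> list[int]:
        cuts = sorted(rng.randint(0, total) for _ in range(k - 1))
        return [b - a for a, b in zip([0] + cuts, cuts + [total])]
    g = Genome(("I", *core, "F"), tuple(vec(n_core + 1)))
    h = Genome(("I", *target, "F"), tuple(vec(n_core + 1)))
    return g, h
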