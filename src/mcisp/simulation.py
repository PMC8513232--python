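"""Simulated-genome experiment: does the 2k partition improve distances?

The generator emulates the benchmark protocol: a source genome of
``n_genes`` labels drawn uniformly from an ``m``-letter alphabet with
intergenic sizes uniform on ``[0, max_intergenic]``; a target genome
obtained by applying ``o`` random operations of the model (transposition,
reversal, or an even split of both in random order); both genomes then
capped with one fresh gene pair so every pair is balanced and co-tailed.
For each pair the rearrangement distance is estimated over sampled
orthologous assignments, once with assignments consistent with the
computed partition and once with unconstrained assignments, and the
per-pair minima and means are aggregated.

Defaults are reduced-scale; the full benchmark scale (pairs of size 102,
100 pairs, 100 assignments) is supported through the configuration.
"""

from __future__ import annotations

import random
import time
from dataclasses import dataclass, field
from typing import Literal

from .core import Genome, cap, is_balanced, is_cotailed, make_genome
from .operations import Reversal, Transposition, apply_operation
from .sorting import Model, estimate_distance

ModelName = Literal["TRANS", "REV", "REVTRANS"]

_MODEL_MAP: dict[ModelName, Model] = {
    "TRANS": "transposition",
    "REV": "reversal",
    "REVTRANS": "mixed",
}

CAP_START = "<start>"
CAP_END = "<end>"


@dataclass(frozen=True)
class ExperimentConfig:
    model: ModelName = "TRANS"
    alphabet_size: int = 5
    n_genes: int = 30
    max_intergenic: int = 100
    n_operations: int = 10
    n_pairs: int = 10
    n_assignments: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alphabet_size < 1 or min(
            self.n_genes, self.n_pairs, self.n_assignments
        ) < 1 or self.n_operations < 0 or self.max_intergenic < 0:
            raise ValueError("all experiment counts must be positive")
        if self.model not in _MODEL_MAP:
            raise ValueError(f"unknown model {self.model!r}")


@dataclass(frozen=True)
class Triple:
    min: float
    avg: float
    max: float


@dataclass(frozen=True)
class SummaryRow:
    model: ModelName
    n_operations: int
    alphabet_size: int
    with_min: Triple
    with_avg: Triple
    with_time: float
    without_min: Triple
    without_avg: Triple
    without_time: float


def generate_source_genome(
    n: int, m: int, max_intergenic: int, rng: random.Random
) -> Genome:
    """Uniform random genome: n genes over m labels, intergenic sizes on
    the inclusive interval [0, max_intergenic]."""
    labels = [f"G{rng.randrange(m)}" for _ in range(n)]
    inter = [rng.randint(0, max_intergenic) for _ in range(n - 1)]
    return make_genome(labels, inter)


def _random_transposition(g: Genome, rng: random.Random) -> Transposition:
    n = g.n
    i, j, k = sorted(rng.sample(range(2, n + 1), 3))
    return Transposition(
        i,
        j,
        k,
        rng.randint(0, g.region(i - 1)),
        rng.randint(0, g.region(j - 1)),
        rng.randint(0, g.region(k - 1)),
    )


def _random_reversal(g: Genome, rng: random.Random) -> Reversal:
    n = g.n
    i, j = sorted(rng.sample(range(2, n), 2))
    return Reversal(i, j, rng.randint(0, g.region(i - 1)), rng.randint(0, g.region(j)))


def generate_target_genome(
    g: Genome, model: ModelName, o: int, rng: random.Random
) -> Genome:
    """Apply ``o`` random operations of the model: indices uniform over
    the valid tuples, then cuts uniform over their current ranges.  The
    mixed model applies ⌊o/2⌋ reversals and ⌈o/2⌉ transpositions in a
    uniformly shuffled order."""
    if model == "TRANS":
        kinds = ["T"] * o
    elif model == "REV":
        kinds = ["R"] * o
    else:
        kinds = ["R"] * (o // 2) + ["T"] * (o - o // 2)
        rng.shuffle(kinds)
    out = g
    for kind in kinds:
        op = (
            _random_transposition(out, rng)
            if kind == "T"
            else _random_reversal(out, rng)
        )
        out = apply_operation(out, op)
    return out


def build_database(config: ExperimentConfig) -> list[tuple[Genome, Genome]]:
    """Generate ``n_pairs`` capped genome pairs.

    Operations are applied to the uncapped source; both genomes of a
    pair are then capped with the same fresh labels and the same gap
    sizes (drawn uniformly on [0, max_intergenic]), which keeps the pair
    balanced and co-tailed by construction.
    """
    rng = random.Random(config.seed)
    pairs = []
    for _ in range(config.n_pairs):
        g = generate_source_genome(
            config.n_genes, config.alphabet_size, config.max_intergenic, rng
        )
        h = generate_target_genome(g, config.model, config.n_operations, rng)
        start_gap = rng.randint(0, config.max_intergenic)
        end_gap = rng.randint(0, config.max_intergenic)
        gc = cap(g, CAP_START, CAP_END, start_gap, end_gap)
        hc = cap(h, CAP_START, CAP_END, start_gap, end_gap)
        assert is_balanced(gc, hc) and is_cotailed(gc, hc)
        pairs.append((gc, hc))
    return pairs


@dataclass
class _Acc:
    mins: list[int] = field(default_factory=list)
    avgs: list[float] = field(default_factory=list)
    seconds: float = 0.0

    def triples(self) -> tuple[Triple, Triple]:
        return (
            Triple(min(self.mins), sum(self.mins) / len(self.mins), max(self.mins)),
            Triple(min(self.avgs), sum(self.avgs) / len(self.avgs), max(self.avgs)),
        )


def run_experiment(config: ExperimentConfig, progress: bool = False) -> SummaryRow:
    """Estimate distances for every pair with and without the partition
    and summarise the per-pair minima and means."""
    pairs = build_database(config)
    model = _MODEL_MAP[config.model]
    arms = {True: _Acc(), False: _Acc()}
    iterator = enumerate(pairs)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(list(iterator), desc=config.model)
    for idx, (g, h) in iterator:
        for use_partition in (True, False):
            rng = random.Random(
                (config.seed * 100003 + idx * 2 + int(use_partition)) % (2**31)
            )
            t0 = time.perf_counter()
            est = estimate_distance(
                g, h, model, config.n_assignments, use_partition, rng
            )
            acc = arms[use_partition]
            acc.seconds += time.perf_counter() - t0
            acc.mins.append(est.min_distance)
            acc.avgs.append(est.avg_distance)
    with_min, with_avg = arms[True].triples()
    without_min, without_avg = arms[False].triples()
    return SummaryRow(
        config.model,
        config.n_operations,
        config.alphabet_size,
        with_min,
        with_avg,
        arms[True].seconds / len(pairs),
        without_min,
        without_avg,
        arms[False].seconds / len(pairs),
    )


def summary_row_fields() -> list[str]:
    return [
        "model",
        "o",
        "m",
        "with_min_min",
        "with_min_avg",
        "with_min_max",
        "with_avg_min",
        "with_avg_avg",
        "with_avg_max",
        "with_time",
        "without_min_min",
        "without_min_avg",
        "without_min_max",
        "without_avg_min",
        "without_avg_avg",
        "without_avg_max",
        "without_time",
    ]


def summary_row_values(row: SummaryRow) -> list[str]:
    def fmt(v: float) -> str:
        return f"{v:.2f}" if isinstance(v, float) else str(v)

    return [
        row.model,
        str(row.n_operations),
        str(row.alphabet_size),
        *[fmt(v) for v in (row.with_min.min, row.with_min.avg, row.with_min.max)],
        *[fmt(v) for v in (row.with_avg.min, row.with_avg.avg, row.with_avg.max)],
        fmt(row.with_time),
        *[
            fmt(v)
            for v in (row.without_min.min, row.without_min.avg, row.without_min.max)
        ],
        *[
            fmt(v)
            for v in (row.without_avg.min, row.without_avg.avg, row.without_avg.max)
        ],
        fmt(row.without_time),
    ]
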