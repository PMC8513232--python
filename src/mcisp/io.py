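"""Plain-text genome files and experiment configurations.

A genome file holds two whitespace-separated lines: gene labels, then
the intergenic sizes (one fewer).  Lines starting with ``#`` are
ignored.  Labels are arbitrary non-whitespace tokens.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .core import Genome, make_genome
from .simulation import ExperimentConfig


class ParseError(ValueError):
    pass


def parse_genome(text: str, name: str = "<string>") -> Genome:
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        rows.append((lineno, stripped))
    if len(rows) != 2:
        raise ParseError(
            f"{name}: expected 2 data lines (genes, intergenic sizes), "
            f"found {len(rows)}"
        )
    genes = rows[0][1].split()
    raw = rows[1][1].split()
    try:
        inter = [int(v) for v in raw]
    except ValueError as exc:
        raise ParseError(f"{name}:{rows[1][0]}: non-integer intergenic size") from exc
    if len(inter) != len(genes) - 1:
        raise ParseError(
            f"{name}:{rows[1][0]}: expected {len(genes) - 1} intergenic "
            f"sizes for {len(genes)} genes, found {len(inter)}"
        )
    if any(v < 0 for v in inter):
        raise ParseError(f"{name}:{rows[1][0]}: negative intergenic size")
    return make_genome(genes, inter)


def format_genome(g: Genome) -> str:
    return " ".join(g.genes) + "\n" + " ".join(str(v) for v in g.intergenic) + "\n"


def read_genome(path: str | Path) -> Genome:
    return parse_genome(Path(path).read_text(), name=str(path))


def write_genome(g: Genome, path: str | Path) -> None:
    Path(path).write_text(format_genome(g))


def read_experiment_config(path: str | Path) -> ExperimentConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: expected a mapping of config keys")
    try:
        return ExperimentConfig(**data)
    except TypeError as exc:
        raise ParseError(f"{path}: {exc}") from exc
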