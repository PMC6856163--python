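"""Plain-text serialization: genome files, context files, result tables.

Genome files hold one genome per line as an N-character 0/1 string; ``#``
lines are comments.  Context files are JSON (a list of {"initial", "target"}
objects) or CSV with ``initial``/``target`` columns of n-character 0/1
strings.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

from .network import Context, Genome, encode_state

__all__ = [
    "load_genome", "load_genomes", "save_genome", "save_genomes",
    "load_contexts", "save_contexts",
]


class FormatError(ValueError):
    """Malformed input file, with a line-addressed message."""


def _parse_genome_line(line: str, lineno: int, path: str,
                       n: int | None) -> Genome:
    bad = set(line) - {"0", "1"}
    if bad:
        raise FormatError(
            f"{path}:{lineno}: genome line contains non-binary "
            f"character(s) {sorted(bad)}"
        )
    if n is not None:
        expected = n * (1 << n)
        if len(line) != expected:
            raise FormatError(
                f"{path}:{lineno}: genome for n={n} requires {expected} "
                f"characters, got {len(line)}"
            )
    try:
        return Genome.from_string(line, n=n)
    except ValueError as e:
        raise FormatError(f"{path}:{lineno}: {e}") from e


def load_genomes(path: str | Path, n: int | None = None) -> list[Genome]:
    """Read all genomes from a text file (one 0/1 line each, # comments)."""
    path = Path(path)
    genomes = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        genomes.append(_parse_genome_line(line, lineno, str(path), n))
    if not genomes:
        raise FormatError(f"{path}: no genome lines found")
    return genomes


def load_genome(path: str | Path, n: int | None = None) -> Genome:
    """Read a single-genome file."""
    genomes = load_genomes(path, n=n)
    if len(genomes) != 1:
        raise FormatError(f"{path}: expected exactly one genome, found {len(genomes)}")
    return genomes[0]


def save_genomes(genomes: Sequence[Genome], path: str | Path,
                 comment: str | None = None) -> None:
    path = Path(path)
    lines = []
    if comment:
        lines.extend(f"# {c}" for c in comment.splitlines())
    lines.extend(g.to_string() for g in genomes)
    path.write_text("\n".join(lines) + "\n")


def save_genome(genome: Genome, path: str | Path,
                comment: str | None = None) -> None:
    save_genomes([genome], path, comment=comment)


def _context_from_strings(initial: str, target: str, where: str) -> Context:
    try:
        ctx = Context(encode_state(initial), encode_state(target))
    except ValueError as e:
        raise FormatError(f"{where}: {e}") from e
    return ctx


def load_contexts(path: str | Path) -> list[Context]:
    """Read contexts from JSON (list of objects) or CSV (initial,target)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        if not isinstance(data, list):
            raise FormatError(f"{path}: expected a JSON list of contexts")
        contexts = []
        for i, item in enumerate(data):
            if not isinstance(item, dict) or "initial" not in item or "target" not in item:
                raise FormatError(
                    f"{path}: entry {i}: expected an object with "
                    "'initial' and 'target' keys"
                )
            contexts.append(_context_from_strings(
                item["initial"], item["target"], f"{path}: entry {i}"))
    else:
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or \
                    not {"initial", "target"} <= set(reader.fieldnames):
                raise FormatError(
                    f"{path}: CSV must have 'initial' and 'target' columns"
                )
            contexts = [
                _context_from_strings(row["initial"], row["target"],
                                      f"{path}:{lineno}")
                for lineno, row in enumerate(reader, start=2)
            ]
    if not contexts:
        raise FormatError(f"{path}: no contexts found")
    ns = {c.n for c in contexts}
    if len(ns) != 1:
        raise FormatError(f"{path}: contexts mix gene counts {sorted(ns)}")
    return contexts


def save_contexts(contexts: Sequence[Context], path: str | Path) -> None:
    path = Path(path)
    data = [
        {"initial": c.initial.to_string(), "target": c.target.to_string()}
        for c in contexts
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["initial", "target"])
            writer.writeheader()
            writer.writerows(data)
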