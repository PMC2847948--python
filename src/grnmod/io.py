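"""Plain-text serialization of networks, patterns and analysis results.

Two network dialects, auto-detected by header:

* matrix: ``# grnmod matrix`` followed by N whitespace-separated rows of N
  integers in {-1, 0, 1}; row i = regulated gene, column j = regulator.
* edge list: ``# grnmod edges n=<N>`` followed by one ``regulator target
  sign`` triple per line (0-based gene indices, sign in {-1, +1}).

Headerless files are accepted with a sniffing rule: square integer tables
parse as matrices, three-column tables as edge lists.  Patterns use a
FASTA-like text format: ``>name`` then a 0/1 line, gene 0 leftmost.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Union

import numpy as np

from .core import GeneNetwork, pattern_from_bits, pattern_to_bits
from .modularity import ModularityResult, Partition

__all__ = [
    "write_network",
    "read_network",
    "write_patterns",
    "read_patterns",
    "write_partition",
    "read_partition",
    "modularity_result_to_dict",
    "write_modularity_result",
]

MATRIX_HEADER = "# grnmod matrix"
EDGES_HEADER = "# grnmod edges"


class NetworkParseError(ValueError):
    """Malformed network file (message carries the offending line number)."""


def write_network(network: GeneNetwork, path: Union[str, Path], dialect: str = "matrix") -> None:
    path = Path(path)
    n = network.n_genes
    if dialect == "matrix":
        lines = [MATRIX_HEADER]
        for row in network.interactions:
            lines.append(" ".join(f"{int(x):2d}" for x in row))
    elif dialect == "edges":
        lines = [f"{EDGES_HEADER} n={n}"]
        for i, j in zip(*np.nonzero(network.interactions)):
            # edge-list columns are regulator, target: transpose of the matrix
            lines.append(f"{int(j)}\t{int(i)}\t{int(network.interactions[i, j])}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(lines) + "\n")


def _parse_matrix(rows, line_nos, n_expected=None) -> GeneNetwork:
    n = len(rows[0])
    if n_expected is not None:
        n = n_expected
    if len(rows) != n:
        raise NetworkParseError(
            f"matrix has {len(rows)} rows but {n} columns (line {line_nos[-1]})"
        )
    w = np.zeros((n, n), dtype=np.int64)
    for r, (row, ln) in enumerate(zip(rows, line_nos)):
        if len(row) != n:
            raise NetworkParseError(f"line {ln}: expected {n} entries, found {len(row)}")
        for c, tok in enumerate(row):
            if tok not in (-1, 0, 1):
                raise NetworkParseError(f"line {ln}: entry {tok} outside {{-1, 0, 1}}")
            w[r, c] = tok
    return GeneNetwork(w)


def _parse_edges(rows, line_nos, n: int) -> GeneNetwork:
    w = np.zeros((n, n), dtype=np.int64)
    for row, ln in zip(rows, line_nos):
        if len(row) != 3:
            raise NetworkParseError(f"line {ln}: edge lines need 3 columns, found {len(row)}")
        reg, tgt, sign = row
        if sign not in (-1, 1):
            raise NetworkParseError(f"line {ln}: sign {sign} outside {{-1, +1}}")
        if not (0 <= reg < n and 0 <= tgt < n):
            raise NetworkParseError(f"line {ln}: gene index out of range [0, {n})")
        w[tgt, reg] = sign
    return GeneNetwork(w)


def read_network(path: Union[str, Path]) -> GeneNetwork:
    """Parse either network dialect; the header line picks the parser and,
    for edge lists, the gene count."""
    path = Path(path)
    dialect = None
    n_genes = None
    rows = []
    line_nos = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith(EDGES_HEADER):
                dialect = "edges"
                try:
                    n_genes = int(line.split("n=")[1])
                except (IndexError, ValueError) as exc:
                    raise NetworkParseError(f"line {ln}: edge header needs n=<genes>") from exc
            elif line.startswith(MATRIX_HEADER):
                dialect = "matrix"
            continue
        try:
            rows.append([int(tok) for tok in line.split()])
        except ValueError as exc:
            raise NetworkParseError(f"line {ln}: non-integer entry in {line!r}") from exc
        line_nos.append(ln)
    if not rows:
        raise NetworkParseError("no data lines found")
    if dialect is None:  # headerless: square table = matrix, else edge list
        dialect = "matrix" if len(rows) == len(rows[0]) else "edges"
        if dialect == "edges":
            if any(len(r) != 3 for r in rows):
                raise NetworkParseError("cannot sniff dialect: not square, not 3-column")
            n_genes = max(max(r[0], r[1]) for r in rows) + 1
    if dialect == "matrix":
        return _parse_matrix(rows, line_nos)
    assert n_genes is not None
    return _parse_edges(rows, line_nos, n_genes)


def write_patterns(patterns: Dict[str, np.ndarray], path: Union[str, Path]) -> None:
    lines = []
    for name, pat in patterns.items():
        lines.append(f">{name}")
        lines.append(pattern_to_bits(pat))
    Path(path).write_text("\n".join(lines) + "\n")


def read_patterns(path: Union[str, Path]) -> Dict[str, np.ndarray]:
    out: Dict[str, np.ndarray] = {}
    name = None
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].strip()
            continue
        if name is None:
            raise ValueError(f"line {ln}: pattern line before any >name header")
        out[name] = pattern_from_bits(line)
        name = None
    return out


def write_partition(partition: Partition, path: Union[str, Path]) -> None:
    lines = ["node\tmodule"]
    for node, label in enumerate(partition.labels):
        lines.append(f"{node}\t{int(label)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_partition(path: Union[str, Path]) -> Partition:
    labels = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("node"):
            continue
        node, label = line.split("\t")
        if int(node) != len(labels):
            raise ValueError(f"line {ln}: nodes must appear in order 0..n-1")
        labels.append(int(label))
    return Partition(np.array(labels, dtype=np.int64))


def modularity_result_to_dict(result: ModularityResult) -> dict:
    d = asdict(result)
    d["partition"] = [int(x) for x in result.partition.labels]
    d["n_modules"] = result.partition.n_modules
    return d


def write_modularity_result(result: ModularityResult, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(modularity_result_to_dict(result), indent=2) + "\n")
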