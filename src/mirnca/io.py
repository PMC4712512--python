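"""Readers and writers for the plain-text interchange formats.

Expression matrices travel as TSV (first column gene ID, header row of
time stamps), raw replicate arrays as TSV with ``<time>:<replicate>``
column labels, connectivity as two-column adjacency lists, networks as
TSV edge tables and SIF (``source<TAB>type<TAB>target``) for Cytoscape,
and gene sets as GMT. Writers use a fixed float format so identical
runs produce byte-identical files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from .nca import ConnectivityPattern
from .networks import IntegratedNetwork
from .synthetic import RawMicroarray, TimeGrid

__all__ = [
    "ParseError",
    "read_expression_tsv", "write_expression_tsv",
    "read_replicates_tsv", "write_replicates_tsv",
    "read_adjacency", "write_adjacency",
    "read_sif", "write_sif", "write_integrated_sif",
    "read_gmt", "write_gmt",
    "read_synergy_tsv", "write_synergy_tsv",
]

FLOAT_FMT = "%.10g"


class ParseError(ValueError):
    """Malformed input file; the message carries the line number."""


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


def read_expression_tsv(path) -> pd.DataFrame:
    """Genes x time points matrix; duplicate gene IDs are rejected."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}:1: header needs a gene column and time stamps")
        try:
            times = [float(t) for t in header[1:]]
        except ValueError as exc:
            raise ParseError(f"{path}:1: non-numeric time stamp ({exc})") from None
        genes, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(parts)}"
                )
            if parts[0] in genes:
                raise ParseError(f"{path}:{lineno}: duplicate gene ID {parts[0]!r}")
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            genes.append(parts[0])
    return pd.DataFrame(rows, index=genes, columns=times)


def write_expression_tsv(path, matrix: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(_fmt(float(c)) for c in matrix.columns) + "\n")
        for gene, row in matrix.iterrows():
            fh.write(str(gene) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def write_replicates_tsv(path, data: np.ndarray, genes, grid: TimeGrid) -> None:
    """(N, M, R) replicate array with ``<time>:<rep>`` column labels."""
    N, M, R = data.shape
    cols = [f"{_fmt(float(t))}:{r + 1}" for t in grid.times for r in range(R)]
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(cols) + "\n")
        flat = data.reshape(N, M * R)
        for g, row in zip(genes, flat):
            fh.write(str(g) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_replicates_tsv(path) -> tuple[np.ndarray, list[str], TimeGrid]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        try:
            pairs = [(float(c.split(":")[0]), int(c.split(":")[1])) for c in header]
        except (ValueError, IndexError):
            raise ParseError(f"{path}:1: columns must be '<time>:<replicate>'") from None
        times = sorted({t for t, _ in pairs})
        R = max(r for _, r in pairs)
        genes, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header) + 1:
                raise ParseError(f"{path}:{lineno}: ragged row")
            genes.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    arr = np.asarray(rows, dtype=float)
    data = np.empty((len(genes), len(times), R))
    tidx = {t: i for i, t in enumerate(times)}
    for j, (t, r) in enumerate(pairs):
        data[:, tidx[t], r - 1] = arr[:, j]
    return data, genes, TimeGrid(tuple(times))


def read_adjacency(path) -> list[tuple[str, str]]:
    """Two-column edge list, de-duplicated, first-seen order kept."""
    edges: list[tuple[str, str]] = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            edge = (parts[0], parts[1])
            if edge not in seen:
                seen.add(edge)
                edges.append(edge)
    return edges


def write_adjacency(path, edges) -> None:
    with open(path, "w") as fh:
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")


def read_sif(path) -> list[tuple[str, str, str]]:
    """(source, type, target) triples."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: SIF needs 3 columns")
            out.append((parts[0], parts[1], parts[2]))
    return out


def write_sif(path, triples) -> None:
    with open(path, "w") as fh:
        for u, etype, v in triples:
            fh.write(f"{u}\t{etype}\t{v}\n")


def write_integrated_sif(path, net: IntegratedNetwork) -> None:
    write_sif(path, sorted((u, key, v) for u, v, key, _ in net.edges()))


def read_gmt(path) -> list[tuple[str, str, list[str]]]:
    """GMT gene sets: name, description, members."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT rows need name, description, >=1 member"
                )
            sets.append((parts[0], parts[1], [m for m in parts[2:] if m]))
    return sets


def write_gmt(path, sets) -> None:
    with open(path, "w") as fh:
        for name, desc, members in sets:
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_synergy_tsv(path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["source", "target"]:
            raise ParseError(f"{path}:1: expected header source/target/pcc/shared")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            g.add_edge(parts[0], parts[1], pcc=float(parts[2]), shared=int(parts[3]))
    return g


def write_synergy_tsv(path, g: nx.Graph) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tpcc\tshared\n")
        for u, v, data in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{v}\t{_fmt(data['pcc'])}\t{data['shared']}\n")


def pattern_to_adjacency(path, Z0: ConnectivityPattern) -> None:
    write_adjacency(path, Z0.to_edges())


def adjacency_to_pattern(path) -> ConnectivityPattern:
    return ConnectivityPattern.from_edges(read_adjacency(path))
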