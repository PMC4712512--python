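"""Synergy and integrated regulatory networks.

A miRNA-miRNA synergistic edge joins two regulators whose reconstructed
activity profiles correlate above a threshold (Pearson r > 0.7 by
default, strict) and which share at least ``min_shared`` target genes
(>= 3 by default). The integrated network unions the typed regulatory
layers — miRNA->TG, TF->TG, TF->miRNA and the undirected miRNA-miRNA
synergy edges — over a heterogeneous node set in which an entity can
hold several roles (a TF is frequently also somebody's target gene).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .nca import ConnectivityPattern

__all__ = [
    "IntegratedNetwork",
    "pairwise_activity_correlation",
    "shared_target_counts",
    "build_synergy_network",
    "build_integrated_network",
    "hub_ranking",
    "edge_overlap",
]

EDGE_TYPES = ("miRNA-TG", "TF-TG", "TF-miRNA", "miRNA-miRNA")


def pairwise_activity_correlation(T) -> pd.DataFrame:
    """Pearson correlation between all pairs of activity profiles.

    ``T`` is an (L x M) array or DataFrame (rows = regulators, M >= 3
    time points). Constant rows have undefined correlation; their
    off-diagonal entries are recorded as 0 and the row IDs are attached
    to the result as ``.attrs["constant_rows"]``. The diagonal is 1.
    """
    ids = list(T.index) if isinstance(T, pd.DataFrame) else None
    x = T.to_numpy(dtype=float) if isinstance(T, pd.DataFrame) else np.asarray(T, float)
    if x.shape[1] < 3:
        raise ValueError("need at least 3 time points for correlations")
    sd = x.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr = np.atleast_2d(corr)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    if ids is None:
        ids = list(range(x.shape[0]))
    out = pd.DataFrame(corr, index=ids, columns=ids)
    out.attrs["constant_rows"] = [i for i, c in zip(ids, constant) if c]
    return out


def shared_target_counts(Z0: ConnectivityPattern) -> pd.DataFrame:
    """Pairwise common-target counts; the diagonal is each out-degree."""
    s = Z0.support.astype(np.int64)
    counts = s.T @ s
    return pd.DataFrame(counts, index=Z0.regulators, columns=Z0.regulators)


def build_synergy_network(
    T,
    Z0: ConnectivityPattern,
    pcc_threshold: float = 0.7,
    min_shared: int = 3,
) -> nx.Graph:
    """miRNA-miRNA synergistic network from activities and shared targets.

    An edge (i, j) is present iff Pearson r(i, j) > ``pcc_threshold``
    (strict) and the regulators share >= ``min_shared`` targets. Edges
    carry ``pcc`` and ``shared`` attributes; regulators with no edge are
    dropped. ``T`` must be a DataFrame whose index covers ``Z0.regulators``
    (or an array with rows aligned to them).
    """
    if isinstance(T, pd.DataFrame):
        missing = [r for r in Z0.regulators if r not in T.index]
        if missing:
            raise ValueError(f"activity matrix missing regulators: {missing}")
        T = T.loc[Z0.regulators]
    else:
        T = pd.DataFrame(np.asarray(T, float), index=Z0.regulators)
        if T.shape[0] != Z0.n_regulators:
            raise ValueError("activity rows do not match Z0 regulators")
    corr = pairwise_activity_correlation(T)
    shared = shared_target_counts(Z0)

    g = nx.Graph()
    regs = Z0.regulators
    for a in range(len(regs)):
        for b in range(a + 1, len(regs)):
            pcc = float(corr.iat[a, b])
            k = int(shared.iat[a, b])
            if pcc > pcc_threshold and k >= min_shared:
                g.add_edge(regs[a], regs[b], pcc=pcc, shared=k)
    return g


@dataclass
class IntegratedNetwork:
    """Heterogeneous regulatory network with typed edges and role sets.

    Directed edges (miRNA->TG, TF->TG, TF->miRNA) live in a MultiDiGraph
    with one key per edge type; each undirected synergy edge is stored
    once (as written) and contributes one incidence to each endpoint's
    total degree. ``roles[node]`` is a set drawn from {"miRNA", "TF", "TG"}.
    """

    graph: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)
    roles: dict[str, set[str]] = field(default_factory=dict)
    n_skipped: int = 0

    def _add_role(self, node: str, role: str) -> None:
        self.roles.setdefault(node, set()).add(role)
        if node not in self.graph:
            self.graph.add_node(node)

    def add_edge(self, u: str, v: str, etype: str, **attrs) -> bool:
        """Add a typed edge once; returns False on a duplicate."""
        if etype not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {etype!r}")
        if etype == "miRNA-miRNA" and self.graph.has_edge(v, u, key=etype):
            return False
        if self.graph.has_edge(u, v, key=etype):
            return False
        self.graph.add_edge(u, v, key=etype, etype=etype, **attrs)
        src_role, dst_role = etype.split("-")
        self._add_role(u, src_role)
        self._add_role(v, dst_role)
        return True

    def edges(self, etype: str | None = None):
        for u, v, key, data in self.graph.edges(keys=True, data=True):
            if etype is None or key == etype:
                yield u, v, key, data

    def total_degree(self, node: str) -> int:
        """in + out connections; an undirected synergy incidence counts 1."""
        return self.graph.in_degree(node) + self.graph.out_degree(node)

    def directed_edge_count(self) -> int:
        return sum(1 for *_, k, _ in self.edges() if k != "miRNA-miRNA")

    @property
    def nodes(self):
        return self.graph.nodes

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def synergy_view(self) -> nx.Graph:
        g = nx.Graph()
        for u, v, _, data in self.edges("miRNA-miRNA"):
            g.add_edge(u, v, **{k: w for k, w in data.items() if k != "etype"})
        return g


def _clean_pairs(table, n_skipped: list[int]):
    for row in table:
        if len(row) != 2 or not row[0] or not row[1]:
            n_skipped[0] += 1
            continue
        yield str(row[0]), str(row[1])


def build_integrated_network(
    mirna_tg=(),
    tf_tg=(),
    tf_mirna=(),
    synergy: nx.Graph | None = None,
    node_filter: set[str] | None = None,
) -> IntegratedNetwork:
    """Union the typed regulatory layers into one heterogeneous network.

    Edge tables are iterables of (source, target) pairs; duplicates of
    the same type between the same pair collapse to one edge. When
    ``node_filter`` is given, edges into target genes are kept only for
    TGs in the filter (typically the DEG list); TF->miRNA and synergy
    edges are unaffected. Malformed rows are skipped and counted.
    """
    net = IntegratedNetwork()
    skipped = [0]
    for reg, tg in _clean_pairs(mirna_tg, skipped):
        if node_filter is None or tg in node_filter:
            net.add_edge(reg, tg, "miRNA-TG")
    for tf, tg in _clean_pairs(tf_tg, skipped):
        if node_filter is None or tg in node_filter:
            net.add_edge(tf, tg, "TF-TG")
    for tf, mir in _clean_pairs(tf_mirna, skipped):
        net.add_edge(tf, mir, "TF-miRNA")
    if synergy is not None:
        for u, v, data in synergy.edges(data=True):
            net.add_edge(u, v, "miRNA-miRNA", **data)
    net.n_skipped = skipped[0]
    return net


def hub_ranking(
    net: IntegratedNetwork, role: str, top_k: int = 20
) -> list[tuple[str, int]]:
    """Top-k nodes of a given role by total degree (in + out).

    Ties are broken lexicographically by node ID, so rankings are
    deterministic.
    """
    nodes = [n for n, roles in net.roles.items() if role in roles]
    ranked = sorted(nodes, key=lambda n: (-net.total_degree(n), n))
    return [(n, net.total_degree(n)) for n in ranked[:top_k]]


def edge_overlap(a: nx.Graph, b) -> tuple[int, float]:
    """Overlap of a synergy network's edges with an external edge set.

    ``b`` is any iterable of node pairs (order ignored). Returns the
    intersection count and its fraction of ``a``'s edges (0.0 for an
    edgeless ``a``).
    """
    a_edges = {frozenset(e) for e in a.edges()}
    b_edges = {frozenset(e) for e in (b.edges() if isinstance(b, nx.Graph) else b)}
    inter = len(a_edges & b_edges)
    frac = inter / len(a_edges) if a_edges else 0.0
    return inter, frac
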