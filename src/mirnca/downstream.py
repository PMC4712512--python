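"""Peak-activity timing and gene-set enrichment.

An entity (target gene, TF or miRNA) is "active" at the time point
where its profile peaks — by default the maximum *absolute* value, so
that repression peaks count as activity. Counting active entities per
time point exposes the regulatory cascade after stimulation, and the
correlation between target-gene and regulator counts quantifies how
tightly the waves coincide.

Enrichment of a gene list against GMT collections uses the upper-tail
hypergeometric probability (Fisher's exact test one-sided), with the
conventional call of significance requiring both a minimum overlap and
a p-value cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .networks import IntegratedNetwork
from .synthetic import TimeGrid

__all__ = [
    "PeakAssignment",
    "peak_time",
    "assign_peaks",
    "active_counts",
    "count_correlation",
    "hypergeometric_enrichment",
    "extract_subnetwork",
]

ENTITY_CLASSES = ("TG", "TF", "miRNA")


@dataclass(frozen=True)
class PeakAssignment:
    entity: str
    entity_class: str  # one of ENTITY_CLASSES
    peak_time: float


def peak_time(profile, grid: TimeGrid, signed: bool = False) -> float:
    """Time stamp of the profile's peak.

    By default the peak is the maximum |value| (a repression trough is a
    peak of activity); ``signed=True`` takes the plain maximum. Ties go
    to the earliest time point.
    """
    y = np.asarray(profile, dtype=float)
    if y.shape != (len(grid),):
        raise ValueError("profile length must equal the grid length")
    idx = int(np.argmax(y if signed else np.abs(y)))
    return float(grid.times[idx])


def assign_peaks(
    profiles: pd.DataFrame, entity_class: str, grid: TimeGrid, signed: bool = False
) -> list[PeakAssignment]:
    """Peak assignment for every row of a profiles DataFrame."""
    if entity_class not in ENTITY_CLASSES:
        raise ValueError(f"entity_class must be one of {ENTITY_CLASSES}")
    return [
        PeakAssignment(str(name), entity_class, peak_time(row, grid, signed=signed))
        for name, row in profiles.iterrows()
    ]


def active_counts(
    assignments: list[PeakAssignment], grid: TimeGrid
) -> pd.DataFrame:
    """Entities peaking at each time point, per class.

    Returns a DataFrame indexed by time stamp with one column per entity
    class; per class the counts sum to the number of assigned entities.
    """
    counts = pd.DataFrame(
        0, index=list(grid.times), columns=list(ENTITY_CLASSES), dtype=int
    )
    for a in assignments:
        if a.peak_time not in counts.index:
            raise ValueError(f"peak time {a.peak_time} not on the grid")
        counts.loc[a.peak_time, a.entity_class] += 1
    return counts


def count_correlation(counts_a, counts_b) -> float:
    """Pearson correlation of two per-time-point count vectors."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("count vectors must have equal length >= 3")
    return float(stats.pearsonr(a, b).statistic)


def hypergeometric_enrichment(
    query,
    collections: list[tuple[str, str, list[str]]],
    background,
    min_overlap: int = 10,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a gene list.

    For each set of size K (after intersection with the background of
    size B), an overlap of k out of the n query genes has p-value
    P(X >= k) with X ~ Hypergeom(B, K, n). A set is significant when
    k >= ``min_overlap`` and p < ``alpha``. Results come back sorted by
    p-value with columns name, overlap, set_size, query_size,
    background_size, p_value, significant.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background universe")
    query = set(query)
    if not query <= background:
        extra = sorted(query - background)
        raise ValueError(f"query genes outside the background: {extra[:5]}")
    B, n = len(background), len(query)
    rows = []
    for name, _desc, members in collections:
        members = set(members) & background
        K = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, B, K, n)) if K else 1.0
        rows.append(
            {
                "name": name,
                "overlap": k,
                "set_size": K,
                "query_size": n,
                "background_size": B,
                "p_value": min(p, 1.0),
                "significant": (k >= min_overlap) and (p < alpha),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "name", "overlap", "set_size", "query_size",
            "background_size", "p_value", "significant",
        ],
    )
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


def extract_subnetwork(net: IntegratedNetwork, gene_set) -> IntegratedNetwork:
    """Sub-network induced by a target-gene set and its regulators.

    Keeps target genes in ``gene_set``, every miRNA/TF with at least one
    edge into a retained TG, edges among retained nodes of the regulatory
    types, and synergy edges among retained regulators.
    """
    gene_set = set(gene_set)
    kept_tgs = {
        n for n, roles in net.roles.items() if "TG" in roles and n in gene_set
    }
    regulators = set()
    for u, v, key, _ in net.edges():
        if key in ("miRNA-TG", "TF-TG") and v in kept_tgs:
            regulators.add(u)
    keep = kept_tgs | regulators
    sub = IntegratedNetwork()
    for u, v, key, data in net.edges():
        attrs = {k: w for k, w in data.items() if k != "etype"}
        if key in ("miRNA-TG", "TF-TG"):
            if u in regulators and v in kept_tgs:
                sub.add_edge(u, v, key, **attrs)
        elif u in keep and v in keep:
            sub.add_edge(u, v, key, **attrs)
    return sub
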