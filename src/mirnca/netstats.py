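"""Topology statistics and the degree-preserving null model.

The synergy network's cohesion is summarized by the mean local
clustering coefficient and the mean connectivity (2E/N); its degree
distribution is fit by ordinary least squares on log10(degree) vs
log10(count). Whether the observed clustering is exceptional is judged
against null networks generated by double-edge swaps, which preserve
the exact degree sequence while destroying higher-order structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "RandomizationResult",
    "clustering_coefficient",
    "mean_connectivity",
    "mean_path_length",
    "degree_distribution",
    "powerlaw_slope",
    "degree_preserving_randomize",
    "randomization_test",
]


def clustering_coefficient(net: nx.Graph, exclude_low_degree: bool = False) -> float:
    """Mean local clustering coefficient.

    The local coefficient of a node with degree k >= 2 is
    2 * (links among its neighbours) / (k * (k - 1)); nodes with k < 2
    contribute 0 unless ``exclude_low_degree`` drops them from the mean.
    """
    if net.number_of_nodes() == 0:
        return 0.0
    return float(nx.average_clustering(net, count_zeros=not exclude_low_degree))


def mean_connectivity(net: nx.Graph) -> float:
    """Mean degree, 2|E| / |V| (0 for an empty graph)."""
    n = net.number_of_nodes()
    return 2.0 * net.number_of_edges() / n if n else 0.0


def mean_path_length(net: nx.Graph) -> float:
    """Mean shortest-path length over all connected node pairs."""
    total = 0.0
    pairs = 0
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        k = sub.number_of_nodes()
        if k < 2:
            continue
        total += nx.average_shortest_path_length(sub) * k * (k - 1) / 2
        pairs += k * (k - 1) / 2
    return total / pairs if pairs else 0.0


def degree_distribution(net, direction: str = "total") -> dict[int, int]:
    """Histogram {degree: node count} for present nodes.

    ``direction`` is "in", "out" or "total"; in/out require a directed
    graph (for the integrated network, "total" is in + out).
    """
    if direction == "in":
        degs = dict(net.in_degree())
    elif direction == "out":
        degs = dict(net.out_degree())
    elif direction == "total":
        degs = dict(net.degree())
    else:
        raise ValueError("direction must be 'in', 'out' or 'total'")
    hist: dict[int, int] = {}
    for d in degs.values():
        hist[d] = hist.get(d, 0) + 1
    return dict(sorted(hist.items()))


def powerlaw_slope(hist: dict[int, int], k_min: int = 1) -> float:
    """OLS slope of log10(count) on log10(degree) over usable bins.

    Bins with degree >= k_min and count > 0 enter the fit; fewer than 3
    such bins is an error. A pure power law count ∝ k^gamma returns
    gamma exactly.
    """
    ks = np.array([k for k, c in hist.items() if k >= max(k_min, 1) and c > 0], float)
    cs = np.array([c for k, c in hist.items() if k >= max(k_min, 1) and c > 0], float)
    if ks.size < 3:
        raise ValueError("need at least 3 non-empty bins with degree >= k_min")
    slope, _ = np.polyfit(np.log10(ks), np.log10(cs), 1)
    return float(slope)


def degree_preserving_randomize(
    net: nx.Graph, n_swaps: int | None = None, seed: int = 0
) -> nx.Graph:
    """Rewire by repeated double-edge swaps with rejection.

    Each attempt picks two edges (a, b) and (c, d) and proposes the
    rewiring (a, d), (c, b); proposals creating self-loops or multi-edges
    are rejected, so the node set and the full degree sequence are
    preserved exactly. ``n_swaps`` counts attempts (default 10 per edge).
    Graphs whose degree sequence admits a single realization — a
    triangle, say — come back unchanged.
    """
    g = net.copy()
    edges = list(g.edges())
    m = len(edges)
    if m < 2:
        return g
    if n_swaps is None:
        n_swaps = 10 * m
    rng = np.random.default_rng(seed)
    for _ in range(n_swaps):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if len({a, b, c, d}) < 4:
            continue
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d)
        g.add_edge(c, b)
        edges[i] = (a, d)
        edges[j] = (c, b)
    return g


@dataclass
class RandomizationResult:
    """Observed statistic against a degree-preserving null ensemble.

    ``p_value`` is a two-sided one-sample t-test of the null sample
    against the observed value (the parametric figure a very small
    p-value must come from: the empirical p cannot drop below
    1/(n_random + 1)); ``empirical_p`` is (#null >= observed + 1) /
    (n_random + 1).
    """

    observed_stat: float
    null_stats: list[float]
    mean_null: float
    p_value: float
    empirical_p: float
    seed: int


_STATISTICS = {
    "clustering_coefficient": clustering_coefficient,
    "mean_path_length": mean_path_length,
}


def randomization_test(
    net: nx.Graph,
    statistic: str = "clustering_coefficient",
    n_random: int = 100,
    seed: int = 0,
) -> RandomizationResult:
    """Compare a topology statistic against degree-preserving nulls."""
    if statistic not in _STATISTICS:
        raise ValueError(f"statistic must be one of {sorted(_STATISTICS)}")
    fn = _STATISTICS[statistic]
    observed = fn(net)
    children = np.random.SeedSequence(seed).spawn(n_random)
    null = [
        fn(degree_preserving_randomize(net, seed=child))
        for child in children
    ]
    null_arr = np.asarray(null, dtype=float)
    if np.ptp(null_arr) == 0.0:
        p = 1.0 if null_arr[0] == observed else 0.0
    else:
        p = float(stats.ttest_1samp(null_arr, observed).pvalue)
    empirical = (int(np.sum(null_arr >= observed)) + 1) / (n_random + 1)
    return RandomizationResult(
        observed_stat=float(observed),
        null_stats=[float(x) for x in null],
        mean_null=float(null_arr.mean()),
        p_value=p,
        empirical_p=float(empirical),
        seed=seed,
    )
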