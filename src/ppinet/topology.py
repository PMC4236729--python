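"""Network statistics: degree, betweenness, clustering, power-law fit,
components, shortest paths, degree-preserving rewiring and sub-networks.

Graphs are plain undirected simple :class:`networkx.Graph` objects; all
randomness goes through an explicit seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PowerLawFit:
    """y = coefficient * x^-exponent fitted by OLS on (log x, log y)."""

    coefficient: float
    exponent: float
    r_squared: float


def degree_histogram(net: nx.Graph) -> dict[int, int]:
    """Map degree -> node count, positive degrees only."""
    out: dict[int, int] = {}
    for _, d in net.degree():
        if d > 0:
            out[d] = out.get(d, 0) + 1
    return out


def fit_power_law(histogram: dict[int, int]) -> PowerLawFit:
    """Discrete log-log least squares over degrees with count >= 1."""
    points = sorted((x, y) for x, y in histogram.items() if x > 0 and y >= 1)
    if len(points) < 3:
        raise ValidationError(
            f"power-law fit needs >= 3 distinct degrees, got {len(points)}"
        )
    log_x = np.log([x for x, _ in points])
    log_y = np.log([y for _, y in points])
    slope, intercept = np.polyfit(log_x, log_y, 1)
    predicted = slope * log_x + intercept
    ss_res = float(np.sum((log_y - predicted) ** 2))
    ss_tot = float(np.sum((log_y - log_y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PowerLawFit(coefficient=float(np.exp(intercept)),
                       exponent=float(-slope), r_squared=r2)


def betweenness(net: nx.Graph) -> dict[str, float]:
    """Exact betweenness centrality, normalized into [0, 1]."""
    if net.number_of_nodes() == 0:
        raise ValidationError("betweenness of an empty network is undefined")
    return nx.betweenness_centrality(net, normalized=True)


def clustering_coefficients(net: nx.Graph) -> tuple[dict[str, float], float]:
    """Local clustering coefficients and the all-node average.

    Nodes with degree < 2 contribute 0 and are included in the average.
    """
    local = nx.clustering(net)
    avg = sum(local.values()) / len(local) if local else 0.0
    return dict(local), avg


def degree_preserving_random(
    net: nx.Graph, seed: int, swaps_per_edge: int = 10
) -> nx.Graph:
    """Double-edge-swap rewiring; the degree sequence is preserved exactly.

    Swaps that would create a self-loop or a parallel edge are rejected
    and retried; on graphs with no legal swap (e.g. a triangle) the
    input is returned unchanged once the attempt budget is exhausted.
    """
    if net.number_of_edges() < 2:
        raise ValidationError("rewiring needs at least 2 edges")
    rng = np.random.default_rng(seed)
    g = net.copy()
    edges = [tuple(e) for e in sorted(map(sorted, g.edges()))]
    target = swaps_per_edge * len(edges)
    max_attempts = max(1000, 100 * target)
    swaps = 0
    attempts = 0
    while swaps < target and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(len(edges), size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # proposed swap: (a,b),(c,d) -> (a,d),(c,b)
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
        swaps += 1
    return g


def components(net: nx.Graph) -> list[set[str]]:
    """Connected components, largest first (ties by sorted member list)."""
    comps = [set(c) for c in nx.connected_components(net)]
    comps.sort(key=lambda c: (-len(c), sorted(c)))
    return comps


def average_shortest_path(
    net: nx.Graph,
    sample_size: int | None = None,
    seed: int | None = None,
) -> float:
    """Average shortest path length on the largest component.

    Exact (all pairs, BFS per source) when ``sample_size`` is None,
    otherwise the mean over ``sample_size`` uniformly sampled distinct
    node pairs.
    """
    comps = components(net)
    if not comps or len(comps[0]) < 2:
        raise ValidationError("largest component has < 2 nodes")
    sub = net.subgraph(comps[0])
    nodes = sorted(sub.nodes)
    if sample_size is None:
        total = 0
        count = 0
        for source in nodes:
            lengths = nx.single_source_shortest_path_length(sub, source)
            total += sum(lengths.values())
            count += len(lengths) - 1  # exclude self
        return total / count
    rng = np.random.default_rng(seed)
    by_source: dict[str, list[str]] = {}
    for _ in range(sample_size):
        i, j = rng.choice(len(nodes), size=2, replace=False)
        by_source.setdefault(nodes[int(i)], []).append(nodes[int(j)])
    total = 0.0
    count = 0
    for source, targets in by_source.items():
        lengths = nx.single_source_shortest_path_length(sub, source)
        for t in targets:
            total += lengths[t]
            count += 1
    return total / count


def top_k(net: nx.Graph, metric: str, k: int) -> list[tuple[str, float]]:
    """Top-k nodes by 'degree' or 'betweenness'; ties broken by node ID."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    if metric == "degree":
        values = {n: float(d) for n, d in net.degree()}
    elif metric == "betweenness":
        values = betweenness(net)
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    ranked = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def induced_subnetwork(
    net: nx.Graph,
    node_list: list[str],
    exclude_list: list[str] | tuple[str, ...] = (),
) -> nx.Graph:
    """Induced subgraph on node_list minus exclude_list; unknown IDs skipped."""
    keep = []
    for n in node_list:
        if n in net:
            keep.append(n)
        else:
            logger.warning("node %r not in network; skipped", n)
    for n in exclude_list:
        if n not in net:
            logger.warning("exclude node %r not in network; skipped", n)
    excluded = set(exclude_list)
    return net.subgraph([n for n in keep if n not in excluded]).copy()


def summarize(net: nx.Graph) -> dict[str, float]:
    """One-shot network summary used by the CLI report."""
    comps = components(net)
    _, avg_cc = clustering_coefficients(net)
    summary: dict[str, float] = {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "n_components": len(comps),
        "largest_component": len(comps[0]) if comps else 0,
        "average_clustering": avg_cc,
    }
    try:
        fit = fit_power_law(degree_histogram(net))
        summary["powerlaw_coefficient"] = fit.coefficient
        summary["powerlaw_exponent"] = fit.exponent
        summary["powerlaw_r_squared"] = fit.r_squared
    except ValidationError:
        pass
    if comps and len(comps[0]) >= 2:
        n = len(comps[0])
        sample = None if n <= 2000 else 100_000
        summary["average_shortest_path"] = average_shortest_path(
            net, sample_size=sample, seed=0
        )
    return summary
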