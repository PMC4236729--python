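"""From-scratch Markov Clustering (MCL) and protein-complex mapping.

The transition matrix (adjacency plus unit self-loops, column
normalized) is alternately expanded (matrix power), inflated
(elementwise power, column renormalized) and pruned until it stops
changing; clusters are read off the attractor structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ClusterSet:
    clusters: list[frozenset[str]]
    converged: bool = True
    n_iterations: int = 0

    def __len__(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for i, cluster in enumerate(self.clusters):
            for node in cluster:
                out[node] = i
        return out


def mcl(
    net: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    prune_threshold: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> ClusterSet:
    """Cluster an undirected simple graph by Markov clustering.

    Deterministic: nodes are processed in sorted order and argmax ties
    resolve to the lowest index.  Non-convergence within ``max_iter``
    returns the current clustering flagged ``converged=False``.
    """
    if net.number_of_nodes() == 0:
        raise ValidationError("cannot cluster an empty network")
    if inflation <= 1:
        raise ValidationError(f"inflation must be > 1, got {inflation}")
    nodes = sorted(net.nodes)
    n = len(nodes)
    index = {node: i for i, node in enumerate(nodes)}
    m = np.zeros((n, n))
    for a, b in net.edges:
        m[index[a], index[b]] = 1.0
        m[index[b], index[a]] = 1.0
    np.fill_diagonal(m, 1.0)  # self-loops stabilize odd-length walks
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        previous = m
        m = np.linalg.matrix_power(m, expansion)
        m = np.power(m, inflation)
        m[m < prune_threshold] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m /= colsum
        if np.abs(m - previous).max() < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations", max_iter)

    # each node follows its largest-weight attractor; clusters are the
    # connected components of the resulting assignment graph
    assign = nx.Graph()
    assign.add_nodes_from(range(n))
    for j in range(n):
        column = m[:, j]
        if column.max() <= 0:  # fully pruned column: node stays alone
            continue
        assign.add_edge(j, int(np.argmax(column)))
    clusters = [
        frozenset(nodes[i] for i in comp)
        for comp in nx.connected_components(assign)
    ]
    clusters.sort(key=lambda c: (-len(c), sorted(c)))
    return ClusterSet(clusters=clusters, converged=converged,
                      n_iterations=iterations)


def map_complexes(
    reference_complexes: list[tuple[str, frozenset[str]]],
    best_hit_table: dict[str, str],
) -> dict[str, frozenset[str]]:
    """Translate reference complexes into target space via best hits.

    Members without a best hit are dropped; complexes reduced below two
    members are discarded (with a counter logged).
    """
    mapped: dict[str, frozenset[str]] = {}
    discarded = 0
    for name, members in reference_complexes:
        target = frozenset(
            best_hit_table[m] for m in members if m in best_hit_table
        )
        if len(target) >= 2:
            mapped[name] = target
        else:
            discarded += 1
    if discarded:
        logger.info("discarded %d complex(es) with < 2 mapped members", discarded)
    return mapped


def clusters_to_network(
    clusters: list[frozenset[str]] | ClusterSet,
    parent_net: nx.Graph,
) -> nx.Graph:
    """Union of the induced subgraphs of each cluster (no inter-cluster edges)."""
    if isinstance(clusters, ClusterSet):
        clusters = clusters.clusters
    out = nx.Graph()
    for cluster in clusters:
        members = [n for n in cluster if n in parent_net]
        sub = parent_net.subgraph(members)
        out.add_nodes_from(sub.nodes(data=True))
        out.add_edges_from(sub.edges(data=True))
    return out
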