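"""GO shortest-distance quality assessment.

Interacting pairs in a trustworthy network should carry ontology terms
that sit close together; the distributions compare the per-edge minimum
term distance against equally sized sets of annotated non-interacting
pairs.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .errors import ValidationError
from .io_formats import OntologyGraph, canonical_pair

logger = logging.getLogger(__name__)

#: sentinel distance for cross-namespace / disconnected term pairs
UNREACHABLE = math.inf


class _DistanceCache:
    """Per-source BFS over the undirected is_a graph, computed lazily."""

    def __init__(self, ontology: OntologyGraph) -> None:
        self.ontology = ontology
        self.undirected = ontology.graph.to_undirected(as_view=True)
        self._bfs: dict[str, dict[str, int]] = {}

    def from_term(self, term: str) -> dict[str, int]:
        if term not in self._bfs:
            self._bfs[term] = dict(
                nx.single_source_shortest_path_length(self.undirected, term)
            )
        return self._bfs[term]


def term_distance(t1: str, t2: str, ontology: OntologyGraph,
                  _cache: _DistanceCache | None = None) -> float:
    """Shortest is_a path length (edges traversed undirected) within a namespace."""
    for t in (t1, t2):
        if t not in ontology:
            raise ValidationError(f"unknown term {t!r}")
    if ontology.namespace(t1) != ontology.namespace(t2):
        return UNREACHABLE
    if t1 == t2:
        return 0
    cache = _cache or _DistanceCache(ontology)
    return cache.from_term(t1).get(t2, UNREACHABLE)


def pair_distance(
    protein_a: str,
    protein_b: str,
    annotations: dict[str, set[str]],
    ontology: OntologyGraph,
    _cache: _DistanceCache | None = None,
) -> float:
    """Minimum term distance over the two proteins' annotation cross product."""
    terms_a = annotations.get(protein_a, set())
    terms_b = annotations.get(protein_b, set())
    if not terms_a or not terms_b:
        raise ValidationError(
            f"both proteins must be annotated ({protein_a!r}, {protein_b!r})"
        )
    if terms_a & terms_b:
        return 0
    cache = _cache or _DistanceCache(ontology)
    best = UNREACHABLE
    for t1 in sorted(terms_a):
        reach = None
        ns1 = ontology.namespace(t1)
        for t2 in sorted(terms_b):
            if ontology.namespace(t2) != ns1:
                continue
            if reach is None:
                reach = cache.from_term(t1)
            d = reach.get(t2, UNREACHABLE)
            if d < best:
                best = d
    return best


@dataclass
class DistanceSummary:
    observed_median: float
    random_medians: list[float]
    n_edges_used: int
    n_edges_skipped: int
    rank_sum_p: float


def _histogram(distances: list[float]) -> dict[str, int]:
    """Counter keyed by integer distance, with 'inf' as the overflow bin."""
    counter: Counter[str] = Counter()
    for d in distances:
        counter["inf" if math.isinf(d) else str(int(d))] += 1
    return dict(counter)


def distance_distributions(
    net: nx.Graph,
    annotations: dict[str, set[str]],
    ontology: OntologyGraph,
    n_random_sets: int = 5,
    seed: int | None = None,
) -> tuple[dict[str, int], list[dict[str, int]], DistanceSummary]:
    """Observed edge distances vs. uniformly sampled annotated non-edges.

    Each random set contains exactly as many pairs as there are usable
    (both-annotated) network edges, drawn over the same annotated
    protein set but restricted to non-edges.
    """
    cache = _DistanceCache(ontology)
    annotated = sorted(n for n in net.nodes if annotations.get(n))
    if len(annotated) < 10:
        raise ValidationError("need >= 10 annotated proteins in the network")

    observed: list[float] = []
    skipped = 0
    for a, b in net.edges:
        if annotations.get(a) and annotations.get(b):
            observed.append(pair_distance(a, b, annotations, ontology, cache))
        else:
            skipped += 1
    if not observed:
        raise ValidationError("no annotated edges to evaluate")

    n_possible = len(annotated) * (len(annotated) - 1) // 2
    if n_possible - net.number_of_edges() < len(observed):
        raise ValidationError("network too dense to sample required non-edges")

    rng = np.random.default_rng(seed)
    random_sets: list[list[float]] = []
    for _ in range(n_random_sets):
        pairs: set[tuple[str, str]] = set()
        budget = 200 * len(observed)
        while len(pairs) < len(observed) and budget > 0:
            budget -= 1
            i, j = rng.choice(len(annotated), size=2, replace=False)
            a, b = annotated[int(i)], annotated[int(j)]
            if net.has_edge(a, b):
                continue
            pairs.add(canonical_pair(a, b))
        if len(pairs) < len(observed):
            raise ValidationError("could not sample enough non-edges")
        random_sets.append(
            [pair_distance(a, b, annotations, ontology, cache)
             for a, b in sorted(pairs)]
        )

    pooled = [d for s in random_sets for d in s]
    finite_obs = [d for d in observed if not math.isinf(d)]
    finite_rand = [d for d in pooled if not math.isinf(d)]
    if finite_obs and finite_rand:
        p = float(stats.mannwhitneyu(observed, pooled, alternative="less").pvalue)
    else:  # degenerate: everything unreachable
        p = 1.0
    summary = DistanceSummary(
        observed_median=float(np.median(observed)),
        random_medians=[float(np.median(s)) for s in random_sets],
        n_edges_used=len(observed),
        n_edges_skipped=skipped,
        rank_sum_p=p,
    )
    return _histogram(observed), [_histogram(s) for s in random_sets], summary
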