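"""KNN-based validation and filtering of merged candidate interactions.

Five independently trained k-nearest-neighbour classifiers each vote on
every candidate pair; a candidate is kept when at least ``min_votes``
classifiers support it.

The feature representation per pair (an explicit design choice, since
only the training scheme — five balanced positive/negative groups — is
prescribed): ortholog-transfer score, domain-combination score, Pearson
expression correlation across tissues, and the maximum ontology depth of
a shared annotation term.  Features are z-scaled per training group;
distance ties resolve by training-set insertion order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .domains import DcPairScoreTable, DomainArchitecture, score_domain_pair
from .errors import ValidationError
from .interolog import CandidateInteraction, OrthologMap, score_interolog_pair
from .io_formats import EdgeList, ExpressionMatrix, OntologyGraph, canonical_pair

logger = logging.getLogger(__name__)

N_GROUPS = 5
DEFAULT_K = 5
DEFAULT_MIN_VOTES = 2
CORRELATION_CUT = 0.3


def merge_candidates(
    ortholog_candidates: Iterable[CandidateInteraction],
    domain_candidates: Iterable[CandidateInteraction],
) -> list[CandidateInteraction]:
    """Set union on unordered pairs; scores and provenance flags merged."""
    merged: dict[tuple[str, str], CandidateInteraction] = {}
    for cand in list(ortholog_candidates) + list(domain_candidates):
        cur = merged.get(cand.pair)
        if cur is None:
            merged[cand.pair] = CandidateInteraction(
                cand.a, cand.b,
                score_ortho=cand.score_ortho,
                score_domain=cand.score_domain,
                n_support=cand.n_support,
                provenance=cand.provenance,
            )
        else:
            cur.score_ortho = max(cur.score_ortho, cand.score_ortho)
            cur.score_domain = max(cur.score_domain, cand.score_domain)
            cur.n_support = max(cur.n_support, cand.n_support)
            cur.provenance = cur.provenance | cand.provenance
    return [merged[k] for k in sorted(merged)]


class PairFeaturizer:
    """Compute the 4-feature vector for any unordered protein pair."""

    def __init__(
        self,
        ortho_map: OrthologMap,
        ref_ppis: Mapping[str, EdgeList],
        architectures: Mapping[str, DomainArchitecture],
        dc_table: DcPairScoreTable,
        expression: ExpressionMatrix | None = None,
        annotations: Mapping[str, set[str]] | None = None,
        ontology: OntologyGraph | None = None,
    ) -> None:
        self.ortho_map = ortho_map
        self.ref_ppis = dict(ref_ppis)
        self.architectures = architectures
        self.dc_table = dc_table
        self.expression = expression
        self.annotations = annotations or {}
        self._depth = self._term_depths(ontology) if ontology is not None else {}

    @staticmethod
    def _term_depths(ontology: OntologyGraph) -> dict[str, int]:
        """Depth of each term = shortest is_a distance to its namespace root."""
        depths: dict[str, int] = {}
        graph = ontology.graph
        roots = [n for n in graph.nodes if graph.out_degree(n) == 0]
        reverse = graph.reverse(copy=False)
        for root in roots:
            for term, d in nx.single_source_shortest_path_length(
                reverse, root
            ).items():
                if term not in depths or d < depths[term]:
                    depths[term] = d
        return depths

    def expression_correlation(self, a: str, b: str) -> float:
        """Pearson correlation across tissues; 0 when undefined."""
        if self.expression is None:
            return 0.0
        if a not in self.expression or b not in self.expression:
            return 0.0
        x = self.expression.row(a)
        y = self.expression.row(b)
        if len(x) < 2 or x.std() == 0 or y.std() == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    def shared_go_depth(self, a: str, b: str) -> int:
        shared = self.annotations.get(a, set()) & self.annotations.get(b, set())
        if not shared:
            return 0
        return max(self._depth.get(t, 0) for t in shared)

    def features(self, a: str, b: str) -> np.ndarray:
        a, b = canonical_pair(a, b)
        score_o = score_interolog_pair(a, b, self.ortho_map, self.ref_ppis)
        arch_a = self.architectures.get(a)
        arch_b = self.architectures.get(b)
        score_d = (
            score_domain_pair(arch_a, arch_b, self.dc_table)
            if arch_a is not None and arch_b is not None
            else 0.0
        )
        return np.array(
            [score_o, score_d, self.expression_correlation(a, b),
             float(self.shared_go_depth(a, b))]
        )


@dataclass
class TrainingGroup:
    """One balanced positive/negative training group with its z-scaling."""

    features: np.ndarray  # raw feature rows, positives first
    labels: np.ndarray    # 1 = positive, 0 = negative
    mean: np.ndarray = field(init=False)
    std: np.ndarray = field(init=False)
    scaled: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.mean = self.features.mean(axis=0)
        std = self.features.std(axis=0)
        std[std == 0] = 1.0
        self.std = std
        self.scaled = (self.features - self.mean) / self.std

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class TrainingSplit:
    groups: list[TrainingGroup]


def build_training_splits(
    positives: Sequence[tuple[str, str]],
    universe_proteins: Sequence[str],
    featurizer: PairFeaturizer,
    expression: ExpressionMatrix | None,
    seed: int,
    n_groups: int = N_GROUPS,
    correlation_cut: float = CORRELATION_CUT,
) -> TrainingSplit:
    """Shuffle positives into ``n_groups`` equal groups; sample balanced negatives.

    Negative candidates are uniform random protein pairs; a candidate is
    rejected when it is itself a positive pair or when its two members'
    expression profiles correlate above ``correlation_cut`` (such pairs
    may be genuinely related and would poison the negative set).
    """
    positive_set = {canonical_pair(a, b) for a, b in positives}
    ordered = sorted(positive_set)
    if not ordered:
        raise ValidationError("positive set is empty")
    rng = np.random.default_rng(seed)
    rng.shuffle(ordered)
    group_size = len(ordered) // n_groups
    if group_size == 0:
        raise ValidationError(
            f"{len(ordered)} positives cannot fill {n_groups} groups"
        )
    dropped = len(ordered) - group_size * n_groups
    if dropped:
        logger.info("dropping %d positive(s) to equalize groups", dropped)

    proteins = sorted(universe_proteins)
    needed = group_size * n_groups
    negatives: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    budget = 500 * needed
    while len(negatives) < needed and budget > 0:
        budget -= 1
        i, j = rng.integers(len(proteins), size=2)
        if i == j:
            continue
        pair = canonical_pair(proteins[int(i)], proteins[int(j)])
        if pair in positive_set or pair in seen:
            continue
        if (
            expression is not None
            and featurizer.expression_correlation(*pair) > correlation_cut
        ):
            continue
        seen.add(pair)
        negatives.append(pair)
    if len(negatives) < needed:
        raise ValidationError(
            f"insufficient eligible negatives: needed {needed}, "
            f"found {len(negatives)}"
        )

    groups: list[TrainingGroup] = []
    for g in range(n_groups):
        pos = ordered[g * group_size:(g + 1) * group_size]
        neg = negatives[g * group_size:(g + 1) * group_size]
        rows = [featurizer.features(a, b) for a, b in pos]
        rows += [featurizer.features(a, b) for a, b in neg]
        labels = np.array([1] * len(pos) + [0] * len(neg))
        groups.append(TrainingGroup(np.array(rows), labels))
    return TrainingSplit(groups=groups)


def knn_vote(
    pair_features: np.ndarray, group: TrainingGroup, k: int = DEFAULT_K
) -> bool:
    """Majority label among the k nearest training rows (Euclidean, z-scaled)."""
    if len(group) == 0:
        raise ValidationError("training group is empty")
    if k > len(group):
        logger.warning("k=%d larger than group size %d; clamped", k, len(group))
        k = len(group)
    query = (np.asarray(pair_features) - group.mean) / group.std
    distances = np.linalg.norm(group.scaled - query, axis=1)
    nearest = np.argsort(distances, kind="stable")[:k]  # stable = insertion order
    return int(group.labels[nearest].sum()) * 2 > k


def count_votes(
    pair_features: np.ndarray, splits: TrainingSplit, k: int = DEFAULT_K
) -> int:
    return sum(knn_vote(pair_features, g, k) for g in splits.groups)


def filter_network(
    candidates: Iterable[CandidateInteraction],
    splits: TrainingSplit,
    featurizer: PairFeaturizer,
    k: int = DEFAULT_K,
    min_votes: int = DEFAULT_MIN_VOTES,
) -> nx.Graph:
    """Keep candidates supported by >= min_votes of the classifiers."""
    net = nx.Graph()
    for cand in candidates:
        votes = count_votes(featurizer.features(cand.a, cand.b), splits, k)
        cand.votes = votes
        if votes >= min_votes:
            net.add_edge(
                cand.a, cand.b,
                score_ortho=cand.score_ortho,
                score_domain=cand.score_domain,
                votes=votes,
                provenance="+".join(sorted(cand.provenance)),
            )
    return net


def verification_rate(
    pairs: Sequence[tuple[str, str]],
    splits: TrainingSplit,
    featurizer: PairFeaturizer,
    k: int = DEFAULT_K,
    min_votes: int = DEFAULT_MIN_VOTES,
) -> float:
    """Fraction of pairs supported by >= min_votes classifiers."""
    pairs = list(pairs)
    if not pairs:
        raise ValidationError("cannot compute a verification rate of no pairs")
    supported = sum(
        count_votes(featurizer.features(a, b), splits, k) >= min_votes
        for a, b in pairs
    )
    return supported / len(pairs)
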