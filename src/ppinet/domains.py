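"""Domain-combination (dc-pair) interaction prediction.

A protein with ``m`` distinct domains has ``2^m - 1`` nonempty domain
combinations; a pair of proteins therefore yields
``(2^m - 1)(2^n - 1)`` dc-pairs.  Each dc-pair observed on a reference
interaction is scored ``1 / ((2^m - 1)(2^n - 1))`` with m, n taken from
that reference pair, and the per-dc-pair maximum over all reference
interactions is kept.  The pair-level score is the sum of the rated
dc-pair scores times the rated/all dc-pair ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ValidationError
from .interolog import CandidateInteraction
from .io_formats import DomainHit, EdgeList, canonical_pair

logger = logging.getLogger(__name__)

DEFAULT_EVALUE = 1e-3
DEFAULT_COV_MULTI = 0.6
DEFAULT_COV_SINGLE = 0.9
#: warn above this architecture size; subset counts grow as 2^m
LARGE_ARCHITECTURE = 10

# a domain combination is a sorted tuple of domain IDs; a canonical dc-pair
# is the sorted pair of two combinations, so (L, R) == (R, L)
Combination = tuple[str, ...]
DcPair = tuple[Combination, Combination]


@dataclass(frozen=True)
class DomainArchitecture:
    """A protein's distinct-domain set (duplicate hits collapse)."""

    protein_id: str
    domains: frozenset[str]

    def __post_init__(self) -> None:
        if not self.domains:
            raise ValidationError(
                f"architecture for {self.protein_id!r} must be nonempty"
            )

    @property
    def size(self) -> int:
        return len(self.domains)


class DcPairScoreTable:
    """Canonical dc-pair -> maximum observed score in (0, 1]."""

    def __init__(self) -> None:
        self.scores: dict[DcPair, float] = {}

    def record(self, dc_pair: DcPair, score: float) -> None:
        cur = self.scores.get(dc_pair)
        if cur is None or score > cur:
            self.scores[dc_pair] = score

    def __len__(self) -> int:
        return len(self.scores)

    def __contains__(self, dc_pair: DcPair) -> bool:
        return dc_pair in self.scores

    def get(self, dc_pair: DcPair) -> float | None:
        return self.scores.get(dc_pair)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("left\tright\tscore\n")
            for (left, right), score in sorted(self.scores.items()):
                fh.write(f"{'+'.join(left)}\t{'+'.join(right)}\t{score:.12g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DcPairScoreTable":
        table = cls()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("left\t"):
                raise ValidationError(f"{path}: missing dc-pair table header")
            for line in fh:
                left_s, right_s, score_s = line.rstrip("\n").split("\t")
                key = _canonical_dc_pair(
                    tuple(left_s.split("+")), tuple(right_s.split("+"))
                )
                table.record(key, float(score_s))
        return table


def _canonical_dc_pair(left: Combination, right: Combination) -> DcPair:
    return (left, right) if left <= right else (right, left)


def _nonempty_subsets(domains: frozenset[str]) -> list[Combination]:
    ordered = sorted(domains)
    out: list[Combination] = []
    for size in range(1, len(ordered) + 1):
        out.extend(combinations(ordered, size))
    return out


def filter_domain_hits(
    hits: Iterable[DomainHit],
    e_max: float = DEFAULT_EVALUE,
    cov_multi: float = DEFAULT_COV_MULTI,
    cov_single: float = DEFAULT_COV_SINGLE,
) -> dict[str, DomainArchitecture]:
    """E-value then coverage filtering of raw domain hits.

    The multi/single classification uses the distinct-domain count that
    survives the e-value filter; multi-domain proteins need coverage
    strictly > ``cov_multi``, single-domain strictly > ``cov_single``.
    Proteins with no surviving hit are absent from the result.
    """
    by_protein: dict[str, list[DomainHit]] = {}
    for hit in hits:
        if hit.e_value <= e_max:
            by_protein.setdefault(hit.protein_id, []).append(hit)
    out: dict[str, DomainArchitecture] = {}
    for protein, phits in by_protein.items():
        n_distinct = len({h.domain_id for h in phits})
        cut = cov_multi if n_distinct >= 2 else cov_single
        surviving = frozenset(h.domain_id for h in phits if h.coverage > cut)
        if surviving:
            out[protein] = DomainArchitecture(protein, surviving)
    return out


def score_dc_pair(m: int, n: int) -> float:
    """1 / ((2^m - 1)(2^n - 1)) for a reference pair with m and n domains."""
    if m < 1 or n < 1:
        raise ValidationError(f"domain counts must be >= 1, got m={m}, n={n}")
    return 1.0 / ((2**m - 1) * (2**n - 1))


def enumerate_dc_pairs(
    arch_a: DomainArchitecture, arch_b: DomainArchitecture
) -> list[DcPair]:
    """All canonical dc-pairs between two architectures.

    For disjoint domain sets the count is exactly
    ``(2^m - 1)(2^n - 1)``; overlapping architectures can produce the
    same canonical pair from both orientations, which is deduplicated.
    """
    for arch in (arch_a, arch_b):
        if arch.size > LARGE_ARCHITECTURE:
            logger.warning(
                "architecture %s has %d domains; 2^m combinations is large",
                arch.protein_id, arch.size,
            )
    seen: set[DcPair] = set()
    out: list[DcPair] = []
    for left in _nonempty_subsets(arch_a.domains):
        for right in _nonempty_subsets(arch_b.domains):
            key = _canonical_dc_pair(left, right)
            if key not in seen:
                seen.add(key)
                out.append(key)
    return out


def build_score_table(
    ref_ppis: Mapping[str, EdgeList],
    ref_architectures: Mapping[str, DomainArchitecture],
) -> DcPairScoreTable:
    """Score every dc-pair of every reference edge; keep the per-key maximum."""
    table = DcPairScoreTable()
    skipped = 0
    total = 0
    for organism in sorted(ref_ppis):
        for a, b in sorted(ref_ppis[organism].edges):
            total += 1
            arch_a = ref_architectures.get(a)
            arch_b = ref_architectures.get(b)
            if arch_a is None or arch_b is None:
                skipped += 1
                continue
            score = score_dc_pair(arch_a.size, arch_b.size)
            for dc_pair in enumerate_dc_pairs(arch_a, arch_b):
                table.record(dc_pair, score)
    if total == 0:
        logger.warning("no reference edges; dc-pair table is empty")
    elif skipped:
        logger.info("skipped %d/%d reference edges lacking architectures",
                    skipped, total)
    return table


def score_domain_pair(
    arch_a: DomainArchitecture,
    arch_b: DomainArchitecture,
    table: DcPairScoreTable,
) -> float:
    """(sum of rated dc-pair table scores) * (|rated| / |all dc-pairs|)."""
    all_pairs = enumerate_dc_pairs(arch_a, arch_b)
    rated = [p for p in all_pairs if p in table]
    if not rated:
        return 0.0
    total = sum(table.scores[p] for p in rated)
    return total * (len(rated) / len(all_pairs))


def predict_domain_interactions(
    architectures: Mapping[str, DomainArchitecture],
    table: DcPairScoreTable,
    threshold: float = 0.25,
) -> list[CandidateInteraction]:
    """Candidate pairs among proteins sharing at least one rated dc-pair.

    An inverted index from rated combinations to proteins containing
    them restricts the quadratic pair enumeration to plausible pairs.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    # index: rated combination -> proteins whose architecture contains it
    combo_proteins: dict[Combination, set[str]] = {}
    rated_combos = {c for pair in table.scores for c in pair}
    for protein in sorted(architectures):
        domains = architectures[protein].domains
        for combo in rated_combos:
            if domains.issuperset(combo):
                combo_proteins.setdefault(combo, set()).add(protein)
    candidates: set[tuple[str, str]] = set()
    for left, right in table.scores:
        for a in combo_proteins.get(left, ()):
            for b in combo_proteins.get(right, ()):
                if a != b:
                    candidates.add(canonical_pair(a, b))
    out: list[CandidateInteraction] = []
    for a, b in sorted(candidates):
        score = score_domain_pair(architectures[a], architectures[b], table)
        if score > 0 and score >= threshold:
            out.append(
                CandidateInteraction(
                    a, b, score_domain=score, provenance=frozenset({"domain"})
                )
            )
    return out
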