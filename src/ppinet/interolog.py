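"""Ortholog-transfer (interolog) interaction prediction.

A candidate pair of target proteins is supported by reference organism
``i`` when both members have an ortholog in organism ``i`` and those two
orthologs interact there.  The pair score is the sum, over supporting
organisms, of the product of the two normalized ortholog scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import ValidationError
from .io_formats import EdgeList, OrthologRow, canonical_pair

logger = logging.getLogger(__name__)

DEFAULT_CAP = 4600.0
DEFAULT_THRESHOLD = 0.15


@dataclass
class CandidateInteraction:
    """An unordered candidate pair with its evidence scores."""

    a: str
    b: str
    score_ortho: float = 0.0
    score_domain: float = 0.0
    n_support: int = 0
    provenance: frozenset[str] = frozenset()
    votes: int = -1

    def __post_init__(self) -> None:
        self.a, self.b = canonical_pair(self.a, self.b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a, self.b)


# OrthologMap: organism -> target protein -> (ref protein, normalized score)
OrthologMap = dict[str, dict[str, tuple[str, float]]]


def normalize_inparanoid(raw_score: float, cap: float = DEFAULT_CAP) -> float:
    """min(raw, cap) / cap, mapping raw ortholog scores into [0, 1]."""
    if raw_score < 0:
        raise ValidationError(f"raw score must be >= 0, got {raw_score}")
    if cap <= 0:
        raise ValidationError(f"cap must be > 0, got {cap}")
    return min(raw_score, cap) / cap


def build_ortholog_map(rows: list[OrthologRow], cap: float = DEFAULT_CAP) -> OrthologMap:
    """Keep the best-raw-score ortholog per (target, organism), then normalize.

    Ties on raw score are broken toward the lexicographically smallest
    reference protein ID so the map is deterministic.
    """
    best: dict[tuple[str, str], OrthologRow] = {}
    for row in rows:
        key = (row.ref_organism, row.query_id)
        cur = best.get(key)
        if (
            cur is None
            or row.raw_score > cur.raw_score
            or (row.raw_score == cur.raw_score and row.ref_id < cur.ref_id)
        ):
            best[key] = row
    omap: OrthologMap = {}
    for (organism, target), row in best.items():
        omap.setdefault(organism, {})[target] = (
            row.ref_id,
            normalize_inparanoid(row.raw_score, cap),
        )
    return omap


def score_interolog_pair(
    a: str,
    b: str,
    ortho_map: OrthologMap,
    ref_ppis: dict[str, EdgeList],
) -> float:
    """Sum over organisms of InScore_a * InScore_b where the orthologs interact."""
    if a == b:
        raise ValidationError(f"self-pair {a!r} cannot be scored")
    total = 0.0
    for organism, edges in ref_ppis.items():
        targets = ortho_map.get(organism, {})
        if a not in targets or b not in targets:
            continue
        ref_a, score_a = targets[a]
        ref_b, score_b = targets[b]
        if ref_a != ref_b and (ref_a, ref_b) in edges:
            total += score_a * score_b
    return total


def predict_interologs(
    ortho_map: OrthologMap,
    ref_ppis: dict[str, EdgeList],
    threshold: float = DEFAULT_THRESHOLD,
    proteome: set[str] | None = None,
) -> list[CandidateInteraction]:
    """Score all pairs reachable from reference edges; keep score >= threshold.

    Enumeration is driven from the reference edges (via the reverse
    ortholog lookup), so the cost is linear in the total number of
    reference interactions rather than quadratic in the proteome.
    """
    if not any(len(e) for e in ref_ppis.values()):
        logger.warning("all reference PPI sets are empty; no candidates")
        return []
    # accumulate per-pair score and support count
    scores: dict[tuple[str, str], float] = {}
    support: dict[tuple[str, str], int] = {}
    for organism, edges in ref_ppis.items():
        targets = ortho_map.get(organism, {})
        reverse: dict[str, list[tuple[str, float]]] = {}
        for tgt, (ref, inscore) in targets.items():
            if proteome is not None and tgt not in proteome:
                continue
            reverse.setdefault(ref, []).append((tgt, inscore))
        for ref_a, ref_b in edges:
            for tgt_a, s_a in reverse.get(ref_a, ()):
                for tgt_b, s_b in reverse.get(ref_b, ()):
                    if tgt_a == tgt_b:
                        continue
                    key = canonical_pair(tgt_a, tgt_b)
                    scores[key] = scores.get(key, 0.0) + s_a * s_b
                    support[key] = support.get(key, 0) + 1
    out = [
        CandidateInteraction(
            a,
            b,
            score_ortho=score,
            n_support=support[(a, b)],
            provenance=frozenset({"ortholog"}),
        )
        for (a, b), score in scores.items()
        if score >= threshold
    ]
    out.sort(key=lambda c: c.pair)
    return out
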