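"""Expression statistics over interaction networks.

Implements RPKM, the per-gene expression difference of interactors
(EDI: sum over partners of |RPKM_A/D_A - RPKM_i/D_i|), its cross-tissue
range (EDI variation, with the minimum forced to 0 for genes silent in
any tissue), class- and topology-stratified EDI distributions, the
node-removal robustness sweep and the highly-expressed sub-network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .errors import ValidationError
from .io_formats import ExpressionMatrix
from .topology import average_shortest_path, betweenness, components

logger = logging.getLogger(__name__)


def rpkm(read_count: int, exon_length_bp: int, mapped_reads: int) -> float:
    """Reads per kilobase of exon model per million mapped reads."""
    if read_count < 0:
        raise ValidationError("read count must be >= 0")
    if exon_length_bp <= 0 or mapped_reads <= 0:
        raise ValidationError("exon length and library size must be > 0")
    return read_count / ((exon_length_bp / 1000.0) * (mapped_reads / 1e6))


def edi(
    gene: str,
    net: nx.Graph,
    tissue_expression: Mapping[str, float],
    mode: str = "abs",
) -> float:
    """Sum over interaction partners of the degree-normalized RPKM difference.

    ``mode='abs'`` (default) sums absolute differences; ``'signed'``
    sums raw differences.  Partners missing from the expression map are
    treated as unexpressed (0).
    """
    if gene not in net:
        raise ValidationError(f"gene {gene!r} not in network")
    partners = list(net.neighbors(gene))
    if not partners:
        raise ValidationError(f"EDI undefined for isolated gene {gene!r}")
    if mode not in ("abs", "signed"):
        raise ValidationError(f"unknown EDI mode {mode!r}")
    own = tissue_expression.get(gene, 0.0) / net.degree(gene)
    total = 0.0
    for p in partners:
        term = own - tissue_expression.get(p, 0.0) / net.degree(p)
        total += abs(term) if mode == "abs" else term
    return total


def edi_variation(
    per_tissue_edi: Mapping[str, float],
    expressed: Mapping[str, bool],
) -> float:
    """max(EDI) - min(EDI) across tissues; min forced to 0 if any tissue silent."""
    if not per_tissue_edi:
        raise ValidationError("need EDI for at least one tissue")
    values = [per_tissue_edi[t] for t in per_tissue_edi]
    highest = max(values)
    lowest = min(values)
    if not all(expressed.get(t, False) for t in per_tissue_edi):
        lowest = 0.0
    return highest - lowest


@dataclass
class EdiProfile:
    gene: str
    per_tissue: dict[str, float]
    variation: float
    degree: int


def edi_profiles(
    net: nx.Graph,
    expression: ExpressionMatrix,
    mode: str = "abs",
) -> dict[str, EdiProfile]:
    """Per-tissue EDI plus variation for every non-isolated network gene."""
    profiles: dict[str, EdiProfile] = {}
    tissues = expression.tissues
    columns = {t: expression.df[t].to_dict() for t in tissues}
    for gene in net.nodes:
        if net.degree(gene) == 0 or gene not in expression:
            continue
        per_tissue = {
            t: edi(gene, net, columns[t], mode=mode) for t in tissues
        }
        expressed = {t: columns[t].get(gene, 0.0) > 0 for t in tissues}
        profiles[gene] = EdiProfile(
            gene=gene,
            per_tissue=per_tissue,
            variation=edi_variation(per_tissue, expressed),
            degree=net.degree(gene),
        )
    return profiles


def _summary_edi(profile: EdiProfile) -> float:
    """Scalar per-gene EDI used for histograms: mean across tissues."""
    return float(np.mean(list(profile.per_tissue.values())))


def edi_distribution_by_class(
    networks: Mapping[str, nx.Graph],
    expression: ExpressionMatrix,
    n_bins: int = 50,
    mode: str = "abs",
) -> dict[str, dict]:
    """Per-network EDI histograms on one shared binning centered at 0."""
    values: dict[str, np.ndarray] = {}
    for label, net in networks.items():
        profiles = edi_profiles(net, expression, mode=mode)
        values[label] = np.array(
            [_summary_edi(p) for _, p in sorted(profiles.items())]
        )
    nonempty = [v for v in values.values() if len(v)]
    if nonempty:
        hi = max(float(np.max(np.abs(v))) for v in nonempty) or 1.0
    else:
        hi = 1.0
    edges = np.linspace(-hi, hi, n_bins + 1)
    out: dict[str, dict] = {}
    for label, v in values.items():
        counts, _ = np.histogram(v, bins=edges)
        out[label] = {"values": v, "hist": counts, "bin_edges": edges}
    return out


def stratify_by_topology(
    net: nx.Graph,
    expression: ExpressionMatrix,
    degree_cut: int = 10,
    bc_split: float | None = None,
    mode: str = "abs",
) -> dict[str, np.ndarray]:
    """EDI values in three strata: low-degree, high-degree/high-BC,
    high-degree/low-BC.

    ``bc_split`` defaults to the median betweenness of the high-degree
    genes.
    """
    profiles = edi_profiles(net, expression, mode=mode)
    bc = betweenness(net)
    high = [g for g in profiles if profiles[g].degree > degree_cut]
    if bc_split is None:
        bc_split = float(np.median([bc[g] for g in high])) if high else 0.0
    strata: dict[str, list[float]] = {
        "low_degree": [], "high_degree_high_bc": [], "high_degree_low_bc": []
    }
    for gene, profile in sorted(profiles.items()):
        value = _summary_edi(profile)
        if profile.degree <= degree_cut:
            strata["low_degree"].append(value)
        elif bc[gene] > bc_split:
            strata["high_degree_high_bc"].append(value)
        else:
            strata["high_degree_low_bc"].append(value)
    for label, vals in strata.items():
        if not vals:
            logger.warning("stratum %s is empty", label)
    return {k: np.array(v) for k, v in strata.items()}


@dataclass
class RemovalRow:
    threshold: float
    n_removed: int
    asp_targeted: float | None
    asp_random: float | None
    flagged: bool


def removal_experiment(
    net: nx.Graph,
    edi_var: Mapping[str, float],
    thresholds: Iterable[float] = range(10, 101),
    seed: int | None = None,
    path_sample: int | None = None,
) -> list[RemovalRow]:
    """Targeted (EDI-variation > threshold) vs. random node removal.

    For each threshold the average shortest path of the largest
    remaining component is compared against removing the same number of
    uniformly chosen nodes.
    """
    missing = [n for n in net.nodes if n not in edi_var]
    if missing:
        raise ValidationError(
            f"EDI variation missing for {len(missing)} node(s), e.g. {missing[0]!r}"
        )
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes)
    rows: list[RemovalRow] = []
    for threshold in thresholds:
        targeted = [n for n in nodes if edi_var[n] > threshold]
        rand_idx = rng.choice(len(nodes), size=len(targeted), replace=False)
        random_removed = [nodes[int(i)] for i in rand_idx]
        row = RemovalRow(float(threshold), len(targeted), None, None, False)
        for attr, removed in (
            ("asp_targeted", targeted), ("asp_random", random_removed)
        ):
            remaining = net.copy()
            remaining.remove_nodes_from(removed)
            try:
                asp = average_shortest_path(
                    remaining, sample_size=path_sample, seed=seed
                )
            except ValidationError:
                row.flagged = True
                continue
            setattr(row, attr, asp)
        rows.append(row)
    return rows


def high_expression_subnetwork(
    net: nx.Graph,
    expression: ExpressionMatrix,
    min_tissues: int = 3,
    quantile_cut: float = 0.75,
) -> nx.Graph:
    """Induced subgraph of genes above the per-tissue expression quantile
    (and expressed at all) in at least ``min_tissues`` tissues."""
    if not (0 <= quantile_cut <= 1):
        raise ValidationError("quantile_cut must be in [0, 1]")
    cuts = {
        t: float(np.quantile(expression.df[t].to_numpy(), quantile_cut))
        for t in expression.tissues
    }
    keep = []
    for gene in sorted(net.nodes):
        if gene not in expression:
            continue
        n_high = sum(
            1
            for t in expression.tissues
            if expression.value(gene, t) >= cuts[t] and expression.value(gene, t) > 0
        )
        if n_high >= min_tissues:
            keep.append(gene)
    return net.subgraph(keep).copy()
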