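"""End-to-end pipeline orchestration: predict -> filter -> assess.

A single flat :class:`PipelineConfig` carries every tunable with the
published defaults (score cap 4600, transfer threshold 0.15, e-value
1e-3, coverage 0.6/0.9, five training groups, two votes, removal
thresholds 10..100).  Runs are fully seeded and write a manifest with
input checksums so identical configurations produce identical output
trees byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from . import (
    domains,
    expression as expr_mod,
    go_validation,
    interolog,
    knn_filter,
    mcl as mcl_mod,
    synthetic,
    topology,
)
from .errors import ConfigurationError
from .io_formats import (
    EdgeList,
    graph_to_edgelist,
    read_annotations,
    read_complexes,
    read_domtblout,
    read_edge_list,
    read_expression,
    read_obo,
    read_ortholog_table,
    write_edge_list,
    write_sif,
)

logger = logging.getLogger(__name__)

STAGE_ORDER = [
    "simulate",
    "predict-ortho",
    "predict-domain",
    "merge",
    "knn-filter",
    "topology",
    "go-validate",
    "mcl",
    "map-complexes",
    "edi",
    "edi-removal",
]


@dataclass
class PipelineConfig:
    seed: int = 0
    # interolog transfer
    cap: float = 4600.0
    ortho_threshold: float = 0.15
    # domain prediction
    evalue: float = 1e-3
    cov_multi: float = 0.6
    cov_single: float = 0.9
    domain_threshold: float = 0.25
    # knn filter
    knn_k: int = 5
    n_groups: int = 5
    min_votes: int = 2
    correlation_cut: float = 0.3
    # analyses
    inflation: float = 2.0
    degree_cut: int = 10
    removal_min: int = 10
    removal_max: int = 100
    removal_step: int = 1
    min_tissues: int = 3
    quantile_cut: float = 0.75
    n_random_go_sets: int = 5
    # synthetic universe (used when input_dir is unset)
    n_proteins: int = 300
    n_domains: int = 30
    n_ddi_rules: int = 40
    noise_rate: float = 0.05
    n_tissues: int = 4
    # input/stage selection
    input_dir: str | None = None
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {', '.join(unknown)}")
        config = cls(**data)
        bad = sorted(set(config.stages) - set(STAGE_ORDER))
        if bad:
            raise ConfigurationError(f"unknown stage(s): {', '.join(bad)}")
        return config

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


INPUT_FILES = [
    "ortholog_table.tsv",
    "target.domtblout",
    "ontology.obo",
    "annotations.tsv",
    "expression.tsv",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj: object, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _round(x: float | None, digits: int = 10) -> float | None:
    return None if x is None else round(float(x), digits)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the requested stages in dependency order; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGE_ORDER if s in config.stages]
    manifest: dict = {"config": config.to_dict(), "stages": {}, "inputs": {}}

    # --- inputs: simulate or load ----------------------------------------
    if config.input_dir is None:
        input_dir = outdir / "universe"
        if "simulate" in stages or not input_dir.exists():
            universe = synthetic.generate_universe(
                seed=config.seed,
                n_proteins=config.n_proteins,
                n_domains=config.n_domains,
                n_ddi_rules=config.n_ddi_rules,
                noise_rate=config.noise_rate,
                n_tissues=config.n_tissues,
            )
            synthetic.write_universe(universe, input_dir)
            manifest["stages"]["simulate"] = {
                "n_proteins": len(universe.proteins),
                "n_true_edges": len(universe.true_edges),
                "n_ddi_rules": len(universe.ddi_rules),
                "n_complexes": len(universe.complexes),
            }
    else:
        input_dir = Path(config.input_dir)
    for name in INPUT_FILES:
        path = input_dir / name
        if not path.is_file():
            raise ConfigurationError(f"missing input file: {path}")
        manifest["inputs"][name] = _sha256(path)

    # --- shared inputs ----------------------------------------------------
    rows = read_ortholog_table(input_dir / "ortholog_table.tsv")
    ortho_map = interolog.build_ortholog_map(rows, cap=config.cap)
    ref_ppis: dict[str, EdgeList] = {}
    for path in sorted((input_dir / "ref_ppis").glob("*.tsv")):
        ref_ppis[path.stem] = read_edge_list(path)
    expression = read_expression(input_dir / "expression.tsv")
    annotations = read_annotations(input_dir / "annotations.tsv")
    ontology = read_obo(input_dir / "ontology.obo")
    proteome = set(expression.genes)

    target_hits = read_domtblout(input_dir / "target.domtblout")
    architectures = domains.filter_domain_hits(
        target_hits, e_max=config.evalue,
        cov_multi=config.cov_multi, cov_single=config.cov_single,
    )
    ref_architectures: dict[str, domains.DomainArchitecture] = {}
    for path in sorted((input_dir / "ref_domtblout").glob("*.domtblout")):
        ref_architectures.update(
            domains.filter_domain_hits(
                read_domtblout(path), e_max=config.evalue,
                cov_multi=config.cov_multi, cov_single=config.cov_single,
            )
        )
    dc_table = domains.build_score_table(ref_ppis, ref_architectures)
    featurizer = knn_filter.PairFeaturizer(
        ortho_map, ref_ppis, architectures, dc_table,
        expression=expression, annotations=annotations, ontology=ontology,
    )

    ortho_cands: list[interolog.CandidateInteraction] = []
    domain_cands: list[interolog.CandidateInteraction] = []
    merged: list[interolog.CandidateInteraction] = []
    net: nx.Graph | None = None
    clusters: mcl_mod.ClusterSet | None = None

    def _load_network() -> nx.Graph:
        path = outdir / "network.tsv"
        if net is not None:
            return net
        if not path.is_file():
            raise ConfigurationError(
                "network.tsv not found; run the knn-filter stage first"
            )
        return read_edge_list(path).to_graph()

    for stage in stages:
        if stage == "simulate":
            continue  # handled above

        elif stage == "predict-ortho":
            ortho_cands = interolog.predict_interologs(
                ortho_map, ref_ppis, threshold=config.ortho_threshold,
                proteome=proteome,
            )
            el = EdgeList()
            for c in ortho_cands:
                el.add(c.a, c.b, score_ortho=f"{c.score_ortho:.6g}",
                       n_support=c.n_support)
            write_edge_list(el, outdir / "candidates_ortholog.tsv")
            manifest["stages"][stage] = {"n_candidates": len(ortho_cands)}
            logger.info("predict-ortho: %d candidates", len(ortho_cands))

        elif stage == "predict-domain":
            dc_table.to_tsv(outdir / "dc_pair_scores.tsv")
            domain_cands = domains.predict_domain_interactions(
                architectures, dc_table, threshold=config.domain_threshold
            )
            el = EdgeList()
            for c in domain_cands:
                el.add(c.a, c.b, score_domain=f"{c.score_domain:.6g}")
            write_edge_list(el, outdir / "candidates_domain.tsv")
            manifest["stages"][stage] = {
                "n_candidates": len(domain_cands),
                "n_dc_pairs": len(dc_table),
            }
            logger.info("predict-domain: %d candidates", len(domain_cands))

        elif stage == "merge":
            merged = knn_filter.merge_candidates(ortho_cands, domain_cands)
            el = EdgeList()
            for c in merged:
                el.add(c.a, c.b, score_ortho=f"{c.score_ortho:.6g}",
                       score_domain=f"{c.score_domain:.6g}",
                       provenance="+".join(sorted(c.provenance)))
            write_edge_list(el, outdir / "candidates_merged.tsv")
            manifest["stages"][stage] = {"n_candidates": len(merged)}
            logger.info("merge: %d candidates", len(merged))

        elif stage == "knn-filter":
            positives: set[tuple[str, str]] = set()
            for organism, edges in ref_ppis.items():
                reverse: dict[str, list[str]] = {}
                for tgt, (ref, _) in ortho_map.get(organism, {}).items():
                    reverse.setdefault(ref, []).append(tgt)
                for ra, rb in edges:
                    for ta in reverse.get(ra, ()):
                        for tb in reverse.get(rb, ()):
                            if ta != tb:
                                positives.add(
                                    interolog.canonical_pair(ta, tb)
                                )
            splits = knn_filter.build_training_splits(
                sorted(positives), sorted(proteome), featurizer, expression,
                seed=config.seed, n_groups=config.n_groups,
                correlation_cut=config.correlation_cut,
            )
            net = knn_filter.filter_network(
                merged, splits, featurizer,
                k=config.knn_k, min_votes=config.min_votes,
            )
            write_edge_list(graph_to_edgelist(net), outdir / "network.tsv")
            write_sif(net, outdir / "network.sif")
            rate = (
                knn_filter.verification_rate(
                    [c.pair for c in merged], splits, featurizer,
                    k=config.knn_k, min_votes=config.min_votes,
                )
                if merged else 0.0
            )
            manifest["stages"][stage] = {
                "n_candidates_in": len(merged),
                "n_kept": net.number_of_edges(),
                "verification_rate": _round(rate, 6),
            }
            logger.info("knn-filter: %d in -> %d kept (%.1f%% verified)",
                        len(merged), net.number_of_edges(), 100 * rate)

        elif stage == "topology":
            net = _load_network()
            summary = {k: _round(v, 6) for k, v in topology.summarize(net).items()}
            bc = topology.betweenness(net)
            cc, _ = topology.clustering_coefficients(net)
            with open(outdir / "node_metrics.tsv", "w") as fh:
                fh.write("protein\tdegree\tbetweenness\tclustering\n")
                for n in sorted(net.nodes):
                    fh.write(f"{n}\t{net.degree(n)}\t{bc[n]:.6g}\t{cc[n]:.6g}\n")
            if net.number_of_edges() >= 2:
                random_net = topology.degree_preserving_random(net, seed=config.seed)
                _, random_cc = topology.clustering_coefficients(random_net)
                summary["random_average_clustering"] = _round(random_cc, 6)
            _write_json(summary, outdir / "topology_summary.json")
            manifest["stages"][stage] = summary

        elif stage == "go-validate":
            net = _load_network()
            observed, randoms, summary = go_validation.distance_distributions(
                net, annotations, ontology,
                n_random_sets=config.n_random_go_sets, seed=config.seed,
            )
            _write_json(
                {
                    "observed": observed,
                    "random_sets": randoms,
                    "observed_median": summary.observed_median,
                    "random_medians": summary.random_medians,
                    "rank_sum_p": _round(summary.rank_sum_p, 12),
                    "n_edges_used": summary.n_edges_used,
                    "n_edges_skipped": summary.n_edges_skipped,
                },
                outdir / "go_distances.json",
            )
            manifest["stages"][stage] = {
                "observed_median": summary.observed_median,
                "random_medians": summary.random_medians,
            }

        elif stage == "mcl":
            net = _load_network()
            clusters = mcl_mod.mcl(net, inflation=config.inflation)
            with open(outdir / "clusters.tsv", "w") as fh:
                fh.write("cluster_id\tmember\n")
                for i, cluster in enumerate(clusters.clusters):
                    for member in sorted(cluster):
                        fh.write(f"{i}\t{member}\n")
            manifest["stages"][stage] = {
                "n_clusters": len(clusters),
                "converged": clusters.converged,
            }

        elif stage == "map-complexes":
            ref_complexes_path = input_dir / "ref_complexes.tsv"
            best_hits_path = input_dir / "best_hits.tsv"
            if not (ref_complexes_path.is_file() and best_hits_path.is_file()):
                logger.warning("complex inputs absent; skipping map-complexes")
                continue
            ref_complexes = read_complexes(ref_complexes_path)
            best_hits: dict[str, str] = {}
            with open(best_hits_path) as fh:
                for line in fh:
                    fields = line.rstrip("\n").split("\t")
                    if len(fields) == 2 and fields[0] != "ref_id":
                        best_hits[fields[0]] = fields[1]
            mapped = mcl_mod.map_complexes(ref_complexes, best_hits)
            with open(outdir / "complexes_mapped.tsv", "w") as fh:
                for name in sorted(mapped):
                    fh.write("\t".join([name, *sorted(mapped[name])]) + "\n")
            manifest["stages"][stage] = {"n_complexes": len(mapped)}

        elif stage == "edi":
            net = _load_network()
            profiles = expr_mod.edi_profiles(net, expression)
            with open(outdir / "edi.tsv", "w") as fh:
                fh.write("gene\tdegree\t"
                         + "\t".join(f"edi_{t}" for t in expression.tissues)
                         + "\tedi_variation\n")
                for gene in sorted(profiles):
                    p = profiles[gene]
                    per_tissue = "\t".join(
                        f"{p.per_tissue[t]:.6g}" for t in expression.tissues
                    )
                    fh.write(f"{gene}\t{p.degree}\t{per_tissue}\t"
                             f"{p.variation:.6g}\n")
            networks = {"network": net}
            if net.number_of_edges() >= 2:
                networks["random"] = topology.degree_preserving_random(
                    net, seed=config.seed
                )
            if clusters is not None:
                networks["mcl_modules"] = mcl_mod.clusters_to_network(clusters, net)
            mapped_path = outdir / "complexes_mapped.tsv"
            if mapped_path.is_file():
                complex_sets = [m for _, m in read_complexes(mapped_path)]
                networks["complexes"] = mcl_mod.clusters_to_network(
                    complex_sets, net
                )
            dist = expr_mod.edi_distribution_by_class(networks, expression)
            _write_json(
                {
                    label: {
                        "median": _round(float(np.median(d["values"])), 6)
                        if len(d["values"]) else None,
                        "n_genes": int(len(d["values"])),
                        "hist": [int(c) for c in d["hist"]],
                        "bin_edges": [_round(float(e), 6) for e in d["bin_edges"]],
                    }
                    for label, d in dist.items()
                },
                outdir / "edi_by_class.json",
            )
            high = expr_mod.high_expression_subnetwork(
                net, expression,
                min_tissues=config.min_tissues, quantile_cut=config.quantile_cut,
            )
            write_edge_list(graph_to_edgelist(high),
                            outdir / "high_expression_network.tsv")
            manifest["stages"][stage] = {
                "n_profiled": len(profiles),
                "high_expression_nodes": high.number_of_nodes(),
            }

        elif stage == "edi-removal":
            net = _load_network()
            profiles = expr_mod.edi_profiles(net, expression)
            edi_var = {
                n: (profiles[n].variation if n in profiles else 0.0)
                for n in net.nodes
            }
            thresholds = range(config.removal_min, config.removal_max + 1,
                               config.removal_step)
            rows_out = expr_mod.removal_experiment(
                net, edi_var, thresholds=thresholds, seed=config.seed
            )
            with open(outdir / "removal_sweep.tsv", "w") as fh:
                fh.write("threshold\tn_removed\tasp_targeted\tasp_random\tflagged\n")
                for r in rows_out:
                    t = "" if r.asp_targeted is None else f"{r.asp_targeted:.6g}"
                    rr = "" if r.asp_random is None else f"{r.asp_random:.6g}"
                    fh.write(f"{r.threshold:g}\t{r.n_removed}\t{t}\t{rr}\t"
                             f"{int(r.flagged)}\n")
            n_longer = sum(
                1 for r in rows_out
                if r.asp_targeted is not None and r.asp_random is not None
                and r.asp_targeted >= r.asp_random
            )
            manifest["stages"][stage] = {
                "n_thresholds": len(rows_out),
                "n_targeted_ge_random": n_longer,
            }

    manifest["seed"] = config.seed
    _write_json(manifest, outdir / "manifest.json")
    return manifest

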