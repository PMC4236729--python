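"""Seeded synthetic universe with known ground truth.

The generator plants a modular structure: proteins are partitioned into
expression modules, each module owns a few characteristic domains, and
interacting domain pairs (DDI rules) are drawn within modules.  The
ground-truth interactions are exactly the protein pairs that share a
planted rule, mirrored into six reference organisms (plus optional
noise), so both prediction routes — ortholog transfer and
dc-pair scoring — can recover them.  Expression, GO annotations and
protein complexes are all correlated with the same module structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io_formats import (
    REFERENCE_ORGANISMS,
    DomainHit,
    EdgeList,
    ExpressionMatrix,
    OntologyGraph,
    OrthologRow,
    canonical_pair,
    write_annotations,
    write_complexes,
    write_domtblout,
    write_edge_list,
    write_expression,
    write_obo,
    write_ortholog_table,
)

DEFAULT_TISSUES = ("callus", "leaf", "flower", "fruit")

#: raw ortholog scores are drawn over [0.2*cap, 2*cap]: the range spans the
#: 4600 cap (so capping is exercised) while the floor keeps every
#: six-organism-supported pair above the 0.15 transfer threshold
RAW_SCORE_LOW_FRAC = 0.2
RAW_SCORE_HIGH_FRAC = 2.0

MODULE_SIZE = 8
MODULE_DOMAINS = 3
LOGNORMAL_MU = 1.0
LOGNORMAL_SIGMA = 1.0
JITTER_SIGMA = 0.2
ZERO_CELL_RATE = 0.02


@dataclass
class SyntheticUniverse:
    seed: int
    proteins: list[str]
    modules: list[list[str]]
    architectures: dict[str, frozenset[str]]
    domain_hits: list[DomainHit]
    ddi_rules: set[tuple[str, str]]
    reference_organisms: tuple[str, ...]
    ref_architectures: dict[str, frozenset[str]]
    ref_ppis: dict[str, EdgeList]
    ortholog_rows: list[OrthologRow]
    ontology: OntologyGraph
    annotations: dict[str, set[str]]
    expression: ExpressionMatrix
    true_edges: EdgeList
    complexes: list[tuple[str, frozenset[str]]] = field(default_factory=list)

    def ref_id(self, organism: str, protein: str) -> str:
        return f"{organism}_{protein}"


def _rngs(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    """Independent per-component streams so adding one never shifts others."""
    base = np.random.SeedSequence(seed)
    children = base.spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def generate_universe(
    seed: int,
    n_proteins: int = 300,
    n_domains: int = 30,
    n_ddi_rules: int = 40,
    noise_rate: float = 0.05,
    n_tissues: int = 4,
) -> SyntheticUniverse:
    """Build a deterministic synthetic universe; see module docstring."""
    if n_proteins < 20:
        raise ConfigurationError(f"n_proteins must be >= 20, got {n_proteins}")
    if n_domains < 5:
        raise ConfigurationError(f"n_domains must be >= 5, got {n_domains}")
    if not (0 <= noise_rate <= 1):
        raise ConfigurationError(f"noise_rate must be in [0, 1], got {noise_rate}")
    if n_tissues < 1:
        raise ConfigurationError(f"n_tissues must be >= 1, got {n_tissues}")

    rngs = _rngs(seed, ["modules", "arch", "rules", "complexes", "ortho",
                        "noise", "expression", "ontology", "hits"])

    proteins = [f"P{i:04d}" for i in range(1, n_proteins + 1)]
    domains = [f"D{i:03d}" for i in range(1, n_domains + 1)]

    # --- modules ---------------------------------------------------------
    order = list(proteins)
    rngs["modules"].shuffle(order)
    modules = [order[i:i + MODULE_SIZE] for i in range(0, len(order), MODULE_SIZE)]
    if len(modules) > 1 and len(modules[-1]) < 3:  # fold a tiny tail module in
        modules[-2].extend(modules.pop())
    module_of = {p: mi for mi, mod in enumerate(modules) for p in mod}

    # --- module domains + architectures ----------------------------------
    rng_a = rngs["arch"]
    # modules take consecutive slices of a shuffled pool, so their
    # characteristic domains are disjoint whenever the pool is big enough
    pool = list(domains)
    rng_a.shuffle(pool)
    module_domains: list[list[str]] = [
        sorted(pool[(mi * MODULE_DOMAINS + j) % len(pool)]
               for j in range(min(MODULE_DOMAINS, n_domains)))
        for mi in range(len(modules))
    ]
    architectures: dict[str, set[str]] = {}
    for mi, mod in enumerate(modules):
        for p in mod:
            k = int(rng_a.integers(1, 5))  # 1..4 domains per protein
            own: set[str] = set()
            for _ in range(k):
                if rng_a.random() < 0.95:
                    own.add(str(rng_a.choice(module_domains[mi])))
                else:
                    own.add(str(rng_a.choice(domains)))
            architectures[p] = own

    # --- DDI rules (within-module domain pairs) ---------------------------
    rng_r = rngs["rules"]
    rules: set[tuple[str, str]] = set()
    attempts = 0
    while len(rules) < n_ddi_rules and attempts < 50 * n_ddi_rules:
        attempts += 1
        mi = int(rng_r.integers(len(modules)))
        cand = module_domains[mi]
        if len(cand) < 2:
            continue
        d1, d2 = rng_r.choice(cand, size=2, replace=False)
        rules.add(tuple(sorted((str(d1), str(d2)))))

    # --- complexes: one dedicated self-interacting domain per complex -----
    rng_c = rngs["complexes"]
    complexes: list[tuple[str, frozenset[str]]] = []
    n_complexes = max(2, len(modules) // 3)
    chosen_modules = rng_c.choice(len(modules), size=min(n_complexes, len(modules)),
                                  replace=False)
    for ci, mi in enumerate(sorted(int(m) for m in chosen_modules), start=1):
        size = int(rng_c.integers(3, 6))
        members = sorted(
            str(p) for p in rng_c.choice(modules[mi],
                                         size=min(size, len(modules[mi])),
                                         replace=False)
        )
        if len(members) < 2:
            continue
        cdom = f"CD{ci:03d}"
        for p in members:
            architectures[p].add(cdom)
        rules.add((cdom, cdom))
        complexes.append((f"CPX{ci:03d}", frozenset(members)))

    arch_frozen = {p: frozenset(d) for p, d in architectures.items()}

    # --- true edges: every pair sharing a planted rule --------------------
    true_edges = EdgeList()
    for i, a in enumerate(proteins):
        for b in proteins[i + 1:]:
            da, db = arch_frozen[a], arch_frozen[b]
            if any(
                (d1 in da and d2 in db) or (d2 in da and d1 in db)
                for d1, d2 in rules
            ):
                true_edges.add(a, b)

    # --- reference organisms: mirrored proteomes + PPIs -------------------
    organisms = REFERENCE_ORGANISMS
    ref_architectures: dict[str, frozenset[str]] = {}
    ref_ppis: dict[str, EdgeList] = {}
    rng_n = rngs["noise"]
    # one shared spurious-pair pool (mimics contamination propagated across
    # source databases); every organism carries the same noise edges
    n_noise = int(round(noise_rate * len(true_edges)))
    noise_pairs: set[tuple[str, str]] = set()
    tries = 0
    while len(noise_pairs) < n_noise and tries < 50 * max(1, n_noise):
        tries += 1
        a, b = (str(x) for x in rng_n.choice(proteins, size=2, replace=False))
        if (a, b) in true_edges:
            continue
        noise_pairs.add(canonical_pair(a, b))
    for organism in organisms:
        el = EdgeList()
        for a, b in sorted(true_edges.edges | noise_pairs):
            el.add(f"{organism}_{a}", f"{organism}_{b}")
        ref_ppis[organism] = el
        for p in proteins:
            ref_architectures[f"{organism}_{p}"] = arch_frozen[p]

    # --- ortholog rows ----------------------------------------------------
    rng_o = rngs["ortho"]
    cap = 4600.0
    ortholog_rows: list[OrthologRow] = []
    for organism in organisms:
        for p in proteins:
            raw = float(rng_o.uniform(RAW_SCORE_LOW_FRAC * cap,
                                      RAW_SCORE_HIGH_FRAC * cap))
            ortholog_rows.append(OrthologRow(p, organism, f"{organism}_{p}", raw))
            if rng_o.random() < 0.1:  # sub-optimal duplicate, exercises best-hit
                worse = float(rng_o.uniform(0, raw))
                ortholog_rows.append(
                    OrthologRow(p, organism, f"{organism}_{p}_alt", worse)
                )

    # --- expression -------------------------------------------------------
    rng_e = rngs["expression"]
    tissues = list(DEFAULT_TISSUES[:n_tissues])
    tissues += [f"tissue{i}" for i in range(len(tissues) + 1, n_tissues + 1)]
    values = np.zeros((len(proteins), n_tissues))
    index = {p: i for i, p in enumerate(proteins)}
    for mi, mod in enumerate(modules):
        means = rng_e.lognormal(LOGNORMAL_MU, LOGNORMAL_SIGMA, size=n_tissues)
        for p in mod:
            jitter = np.exp(rng_e.normal(0.0, JITTER_SIGMA, size=n_tissues))
            values[index[p]] = means * jitter
    zero_mask = rng_e.random(values.shape) < ZERO_CELL_RATE
    values[zero_mask] = 0.0
    expression = ExpressionMatrix(
        pd.DataFrame(values, index=proteins, columns=tissues)
    )

    # --- ontology + annotations ------------------------------------------
    rng_g = rngs["ontology"]
    onto = OntologyGraph()
    root = "GO:0000001"
    onto.add_term(root, name="root")
    background = "GO:0000002"
    onto.add_term(background, name="background")
    onto.add_is_a(background, root)
    module_terms = []
    next_id = 3
    for mi in range(len(modules)):
        term = f"GO:{next_id:07d}"
        next_id += 1
        onto.add_term(term, name=f"module_{mi}")
        onto.add_is_a(term, root)
        module_terms.append(term)
    domain_term: dict[str, str] = {}
    all_domains = sorted({d for a in arch_frozen.values() for d in a})
    owner: dict[str, int] = {}
    for mi, mdoms in enumerate(module_domains):
        for d in mdoms:
            owner.setdefault(d, mi)
    for name, members in complexes:  # complex domains live in their module
        mi = module_of[sorted(members)[0]]
        for d in sorted(frozenset.intersection(*(arch_frozen[m] for m in members))):
            if d.startswith("CD"):
                owner.setdefault(d, mi)
    for d in all_domains:
        term = f"GO:{next_id:07d}"
        next_id += 1
        onto.add_term(term, name=f"domain_{d}")
        parent = module_terms[owner[d]] if d in owner else background
        onto.add_is_a(term, parent)
        domain_term[d] = term
    annotations: dict[str, set[str]] = {}
    all_terms = sorted(domain_term.values())
    for p in proteins:
        terms = {domain_term[d] for d in arch_frozen[p]}
        if rng_g.random() < 0.1:  # annotation noise
            terms.add(str(rng_g.choice(all_terms)))
        annotations[p] = terms

    # --- raw domain hits consistent with the filtered architectures -------
    rng_h = rngs["hits"]
    model_length = 100
    hits: list[DomainHit] = []
    for p in proteins:
        arch = sorted(arch_frozen[p])
        multi = len(arch) >= 2
        for d in arch:
            e_value = float(10.0 ** rng_h.uniform(-10, -4))
            low = 62 if multi else 92
            end = int(rng_h.integers(low, model_length + 1))
            hits.append(DomainHit(p, d, e_value, 1, end, model_length))
        if rng_h.random() < 0.3:  # decoys that the filters must remove
            decoy = str(rng_h.choice(domains))
            if rng_h.random() < 0.5:
                hits.append(DomainHit(p, decoy, 1e-2, 1, model_length, model_length))
            else:
                hits.append(
                    DomainHit(p, decoy, float(10.0 ** rng_h.uniform(-8, -4)),
                              1, 30, model_length)
                )

    return SyntheticUniverse(
        seed=seed,
        proteins=proteins,
        modules=modules,
        architectures=arch_frozen,
        domain_hits=hits,
        ddi_rules=rules,
        reference_organisms=organisms,
        ref_architectures=ref_architectures,
        ref_ppis=ref_ppis,
        ortholog_rows=ortholog_rows,
        ontology=onto,
        annotations=annotations,
        expression=expression,
        true_edges=true_edges,
        complexes=complexes,
    )


def ground_truth_labels(
    universe: SyntheticUniverse,
    candidate_pairs: list[tuple[str, str]],
) -> dict[tuple[str, str], bool]:
    """Label unordered pairs by membership in the planted true edges."""
    known = set(universe.proteins)
    out: dict[tuple[str, str], bool] = {}
    for a, b in candidate_pairs:
        if a not in known or b not in known:
            raise ValidationError(f"unknown protein in pair ({a!r}, {b!r})")
        key = canonical_pair(a, b)
        out[key] = key in universe.true_edges
    return out


def write_universe(universe: SyntheticUniverse, outdir: str | Path) -> None:
    """Serialize the universe into the pipeline's plain-text input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "ref_ppis").mkdir(exist_ok=True)
    (outdir / "ref_domtblout").mkdir(exist_ok=True)

    write_ortholog_table(universe.ortholog_rows, outdir / "ortholog_table.tsv")
    write_domtblout(universe.domain_hits, outdir / "target.domtblout")
    for organism in universe.reference_organisms:
        write_edge_list(universe.ref_ppis[organism],
                        outdir / "ref_ppis" / f"{organism}.tsv")
        ref_hits = [
            DomainHit(universe.ref_id(organism, h.protein_id), h.domain_id,
                      h.e_value, h.ali_start, h.ali_end, h.model_length)
            for h in universe.domain_hits
        ]
        write_domtblout(ref_hits, outdir / "ref_domtblout" / f"{organism}.domtblout")
    write_obo(universe.ontology, outdir / "ontology.obo")
    write_annotations(universe.annotations, outdir / "annotations.tsv")
    write_expression(universe.expression, outdir / "expression.tsv")
    write_edge_list(universe.true_edges, outdir / "true_edges.tsv")
    write_complexes(universe.complexes, outdir / "complexes.tsv")
    # yeast-space complex catalogue + best-hit table for the mapping stage
    yeast = "scerevisiae"
    ref_complexes = [
        (name, frozenset(universe.ref_id(yeast, m) for m in members))
        for name, members in universe.complexes
    ]
    write_complexes(ref_complexes, outdir / "ref_complexes.tsv")
    with open(outdir / "best_hits.tsv", "w") as fh:
        fh.write("ref_id\ttarget_id\n")
        for p in universe.proteins:
            fh.write(f"{universe.ref_id(yeast, p)}\t{p}\n")
    with open(outdir / "proteins.txt", "w") as fh:
        for p in universe.proteins:
            fh.write(p + "\n")
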