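"""Readers and writers for every external file the pipeline touches.

All parsers validate on entry and hand the rest of the package plain
in-memory types (dataclasses, :class:`EdgeList`, :class:`OntologyGraph`,
:class:`ExpressionMatrix`).  Protein and term identifiers are opaque
strings and are never case-folded or otherwise rewritten.

Formats: 4-column ortholog TSV, HMMER3 ``domtblout``, 2+N column edge
TSV, SIF, OBO 1.2 (``[Term]`` stanzas with ``is_a``), annotation TSV,
gene x tissue expression TSV, and complex-membership TSV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: The closed set of reference-organism labels accepted by the ortholog reader.
REFERENCE_ORGANISMS: tuple[str, ...] = (
    "athaliana",
    "celegans",
    "dmelanogaster",
    "hsapiens",
    "mmusculus",
    "scerevisiae",
)


# ---------------------------------------------------------------------------
# Row-level domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrthologRow:
    """One ortholog assignment with its raw (un-normalized) score."""

    query_id: str
    ref_organism: str
    ref_id: str
    raw_score: float

    def __post_init__(self) -> None:
        if self.raw_score < 0:
            raise ValidationError(
                f"raw ortholog score must be >= 0, got {self.raw_score!r} "
                f"for {self.query_id}/{self.ref_id}"
            )


@dataclass(frozen=True)
class DomainHit:
    """One per-domain HMM hit; coordinates are on the HMM model, 1-based inclusive."""

    protein_id: str
    domain_id: str
    e_value: float
    ali_start: int
    ali_end: int
    model_length: int

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise ValidationError(f"e-value must be > 0, got {self.e_value!r}")
        if not (1 <= self.ali_start <= self.ali_end <= self.model_length):
            raise ValidationError(
                f"hit coordinates violate 1 <= start <= end <= model_length: "
                f"{self.ali_start}..{self.ali_end} / {self.model_length} "
                f"({self.protein_id}/{self.domain_id})"
            )

    @property
    def coverage(self) -> float:
        return (self.ali_end - self.ali_start + 1) / self.model_length


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) form of an unordered protein pair."""
    return (a, b) if a <= b else (b, a)


class EdgeList:
    """An undirected simple edge set with optional per-edge attributes.

    Self-loops are silently rejected by :meth:`add` (callers log counts),
    and the unordered pair (a, b) == (b, a) is stored once.
    """

    def __init__(self) -> None:
        self.edges: set[tuple[str, str]] = set()
        self.attributes: dict[tuple[str, str], dict[str, str]] = {}

    def add(self, a: str, b: str, **attrs: object) -> bool:
        if a == b:
            return False
        key = canonical_pair(a, b)
        self.edges.add(key)
        if attrs:
            self.attributes.setdefault(key, {}).update(
                {k: str(v) for k, v in attrs.items()}
            )
        return True

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self.edges

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EdgeList):
            return NotImplemented
        return self.edges == other.edges

    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for a, b in sorted(self.edges):
            g.add_edge(a, b, **self.attributes.get((a, b), {}))
        return g

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "EdgeList":
        el = cls()
        for a, b in pairs:
            el.add(a, b)
        return el


@dataclass
class OntologyGraph:
    """Directed acyclic ``is_a`` graph, child -> parent, namespaced per term."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def add_term(self, term: str, namespace: str = "biological_process",
                 name: str = "") -> None:
        self.graph.add_node(term, namespace=namespace, name=name)

    def add_is_a(self, child: str, parent: str) -> None:
        self.graph.add_edge(child, parent)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def terms(self) -> list[str]:
        return sorted(self.graph.nodes)

    def namespace(self, term: str) -> str:
        return self.graph.nodes[term]["namespace"]


class ExpressionMatrix:
    """Gene x tissue matrix of nonnegative RPKM values."""

    def __init__(self, df: pd.DataFrame) -> None:
        if df.columns.duplicated().any():
            raise ValidationError("tissue labels must be unique")
        values = df.to_numpy(dtype=float)
        if not (values >= 0).all() or not math.isfinite(values.sum()):
            raise ValidationError("expression values must be finite and >= 0")
        self.df = df.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.df.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.df.columns)

    def __contains__(self, gene: str) -> bool:
        return gene in self.df.index

    def row(self, gene: str):
        return self.df.loc[gene].to_numpy(dtype=float)

    def value(self, gene: str, tissue: str) -> float:
        return float(self.df.at[gene, tissue])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        a = self.df.sort_index()
        b = other.df.sort_index()
        return a.equals(b)


# ---------------------------------------------------------------------------
# Ortholog tables
# ---------------------------------------------------------------------------


def read_ortholog_table(
    path: str | Path,
    organisms: Iterable[str] = REFERENCE_ORGANISMS,
) -> list[OrthologRow]:
    """Read a 4-column TSV (query, organism, ref, raw_score); header optional."""
    organisms = frozenset(organisms)
    rows: list[OrthologRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                score = float(fields[3])
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ParseError(
                    f"{path}:{lineno}: raw_score {fields[3]!r} is not a number"
                ) from None
            if fields[1] not in organisms:
                raise ValidationError(
                    f"{path}:{lineno}: unknown organism label {fields[1]!r}"
                )
            rows.append(OrthologRow(fields[0], fields[1], fields[2], score))
    if not rows:
        logger.warning("ortholog table %s is empty", path)
    return rows


def write_ortholog_table(rows: Iterable[OrthologRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tref_organism\tref_id\traw_score\n")
        for r in rows:
            fh.write(f"{r.query_id}\t{r.ref_organism}\t{r.ref_id}\t{r.raw_score:g}\n")


# ---------------------------------------------------------------------------
# HMMER3 domtblout
# ---------------------------------------------------------------------------

# column indices of the 23-column HMMER3 --domtblout layout (hmmscan
# orientation: target = domain model, query = protein)
_DT_TARGET_NAME = 0
_DT_TARGET_ACC = 1
_DT_TLEN = 2
_DT_QUERY_NAME = 3
_DT_IEVALUE = 12
_DT_HMM_FROM = 15
_DT_HMM_TO = 16
_DT_MIN_COLUMNS = 23


def read_domtblout(path: str | Path) -> list[DomainHit]:
    """Parse HMMER3 per-domain tabular output; no filtering is applied here."""
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split()
            if len(fields) < _DT_MIN_COLUMNS:
                raise ParseError(
                    f"{path}:{lineno}: domtblout line has {len(fields)} columns, "
                    f"expected >= {_DT_MIN_COLUMNS}"
                )
            acc = fields[_DT_TARGET_ACC]
            domain_id = fields[_DT_TARGET_NAME] if acc == "-" else acc
            try:
                hits.append(
                    DomainHit(
                        protein_id=fields[_DT_QUERY_NAME],
                        domain_id=domain_id,
                        e_value=float(fields[_DT_IEVALUE]),
                        ali_start=int(fields[_DT_HMM_FROM]),
                        ali_end=int(fields[_DT_HMM_TO]),
                        model_length=int(fields[_DT_TLEN]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return hits


def write_domtblout(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Emit a minimal but column-compatible domtblout file."""
    with open(path, "w") as fh:
        fh.write("# target name        accession   tlen query name           "
                 "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
                 "i-Evalue  score  bias  from    to  from    to  from    to  acc "
                 "description of target\n")
        for h in hits:
            fh.write(
                f"{h.domain_id} {h.domain_id} {h.model_length} {h.protein_id} - "
                f"500 {h.e_value:.2g} 100.0 0.1 1 1 {h.e_value:.2g} {h.e_value:.2g} "
                f"100.0 0.1 {h.ali_start} {h.ali_end} {h.ali_start} {h.ali_end} "
                f"{h.ali_start} {h.ali_end} 0.95 -\n"
            )


# ---------------------------------------------------------------------------
# Edge lists / SIF
# ---------------------------------------------------------------------------


def read_edge_list(path: str | Path) -> EdgeList:
    """Read a 2+N column TSV of undirected edges; extra columns are attributes."""
    el = EdgeList()
    attr_names: list[str] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(
                    f"{path}:{lineno}: edge line needs at least 2 columns"
                )
            if lineno == 1 and fields[0] == "protein_a":
                attr_names = fields[2:]
                continue
            attrs = dict(zip(attr_names, fields[2:]))
            if not el.add(fields[0], fields[1], **attrs):
                dropped += 1
    if dropped:
        logger.warning("%s: dropped %d self-loop edge(s)", path, dropped)
    return el


def write_edge_list(el: EdgeList, path: str | Path) -> None:
    attr_names = sorted({k for attrs in el.attributes.values() for k in attrs})
    with open(path, "w") as fh:
        fh.write("\t".join(["protein_a", "protein_b", *attr_names]) + "\n")
        for a, b in sorted(el.edges):
            attrs = el.attributes.get((a, b), {})
            extra = [attrs.get(k, "") for k in attr_names]
            fh.write("\t".join([a, b, *extra]) + "\n")


def write_sif(net: nx.Graph, path: str | Path, relation: str = "pp") -> None:
    """SIF export; topology only, isolated nodes emitted bare."""
    with open(path, "w") as fh:
        for a, b in sorted(canonical_pair(u, v) for u, v in net.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")
        for n in sorted(net.nodes):
            if net.degree(n) == 0:
                fh.write(f"{n}\n")


def graph_to_edgelist(net: nx.Graph) -> EdgeList:
    el = EdgeList()
    for a, b, attrs in net.edges(data=True):
        el.add(a, b, **attrs)
    return el


# ---------------------------------------------------------------------------
# OBO / annotations
# ---------------------------------------------------------------------------


def read_obo(path: str | Path) -> OntologyGraph:
    """Parse OBO 1.2 ``[Term]`` stanzas with ``is_a`` links.

    Obsolete terms are excluded; an ``is_a`` pointing at a term never
    defined in the file is a validation error, while a link to an
    obsolete term is dropped.
    """
    terms: dict[str, dict] = {}
    current: dict | None = None
    in_term = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("["):
                in_term = line == "[Term]"
                current = {"is_a": [], "obsolete": False,
                           "namespace": "biological_process", "name": ""} if in_term else None
                continue
            if not in_term or current is None or not line:
                continue
            if ":" not in line:
                continue
            key, _, value = line.partition(":")
            value = value.split("!")[0].strip()
            if key == "id":
                current["id"] = value
                terms[value] = current
            elif key == "name":
                current["name"] = value
            elif key == "namespace":
                current["namespace"] = value
            elif key == "is_a":
                current["is_a"].append(value)
            elif key == "is_obsolete" and value == "true":
                current["obsolete"] = True
    onto = OntologyGraph()
    for tid, data in terms.items():
        if data["obsolete"]:
            continue
        onto.add_term(tid, namespace=data["namespace"], name=data["name"])
    for tid, data in terms.items():
        if data["obsolete"]:
            continue
        for parent in data["is_a"]:
            if parent not in terms:
                raise ValidationError(
                    f"{path}: term {tid} references undefined parent {parent}"
                )
            if terms[parent]["obsolete"]:
                continue
            onto.add_is_a(tid, parent)
    if not nx.is_directed_acyclic_graph(onto.graph):
        raise ValidationError(f"{path}: is_a graph contains a cycle")
    return onto


def write_obo(onto: OntologyGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term in onto.terms():
            data = onto.graph.nodes[term]
            fh.write(f"\n[Term]\nid: {term}\n")
            fh.write(f"name: {data.get('name', '') or term}\n")
            fh.write(f"namespace: {data.get('namespace', 'biological_process')}\n")
            for parent in sorted(onto.graph.successors(term)):
                fh.write(f"is_a: {parent}\n")


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """TSV of (protein, term) rows -> protein -> term set."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and fields[0] == "protein_id":
                continue
            out.setdefault(fields[0], set()).add(fields[1])
    return out


def write_annotations(annotations: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tterm\n")
        for protein in sorted(annotations):
            for term in sorted(annotations[protein]):
                fh.write(f"{protein}\t{term}\n")


# ---------------------------------------------------------------------------
# Expression / complexes
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> ExpressionMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error surface
        raise ParseError(f"{path}: {exc}") from exc
    try:
        return ExpressionMatrix(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.df.to_csv(path, sep="\t", index_label="gene")


def read_complexes(path: str | Path) -> list[tuple[str, frozenset[str]]]:
    """TSV lines: complex_name<TAB>member1<TAB>member2[...]; >= 2 members."""
    out: list[tuple[str, frozenset[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            members = frozenset(f for f in fields[1:] if f)
            if len(members) < 2:
                raise ValidationError(
                    f"{path}:{lineno}: complex {fields[0]!r} has "
                    f"{len(members)} member(s), need >= 2"
                )
            out.append((fields[0], members))
    return out


def write_complexes(
    complexes: Iterable[tuple[str, frozenset[str]]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for name, members in complexes:
            fh.write("\t".join([name, *sorted(members)]) + "\n")
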