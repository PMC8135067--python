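"""Comparative GO-term enrichment on the 'is_a' ontology graph.

The comparison contrasts two condition-specific gene sets (A = genes specific
to the mutant ovary, B = genes specific to the wildtype ovary). For each GO
term the annotation frequency within each set is computed on ancestor-closed
annotations, and the signed enrichment score is the log2 ratio of
pseudo-count-regularized frequencies:

    score(t) = log2( (freq_A(t) + pseudo) / (freq_B(t) + pseudo) )

Positive scores mean the term is enriched among mutant-specific genes (drawn
red in the graph view), negative among wildtype-specific genes (blue). For
display, a term at GO level < 2 (shortest is_a distance from its namespace
root) or with a score strictly inside (-1.2, 1.2) is rendered as a zero-sized
node; displayed terms get a node size equal to the number of genes carrying
the term. Graphs are exported per namespace in GraphML for Cytoscape.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

from .errors import InvalidInputError, OboFormatError, UnknownTermError

PSEUDO_DEFAULT = 0.01
SCORE_BAND = 1.2
MIN_LEVEL = 2
NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


@dataclass
class GoDag:
    """Gene Ontology restricted to 'is_a' edges, one root per namespace.

    ``graph`` is a directed graph with edges child -> parent; node attributes
    carry ``name`` and ``namespace``.
    """

    graph: nx.DiGraph
    roots: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.roots:
            for node in self.graph.nodes:
                if self.graph.out_degree(node) == 0:
                    ns = self.graph.nodes[node].get("namespace", "unknown")
                    if ns in self.roots:
                        raise OboFormatError(
                            f"namespace {ns!r} has multiple roots: "
                            f"{self.roots[ns]}, {node}"
                        )
                    self.roots[ns] = node
        self._levels: dict[str, int] | None = None

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def namespace(self, term: str) -> str:
        self._require(term)
        return self.graph.nodes[term].get("namespace", "unknown")

    def name(self, term: str) -> str:
        self._require(term)
        return self.graph.nodes[term].get("name", term)

    def parents(self, term: str) -> set[str]:
        self._require(term)
        return set(self.graph.successors(term))

    def ancestors(self, term: str) -> set[str]:
        """All is_a ancestors of a term (the term itself excluded)."""
        self._require(term)
        return set(nx.descendants(self.graph, term))

    def level(self, term: str) -> int:
        """Shortest is_a path length from the namespace root (root = 0)."""
        self._require(term)
        if self._levels is None:
            levels: dict[str, int] = {}
            rev = self.graph.reverse(copy=False)
            for root in self.roots.values():
                levels.update(nx.single_source_shortest_path_length(rev, root))
            self._levels = levels
        try:
            return self._levels[term]
        except KeyError:
            raise OboFormatError(
                f"term {term} is not connected to any namespace root"
            ) from None

    def _require(self, term: str) -> None:
        if term not in self.graph:
            raise UnknownTermError(term)


def go_level(dag: GoDag, term: str) -> int:
    return dag.level(term)


def parse_obo(source) -> GoDag:
    """Parse an OBO 1.2 document into a GoDag.

    ``source`` may be a path, a file handle, or the OBO text itself.
    Only ``is_a`` edges are kept; obsolete terms are dropped and
    ``relationship:`` edges are ignored. A cycle or a parent id without a
    term stanza is a format error.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    multigraph = obonet.read_obo(source, ignore_obsolete=True)
    graph = nx.DiGraph()
    for node, data in multigraph.nodes(data=True):
        graph.add_node(
            node,
            name=data.get("name", node),
            namespace=data.get("namespace", "unknown"),
        )
    for child, parent, key in multigraph.edges(keys=True):
        if key != "is_a":
            continue
        if parent not in multigraph.nodes or "name" not in multigraph.nodes[parent]:
            raise OboFormatError(f"is_a parent {parent} has no term definition")
        graph.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise OboFormatError(
            "is_a cycle detected: " + " -> ".join(edge[0] for edge in cycle)
        )
    return GoDag(graph=graph)


# -- annotations -------------------------------------------------------------


@dataclass
class AnnotationSet:
    """gene_id -> set of GO term ids; ``closed`` marks ancestor completion."""

    mapping: dict[str, set[str]]
    closed: bool = False

    def terms_of(self, gene: str) -> set[str]:
        return self.mapping.get(gene, set())


def propagate_annotations(dag: GoDag, ann: AnnotationSet) -> AnnotationSet:
    """Close annotations over is_a ancestors (the true-path rule). Idempotent."""
    unknown = sorted(
        {t for terms in ann.mapping.values() for t in terms if t not in dag}
    )
    if unknown:
        raise UnknownTermError(f"annotation terms not in DAG: {unknown}")
    closed: dict[str, set[str]] = {}
    cache: dict[str, set[str]] = {}
    for gene, terms in ann.mapping.items():
        full = set(terms)
        for t in terms:
            if t not in cache:
                cache[t] = dag.ancestors(t)
            full |= cache[t]
        closed[gene] = full
    return AnnotationSet(mapping=closed, closed=True)


def term_frequency(gene_set: Iterable[str], term: str, ann_closed: AnnotationSet) -> float:
    """Fraction of genes in the set annotated (after closure) to the term."""
    genes = list(gene_set)
    if not genes:
        raise InvalidInputError("term frequency undefined for an empty gene set")
    n = sum(term in ann_closed.terms_of(g) for g in genes)
    return n / len(genes)


# -- the enrichment score ----------------------------------------------------


def enrichment_score(
    term: str,
    set_a: Iterable[str],
    set_b: Iterable[str],
    ann_closed: AnnotationSet,
    pseudo: float = PSEUDO_DEFAULT,
    log_base: float = 2.0,
) -> float:
    """Signed log-ratio of pseudo-count-regularized term frequencies.

    Antisymmetric under swapping the two sets and zero when the frequencies
    are equal. ``log_base`` defaults to 2 and is pluggable.
    """
    if pseudo <= 0:
        raise InvalidInputError(f"pseudo-count must be positive, got {pseudo}")
    fa = term_frequency(set_a, term, ann_closed)
    fb = term_frequency(set_b, term, ann_closed)
    # difference of logs, not log of a ratio: keeps swap-antisymmetry exact
    return math.log(fa + pseudo, log_base) - math.log(fb + pseudo, log_base)


@dataclass
class EnrichmentResult:
    """Per-term comparative enrichment with graph-view display attributes."""

    term_id: str
    name: str
    namespace: str
    n_genes_a: int
    n_genes_b: int
    freq_a: float
    freq_b: float
    score: float
    level: int
    node_size: int = 0
    displayed: bool = False


def compute_enrichment(
    dag: GoDag,
    ann: AnnotationSet,
    set_a: Iterable[str],
    set_b: Iterable[str],
    pseudo: float = PSEUDO_DEFAULT,
    propagate: bool = True,
    log_base: float = 2.0,
) -> list[EnrichmentResult]:
    """Score every DAG term for enrichment between the two gene sets.

    Set A is the mutant-specific set (positive scores); set B the
    wildtype-specific set. Sets must be non-empty and disjoint.
    """
    set_a, set_b = list(set_a), list(set_b)
    if not set_a or not set_b:
        raise InvalidInputError("both gene sets must be non-empty")
    overlap = set(set_a) & set(set_b)
    if overlap:
        raise InvalidInputError(
            f"gene sets must be disjoint; shared: {sorted(overlap)[:5]}"
        )
    ann_c = propagate_annotations(dag, ann) if propagate and not ann.closed else ann
    results = []
    for term in sorted(dag.terms):
        na = sum(term in ann_c.terms_of(g) for g in set_a)
        nb = sum(term in ann_c.terms_of(g) for g in set_b)
        fa, fb = na / len(set_a), nb / len(set_b)
        score = math.log(fa + pseudo, log_base) - math.log(fb + pseudo, log_base)
        results.append(
            EnrichmentResult(
                term_id=term,
                name=dag.name(term),
                namespace=dag.namespace(term),
                n_genes_a=na,
                n_genes_b=nb,
                freq_a=fa,
                freq_b=fb,
                score=score,
                level=dag.level(term),
            )
        )
    return results


def filter_display(
    results: Iterable[EnrichmentResult],
    min_level: int = MIN_LEVEL,
    score_band: float = SCORE_BAND,
) -> list[EnrichmentResult]:
    """Apply the graph-view masking rule in place.

    A term is displayed iff its level is >= ``min_level`` AND its score lies
    outside the open band (-score_band, score_band); band endpoints are
    therefore displayed. Masked terms stay in the result list with
    node_size 0 (zero-sized node, not removed); displayed terms get
    node_size = number of genes across both sets carrying the term.
    """
    out = []
    for r in results:
        r.displayed = r.level >= min_level and abs(r.score) >= score_band
        r.node_size = (r.n_genes_a + r.n_genes_b) if r.displayed else 0
        out.append(r)
    return out


def results_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "name": r.name,
                "namespace": r.namespace,
                "level": r.level,
                "n_genes_A": r.n_genes_a,
                "n_genes_B": r.n_genes_b,
                "freq_A": r.freq_a,
                "freq_B": r.freq_b,
                "score": r.score,
                "node_size": r.node_size,
                "displayed": r.displayed,
            }
            for r in results
        ]
    )


def export_graph(
    dag: GoDag,
    results: Iterable[EnrichmentResult],
    namespace: str,
    path: str | Path,
) -> nx.DiGraph:
    """Write one namespace's is_a graph with display attributes as GraphML.

    Node attributes: score (positive = red / mutant-enriched, negative =
    blue / wildtype-enriched), node_size, level, displayed.
    """
    if namespace not in NAMESPACES:
        raise InvalidInputError(
            f"unknown namespace {namespace!r}; expected one of {NAMESPACES}"
        )
    by_term = {r.term_id: r for r in results}
    g = nx.DiGraph()
    for term in dag.terms:
        if dag.namespace(term) != namespace:
            continue
        r = by_term.get(term)
        g.add_node(
            term,
            name=dag.name(term),
            score=float(r.score) if r else 0.0,
            node_size=int(r.node_size) if r else 0,
            level=int(r.level) if r else dag.level(term),
            displayed=bool(r.displayed) if r else False,
        )
    for child, parent in dag.graph.edges:
        if child in g and parent in g:
            g.add_edge(child, parent, relation="is_a")
    nx.write_graphml(g, str(path))
    return g


# -- annotation I/O ----------------------------------------------------------


def read_annotations_tsv(path) -> AnnotationSet:
    """Read a two-column TSV: gene_id <tab> comma-joined GO term ids."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, _, terms = line.partition("\t")
            mapping[gene] = {t for t in terms.split(",") if t}
    return AnnotationSet(mapping=mapping, closed=False)


def write_annotations_tsv(ann: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(ann.mapping):
            fh.write(f"{gene}\t{','.join(sorted(ann.mapping[gene]))}\n")
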