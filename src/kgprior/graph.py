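"""Heterogeneous knowledge-graph container and disease gene-list handling.

The graph has three node kinds — genes, diseases, and annotation terms — and
three typed, undirected edge relations between them:

* ``interacts_with``   gene–gene (protein–protein interaction, mapped to the
  encoding genes)
* ``annotated_with``   gene–annotation (e.g. a GO term)
* ``associated_with``  gene–disease

Node identifiers are namespaced strings (``gene:SOD1``, ``disease:C0002736``,
``go:GO:0006915``) so the three namespaces cannot collide.  The container is a
thin typed wrapper over :class:`networkx.Graph`; between any two nodes at most
one edge type is possible, so a simple graph suffices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "NodeKind",
    "EdgeType",
    "NodeRef",
    "EdgeRecord",
    "KnowledgeGraph",
    "DiseaseDefinition",
    "GraphValidationError",
    "gene_node",
    "disease_node",
    "annotation_node",
    "build_graph",
    "delete_disease_links",
    "union_definition",
]


class GraphValidationError(ValueError):
    """An edge or node violates the typed-graph invariants."""


class NodeKind(str, Enum):
    GENE = "gene"
    DISEASE = "disease"
    ANNOTATION = "annotation"


class EdgeType(str, Enum):
    INTERACTS_WITH = "interacts_with"
    ANNOTATED_WITH = "annotated_with"
    ASSOCIATED_WITH = "associated_with"


#: namespace prefix -> node kind
_PREFIX_KIND = {
    "gene": NodeKind.GENE,
    "disease": NodeKind.DISEASE,
    "go": NodeKind.ANNOTATION,
    "annotation": NodeKind.ANNOTATION,
}

#: edge type -> (kind of endpoint a, kind of endpoint b) after normalisation
_EDGE_ENDPOINTS = {
    EdgeType.INTERACTS_WITH: (NodeKind.GENE, NodeKind.GENE),
    EdgeType.ANNOTATED_WITH: (NodeKind.GENE, NodeKind.ANNOTATION),
    EdgeType.ASSOCIATED_WITH: (NodeKind.GENE, NodeKind.DISEASE),
}


def node_kind(node_id: str) -> NodeKind:
    """Kind of a namespaced node id, derived from its prefix."""
    prefix = node_id.split(":", 1)[0]
    try:
        return _PREFIX_KIND[prefix]
    except KeyError:
        raise GraphValidationError(
            f"node id {node_id!r} has no recognised namespace prefix"
        ) from None


def gene_node(symbol: str) -> str:
    """Node id for a gene symbol (upper-cased once at construction)."""
    return f"gene:{symbol.upper()}"


def disease_node(disease_id: str) -> str:
    return f"disease:{disease_id}"


def annotation_node(term_id: str) -> str:
    return f"go:{term_id}"


def gene_symbol(node_id: str) -> str:
    """Inverse of :func:`gene_node`."""
    if node_kind(node_id) is not NodeKind.GENE:
        raise GraphValidationError(f"{node_id!r} is not a gene node")
    return node_id.split(":", 1)[1]


@dataclass(frozen=True)
class NodeRef:
    """A validated reference to a graph node."""

    id: str
    kind: NodeKind

    @classmethod
    def parse(cls, node_id: str) -> "NodeRef":
        return cls(id=node_id, kind=node_kind(node_id))


@dataclass(frozen=True)
class EdgeRecord:
    """One typed edge between two namespaced node ids.

    ``interacts_with`` edges are stored orientation-free with the endpoints in
    lexicographic order; the gene endpoint of the two heterogeneous edge types
    is always ``a``.
    """

    a: str
    b: str
    edge_type: EdgeType
    provenance: str = ""

    def normalized(self) -> "EdgeRecord":
        ka, kb = node_kind(self.a), node_kind(self.b)
        want_a, want_b = _EDGE_ENDPOINTS[self.edge_type]
        a, b = self.a, self.b
        if (ka, kb) == (want_b, want_a) and ka != kb:
            a, b, ka, kb = b, a, kb, ka
        if (ka, kb) != (want_a, want_b):
            raise GraphValidationError(
                f"edge ({self.a}, {self.b}, {self.edge_type.value}) joins node kinds "
                f"({ka.value}, {kb.value}); expected ({want_a.value}, {want_b.value})"
            )
        if self.edge_type is EdgeType.INTERACTS_WITH and b < a:
            a, b = b, a
        if a == b:
            raise GraphValidationError(f"self-edge on {a!r} is not allowed")
        if (a, b) == (self.a, self.b):
            return self
        return EdgeRecord(a, b, self.edge_type, self.provenance)

    @property
    def key(self) -> tuple[str, str, str]:
        """Identity triple used for deduplication (provenance excluded)."""
        e = self.normalized()
        return (e.a, e.b, e.edge_type.value)


class KnowledgeGraph:
    """Typed heterogeneous graph of genes, diseases, and annotation terms.

    Thin wrapper over an undirected :class:`networkx.Graph` carrying ``kind``
    node attributes and ``edge_type`` / ``provenance`` edge attributes.
    Equality compares node sets and (a, b, edge_type) triples; provenance is
    bookkeeping only.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction -----------------------------------------------------

    def add_node(self, node_id: str) -> None:
        self._g.add_node(node_id, kind=node_kind(node_id))

    def add_edge(self, edge: EdgeRecord) -> None:
        e = edge.normalized()
        self.add_node(e.a)
        self.add_node(e.b)
        if not self._g.has_edge(e.a, e.b):
            self._g.add_edge(e.a, e.b, edge_type=e.edge_type, provenance=e.provenance)

    def add_edges(self, edges: Iterable[EdgeRecord]) -> None:
        for e in edges:
            self.add_edge(e)

    def copy(self) -> "KnowledgeGraph":
        out = KnowledgeGraph()
        out._g = self._g.copy()
        return out

    # -- queries ----------------------------------------------------------

    @property
    def nx(self) -> nx.Graph:
        return self._g

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._g

    def nodes(self, kind: NodeKind | None = None) -> set[str]:
        if kind is None:
            return set(self._g.nodes)
        return {n for n, k in self._g.nodes(data="kind") if k == kind}

    @property
    def gene_universe(self) -> set[str]:
        """All gene nodes, the population every enrichment test draws from."""
        return self.nodes(NodeKind.GENE)

    def edges(self) -> Iterator[EdgeRecord]:
        for a, b, data in self._g.edges(data=True):
            yield EdgeRecord(a, b, data["edge_type"], data.get("provenance", "")).normalized()

    def edge_keys(self) -> set[tuple[str, str, str]]:
        return {e.key for e in self.edges()}

    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def neighbors(self, node_id: str, edge_type: EdgeType | None = None) -> set[str]:
        """Neighbours of a node, optionally restricted to one edge type.

        Symmetric for ``interacts_with`` by construction (undirected graph).
        """
        if node_id not in self._g:
            return set()
        if edge_type is None:
            return set(self._g[node_id])
        return {
            m for m, data in self._g[node_id].items() if data["edge_type"] == edge_type
        }

    def degree(self, node_id: str, edge_type: EdgeType | None = None) -> int:
        return len(self.neighbors(node_id, edge_type))

    def has_edge(self, a: str, b: str, edge_type: EdgeType | None = None) -> bool:
        if not self._g.has_edge(a, b):
            return False
        return edge_type is None or self._g[a][b]["edge_type"] == edge_type

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return self.nodes() == other.nodes() and self.edge_keys() == other.edge_keys()

    def __repr__(self) -> str:
        return (
            f"KnowledgeGraph({len(self.gene_universe)} genes, "
            f"{len(self.nodes(NodeKind.DISEASE))} diseases, "
            f"{len(self.nodes(NodeKind.ANNOTATION))} annotations, "
            f"{self.n_edges()} edges)"
        )


def build_graph(*edge_lists: Iterable[EdgeRecord]) -> KnowledgeGraph:
    """Assemble a :class:`KnowledgeGraph` from one or more edge-record lists.

    Duplicate edges (same endpoints and type) across lists collapse to a
    single stored edge; the node set is the union of all endpoints.
    """
    g = KnowledgeGraph()
    for edges in edge_lists:
        g.add_edges(edges)
    return g


def delete_disease_links(
    graph: KnowledgeGraph, disease: str, genes: Iterable[str]
) -> KnowledgeGraph:
    """Return a copy of ``graph`` without the disease→gene association edges.

    ``genes`` may be gene symbols or ``gene:`` node ids.  Deleting an absent
    link is a logged no-op; the input graph is never modified.  This is the
    link-deletion primitive of the cross-validation protocol: held-out genes
    keep every other edge but lose their link to the target disease.
    """
    out = graph.copy()
    n_absent = 0
    for g in genes:
        node = g if g.startswith("gene:") else gene_node(g)
        if out.has_edge(disease, node, EdgeType.ASSOCIATED_WITH):
            out.nx.remove_edge(disease, node)
        else:
            n_absent += 1
    if n_absent:
        logger.info(
            "delete_disease_links: %d of the listed genes had no link to %s",
            n_absent,
            disease,
        )
    return out


@dataclass
class DiseaseDefinition:
    """A named set of positive genes for one disease.

    Genes are stored as upper-cased symbols in first-seen order.  Genes absent
    from a given graph are retained here but flagged by
    :meth:`missing_from`; model training drops them with a logged count.
    """

    name: str
    disease_node: str
    genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g.upper(), None)
        self.genes = tuple(seen)

    def __len__(self) -> int:
        return len(self.genes)

    def gene_nodes(self) -> list[str]:
        return [gene_node(g) for g in self.genes]

    def missing_from(self, graph: KnowledgeGraph) -> list[str]:
        return [g for g in self.genes if gene_node(g) not in graph]

    def present_in(self, graph: KnowledgeGraph) -> list[str]:
        """Gene node ids of definition members that exist in the graph."""
        return [n for n in self.gene_nodes() if n in graph]


def union_definition(
    definitions: Sequence[DiseaseDefinition],
    name: str = "Union",
    disease: str | None = None,
) -> DiseaseDefinition:
    """Union of several gene-list definitions, preserving first-seen order."""
    if len(definitions) < 1:
        raise ValueError("union_definition needs at least one definition")
    diseases = {d.disease_node for d in definitions}
    if disease is None:
        if len(diseases) != 1:
            raise ValueError(
                "definitions target different diseases; pass `disease` explicitly"
            )
        disease = diseases.pop()
    genes: list[str] = []
    for d in definitions:
        genes.extend(d.genes)
    return DiseaseDefinition(name=name, disease_node=disease, genes=tuple(genes))
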