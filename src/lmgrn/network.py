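"""Signed gene regulatory networks in the activity-flow formalism.

A network is a set of elements (transcription factors, enzymes, metabolites,
terminal lipid products, phenotypes, plain genes) connected by signed directed
edges: a triple ``(source, relation, target)`` with relation +1 (activation /
upregulation) or -1 (inhibition / downregulation).  Catalytic reactions
(substrate --enzyme--> product) are rewritten into this formalism by placing
the enzyme between substrate and product with two positive edges, so that
enzyme expression gates the route.

Cell-type-specific subgraphs are obtained by removing transcription factors
and genes whose read count in the given sample falls below an expression
threshold; enzymes of the curated biosynthesis submaps, metabolites, products
and phenotypes are protected and never removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx

__all__ = [
    "Role",
    "SignedGraph",
    "CatalyticReaction",
    "CellSubgraph",
    "transform_catalysis",
    "merge_networks",
    "filter_expressed",
    "PROTECTED_ROLES",
    "EXPRESSION_THRESHOLD",
]

#: roles an element may take
ROLES = ("TF", "enzyme", "metabolite", "product", "phenotype", "gene")

#: roles never removed by expression filtering (curated-submap members and
#: elements that carry no expression measurement)
PROTECTED_ROLES = frozenset({"enzyme", "metabolite", "product", "phenotype"})

#: read-count threshold marking a gene as expressed
EXPRESSION_THRESHOLD = 10.0

Role = str
Edge = tuple[str, int, str]


class MalformedInputError(ValueError):
    """Raised for structurally invalid network input."""


class ConsistencyError(ValueError):
    """Raised when merging networks with conflicting element annotations."""


@dataclass(frozen=True)
class CatalyticReaction:
    """A catalytic step: ``substrate --enzyme--> product``."""

    substrate: str
    enzyme: str
    product: str

    def __post_init__(self) -> None:
        vals = (self.substrate, self.enzyme, self.product)
        if any(not v for v in vals):
            raise MalformedInputError(f"reaction with missing field: {self!r}")
        if len(set(vals)) != 3:
            raise MalformedInputError(
                f"substrate, enzyme and product must be distinct: {self!r}"
            )


class SignedGraph:
    """Directed graph with signed edges and per-node roles.

    Edges are triples ``(source, relation, target)`` with relation in
    {-1, +1}.  Identical triples are deduplicated; the same ordered pair may
    carry both signs as two distinct edges.  Backed by a
    :class:`networkx.MultiDiGraph` keyed by the relation.
    """

    def __init__(self) -> None:
        self._g = nx.MultiDiGraph()

    # -- construction ------------------------------------------------------

    def add_node(self, node: str, role: Role = "gene") -> None:
        if role not in ROLES:
            raise MalformedInputError(f"unknown role {role!r} for node {node!r}")
        existing = self._g.nodes.get(node, {}).get("role")
        if existing is not None and existing != role:
            raise ConsistencyError(
                f"node {node!r} already has role {existing!r}, got {role!r}"
            )
        self._g.add_node(node, role=role)

    def add_edge(self, source: str, relation: int, target: str) -> None:
        if relation not in (-1, 1):
            raise MalformedInputError(
                f"relation must be -1 or +1, got {relation!r}"
            )
        for n in (source, target):
            if n not in self._g:
                self._g.add_node(n, role="gene")
        # keying by the relation deduplicates identical triples
        self._g.add_edge(source, target, key=relation, relation=relation)

    # -- queries -----------------------------------------------------------

    @property
    def vertices(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[Edge]:
        return {(u, k, v) for u, v, k in self._g.edges(keys=True)}

    def role(self, node: str) -> Role:
        return self._g.nodes[node]["role"]

    @property
    def node_roles(self) -> dict[str, Role]:
        return {n: d["role"] for n, d in self._g.nodes(data=True)}

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def out_edges(self, node: str) -> Iterator[Edge]:
        """Signed edges leaving ``node``."""
        for u, v, k in self._g.out_edges(node, keys=True):
            yield (u, k, v)

    def in_edges(self, node: str) -> Iterator[Edge]:
        for u, v, k in self._g.in_edges(node, keys=True):
            yield (u, k, v)

    def successors(self, node: str) -> Iterator[str]:
        return self._g.successors(node)

    def predecessors(self, node: str) -> Iterator[str]:
        return self._g.predecessors(node)

    def degree(self, node: str) -> int:
        """Number of interactions (in + out), each triple counted once."""
        return self._g.degree(node)

    def nodes_with_role(self, *roles: Role) -> set[str]:
        want = set(roles)
        return {n for n, d in self._g.nodes(data=True) if d["role"] in want}

    # -- derived graphs ----------------------------------------------------

    def subgraph(self, nodes: Iterable[str]) -> "SignedGraph":
        """Induced subgraph on ``nodes`` (copy, not a view)."""
        keep = set(nodes) & self.vertices
        sub = SignedGraph()
        for n in keep:
            sub.add_node(n, self.role(n))
        for u, k, v in self.edges:
            if u in keep and v in keep:
                sub.add_edge(u, k, v)
        return sub

    def copy(self) -> "SignedGraph":
        return self.subgraph(self.vertices)

    def to_networkx(self) -> nx.MultiDiGraph:
        return self._g.copy()

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self._g)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedGraph):
            return NotImplemented
        return self.node_roles == other.node_roles and self.edges == other.edges

    def __repr__(self) -> str:
        return (
            f"SignedGraph({len(self)} nodes, {self.number_of_edges()} edges)"
        )


@dataclass
class CellSubgraph:
    """Expression-filtered view of a parent network for one sample.

    ``protected`` lists the vertices that were exempt from filtering
    (enzymes, metabolites, products, phenotypes).
    """

    parent: SignedGraph
    sample: str
    retained_vertices: set[str]
    protected: frozenset[str]
    threshold: float = EXPRESSION_THRESHOLD
    _graph: SignedGraph | None = field(default=None, repr=False, compare=False)

    @property
    def graph(self) -> SignedGraph:
        """The induced subgraph on the retained vertices."""
        if self._graph is None:
            self._graph = self.parent.subgraph(self.retained_vertices)
        return self._graph

    @property
    def retained_edges(self) -> set[Edge]:
        return self.graph.edges

    def __contains__(self, node: str) -> bool:
        return node in self.retained_vertices


def transform_catalysis(reactions: Iterable[CatalyticReaction]) -> SignedGraph:
    """Rewrite catalytic reactions into activity-flow form.

    Each reaction contributes the two positive edges
    ``substrate -> enzyme -> product``; no direct substrate->product edge is
    added.  Enzymes catalysing several reactions appear once.  Substrates and
    products default to role ``metabolite``; callers can re-annotate terminal
    products afterwards.
    """
    g = SignedGraph()
    for rxn in reactions:
        if not isinstance(rxn, CatalyticReaction):
            rxn = CatalyticReaction(*rxn)
        for node, role in (
            (rxn.substrate, "metabolite"),
            (rxn.enzyme, "enzyme"),
            (rxn.product, "metabolite"),
        ):
            if node not in g:
                g.add_node(node, role)
        g.add_edge(rxn.substrate, +1, rxn.enzyme)
        g.add_edge(rxn.enzyme, +1, rxn.product)
    return g


def merge_networks(pathway: SignedGraph, tf_edges: SignedGraph) -> SignedGraph:
    """Union of a biosynthesis pathway graph and a TF-target graph.

    Vertex and edge sets are united; a node present in both with different
    roles raises :class:`ConsistencyError`.
    """
    merged = SignedGraph()
    for n, role in pathway.node_roles.items():
        merged.add_node(n, role)
    for n, role in tf_edges.node_roles.items():
        merged.add_node(n, role)  # raises on role conflict
    for u, k, v in pathway.edges | tf_edges.edges:
        merged.add_edge(u, k, v)
    return merged


def filter_expressed(
    graph: SignedGraph,
    expression: "ExpressionMatrix",
    sample: str,
    threshold: float = EXPRESSION_THRESHOLD,
) -> CellSubgraph:
    """Cell-type-specific subgraph: drop unexpressed TFs/genes.

    A TF or gene vertex is removed, with its incident edges, when its raw
    read count in ``sample`` is below ``threshold`` (a count exactly at the
    threshold counts as expressed).  Vertices with protected roles — enzymes
    of the curated submaps, metabolites, products, phenotypes — are retained
    regardless of expression, as are TF/gene vertices absent from the
    expression matrix (no measurement is not evidence of absence).
    """
    from .expression import ExpressionMatrix  # local import to avoid a cycle

    if not isinstance(expression, ExpressionMatrix):
        raise TypeError("expression must be an ExpressionMatrix")
    counts = expression.sample_counts(sample)  # raises KeyError if unknown

    protected = frozenset(
        n for n, role in graph.node_roles.items() if role in PROTECTED_ROLES
    )
    keep: set[str] = set()
    for node in graph.vertices:
        if node in protected:
            keep.add(node)
        elif node not in counts.index or counts[node] >= threshold:
            keep.add(node)
    return CellSubgraph(
        parent=graph,
        sample=sample,
        retained_vertices=keep,
        protected=protected,
        threshold=threshold,
    )
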