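"""Path algebra and topological analysis of signed networks.

The sign of a path is the product of its edge relations, so two inhibitions
compose to a net activation.  Shortest paths use breadth-first search with
lexicographic tie-breaking for determinism.  Core regulatory networks (CRNs)
are unions of widest (maximum-bottleneck) paths from regulators to LM
enzymes, found with an adaptation of Dijkstra's algorithm in which an edge's
weight is the regulatory score of its *target* node.

The topological weight of an element e for an LM class p measures e's share
of the routes into p within the acyclic biosynthesis submap:

    w(e, p) = sign(SP(e, p)) * (Npaths_e / Npaths + Nnodes_e / Nnodes)

where Npaths counts all simple precursor->product paths, Npaths_e those
passing through e, Nnodes the elements connected to (i.e. upstream of) the
products, and Nnodes_e the elements on the shortest path from e to a
product.  |w| <= 2, with 2 attained only by an element sitting on every
route whose shortest path touches every connected element.
"""

from __future__ import annotations

import heapq
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .lipid_classes import LMClassSpec
from .network import CellSubgraph, SignedGraph

__all__ = [
    "SignedPath",
    "CoreRegulatoryNetwork",
    "CyclicSubmapError",
    "path_sign",
    "shortest_path",
    "topological_weight",
    "class_weights",
    "widest_path",
    "extract_crn",
]


class CyclicSubmapError(ValueError):
    """Raised when path counting is requested on a cyclic submap."""


@dataclass(frozen=True)
class SignedPath:
    """A directed path with its edge relations.

    ``sign`` is the product of the relations; a zero-length path has sign +1
    (the multiplicative identity).
    """

    vertices: tuple[str, ...]
    relations: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.vertices) != len(self.relations) + 1:
            raise ValueError("need exactly one relation per edge")
        if any(r not in (-1, 1) for r in self.relations):
            raise ValueError("relations must be -1 or +1")

    @property
    def length(self) -> int:
        return len(self.relations)

    @property
    def sign(self) -> int:
        return path_sign(self)

    def concat(self, other: "SignedPath") -> "SignedPath":
        if self.vertices[-1] != other.vertices[0]:
            raise ValueError("paths do not join")
        return SignedPath(
            self.vertices + other.vertices[1:], self.relations + other.relations
        )


def path_sign(path: SignedPath | Sequence[int]) -> int:
    """Product of the edge relations along a path; +1 for the empty path."""
    relations = path.relations if isinstance(path, SignedPath) else tuple(path)
    sign = 1
    for r in relations:
        if r not in (-1, 1):
            raise ValueError(f"invalid relation {r!r}")
        sign *= r
    return sign


def _edge_relation(graph: SignedGraph, u: str, v: str) -> int:
    """Relation of the edge u->v; +1 preferred if both signs exist."""
    rels = [k for (s, k, t) in graph.out_edges(u) if t == v]
    if not rels:
        raise ValueError(f"no edge {u!r}->{v!r}")
    return max(rels)


def _as_signed_path(graph: SignedGraph, vertices: Sequence[str]) -> SignedPath:
    rels = tuple(
        _edge_relation(graph, u, v) for u, v in zip(vertices, vertices[1:])
    )
    return SignedPath(tuple(vertices), rels)


def shortest_path(
    graph: SignedGraph, source: str, target: str | Iterable[str]
) -> SignedPath | None:
    """BFS shortest directed path, or None if unreachable.

    ``target`` may be a single vertex or a collection (path to the nearest
    member).  Among equally short paths the lexicographically smallest
    vertex sequence is returned, which BFS with sorted neighbor expansion
    guarantees.
    """
    targets = {target} if isinstance(target, str) else set(target)
    if source not in graph:
        raise KeyError(f"unknown vertex {source!r}")
    missing = targets - graph.vertices
    if missing:
        raise KeyError(f"unknown vertex {sorted(missing)[0]!r}")
    if source in targets:
        return SignedPath((source,), ())

    parent: dict[str, str] = {source: source}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in sorted(set(graph.successors(u))):
            if v in parent:
                continue
            parent[v] = u
            if v in targets:
                # first target reached at the minimal depth with
                # lexicographically minimal parents
                verts = [v]
                while verts[-1] != source:
                    verts.append(parent[verts[-1]])
                verts.reverse()
                return _as_signed_path(graph, verts)
            queue.append(v)
    return None


def topological_weight(
    submap: SignedGraph,
    element: str,
    lm_class: LMClassSpec,
) -> float:
    """Topological weight of ``element`` for an LM class on its submap.

    Path and node counts pool all terminal products of the class present in
    the submap.  Returns 0.0 when the element has no route to any product.
    Raises :class:`CyclicSubmapError` on cyclic submaps, where simple-path
    counts are not meaningful.
    """
    if not submap.is_acyclic():
        raise CyclicSubmapError(
            f"submap for class {lm_class.name!r} is cyclic; path counts undefined"
        )
    products = [p for p in lm_class.products if p in submap]
    if not products or element not in submap:
        return 0.0

    sp = shortest_path(submap, element, products)
    if sp is None:
        return 0.0

    g = submap.to_networkx()
    all_paths: list[list[str]] = []
    if lm_class.precursor in submap:
        for prod in products:
            all_paths.extend(
                nx.all_simple_paths(g, lm_class.precursor, prod)
            )
        # the zero-length "path" when a precursor is itself a product cannot
        # occur (class invariant forbids precursor in products)
    n_paths = len(all_paths)
    n_paths_e = sum(1 for p in all_paths if element in p)

    connected = set()
    for prod in products:
        connected |= nx.ancestors(g, prod)
    connected -= set(products)
    n_nodes = len(connected)
    n_nodes_e = len(sp.vertices)

    path_frac = n_paths_e / n_paths if n_paths else 0.0
    node_frac = n_nodes_e / n_nodes if n_nodes else 0.0
    return sp.sign * (path_frac + node_frac)


def class_weights(
    graph: SignedGraph, lm_class: LMClassSpec
) -> dict[str, float]:
    """Topological weights of every class enzyme, on the class submap."""
    submap = lm_class.submap(graph)
    return {
        e: topological_weight(submap, e, lm_class)
        for e in lm_class.enzymes
        if e in submap
    }


def widest_path(
    graph: SignedGraph,
    source: str,
    target: str,
    node_weight: Mapping[str, float],
) -> SignedPath | None:
    """Maximum-bottleneck path via an adapted Dijkstra.

    Each edge carries the weight of its *target* node (missing nodes default
    to 0), and the returned path maximizes the minimum edge weight along it.
    Among equal-bottleneck paths the shorter one wins, then the
    lexicographically smallest vertex sequence.  Zero-weight vertices are
    traversable but any path through them has bottleneck <= 0.
    """
    if source not in graph or target not in graph:
        raise KeyError("source or target not in graph")
    if source == target:
        return SignedPath((source,), ())

    # heap orders by (-bottleneck, length, vertex sequence): pops yield the
    # widest, then shortest, then lexicographically smallest partial path
    heap: list[tuple[float, int, tuple[str, ...]]] = [
        (-math.inf, 0, (source,))
    ]
    done: set[str] = set()
    while heap:
        neg_b, length, path = heapq.heappop(heap)
        u = path[-1]
        if u in done:
            continue
        done.add(u)
        if u == target:
            return _as_signed_path(graph, path)
        for v in sorted(set(graph.successors(u))):
            if v in done:
                continue
            w = float(node_weight.get(v, 0.0))
            bottleneck = min(-neg_b, w)
            heapq.heappush(heap, (-bottleneck, length + 1, path + (v,)))
    return None


@dataclass
class CoreRegulatoryNetwork:
    """Union of widest regulator->enzyme paths with per-vertex scores.

    ``provenance`` records each merged widest path; every vertex of the CRN
    lies on at least one of them.
    """

    lm_class: str
    sample: str
    graph: SignedGraph
    vertex_scores: dict[str, float]
    provenance: list[SignedPath] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return len(self.graph) == 0


def extract_crn(
    cell: CellSubgraph,
    scores: Mapping[str, float],
    lm_class: LMClassSpec,
    mode: str = "single",
) -> CoreRegulatoryNetwork:
    """Core regulatory network of one LM class in one cell subgraph.

    For every regulator with a nonzero score and every class enzyme present
    in the cell subgraph, the widest path (bottleneck on the regulatory
    score of traversed nodes) is found; the CRN is the union of these paths.
    ``mode`` selects the node weight: ``"single"`` uses the score s-bar as
    given, ``"delta"`` its absolute value (for score differences between two
    cell sets).
    """
    if mode not in ("single", "delta"):
        raise ValueError("mode must be 'single' or 'delta'")
    g = cell.graph
    weights = {
        n: (abs(scores.get(n, 0.0)) if mode == "delta" else scores.get(n, 0.0))
        for n in g.vertices
    }
    enzymes = [e for e in lm_class.enzymes if e in g]
    crn_nodes: set[str] = set()
    paths: list[SignedPath] = []
    if enzymes:
        regulators = sorted(
            n
            for n in g.vertices
            if g.role(n) in ("TF", "gene") and weights.get(n, 0.0) != 0.0
        )
        for tf in regulators:
            for enz in sorted(enzymes):
                path = widest_path(g, tf, enz, weights)
                if path is not None and path.length > 0:
                    paths.append(path)
                    crn_nodes.update(path.vertices)
    sub = g.subgraph(crn_nodes)
    # keep only edges that lie on a recorded path
    path_edges = set()
    for p in paths:
        for u, r, v in zip(p.vertices, p.relations, p.vertices[1:]):
            path_edges.add((u, r, v))
    crn = SignedGraph()
    for n in crn_nodes:
        crn.add_node(n, g.role(n))
    for u, r, v in path_edges:
        crn.add_edge(u, r, v)
    return CoreRegulatoryNetwork(
        lm_class=lm_class.name,
        sample=cell.sample,
        graph=crn,
        vertex_scores={n: weights.get(n, 0.0) for n in crn_nodes},
        provenance=paths,
    )
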