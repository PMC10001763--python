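"""Path algebra, topological weighting and widest paths against
independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lmgrn import (
    LMClassSpec,
    SignedGraph,
    SignedPath,
    extract_crn,
    filter_expressed,
    normalize_expression,
    path_sign,
    shortest_path,
    topological_weight,
    widest_path,
)
from lmgrn.topology import CyclicSubmapError

from conftest import random_dag_submap, random_signed_graph


# -- independent oracles ---------------------------------------------------

def enumerate_simple_paths(graph: SignedGraph, source, targets):
    """All simple directed paths source -> any target, by plain DFS."""
    targets = set(targets)
    out = []

    def walk(path):
        node = path[-1]
        if node in targets and len(path) > 1:
            out.append(list(path))
        for nxt in sorted(set(graph.successors(node))):
            if nxt not in path:
                path.append(nxt)
                walk(path)
                path.pop()

    if source in targets:
        out.append([source])
    walk([source])
    return out


def brute_force_widest(graph, source, target, weights):
    """Maximum bottleneck over exhaustively enumerated simple paths."""
    best = None
    for path in enumerate_simple_paths(graph, source, {target}):
        if len(path) < 2:
            continue
        bottleneck = min(weights.get(v, 0.0) for v in path[1:])
        if best is None or bottleneck > best:
            best = bottleneck
    return best


class TestPathSign:
    @pytest.mark.parametrize(
        "relations, expected",
        [((1, 1, 1), 1), ((-1, -1), 1), ((-1, 1, 1), -1), ((), 1)],
    )
    def test_product_of_relations(self, relations, expected):
        assert path_sign(relations) == expected

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.sampled_from([-1, 1]), max_size=8),
        st.lists(st.sampled_from([-1, 1]), max_size=8),
    )
    def test_multiplicative_under_concatenation(self, r1, r2):
        assert path_sign(r1 + r2) == path_sign(r1) * path_sign(r2)

    def test_concat_joins_signed_paths(self):
        p1 = SignedPath(("a", "b"), (-1,))
        p2 = SignedPath(("b", "c"), (-1,))
        joined = p1.concat(p2)
        assert joined.sign == 1 and joined.length == 2


class TestShortestPath:
    def test_direct_edge(self):
        g = SignedGraph()
        g.add_edge("u", -1, "v")
        path = shortest_path(g, "u", "v")
        assert path.vertices == ("u", "v") and path.sign == -1

    def test_unreachable_returns_none(self):
        g = SignedGraph()
        g.add_edge("u", 1, "x")
        g.add_node("v")
        assert shortest_path(g, "u", "v") is None

    def test_prefers_shorter_route(self):
        g = SignedGraph()
        for u, v in [("a", "b"), ("b", "f"), ("a", "c"), ("c", "d"),
                     ("d", "f")]:
            g.add_edge(u, 1, v)
        g.add_node("e")
        path = shortest_path(g, "a", "f")
        assert path.length == 2
        # equals brute-force minimum
        lengths = [len(p) - 1 for p in enumerate_simple_paths(g, "a", {"f"})]
        assert path.length == min(lengths)

    def test_matches_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            g = random_signed_graph(rng, n_nodes=7)
            nodes = sorted(g.vertices)
            u, v = nodes[0], nodes[-1]
            got = shortest_path(g, u, v)
            paths = enumerate_simple_paths(g, u, {v})
            if not paths:
                assert got is None
            else:
                assert got.length == min(len(p) - 1 for p in paths)

    def test_unknown_vertex_raises(self):
        g = SignedGraph()
        g.add_node("u")
        with pytest.raises(KeyError):
            shortest_path(g, "u", "missing")


class TestTopologicalWeight:
    def test_sole_enzyme_on_sole_path_is_maximal(self):
        g = SignedGraph()
        g.add_node("AA", "metabolite")
        g.add_node("e", "enzyme")
        g.add_node("p", "product")
        g.add_edge("AA", 1, "e")
        g.add_edge("e", 1, "p")
        cls = LMClassSpec("c", "AA", ("p",), ("e",))
        assert topological_weight(g, "e", cls) == pytest.approx(2.0)

    def test_inhibiting_shortest_path_gives_negative_weight(self):
        g = SignedGraph()
        g.add_node("AA", "metabolite")
        g.add_node("e", "enzyme")
        g.add_node("p", "product")
        g.add_edge("AA", 1, "e")
        g.add_edge("e", -1, "p")
        cls = LMClassSpec("c", "AA", ("p",), ("e",))
        assert topological_weight(g, "e", cls) < 0

    def test_two_branch_dag_hand_value(self):
        # 7 nodes, 3 simple paths to p, e on 2 of them, shortest path from e
        # has 3 nodes, 6 nodes connected to p -> w = 2/3 + 3/6 = 7/6
        g = SignedGraph()
        for n, role in [("pre", "metabolite"), ("e", "enzyme"),
                        ("m1", "metabolite"), ("m2", "metabolite"),
                        ("f", "enzyme"), ("m3", "metabolite"),
                        ("p", "product")]:
            g.add_node(n, role)
        for u, v in [("pre", "e"), ("e", "m1"), ("e", "m2"), ("m1", "p"),
                     ("m2", "p"), ("pre", "f"), ("f", "m3"), ("m3", "p")]:
            g.add_edge(u, 1, v)
        cls = LMClassSpec("c", "pre", ("p",), ("e", "f"))
        assert topological_weight(g, "e", cls) == pytest.approx(7.0 / 6.0)

    def test_disconnected_element_weighs_zero(self):
        g = SignedGraph()
        g.add_node("pre", "metabolite")
        g.add_node("e", "enzyme")
        g.add_node("lone", "enzyme")
        g.add_node("p", "product")
        g.add_edge("pre", 1, "e")
        g.add_edge("e", 1, "p")
        cls = LMClassSpec("c", "pre", ("p",), ("e", "lone"))
        assert topological_weight(g, "lone", cls) == 0.0

    def test_cyclic_submap_refused(self):
        g = SignedGraph()
        g.add_node("pre", "metabolite")
        g.add_node("e", "enzyme")
        g.add_node("p", "product")
        g.add_edge("pre", 1, "e")
        g.add_edge("e", 1, "p")
        g.add_edge("p", 1, "pre")
        cls = LMClassSpec("c", "pre", ("p",), ("e",))
        with pytest.raises(CyclicSubmapError):
            topological_weight(g, "e", cls)

    def test_matches_brute_force_on_random_dags(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            g, cls = random_dag_submap(rng, n_nodes=int(rng.integers(5, 11)))
            for e in cls.enzymes:
                w = topological_weight(g, e, cls)
                assert abs(w) <= 2.0 + 1e-12
                # oracle: enumerate paths and ancestors by hand
                all_paths = enumerate_simple_paths(
                    g, cls.precursor, set(cls.products)
                )
                through = [p for p in all_paths if e in p]
                connected = {
                    v for v in g.vertices
                    if v not in cls.products
                    and enumerate_simple_paths(g, v, set(cls.products))
                }
                sp = shortest_path(g, e, cls.products)
                if sp is None:
                    assert w == 0.0
                    continue
                expected = sp.sign * (
                    len(through) / len(all_paths)
                    + len(sp.vertices) / len(connected)
                )
                assert w == pytest.approx(expected, abs=1e-12)


class TestWidestPath:
    def test_single_route_returned_regardless_of_weights(self):
        g = SignedGraph()
        g.add_edge("a", 1, "b")
        g.add_edge("b", 1, "c")
        path = widest_path(g, "a", "c", {"b": -5.0, "c": 0.1})
        assert path.vertices == ("a", "b", "c")

    def test_prefers_higher_bottleneck(self):
        g = SignedGraph()
        for u, v in [("s", "x"), ("x", "t"), ("s", "y"), ("y", "t")]:
            g.add_edge(u, 1, v)
        w = {"x": 0.9, "y": 0.4, "t": 1.0}
        assert widest_path(g, "s", "t", w).vertices == ("s", "x", "t")

    def test_unreachable_returns_none(self):
        g = SignedGraph()
        g.add_edge("a", 1, "b")
        g.add_node("z")
        assert widest_path(g, "a", "z", {}) is None

    def test_zero_weight_traversable_but_ranked_below_positive(self):
        g = SignedGraph()
        for u, v in [("s", "x"), ("x", "t"), ("s", "z"), ("z", "t")]:
            g.add_edge(u, 1, v)
        w = {"x": 0.2, "z": 0.0, "t": 0.5}
        assert widest_path(g, "s", "t", w).vertices == ("s", "x", "t")

    def test_equal_bottleneck_prefers_shorter_then_lexicographic(self):
        g = SignedGraph()
        for u, v in [("s", "a"), ("a", "t"), ("s", "b"), ("b", "c"),
                     ("c", "t")]:
            g.add_edge(u, 1, v)
        w = {"a": 1.0, "b": 1.0, "c": 1.0, "t": 1.0}
        assert widest_path(g, "s", "t", w).vertices == ("s", "a", "t")

    def test_bottleneck_matches_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(23)
        for _ in range(60):
            g = random_signed_graph(rng, n_nodes=int(rng.integers(4, 9)))
            nodes = sorted(g.vertices)
            weights = {n: float(rng.normal()) for n in nodes}
            u, v = nodes[0], nodes[-1]
            got = widest_path(g, u, v, weights)
            expected = brute_force_widest(g, u, v, weights)
            if expected is None:
                assert got is None
            else:
                bottleneck = min(
                    weights[x] for x in got.vertices[1:]
                )
                assert bottleneck == pytest.approx(expected)


class TestExtractCrn:
    def test_single_path_crn(self, chain_graph, chain_class,
                             chain_expression):
        cell = filter_expressed(chain_graph, chain_expression, "s1")
        crn = extract_crn(
            cell, {"TF1": 0.8, "E1": 0.5}, chain_class, mode="single"
        )
        assert "TF1" in crn.graph.vertices and "E1" in crn.graph.vertices
        assert crn.provenance and crn.provenance[0].vertices == ("TF1", "E1")

    def test_zero_score_tf_excluded(self, chain_graph, chain_class,
                                    chain_expression):
        cell = filter_expressed(chain_graph, chain_expression, "s1")
        crn = extract_crn(cell, {"TF1": 0.0}, chain_class, mode="single")
        assert crn.is_empty

    def test_absent_enzymes_give_empty_crn(self, chain_graph,
                                           chain_expression):
        cls = LMClassSpec("ghost", "AA", ("Q",), ("EX",))
        cell = filter_expressed(chain_graph, chain_expression, "s1")
        crn = extract_crn(cell, {"TF1": 1.0}, cls, mode="single")
        assert crn.is_empty

    def test_crn_contains_planted_route(self, small_dataset):
        from lmgrn.pipeline import score_all

        ds = small_dataset
        info = ds.truth.planted_regulators[0]
        cname = info["classes"][0]
        cls = next(c for c in ds.classes if c.name == cname)
        sample = "c0_s00"
        scores = score_all(ds.graph, [cls], ds.expression)
        sub = scores[(scores["sample"] == sample)]
        sbar = dict(zip(sub["gene"], sub["score"]))
        expr = normalize_expression(ds.expression)
        cell = filter_expressed(ds.graph, expr, sample)
        crn = extract_crn(cell, sbar, cls, mode="single")
        assert info["tf"] in crn.graph.vertices
        # the planted cascade ends at a class enzyme inside the CRN
        route_edges = {
            (info["tf"], 1, med) for med in info["mediators"]
        }
        assert route_edges & crn.graph.edges
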