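"""Reverse signal propagation against a dense matrix-iteration oracle."""

import numpy as np
import pandas as pd
import pytest

from lmgrn import (
    ExpressionMatrix,
    LMClassSpec,
    SignedGraph,
    filter_expressed,
    normalize_expression,
    regulatory_score,
    run_propagation,
)
from lmgrn.propagation import PropagationModel, ScoreTrajectory, propagate_step

from conftest import random_signed_graph


def dense_oracle(cell, qhat, sources, steps):
    """Independent dense matrix iteration of the propagation law.

    Builds the update matrix entry by entry from the definition
    s_u(t+1) = factor(u) * sum r * s_v(t) / (deg(u) deg(v)) and iterates it
    with explicit source clamping.
    """
    g = cell.graph
    nodes = sorted(g.vertices)
    idx = {n: i for i, n in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for u, r, v in g.edges:
        factor = 1.0
        if g.role(u) in ("TF", "gene", "enzyme") and u in qhat:
            factor = qhat[u]
        a[idx[u], idx[v]] += (
            factor * r / (cell.parent.degree(u) * cell.parent.degree(v))
        )
    s = np.zeros(len(nodes))
    for n, w in sources.items():
        if n in idx:
            s[idx[n]] = w
    out = [s.copy()]
    for _ in range(steps):
        s = a @ s
        for n, w in sources.items():
            if n in idx:
                s[idx[n]] = w
        out.append(s.copy())
    return nodes, np.array(out)


def _chain_setup(q_tf=1.0):
    g = SignedGraph()
    g.add_node("TF", "TF")
    g.add_node("E", "enzyme")
    g.add_edge("TF", 1, "E")
    counts = pd.DataFrame({"s": [q_tf * 100, 100.0]}, index=["TF", "E"])
    expr = normalize_expression(ExpressionMatrix(counts=counts))
    cell = filter_expressed(g, expr, "s", threshold=0.0)
    cls = LMClassSpec("c", "X", ("P",), ("E",))
    return g, cell, expr, cls


class TestPropagateStep:
    def test_unexpressed_tf_scores_zero_forever(self):
        g, cell, expr, cls = _chain_setup()
        qhat = {"TF": 0.0, "E": 1.0}
        traj = run_propagation(cell, cls, {"E": 1.0}, qhat, steps=20)
        assert np.all(traj.series("TF")[1:] == 0.0)

    def test_unit_chain_reaches_constant_one(self):
        g, cell, expr, cls = _chain_setup()
        traj = run_propagation(
            cell, cls, {"E": 1.0}, {"TF": 1.0, "E": 1.0}, steps=5
        )
        # deg(TF)=deg(E)=1, q-hat=1, w=1: s_TF(t)=1 for all t >= 1
        assert traj.series("TF")[0] == 0.0
        assert np.allclose(traj.series("TF")[1:], 1.0)
        assert np.allclose(traj.series("E"), 1.0)

    def test_single_step_matches_manual_sum(self):
        # 2 TFs on one enzyme, one inhibiting, distinct degrees
        g = SignedGraph()
        g.add_node("A", "TF")
        g.add_node("B", "TF")
        g.add_node("E", "enzyme")
        g.add_node("F", "enzyme")
        g.add_edge("A", 1, "E")
        g.add_edge("B", -1, "E")
        g.add_edge("B", 1, "F")
        counts = pd.DataFrame({"s": [80.0, 40.0, 10.0, 10.0]},
                              index=["A", "B", "E", "F"])
        expr = normalize_expression(ExpressionMatrix(counts=counts))
        cell = filter_expressed(g, expr, "s", threshold=0.0)
        qhat = {"A": 1.0, "B": 1.0, "E": 1.0, "F": 1.0}
        nxt = propagate_step(
            cell, {"E": 2.0, "F": 1.0}, qhat,
            source_scores={"E": 2.0, "F": 1.0},
        )
        assert nxt["A"] == pytest.approx(1.0 * 2.0 / (1 * 2))
        assert nxt["B"] == pytest.approx(-2.0 / (2 * 2) + 1.0 / (2 * 1))

    def test_matches_dense_oracle_on_random_graphs(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            g = random_signed_graph(
                rng, n_nodes=8, roles=("TF", "gene", "enzyme")
            )
            genes = sorted(g.vertices)
            counts = pd.DataFrame(
                {"s": rng.integers(0, 200, len(genes)).astype(float)},
                index=genes,
            )
            expr = normalize_expression(ExpressionMatrix(counts=counts))
            cell = filter_expressed(g, expr, "s", threshold=10.0)
            enzymes = [n for n in genes if g.role(n) == "enzyme"]
            cls = LMClassSpec("c", "X", ("P",), tuple(enzymes) or ("none",))
            weights = {e: float(rng.normal()) for e in enzymes}
            qhat = expr.sample_normalized("s").to_dict()
            traj = run_propagation(cell, cls, weights, qhat, steps=30)
            nodes, expected = dense_oracle(
                cell, qhat,
                {e: weights.get(e, 0.0) for e in enzymes}, steps=30,
            )
            assert tuple(nodes) == traj.nodes
            np.testing.assert_allclose(traj.values, expected, atol=1e-10)


class TestRunPropagation:
    def test_zero_steps_equals_initialization(self):
        g, cell, expr, cls = _chain_setup()
        traj = run_propagation(cell, cls, {"E": 0.7}, {"TF": 1.0}, steps=0)
        assert traj.steps == 0
        assert traj.series("E")[0] == 0.7
        assert traj.series("TF")[0] == 0.0

    def test_linear_in_source_weights(self):
        rng = np.random.default_rng(4)
        g = random_signed_graph(rng, n_nodes=7, roles=("TF", "enzyme"))
        genes = sorted(g.vertices)
        counts = pd.DataFrame(
            {"s": rng.integers(20, 100, len(genes)).astype(float)},
            index=genes,
        )
        expr = normalize_expression(ExpressionMatrix(counts=counts))
        cell = filter_expressed(g, expr, "s")
        enzymes = tuple(n for n in genes if g.role(n) == "enzyme")
        cls = LMClassSpec("c", "X", ("P",), enzymes)
        qhat = expr.sample_normalized("s").to_dict()
        w1 = {e: 0.5 for e in enzymes}
        w2 = {e: 1.0 for e in enzymes}
        t1 = run_propagation(cell, cls, w1, qhat, steps=15)
        t2 = run_propagation(cell, cls, w2, qhat, steps=15)
        np.testing.assert_allclose(2.0 * t1.values, t2.values, atol=1e-12)

    def test_isomorphic_graphs_score_identically_under_renaming(self):
        def build(prefix):
            g = SignedGraph()
            g.add_node(f"{prefix}tf1", "TF")
            g.add_node(f"{prefix}tf2", "TF")
            g.add_node(f"{prefix}e", "enzyme")
            g.add_edge(f"{prefix}tf1", 1, f"{prefix}e")
            g.add_edge(f"{prefix}tf2", -1, f"{prefix}e")
            g.add_edge(f"{prefix}tf1", 1, f"{prefix}tf2")
            counts = pd.DataFrame(
                {"s": [60.0, 30.0, 10.0]},
                index=[f"{prefix}tf1", f"{prefix}tf2", f"{prefix}e"],
            )
            expr = normalize_expression(ExpressionMatrix(counts=counts))
            cell = filter_expressed(g, expr, "s")
            cls = LMClassSpec("c", "X", ("P",), (f"{prefix}e",))
            traj = run_propagation(
                cell, cls, {f"{prefix}e": 1.0},
                expr.sample_normalized("s").to_dict(), steps=25,
            )
            return regulatory_score(traj)
        s_a = build("a_")
        s_b = build("b_")
        for node, value in s_a.items():
            assert value == pytest.approx(s_b["b_" + node[2:]])


class TestRegulatoryScore:
    def test_constant_trajectory_integrates_to_area(self):
        traj = ScoreTrajectory(
            nodes=("u",), values=np.full((101, 1), 0.3)
        )
        assert regulatory_score(traj)["u"] == pytest.approx(30.0)

    def test_zero_trajectory_scores_zero(self):
        traj = ScoreTrajectory(nodes=("u",), values=np.zeros((101, 1)))
        assert regulatory_score(traj)["u"] == 0.0

    def test_geometric_decay_matches_closed_form(self):
        t = np.arange(101)
        series = 0.5 ** t
        traj = ScoreTrajectory(
            nodes=("u",), values=series[:, None]
        )
        expected = series[0] / 2 + series[1:-1].sum() + series[-1] / 2
        assert regulatory_score(traj)["u"] == pytest.approx(expected)

    def test_absent_genes_score_zero_in_table(self, small_dataset):
        from lmgrn.pipeline import score_all

        ds = small_dataset
        scores = score_all(ds.graph, ds.classes[:1], ds.expression)
        sample = str(ds.expression.samples[0])
        cell_nodes = None  # genes missing from the subgraph must score 0
        from lmgrn.network import filter_expressed as fe
        expr = normalize_expression(ds.expression)
        cell = fe(ds.graph, expr, sample)
        absent = [
            g for g in ds.graph.nodes_with_role("TF")
            if g not in cell.retained_vertices
        ]
        sub = scores[(scores["sample"] == sample)
                     & (scores["gene"].isin(absent))]
        if len(sub):
            assert (sub["score"] == 0.0).all()
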