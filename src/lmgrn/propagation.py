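"""Reverse signal propagation from LM enzymes through the regulatory network.

Starting scores are placed on the enzymes of one LM class (their topological
weights w(e, p)) and propagated *backwards* through the cell-type-specific
network: a regulator's score at step t+1 collects the scores of its targets
at step t, signed by the edge relation, damped by the product of the two
node degrees (taken in the original, unfiltered network, so that hub genes
are not rewarded for connectivity alone) and scaled by the regulator's
normalized expression:

    s_u(t+1) = qhat_u * sum over edges (u, r, v) of  r * s_v(t) / (deg(u) * deg(v))

Class enzymes are constant sources (clamped at their initial weight); nodes
without an expression measurement — metabolites, products, phenotypes, or
genes absent from the data — relay with an expression factor of 1 rather
than silently absorbing the signal.  The regulatory score s-bar of a node is
the area under its trajectory over 100 steps (trapezoidal rule), measuring
its topological association with the LM class.

The update is linear in the scores, which makes an independent dense
matrix-iteration oracle possible; the implementation here builds the sparse
update operator once per cell subgraph and iterates it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .lipid_classes import LMClassSpec
from .network import CellSubgraph, SignedGraph

__all__ = [
    "ScoreTrajectory",
    "PropagationModel",
    "propagate_step",
    "run_propagation",
    "regulatory_score",
    "score_table",
    "DEFAULT_STEPS",
]

#: number of signaling steps
DEFAULT_STEPS = 100


@dataclass
class ScoreTrajectory:
    """Per-vertex score trajectories s_u(t), t = 0..T."""

    nodes: tuple[str, ...]
    values: np.ndarray  # shape (T+1, n_nodes)

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.nodes):
            raise ValueError("trajectory shape does not match node list")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite value in trajectory")

    @property
    def steps(self) -> int:
        return self.values.shape[0] - 1

    def series(self, node: str) -> np.ndarray:
        return self.values[:, self.nodes.index(node)]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.nodes))


class PropagationModel:
    """Linear propagation operator for one cell subgraph.

    Precomputes the sparse matrix A with
    ``A[u, v] = factor(u) * r(u, v) / (deg(u) * deg(v))`` for retained edges
    (u, r, v), where ``factor(u)`` is the node's normalized expression or 1
    for unmeasured nodes.  Degrees come from the original unfiltered graph
    (each signed triple counted once); parallel edges of opposite sign
    between the same pair cancel in the sum, as the update prescribes.
    """

    def __init__(
        self,
        cell: CellSubgraph,
        qhat: Mapping[str, float],
        signed: bool = True,
    ) -> None:
        from scipy import sparse

        g = cell.graph
        parent = cell.parent
        self.cell = cell
        self.nodes: tuple[str, ...] = tuple(sorted(g.vertices))
        index = {n: i for i, n in enumerate(self.nodes)}
        self._index = index

        measured_roles = ("TF", "gene", "enzyme")
        factors = np.ones(len(self.nodes))
        for n, i in index.items():
            if g.role(n) in measured_roles and n in qhat:
                q = float(qhat[n])
                if not 0.0 <= q <= 1.0:
                    raise ValueError(
                        f"normalized expression of {n!r} outside [0, 1]: {q}"
                    )
                factors[i] = q
        self.factors = factors

        rows, cols, vals = [], [], []
        for u, r, v in g.edges:
            du = parent.degree(u)
            dv = parent.degree(v)
            if du == 0 or dv == 0:
                raise RuntimeError(
                    "zero degree on a node with edges; inconsistent parent graph"
                )
            weight = (r if signed else 1) / (du * dv)
            rows.append(index[u])
            cols.append(index[v])
            vals.append(weight * factors[index[u]])
        self.matrix = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.nodes), len(self.nodes))
        )

    def initial_state(
        self, lm_class: LMClassSpec, weights: Mapping[str, float]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Starting scores and the boolean source mask for one LM class."""
        s0 = np.zeros(len(self.nodes))
        sources = np.zeros(len(self.nodes), dtype=bool)
        for e in lm_class.enzymes:
            i = self._index.get(e)
            if i is not None:
                s0[i] = float(weights.get(e, 0.0))
                sources[i] = True
        return s0, sources

    def step(
        self, state: np.ndarray, s0: np.ndarray, sources: np.ndarray
    ) -> np.ndarray:
        nxt = self.matrix @ state
        nxt[sources] = s0[sources]  # enzymes are constant sources
        return nxt


def propagate_step(
    cell: CellSubgraph,
    scores: Mapping[str, float],
    qhat: Mapping[str, float],
    source_scores: Mapping[str, float] | None = None,
    signed: bool = True,
) -> dict[str, float]:
    """One propagation step on explicit score maps.

    ``source_scores`` holds the clamped enzyme sources (vertex -> s(0));
    omitted sources mean every vertex updates freely.  Mostly useful for
    inspecting single steps; :func:`run_propagation` iterates the
    precomputed operator instead.
    """
    model = PropagationModel(cell, qhat, signed=signed)
    state = np.array([scores.get(n, 0.0) for n in model.nodes])
    nxt = model.matrix @ state
    result = dict(zip(model.nodes, nxt))
    if source_scores:
        for n, v in source_scores.items():
            if n in result:
                result[n] = float(v)
    return result


def run_propagation(
    cell: CellSubgraph,
    lm_class: LMClassSpec,
    weights: Mapping[str, float],
    qhat: Mapping[str, float],
    steps: int = DEFAULT_STEPS,
    signed: bool = True,
    model: PropagationModel | None = None,
) -> ScoreTrajectory:
    """Full score trajectory for one cell subgraph and one LM class.

    ``weights`` are the topological weights of the class enzymes (the
    initial and clamped source scores).  A prebuilt ``model`` for the same
    cell subgraph may be passed to amortize operator construction across
    classes.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    if model is None:
        model = PropagationModel(cell, qhat, signed=signed)
    s0, sources = model.initial_state(lm_class, weights)
    out = np.empty((steps + 1, len(model.nodes)))
    out[0] = s0
    state = s0
    for t in range(steps):
        state = model.step(state, s0, sources)
        out[t + 1] = state
    if not np.isfinite(out).all():
        raise FloatingPointError("propagation diverged to non-finite values")
    return ScoreTrajectory(nodes=model.nodes, values=out)


def regulatory_score(traj: ScoreTrajectory) -> dict[str, float]:
    """AUC of each trajectory over the signaling steps (trapezoidal rule)."""
    if not np.isfinite(traj.values).all():
        raise FloatingPointError("non-finite value in trajectory")
    auc = np.trapezoid(traj.values, dx=1.0, axis=0)
    return dict(zip(traj.nodes, auc))


def score_table(
    per_sample_scores: Mapping[str, Mapping[str, Mapping[str, float]]],
) -> pd.DataFrame:
    """Long-format score table from nested sample -> class -> gene scores."""
    records = [
        (sample, gene, cls, score)
        for sample, by_class in per_sample_scores.items()
        for cls, by_gene in by_class.items()
        for gene, score in by_gene.items()
    ]
    return pd.DataFrame(records, columns=["sample", "gene", "class", "score"])
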