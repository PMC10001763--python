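"""Shared fixtures: tiny hand-built networks and a small synthetic study."""

import numpy as np
import pandas as pd
import pytest

from lmgrn import (
    CatalyticReaction,
    ExpressionMatrix,
    LMClassSpec,
    SignedGraph,
    make_dataset,
    transform_catalysis,
)
from lmgrn.synthetic import SyntheticParams

#: reduced cohort for fast unit tests; the default parameters define the
#: full study conditions exercised in the acceptance suite
SMALL_PARAMS = SyntheticParams(
    n_classes=3, n_enzymes=8, n_tfs=20, n_clusters=2, cells_per_cluster=8
)


@pytest.fixture(scope="session")
def small_dataset():
    return make_dataset(SMALL_PARAMS, seed=0)


@pytest.fixture
def chain_graph():
    """AA -> E1 -> M -> E2 -> P with one TF regulating E1."""
    g = transform_catalysis(
        [CatalyticReaction("AA", "E1", "M"), CatalyticReaction("M", "E2", "P")]
    )
    g.add_node("P", "metabolite")  # no-op role confirmation
    g.add_node("TF1", "TF")
    g.add_edge("TF1", +1, "E1")
    return g


@pytest.fixture
def chain_class():
    return LMClassSpec(
        name="chain", precursor="AA", products=("P",),
        enzymes=("E1", "E2"), intermediates=("M",),
    )


@pytest.fixture
def chain_expression():
    counts = pd.DataFrame(
        {"s1": [50.0, 50.0, 30.0], "s2": [50.0, 0.0, 5.0]},
        index=["E1", "E2", "TF1"],
    )
    return ExpressionMatrix(counts=counts)


def random_signed_graph(rng, n_nodes=8, edge_prob=0.35, neg_prob=0.3,
                        roles=("TF", "gene")):
    """Random signed directed graph for oracle comparisons."""
    g = SignedGraph()
    names = [f"n{i}" for i in range(n_nodes)]
    for i, name in enumerate(names):
        g.add_node(name, roles[i % len(roles)])
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j and rng.random() < edge_prob:
                sign = -1 if rng.random() < neg_prob else 1
                g.add_edge(names[i], sign, names[j])
    return g


def random_dag_submap(rng, n_nodes=10):
    """Random acyclic biosynthesis-like submap plus its class spec.

    Node 0 is the precursor, the last node the product; enzymes and
    metabolites alternate in between, edges only go forward.
    """
    names = [f"v{i}" for i in range(n_nodes)]
    g = SignedGraph()
    g.add_node(names[0], "metabolite")
    g.add_node(names[-1], "product")
    enzymes = []
    for i in range(1, n_nodes - 1):
        role = "enzyme" if i % 2 == 1 else "metabolite"
        g.add_node(names[i], role)
        if role == "enzyme":
            enzymes.append(names[i])
    for i in range(n_nodes - 1):
        # guarantee connectivity along the spine, add extra forward edges
        g.add_edge(names[i], +1, names[i + 1])
        for j in range(i + 2, n_nodes):
            if rng.random() < 0.25:
                sign = -1 if rng.random() < 0.15 else 1
                g.add_edge(names[i], sign, names[j])
    spec = LMClassSpec(
        name="dagclass", precursor=names[0], products=(names[-1],),
        enzymes=tuple(enzymes) or (names[1],),
        intermediates=tuple(
            n for n in names[1:-1] if n not in enzymes
        ),
    )
    return g, spec
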