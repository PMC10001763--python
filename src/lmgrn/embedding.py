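"""Dimensionality reduction, cell clustering and divergent-pair ranking.

Cells are embedded into two dimensions with UMAP, either from expression
features or from per-LM-class regulatory scores; per-class embeddings can be
concatenated and re-embedded into a single combined map.  Clusters are found
with k-means on the 2-D coordinates, with k chosen by the analyst (the
"manual adjustment" step).  Divergent pairs — cells that look alike in
expression but are regulated differently — are ranked by the gap between
their percentile-ranked distances in the two embeddings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import rankdata
from sklearn.cluster import KMeans

__all__ = [
    "Embedding2D",
    "ClusterAssignment",
    "embed_features",
    "combine_class_embeddings",
    "cluster_embedding",
    "rank_divergent_pairs",
    "UMAP_DEFAULTS",
]

#: UMAP hyperparameters (recorded in provenance)
UMAP_DEFAULTS = {"n_neighbors": 15, "min_dist": 0.1, "metric": "euclidean"}


@dataclass
class Embedding2D:
    """2-D coordinates per sample plus provenance."""

    coords: pd.DataFrame  # index: sample ids; columns: x, y
    feature_set: str = ""
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.coords.columns) != ["x", "y"]:
            raise ValueError("coords must have columns x, y")
        if not np.isfinite(self.coords.to_numpy()).all():
            raise ValueError("non-finite embedding coordinates")

    @property
    def samples(self) -> pd.Index:
        return self.coords.index


@dataclass
class ClusterAssignment:
    """k-means labels per sample; cluster ids contiguous from 0."""

    labels: pd.Series
    k: int
    inertia: float

    def __post_init__(self) -> None:
        ids = sorted(self.labels.unique())
        if ids != list(range(len(ids))):
            raise ValueError("cluster ids must be contiguous from 0")


def _umap_embed(matrix: np.ndarray, seed: int, params: dict) -> np.ndarray:
    import umap  # deferred: numba compilation is slow at import

    n = matrix.shape[0]
    n_neighbors = min(params["n_neighbors"], max(2, n - 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns about forced n_jobs=1
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=params["min_dist"],
            metric=params["metric"],
            random_state=seed,
            n_jobs=1,
        )
        return reducer.fit_transform(matrix)


def embed_features(
    features: pd.DataFrame, seed: int = 0, feature_set: str = "", **overrides
) -> Embedding2D:
    """UMAP embedding of a samples x features matrix.

    Deterministic for a fixed seed (UMAP is forced single-threaded).  Exact
    duplicate rows are collapsed before embedding and share the coordinates
    of their representative, so identical cells always land on the same
    point.
    """
    if features.shape[0] < 3:
        raise ValueError("need at least 3 samples to embed")
    mat = features.to_numpy(dtype=float)
    if not np.isfinite(mat).all():
        raise ValueError("non-finite feature values")
    params = {**UMAP_DEFAULTS, **overrides}

    uniq, inverse = np.unique(mat, axis=0, return_inverse=True)
    if uniq.shape[0] >= 3:
        emb_uniq = _umap_embed(uniq, seed, params)
        emb = emb_uniq[inverse]
    else:
        # fewer than 3 distinct rows: no geometry to learn, place the
        # distinct rows apart deterministically
        emb = np.column_stack([inverse.astype(float), np.zeros(len(inverse))])
    coords = pd.DataFrame(emb, index=features.index, columns=["x", "y"])
    return Embedding2D(
        coords=coords, feature_set=feature_set, seed=seed, params=params
    )


def combine_class_embeddings(
    embeddings: Sequence[Embedding2D], seed: int = 0, **overrides
) -> Embedding2D:
    """Concatenate per-class 2-D embeddings and embed the result again.

    All inputs must cover the same samples; the intermediate matrix has
    2 * n_classes columns.
    """
    if not embeddings:
        raise ValueError("no embeddings to combine")
    base = embeddings[0].samples
    for e in embeddings[1:]:
        if not base.equals(e.samples):
            raise ValueError("embeddings cover different samples")
    blocks = []
    for i, e in enumerate(embeddings):
        block = e.coords.copy()
        tag = e.feature_set or str(i)
        block.columns = [f"{tag}_x", f"{tag}_y"]
        blocks.append(block)
    combined = pd.concat(blocks, axis=1)
    out = embed_features(combined, seed=seed, feature_set="combined", **overrides)
    return out


def cluster_embedding(
    emb: Embedding2D, k: int, seed: int = 0, n_init: int = 10
) -> ClusterAssignment:
    """k-means on the 2-D coordinates with a user-chosen k."""
    n = len(emb.samples)
    if not 2 <= k <= n:
        raise ValueError(f"k must satisfy 2 <= k <= n samples ({n}), got {k}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(emb.coords.to_numpy())
    # relabel by first occurrence for a stable, contiguous numbering
    relabel: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in relabel:
            relabel[lab] = len(relabel)
        labels[i] = relabel[lab]
    return ClusterAssignment(
        labels=pd.Series(labels, index=emb.samples, name="cluster"),
        k=k,
        inertia=float(km.inertia_),
    )


def _pair_matrix(rep: "Embedding2D | pd.DataFrame", standardize: bool
                 ) -> tuple[pd.Index, np.ndarray]:
    frame = rep.coords if isinstance(rep, Embedding2D) else rep
    mat = frame.to_numpy(dtype=float)
    if standardize:
        sd = mat.std(axis=0)
        sd[sd == 0] = 1.0
        mat = (mat - mat.mean(axis=0)) / sd
    return frame.index, mat


def rank_divergent_pairs(
    expr_rep: "Embedding2D | pd.DataFrame",
    net_rep: "Embedding2D | pd.DataFrame",
    top_n: int = 10,
    standardize: bool = True,
) -> pd.DataFrame:
    """Cell pairs close in expression space but distant in regulation space.

    Each representation is either a 2-D embedding or a samples x features
    matrix (feature matrices are the default in the pipeline: low-dimensional
    UMAP coordinates preserve neighborhoods, not the large distances that
    characterize a rewired outlier).  Features are z-scored per column
    unless ``standardize`` is off.  For every unordered sample pair the
    Euclidean distance is computed in each representation and converted to
    a percentile rank within it (average ranks for ties, scaled to (0, 1]);
    the divergence score is rank in the network representation minus rank
    in the expression representation.  The top ``top_n`` pairs by
    descending score are returned, ties broken lexicographically on the
    pair ids.
    """
    idx_expr, mat_expr = _pair_matrix(expr_rep, standardize)
    idx_net, mat_net = _pair_matrix(net_rep, standardize)
    if not idx_expr.equals(idx_net):
        raise ValueError("representations cover different samples")
    samples = list(idx_expr)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    d_expr = pdist(mat_expr)
    d_net = pdist(mat_net)
    m = len(d_expr)
    r_expr = rankdata(d_expr) / m
    r_net = rankdata(d_net) / m
    score = r_net - r_expr

    pairs = [
        tuple(sorted((samples[i], samples[j])))
        for i in range(len(samples))
        for j in range(i + 1, len(samples))
    ]
    table = pd.DataFrame(
        {
            "sample_a": [p[0] for p in pairs],
            "sample_b": [p[1] for p in pairs],
            "dist_expression": d_expr,
            "dist_network": d_net,
            "score": score,
        }
    )
    table = table.sort_values(
        ["score", "sample_a", "sample_b"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return table.head(top_n)
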