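"""End-to-end orchestration: from network + counts to scores, clusters,
statistics, divergent pairs and core regulatory networks.

Every stage is a pure function of its inputs and the configured seed, so a
re-run with identical config produces byte-identical output files.  A single
global seed fans out to per-stage seeds through ``numpy.random.SeedSequence``
so stages stay independent yet reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as lm_io
from .capability import capability_matrix
from .embedding import (
    Embedding2D,
    cluster_embedding,
    combine_class_embeddings,
    embed_features,
    rank_divergent_pairs,
)
from .expression import ExpressionMatrix, normalize_expression
from .lipid_classes import LMClassSpec
from .network import EXPRESSION_THRESHOLD, SignedGraph, filter_expressed
from .propagation import DEFAULT_STEPS, PropagationModel, regulatory_score, run_propagation
from .stats import cluster_test_table, rank_delta_tfs, significant_cluster_genes
from .topology import class_weights, extract_crn

__all__ = [
    "PipelineConfig",
    "stage_seeds",
    "score_all",
    "embed_all",
    "divergence_features",
    "delta_ranking_table",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


def stage_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent per-stage seeds (< 2**31) from one seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


@dataclass
class PipelineConfig:
    """Run-wide knobs; validated before any stage executes."""

    threshold: float = EXPRESSION_THRESHOLD
    steps: int = DEFAULT_STEPS
    signed_propagation: bool = True
    seed: int = 0
    k: int = 3  # clusters for k-means, chosen by the analyst
    alpha: float = 0.05
    delta_top_k: int = 3
    delta_by_magnitude: bool = False
    top_divergent: int = 10
    umap: dict = field(default_factory=dict)  # overrides for UMAP params
    crn_samples: Sequence[str] = ()  # samples to export CRNs for
    crn_classes: Sequence[str] = ()  # classes to export CRNs for ((), first)
    delta_groups: tuple[Sequence[str], Sequence[str]] | None = None

    def validate(self, expr: ExpressionMatrix, classes: Sequence[LMClassSpec]) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        if self.steps < 0:
            raise ValueError("steps must be non-negative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        n = len(expr.samples)
        if not 2 <= self.k < n:
            raise ValueError(f"k={self.k} out of range for {n} samples")
        names = {c.name for c in classes}
        unknown = set(self.crn_classes) - names
        if unknown:
            raise ValueError(f"unknown class name(s): {sorted(unknown)}")
        missing = set(self.crn_samples) - set(expr.samples)
        if missing:
            raise ValueError(f"unknown sample(s): {sorted(missing)}")


def score_all(
    graph: SignedGraph,
    classes: Sequence[LMClassSpec],
    expr: ExpressionMatrix,
    threshold: float = EXPRESSION_THRESHOLD,
    steps: int = DEFAULT_STEPS,
    signed: bool = True,
    graph_overrides: Mapping[str, SignedGraph] | None = None,
) -> pd.DataFrame:
    """Regulatory score table over all samples, genes and LM classes.

    For each sample the expression-filtered subgraph is built, the linear
    propagation operator assembled once, and every class propagated on it;
    scores integrate the trajectories over the signaling steps.  Genes
    absent from a sample's subgraph score 0.  ``graph_overrides`` maps
    sample ids to alternative networks (used for rewired variants).
    """
    expr = normalize_expression(expr)
    overrides = dict(graph_overrides or {})
    weight_cache: dict[int, dict[str, dict[str, float]]] = {}

    def weights_for(g: SignedGraph) -> dict[str, dict[str, float]]:
        key = id(g)
        if key not in weight_cache:
            weight_cache[key] = {c.name: class_weights(g, c) for c in classes}
        return weight_cache[key]

    scored_roles = ("TF", "gene")
    universe = sorted(
        n for n, r in graph.node_roles.items() if r in scored_roles
    )
    records: list[tuple[str, str, str, float]] = []
    for sample in expr.samples:
        g = overrides.get(sample, graph)
        cell = filter_expressed(g, expr, sample, threshold=threshold)
        qhat = expr.sample_normalized(sample)
        model = PropagationModel(cell, qhat, signed=signed)
        w_by_class = weights_for(g)
        for cls in classes:
            traj = run_propagation(
                cell, cls, w_by_class[cls.name], qhat,
                steps=steps, signed=signed, model=model,
            )
            sbar = regulatory_score(traj)
            for gene in universe:
                records.append((sample, gene, cls.name, sbar.get(gene, 0.0)))
    return pd.DataFrame(records, columns=["sample", "gene", "class", "score"])


def divergence_features(
    scores: pd.DataFrame, expr: ExpressionMatrix
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression and regulation feature matrices for divergent-pair ranking.

    Expression features are the max-normalized counts; regulation features
    are the per-(class, gene) regulatory scores.  Both are samples x
    features, aligned on the same sample order.
    """
    expr = normalize_expression(expr)
    expr_features = expr.normalized.T.sort_index()
    net_features = scores.pivot_table(
        index="sample", columns=["class", "gene"], values="score",
        fill_value=0.0,
    ).loc[expr_features.index]
    return expr_features, net_features


def _class_feature_matrix(scores: pd.DataFrame, cls_name: str) -> pd.DataFrame:
    sub = scores[scores["class"] == cls_name]
    wide = sub.pivot_table(index="sample", columns="gene", values="score",
                           fill_value=0.0)
    return wide.sort_index()


def embed_all(
    scores: pd.DataFrame,
    expr: ExpressionMatrix,
    classes: Sequence[LMClassSpec],
    seed: int = 0,
    umap_overrides: dict | None = None,
) -> tuple[Embedding2D, dict[str, Embedding2D], Embedding2D]:
    """Expression embedding, per-class score embeddings, combined embedding."""
    overrides = umap_overrides or {}
    seeds = stage_seeds(seed, len(classes) + 2)
    expr = normalize_expression(expr)
    expr_features = expr.normalized.T.sort_index()
    expr_emb = embed_features(
        expr_features, seed=seeds[0], feature_set="expression", **overrides
    )
    per_class: dict[str, Embedding2D] = {}
    for i, cls in enumerate(classes):
        feats = _class_feature_matrix(scores, cls.name)
        per_class[cls.name] = embed_features(
            feats, seed=seeds[i + 1], feature_set=cls.name, **overrides
        )
    combined = combine_class_embeddings(
        list(per_class.values()), seed=seeds[-1], **overrides
    )
    return expr_emb, per_class, combined


def delta_ranking_table(
    scores: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    classes: Sequence[LMClassSpec],
    k: int = 3,
    by_magnitude: bool = False,
) -> pd.DataFrame:
    """Top-k regulators by mean score change from group A to group B."""
    rows = []
    for cls in classes:
        sub = scores[scores["class"] == cls.name]
        wide = sub.pivot_table(index="gene", columns="sample", values="score",
                               fill_value=0.0)
        mean_a = wide.reindex(columns=list(group_a)).mean(axis=1)
        mean_b = wide.reindex(columns=list(group_b)).mean(axis=1)
        ranking = rank_delta_tfs(
            mean_a, mean_b, lm_class=cls.name, k=k, by_magnitude=by_magnitude
        )
        for rank, (_, row) in enumerate(ranking.ranking.head(k).iterrows(), 1):
            rows.append((cls.name, rank, row["gene"], row["delta"]))
    return pd.DataFrame(rows, columns=["class", "rank", "gene", "delta"])


def run_pipeline(
    graph: SignedGraph,
    classes: Sequence[LMClassSpec],
    expr: ExpressionMatrix,
    config: PipelineConfig,
    outdir: str | Path,
    clusters_override: pd.Series | None = None,
    graph_overrides: Mapping[str, SignedGraph] | None = None,
) -> dict[str, Path]:
    """Run every stage and write the output bundle to ``outdir``.

    Returns a name -> path map of the written artifacts.  When
    ``clusters_override`` is given (sample -> cluster id) it replaces the
    k-means assignment in the statistics stage.
    """
    config.validate(expr, classes)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    t0 = time.perf_counter()

    def _stage(name: str) -> None:
        logger.info("stage %-12s done at %.1fs", name, time.perf_counter() - t0)

    cfg_path = outdir / "config.json"
    cfg = asdict(config)
    cfg["delta_groups"] = (
        [list(g) for g in config.delta_groups] if config.delta_groups else None
    )
    cfg_path.write_text(json.dumps(cfg, indent=2, sort_keys=True, default=list))
    artifacts["config"] = cfg_path

    expr = normalize_expression(expr)

    cap = capability_matrix(graph, expr, list(classes), threshold=config.threshold)
    cap_path = outdir / "capability.tsv"
    cap.astype(int).to_csv(cap_path, sep="\t")
    artifacts["capability"] = cap_path
    _stage("capability")

    scores = score_all(
        graph, classes, expr,
        threshold=config.threshold, steps=config.steps,
        signed=config.signed_propagation, graph_overrides=graph_overrides,
    )
    scores_path = outdir / "scores.tsv"
    lm_io.write_score_table(scores, scores_path)
    artifacts["scores"] = scores_path
    _stage("scores")

    expr_emb, per_class, combined = embed_all(
        scores, expr, classes, seed=config.seed, umap_overrides=config.umap
    )
    emb_rows = []
    for emb in [expr_emb, *per_class.values(), combined]:
        for sample, row in emb.coords.iterrows():
            emb_rows.append((sample, emb.feature_set, row["x"], row["y"], emb.seed))
    emb_path = outdir / "embeddings.tsv"
    pd.DataFrame(
        emb_rows, columns=["sample", "feature_set", "x", "y", "seed"]
    ).to_csv(emb_path, sep="\t", index=False)
    artifacts["embeddings"] = emb_path
    _stage("embeddings")

    if clusters_override is not None:
        clusters = clusters_override
        inertia = float("nan")
    else:
        assignment = cluster_embedding(
            combined, k=config.k, seed=stage_seeds(config.seed, 1)[0]
        )
        clusters = assignment.labels
        inertia = assignment.inertia
    clus_path = outdir / "clusters.tsv"
    clusters.rename("cluster").to_frame().assign(inertia=inertia).to_csv(
        clus_path, sep="\t"
    )
    artifacts["clusters"] = clus_path
    _stage("clusters")

    qhat = expr.normalized if expr.normalized is not None else None
    tests = cluster_test_table(qhat, scores, clusters)
    tests_path = outdir / "cluster_tests.tsv"
    tests.to_csv(tests_path, sep="\t", index=False)
    artifacts["cluster_tests"] = tests_path

    sig = significant_cluster_genes(tests, alpha=config.alpha)
    sig_path = outdir / "significant_genes.tsv"
    sig.to_csv(sig_path, sep="\t", index=False)
    artifacts["significant_genes"] = sig_path
    _stage("statistics")

    if config.delta_groups is not None:
        group_a, group_b = config.delta_groups
    else:
        ordered = sorted(clusters.unique())
        group_a = list(clusters[clusters == ordered[0]].index)
        group_b = list(clusters[clusters == ordered[-1]].index)
    delta = delta_ranking_table(
        scores, group_a, group_b, classes,
        k=config.delta_top_k, by_magnitude=config.delta_by_magnitude,
    )
    delta_path = outdir / "delta_ranking.tsv"
    delta.to_csv(delta_path, sep="\t", index=False)
    artifacts["delta_ranking"] = delta_path
    _stage("delta")

    # divergence is ranked on the feature matrices, not the 2-D maps
    expr_features, net_features = divergence_features(scores, expr)
    pairs = rank_divergent_pairs(
        expr_features, net_features, top_n=config.top_divergent
    )
    pairs_path = outdir / "divergent_pairs.tsv"
    pairs.to_csv(pairs_path, sep="\t", index=False)
    artifacts["divergent_pairs"] = pairs_path
    _stage("pairs")

    crn_samples = list(config.crn_samples) or [str(expr.samples[0])]
    crn_classes = list(config.crn_classes) or [classes[0].name]
    by_name = {c.name: c for c in classes}
    for sample in crn_samples:
        g = (graph_overrides or {}).get(sample, graph)
        cell = filter_expressed(g, expr, sample, threshold=config.threshold)
        qhat_col = expr.sample_normalized(sample)
        counts_col = expr.sample_counts(sample)
        for cname in crn_classes:
            sub = scores[(scores["sample"] == sample) & (scores["class"] == cname)]
            sbar = dict(zip(sub["gene"], sub["score"]))
            crn = extract_crn(cell, sbar, by_name[cname], mode="single")
            path = outdir / f"crn_{sample}_{cname}.graphml"
            flags = {
                n: bool(counts_col.get(n, np.inf) < config.threshold)
                for n in crn.graph.vertices
            }
            lm_io.export_crn_graphml(
                crn, path, qhat=qhat_col.to_dict(), threshold_flags=flags
            )
            artifacts[f"crn_{sample}_{cname}"] = path
    _stage("crn")
    return artifacts
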