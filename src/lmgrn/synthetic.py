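"""Synthetic signed GRNs and count matrices with planted ground truth.

The generator emulates the structure of the real inputs — curated
biosynthesis submaps per lipid mediator class, a transcription-factor layer
with signed edges, and overdispersed read-count matrices over clustered cell
populations — while recording everything it plants:

* per-cluster regulators: one TF per cluster wired to the enzymes of its
  affected classes and overexpressed (together with those targets) in its
  cluster by a configurable effect size;
* per-cluster synthesis capabilities: capable (cluster, class) combinations
  get a fully expressed enzyme route, withheld ones get a sub-threshold
  gating enzyme (the private first enzyme of the class, so no route
  survives);
* one divergent pair: an extra cell duplicating another cell's expression
  exactly, but scored against a network variant whose TF->enzyme edges have
  been removed — same transcriptome, rewired regulation.

Counts follow a negative-binomial model with log-normal baseline means and
quadratic overdispersion (variance = m + phi * m^2); phi = 0 degenerates to
Poisson.  Everything is a pure function of the parameters and the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .lipid_classes import CANONICAL_CLASSES, LMClassSpec
from .network import EXPRESSION_THRESHOLD, SignedGraph

__all__ = [
    "SyntheticParams",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_grn",
    "generate_expression",
    "make_dataset",
    "null_feature_table",
]


@dataclass(frozen=True)
class SyntheticParams:
    """Generator knobs; the defaults define the standard study cohort."""

    n_classes: int = 8
    n_enzymes: int = 30
    n_tfs: int = 120
    n_clusters: int = 3
    cells_per_cluster: int = 30
    effect_size: float = 5.0
    dispersion: float = 0.1  # phi in var = m + phi m^2; 0 -> Poisson
    cluster_program_frac: float = 0.4  # genes in each cluster's program
    cluster_program_sd: float = 1.2  # log-scale effect of program genes
    divergent_program_frac: float = 0.3  # private signature of the pair
    divergent_program_sd: float = 1.0
    neg_edge_prob: float = 0.25
    tf_tf_prob: float = 0.3
    branch_prob: float = 0.5
    baseline_log_mean: float = 3.5
    baseline_log_sd: float = 1.0
    classes_per_regulator: int = 2
    with_divergent_pair: bool = True

    def __post_init__(self) -> None:
        if self.n_enzymes < self.n_classes:
            raise ValueError(
                "need at least one enzyme per class "
                f"({self.n_enzymes} enzymes for {self.n_classes} classes)"
            )
        if self.n_classes < 1:
            raise ValueError("need at least one class")
        if self.n_classes > len(CANONICAL_CLASSES):
            raise ValueError(
                f"at most {len(CANONICAL_CLASSES)} classes are defined"
            )
        if self.n_tfs < self.n_clusters:
            raise ValueError("need at least one TF per cluster")


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for end-to-end verification."""

    params: SyntheticParams
    seed: int
    planted_regulators: dict[int, dict]  # cluster -> {tf, classes}
    planted_capabilities: dict[int, list[str]]  # cluster -> capable classes
    capable_routes: dict[str, list[str]]  # "cluster/class" -> route enzymes
    divergent_pair: tuple[str, str] | None
    cluster_of: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        d = {
            "params": asdict(self.params),
            "seed": self.seed,
            "planted_regulators": {
                str(k): v for k, v in self.planted_regulators.items()
            },
            "planted_capabilities": {
                str(k): v for k, v in self.planted_capabilities.items()
            },
            "capable_routes": self.capable_routes,
            "divergent_pair": list(self.divergent_pair)
            if self.divergent_pair
            else None,
            "cluster_of": self.cluster_of,
        }
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class SyntheticDataset:
    """A complete synthetic study: networks, classes, counts, truth."""

    graph: SignedGraph
    variant_graph: SignedGraph | None
    classes: list[LMClassSpec]
    expression: ExpressionMatrix
    truth: SyntheticTruth

    def graph_for(self, sample: str) -> SignedGraph:
        """The network a given sample is scored against."""
        if (
            self.variant_graph is not None
            and self.truth.divergent_pair is not None
            and sample == self.truth.divergent_pair[1]
        ):
            return self.variant_graph
        return self.graph


def _enzyme_name(i: int) -> str:
    return f"Enz{i + 1:02d}"


def _tf_name(i: int) -> str:
    return f"TF{i + 1:03d}"


def generate_grn(
    params: SyntheticParams, rng: np.random.Generator
) -> tuple[SignedGraph, list[LMClassSpec], dict[int, dict]]:
    """Build the signed network, class specs and planted regulator wiring.

    Each class submap is an acyclic precursor -> enzymes -> product cascade:
    either a three-enzyme chain or a two-branch fork after the first enzyme.
    The first enzyme of every class is private to it, so silencing it
    severs every route of exactly that class.  The TF layer adds signed
    TF->enzyme and TF->TF edges; one TF per cluster is planted as a
    regulator of a couple of classes and wired to all their enzymes.
    """
    class_names = list(CANONICAL_CLASSES)[: params.n_classes]
    enzymes = [_enzyme_name(i) for i in range(params.n_enzymes)]
    private = enzymes[: params.n_classes]  # one gating enzyme per class
    shared = enzymes[params.n_classes:]
    tfs = [_tf_name(i) for i in range(params.n_tfs)]

    g = SignedGraph()
    for p in sorted({CANONICAL_CLASSES[c] for c in class_names}):
        g.add_node(p, "metabolite")
    classes: list[LMClassSpec] = []
    for ci, name in enumerate(class_names):
        precursor = CANONICAL_CLASSES[name]
        e_first = private[ci]
        g.add_node(e_first, "enzyme")
        if len(shared) < 2:
            # too few enzymes for deeper cascades: single-enzyme chain
            prod = f"{name}_prod"
            g.add_node(prod, "product")
            g.add_edge(precursor, +1, e_first)
            g.add_edge(e_first, +1, prod)
            classes.append(LMClassSpec(
                name=name, precursor=precursor, products=(prod,),
                enzymes=(e_first,), intermediates=(),
            ))
            continue
        m1 = f"{name}_m1"
        g.add_node(m1, "metabolite")
        g.add_edge(precursor, +1, e_first)
        g.add_edge(e_first, +1, m1)
        branch = rng.random() < params.branch_prob
        if branch:
            e_a, e_b = rng.choice(len(shared), size=2, replace=False)
            e_a, e_b = shared[e_a], shared[e_b]
            prod_a, prod_b = f"{name}_prod_a", f"{name}_prod_b"
            for enz, prod in ((e_a, prod_a), (e_b, prod_b)):
                g.add_node(enz, "enzyme")
                g.add_node(prod, "product")
                g.add_edge(m1, +1, enz)
                g.add_edge(enz, +1, prod)
            spec = LMClassSpec(
                name=name,
                precursor=precursor,
                products=(prod_a, prod_b),
                enzymes=(e_first, e_a, e_b),
                intermediates=(m1,),
            )
        else:
            e2, e3 = rng.choice(len(shared), size=2, replace=False)
            e2, e3 = shared[e2], shared[e3]
            m2 = f"{name}_m2"
            prod = f"{name}_prod"
            for node, role in ((e2, "enzyme"), (m2, "metabolite"),
                               (e3, "enzyme"), (prod, "product")):
                g.add_node(node, role)
            g.add_edge(m1, +1, e2)
            g.add_edge(e2, +1, m2)
            g.add_edge(m2, +1, e3)
            g.add_edge(e3, +1, prod)
            spec = LMClassSpec(
                name=name,
                precursor=precursor,
                products=(prod,),
                enzymes=(e_first, e2, e3),
                intermediates=(m1, m2),
            )
        classes.append(spec)

    used_enzymes = sorted({e for c in classes for e in c.enzymes})
    for tf in tfs:
        g.add_node(tf, "TF")
    # TF -> enzyme edges
    for tf in tfs:
        n_targets = min(int(rng.integers(1, 4)), len(used_enzymes))
        idx = rng.choice(len(used_enzymes), size=n_targets, replace=False)
        for i in idx:
            sign = -1 if rng.random() < params.neg_edge_prob else +1
            g.add_edge(tf, sign, used_enzymes[i])
    # sparse TF -> TF layer
    for ti, tf in enumerate(tfs):
        if rng.random() < params.tf_tf_prob and params.n_tfs > 1:
            tj = int(rng.integers(0, params.n_tfs - 1))
            if tj >= ti:
                tj += 1
            sign = -1 if rng.random() < params.neg_edge_prob else +1
            g.add_edge(tf, sign, tfs[tj])

    # planted regulators: per cluster a two-level cascade
    # regulator TF -> mediator TFs -> every enzyme of the affected classes.
    # The mediators are overexpressed in the cluster, so the regulator's
    # propagated score rises there independently of its own expression —
    # the kind of topology-driven activity change the cluster statistic is
    # built to detect.
    planted: dict[int, dict] = {}
    n_med = min(3, max(0, (params.n_tfs - params.n_clusters) // params.n_clusters))
    picks = rng.choice(
        params.n_tfs, size=params.n_clusters * (1 + n_med), replace=False
    )
    for k in range(params.n_clusters):
        chunk = picks[k * (1 + n_med): (k + 1) * (1 + n_med)]
        tf = tfs[chunk[0]]
        mediators = [tfs[i] for i in chunk[1:]]
        n_aff = min(params.classes_per_regulator, params.n_classes)
        aff_idx = rng.choice(params.n_classes, size=n_aff, replace=False)
        affected = [class_names[i] for i in sorted(aff_idx)]
        for cname in affected:
            spec = next(c for c in classes if c.name == cname)
            if mediators:
                for med in mediators:
                    g.add_edge(tf, +1, med)
                    for enz in spec.enzymes:
                        g.add_edge(med, +1, enz)
            else:
                # too few TFs for a cascade: wire the regulator directly
                for enz in spec.enzymes:
                    g.add_edge(tf, +1, enz)
        planted[k] = {"tf": tf, "mediators": mediators, "classes": affected}
    return g, classes, planted


def _default_capabilities(
    class_names: list[str], n_clusters: int
) -> dict[int, list[str]]:
    """Myeloid-like / partial / lymphoid-like capability pattern.

    Cluster 0 synthesizes every class, the last cluster none, clusters in
    between only the arachidonic-acid-derived classes.
    """
    caps: dict[int, list[str]] = {0: list(class_names)}
    for k in range(1, n_clusters):
        if k == n_clusters - 1 and n_clusters > 1:
            caps[k] = []
        else:
            caps[k] = [c for c in class_names if CANONICAL_CLASSES[c] == "AA"]
    return caps


def generate_expression(
    graph: SignedGraph,
    classes: list[LMClassSpec],
    truth: SyntheticTruth,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    """Draw the count matrix implied by the planted truth.

    Negative-binomial counts around per-gene log-normal baselines; cluster
    effects multiply the planted regulator and its target enzymes; enzyme
    counts are floored along capable routes and capped below the expression
    threshold for the gating enzyme of withheld classes, so the planted
    capability matrix holds exactly.
    """
    params = truth.params
    genes = sorted(graph.nodes_with_role("enzyme")) + sorted(
        graph.nodes_with_role("TF")
    )
    samples = [
        f"c{k}_s{i:02d}"
        for k in range(params.n_clusters)
        for i in range(params.cells_per_cluster)
    ]
    cluster_of = {
        s: int(s[1 : s.index("_")]) for s in samples
    }

    base_mean = np.exp(
        rng.normal(params.baseline_log_mean, params.baseline_log_sd, len(genes))
    )
    gene_idx = {gene: i for i, gene in enumerate(genes)}

    means = np.tile(base_mean[:, None], (1, len(samples)))
    # per-cluster expression programs: each cluster scales a random subset
    # of genes by a log-normal factor, giving the matrix the cluster
    # structure real cell-type cohorts show
    for k in range(params.n_clusters):
        cols = [j for j, s in enumerate(samples) if cluster_of[s] == k]
        in_program = rng.random(len(genes)) < params.cluster_program_frac
        factors = np.exp(
            rng.normal(0.0, params.cluster_program_sd, len(genes))
        )
        means[np.ix_(in_program, cols)] *= factors[in_program, None]
    for k, info in truth.planted_regulators.items():
        cols = [j for j, s in enumerate(samples) if cluster_of[s] == k]
        boosted = [info["tf"]] + list(info.get("mediators", ()))
        for gname in set(boosted):
            means[gene_idx[gname], cols] *= params.effect_size

    if truth.divergent_pair is not None:
        # the pair is its own transcriptomic subtype: a private program
        # separates the duplicated cell (and hence its twin) from its
        # cluster siblings, mirroring how distinctive cell pairs — not
        # arbitrary members of a homogeneous cluster — are what the
        # divergence ranking is meant to surface
        src_col = samples.index(truth.divergent_pair[0])
        in_prog = rng.random(len(genes)) < params.divergent_program_frac
        factors = np.exp(
            rng.normal(0.0, params.divergent_program_sd, len(genes))
        )
        means[in_prog, src_col] *= factors[in_prog]

    phi = params.dispersion
    if phi > 0:
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + means))
    else:
        counts = rng.poisson(means)
    counts = counts.astype(float)

    thr = EXPRESSION_THRESHOLD
    class_by_name = {c.name: c for c in classes}
    for k, capable in truth.planted_capabilities.items():
        cols = [j for j, s in enumerate(samples) if cluster_of[s] == k]
        for cname in capable:
            route = truth.capable_routes[f"{k}/{cname}"]
            for enz in route:
                i = gene_idx[enz]
                counts[i, cols] = np.maximum(counts[i, cols], thr)
        for cname in set(class_by_name) - set(capable):
            gate = class_by_name[cname].enzymes[0]  # private first enzyme
            i = gene_idx[gate]
            counts[i, cols] = np.minimum(counts[i, cols], thr - 1.0)

    frame = pd.DataFrame(counts, index=genes, columns=samples)
    if truth.divergent_pair is not None:
        src, dup = truth.divergent_pair
        frame[dup] = frame[src]
        cluster_of[dup] = cluster_of[src]
    truth.cluster_of = cluster_of

    meta = pd.DataFrame(
        {
            "cell_type": [f"cluster{cluster_of[s]}" for s in frame.columns],
            "cluster": [cluster_of[s] for s in frame.columns],
            "tissue": "synthetic",
            "stimulus": "none",
            "time_point": 0,
        },
        index=pd.Index(frame.columns, name="sample"),
    )
    return ExpressionMatrix(counts=frame, metadata=meta)


def make_dataset(
    params: SyntheticParams | None = None, seed: int = 0
) -> SyntheticDataset:
    """Generate a full synthetic study from a single seed."""
    params = params or SyntheticParams()
    root = np.random.SeedSequence(seed)
    grn_rng, expr_rng = (np.random.default_rng(s) for s in root.spawn(2))

    graph, classes, planted = generate_grn(params, grn_rng)
    class_names = [c.name for c in classes]
    capabilities = _default_capabilities(class_names, params.n_clusters)

    # guaranteed route per capable (cluster, class): chain classes need all
    # three enzymes, branched classes the first enzyme plus one branch
    routes: dict[str, list[str]] = {}
    for k, capable in capabilities.items():
        for cname in capable:
            spec = next(c for c in classes if c.name == cname)
            if len(spec.products) == 1:
                routes[f"{k}/{cname}"] = list(spec.enzymes)
            else:
                routes[f"{k}/{cname}"] = [spec.enzymes[0], spec.enzymes[1]]

    divergent = None
    variant = None
    if params.with_divergent_pair:
        divergent = ("c0_s00", "divergent")
        variant = SignedGraph()
        for n, role in graph.node_roles.items():
            variant.add_node(n, role)
        for u, r, v in graph.edges:
            if graph.role(u) == "TF" and graph.role(v) == "enzyme":
                continue  # rewired: regulation decoupled from the enzymes
            variant.add_edge(u, r, v)

    truth = SyntheticTruth(
        params=params,
        seed=seed,
        planted_regulators=planted,
        planted_capabilities=capabilities,
        capable_routes=routes,
        divergent_pair=divergent,
    )
    expression = generate_expression(graph, classes, truth, expr_rng)
    return SyntheticDataset(
        graph=graph,
        variant_graph=variant,
        classes=classes,
        expression=expression,
        truth=truth,
    )


def null_feature_table(
    n_features: int = 1000,
    n_samples: int = 90,
    n_clusters: int = 3,
    seed: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Null-mode feature generator for statistic calibration.

    Every feature follows the same score-vs-expression law in and out of
    the cluster: qhat ~ Beta(2, 2), sbar = a + b*qhat + Gaussian noise,
    with per-feature random intercept, slope and noise scale and no cluster
    effect anywhere.  Returns (qhat, sbar, in_cluster) with qhat and sbar of
    shape (n_features, n_samples); the mask marks the first of
    ``n_clusters`` equal sample blocks.
    """
    rng = np.random.default_rng(seed)
    qhat = rng.beta(2.0, 2.0, size=(n_features, n_samples))
    a = rng.normal(0.0, 1.0, size=(n_features, 1))
    b = rng.normal(0.0, 2.0, size=(n_features, 1))
    sd = np.exp(rng.normal(-1.0, 0.5, size=(n_features, 1)))
    sbar = a + b * qhat + rng.normal(0.0, 1.0, size=qhat.shape) * sd
    in_cluster = np.zeros(n_samples, dtype=bool)
    in_cluster[: n_samples // n_clusters] = True
    return qhat, sbar, in_cluster
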