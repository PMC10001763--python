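# Methods

This note documents the models and procedures implemented in `lmgrn`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Signed networks and cell-type subgraphs

Networks follow the activity-flow formalism: edges are triples
`(source, relation, target)` with relation +1 (activation/upregulation) or
−1 (inhibition/downregulation). Catalytic reactions are rewritten by
placing the enzyme between substrate and product with two positive edges,
so enzyme expression gates every route; no direct substrate→product edge is
kept. Identical triples are deduplicated, while the same ordered pair may
carry both signs as two distinct edges (the triple model permits genuinely
contradictory evidence).

A cell-type subgraph `G_c` removes TF/gene vertices whose read count in the
sample is below the expression threshold (default 10 counts, the boundary
counting as expressed — a deliberate, literal reading of "below the
threshold"). Enzymes of the curated submaps, metabolites, products and
phenotypes are never removed: they either carry no measurement or their
absence would disconnect the biosynthesis scaffold the analysis is about.
TF/gene vertices with no measurement at all are likewise retained; missing
evidence is not treated as absence.

Per-gene max-normalization maps counts to `q̂ ∈ [0, 1]` with every expressed
gene peaking at exactly 1; all-zero genes map to 0 (they are filtered out
of every `G_c` anyway). Ortholog/ID mapping requires unique source ids;
several sources mapping to one target are aggregated by the maximum count
("expressed if any ortholog is expressed" — the conservative choice for a
threshold-based filter).

## Topological enzyme weighting

For an LM class `p` with pooled terminal products, on the acyclic class
submap:

    w(e, p) = sign(SP(e, p)) · (N_paths^e / N_paths + N_nodes^e / N_nodes)

* `N_paths` — simple directed paths from the precursor to any product;
  `N_paths^e` those through `e`. Path counting is restricted to the curated
  submap: the full GRN is cyclic and simple-path counts there are neither
  meaningful nor tractable. Cyclic submaps are refused with an explicit
  error.
* `N_nodes` — vertices with a directed route to any product, the products
  themselves excluded; `N_nodes^e` — vertices on the BFS shortest path from
  `e` to the nearest product, both endpoints included. This convention
  reproduces the boundary cases exactly: a sole enzyme on a sole chain gets
  the maximal weight 2, and `|w| ≤ 2` always, with equality only when `e`
  lies on every path and its shortest path covers every connected vertex.
* The sign is the relation product along the deterministic BFS shortest
  path (lexicographic tie-break). When several shortest paths exist the
  deterministic one defines `N_nodes^e`; this is documented rather than
  averaged over, keeping the weight reproducible.
* Classes with several terminal products are treated as units: paths may
  end at any product.

## Reverse propagation and regulatory scores

The propagation rule is linear in the scores:

    s_u(t+1) = q̂_u · Σ_{(u, r, v) ∈ E_c} r · s_v(t) / (deg_G(u) · deg_G(v))

with the enzymes of the active class as constant sources clamped at their
topological weights, and degrees taken in the *original unfiltered* network
(each triple once, in + out) so hubs are not rewarded for connectivity that
filtering happened to spare. Signal flows backwards — a regulator collects
from its targets — matching the direction of inference (from enzymes to the
TFs that could drive them).

Choices worth making explicit:

* The update uses exactly three ingredients — own normalized expression,
  targets' previous scores, and the two node degrees — with the
  degree *product* as the damping term. Linearity is what makes an
  independent dense matrix-power oracle possible, and the acceptance tests
  exploit it.
* Edge signs multiply contributions, so inhibitory routes yield negative
  scores; an unsigned mode (`signed=False`) is available for networks whose
  TF→gene edges carry no reliable sign.
* Nodes without a measurement (metabolites, complexes, unmeasured genes)
  relay with an expression factor of 1; absorbing the signal at them would
  disconnect the network for no biological reason.
* Sources persist for all 100 steps (emitting once at t = 0 and decaying
  would make the score depend almost entirely on path length).
* The score `s̄_u` is the trapezoidal integral of the trajectory over
  t = 0…100. The step count is kept even where a fixed point exists — the
  AUC-over-steps definition, not the steady state, is the feature.
* With `q̂ ≤ 1` and degree-product damping the operator's spectral radius is
  below 1 on all generated cohorts; the runner additionally asserts
  finiteness at every step.

## Synthesis capability

A sample can synthesize a class iff some precursor→product route exists in
the class submap in which every *enzyme* has `q ≥ 10`; metabolite
intermediates never gate. Route completeness — not expression of the
class's full enzyme inventory — is the criterion, which matters for
branched classes. The BFS witness path is returned with the call.

## Embeddings, clustering, divergent pairs

UMAP (n_neighbors 15, min_dist 0.1, Euclidean, fixed seed, forced
single-threaded) embeds expression features and per-class score features;
per-class maps are concatenated (2 columns per class) and re-embedded into
the combined map. Exact duplicate rows are collapsed before embedding and
share their representative's coordinates — identical cells must land on
identical points, which stochastic gradient placement does not otherwise
guarantee. k-means runs on the 2-D coordinates with a user-chosen k (the
"manual adjustment"); labels are renumbered by first occurrence for
stability.

Divergent pairs — cells close in expression but far in regulation — are
ranked by `rank_net − rank_expr`, the difference of within-representation
percentile ranks of the pairwise Euclidean distances. The ranking operates
on the *feature matrices* (max-normalized expression; per-(class, gene)
scores, z-scored per column), not on the 2-D UMAP coordinates: UMAP
preserves neighborhoods, not large distances, so a globally rewired cell —
an outlier in score space — is placed essentially arbitrarily relative to
any particular cluster, and pair distances read off the 2-D map fluctuate
from seed to seed. Feature-space distances keep the outlier's geometry.
Both representations are accepted by the function; the pipeline default is
feature space.

## Half-normal cluster statistic

For one gene and one class, scores of all *out-of-cluster* cells are
regressed on `q̂` (ordinary least squares; the score is the response, and
distances are vertical residuals). The absolute residuals `d_i` are modeled
as half-normal; the cluster's mean distance is converted to a z-score and a
one-sided upper-tail p-value — only excess distance (distinct regulation)
is of interest. Parameterization:

* scale: `σ̂² = Σ d_i² / (n_out − 2)` — the residual degrees of freedom, not
  the raw mean square;
* in-cluster distances are shrunk by `√(1 + h_i)` with leverage
  `h_i = 1/n_out + (x_i − x̄)²/S_xx`, since residuals around an estimated
  line are inflated;
* variance of the statistic: `σ̂²(1 − 2/π)/n_in + σ̂²(2/π)/(2 n_out)` — the
  second (delta-method) term carries the uncertainty of the estimated
  centering `μ_HN = σ̂√(2/π)`. Without it the test is visibly
  anti-conservative whenever the cluster is not small relative to the
  background (≈15% of null features at α = 0.05 for a 30-vs-60 split,
  against ≈6–8% with the corrections; the residual excess over 5% is the
  normal approximation to a skewed half-normal mean).

The plain `σ_HN/√n` z-score remains available via `corrected=False`.
Benjamini–Hochberg adjustment is applied within each (cluster, class)
family — the smallest reported unit; a gene is cluster-significant if it
passes in *any* class. Degenerate regressions (no expression spread) fall
back to a flat line through the mean and are flagged.

## Synthetic cohorts and what they show

Default study conditions: 8 LM classes (canonical precursor assignment),
30 enzymes (one private gating enzyme per class, the rest shared), 120 TFs,
3 clusters × 30 cells, negative-binomial counts with log-normal baselines
(log-mean 3.5, log-sd 1.0) and quadratic overdispersion φ = 0.1
(var = m + φm²; φ = 0 degenerates to Poisson). Cluster structure comes from
per-cluster expression programs (40% of genes, log-sd 1.2) — real cell-type
cohorts differ in hundreds of genes, and without this neither embedding has
meaningful geometry.

Planted, recorded ground truth:

* **Capabilities** per cluster (all classes / AA-derived only / none).
  Exactness is enforced: enzymes on one designated route are floored at the
  threshold for capable combinations, and the private first enzyme of each
  withheld class is capped just below it — every route of exactly that
  class dies there. The floors/ceilings slightly distort enzyme count
  distributions; capability truth in exchange holds exactly, not just with
  high probability.
* **Regulators**: per cluster a two-level cascade, regulator TF → three
  mediator TFs → all enzymes of two affected classes, with regulator and
  mediators overexpressed (×5) in the cluster. The cascade is the point: a
  regulator whose score rises only because its own expression rises sits
  *on* the regression line and is invisible to the cluster statistic by
  design; routing the boost through mediators raises the regulator's score
  at unchanged own expression — a topology-driven activity change.
* **Divergent pair**: one extra cell duplicating another cell's counts
  exactly, scored against a network variant with all TF→enzyme edges
  removed. The pair carries a private expression program (30% of genes,
  log-sd 1.0) making it its own transcriptomic subtype; without it the
  duplicated cell has 29 siblings nearly as expression-close as its twin
  and "the closest pair" is not a well-posed planted event.
* A null mode (effect 1, program sd 0, φ = 0) makes clusters statistically
  exchangeable; a separate null feature generator (linear score–expression
  law plus Gaussian noise) sizes the calibration experiment at 1000
  features.

What passing these benchmarks does *not* show: the generator draws
independent counts per gene (no gene–gene count correlations beyond the
planted programs), plants clean multiplicative effects, uses networks far
smaller and more regular than curated atlases, and its residuals match the
statistic's normality assumption more closely than real scores will.
Recovery rates and calibration on real data will be worse; the benchmarks
establish correctness of the machinery, not field performance.

## Determinism and problem sizes

All randomness flows from explicit seeds; a single pipeline seed fans out
to per-stage seeds through `numpy.random.SeedSequence`, and UMAP/k-means run
single-threaded with fixed seeds, so identical configs produce byte-identical
output files. The test and acceptance workloads use 100 random graphs
(≤ 8 vertices) for the widest-path oracle, 200 random DAGs (≤ 10 nodes) for
the weighting oracle, 50 graphs × 100 steps for the propagation oracle,
1000 features for calibration and 20 cohort replicates for the recovery
experiments — sizes at which the brute-force oracles are exact and the
whole suite completes in a few minutes on one core.

## Known limitations

* Simple-path counting is exponential in general; it is deliberately
  restricted to small acyclic submaps.
* The widest-path search keeps full candidate paths for deterministic
  tie-breaking; on networks far larger than curated LM-class GRNs a
  predecessor-based variant would be preferable.
* The propagation rule is one defensible linear realization of
  "expression × target scores × degree damping"; alternatives (e.g.
  out-degree-only damping, decaying sources) would change absolute score
  values, though not the rank-based downstream analyses dramatically.
* The cluster statistic assumes an adequate linear score–expression trend
  and approximately normal residuals out of cluster; heavy-tailed score
  distributions will inflate its false positive rate.
* Divergence ranking treats all score features equally after z-scoring;
  correlated feature blocks (classes sharing enzymes) are not decorrelated.
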