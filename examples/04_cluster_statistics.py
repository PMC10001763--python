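"""Find cluster-specific regulators with the half-normal cluster test.

For each gene and mediator class, scores of all cells outside the cluster
are regressed on normalized expression; the cluster's mean absolute
distance from that line is compared against a half-normal fit of the
background distances.  Genes significant after BH adjustment regulate the
class differently in the cluster than their expression alone explains.
"""

import pandas as pd

from lmgrn import (
    cluster_test_table,
    make_dataset,
    normalize_expression,
    significant_cluster_genes,
)
from lmgrn.pipeline import score_all

ds = make_dataset(seed=0)
scores = score_all(ds.graph, ds.classes, ds.expression)
expr = normalize_expression(ds.expression)
clusters = pd.Series(ds.truth.cluster_of, name="cluster")

table = cluster_test_table(expr.normalized, scores, clusters)
sig = significant_cluster_genes(table, alpha=0.05)

for k, info in ds.truth.planted_regulators.items():
    hits = sig[sig["cluster"] == k]
    planted_found = info["tf"] in set(hits["gene"])
    print(f"cluster {k}: {len(hits)} significant genes; "
          f"planted regulator {info['tf']} recovered: {planted_found}")

best = sig.sort_values("best_adj_p").head(5)
print("\nstrongest cluster-specific regulators:")
print(best.to_string(index=False))
print("\nThe planted regulators act through boosted mediator TFs, so their")
print("score rises in their cluster at unchanged expression — exactly the")
print("off-the-line signal this statistic is built to detect.")
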