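"""Cluster cells by their regulatory profiles.

Per-class regulatory scores are embedded with UMAP, the per-class maps are
combined and re-embedded, and k-means (with analyst-chosen k) labels the
cells.  On the synthetic cohort the recovered clusters match the planted
cell populations almost perfectly.
"""

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from lmgrn import cluster_embedding, make_dataset, normalize_expression
from lmgrn.pipeline import embed_all, score_all, stage_seeds

ds = make_dataset(seed=0)
scores = score_all(ds.graph, ds.classes, ds.expression)
expr = normalize_expression(ds.expression)

expr_emb, per_class, combined = embed_all(scores, expr, ds.classes, seed=0)
labels = cluster_embedding(combined, k=3, seed=stage_seeds(0, 1)[0]).labels

truth = pd.Series(ds.truth.cluster_of)
ari = adjusted_rand_score(truth[labels.index], labels)
print(f"k-means on the combined score embedding, k=3")
print(f"adjusted Rand index vs planted clusters: {ari:.2f}")
print("\ncluster sizes:")
print(labels.value_counts().sort_index().to_string())
print("\nAn ARI near 1 means the regulatory-score features alone recover")
print("the planted cell populations without using the cluster labels.")
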