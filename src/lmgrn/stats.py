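"""Cluster-level statistics on regulatory scores.

Regulatory scores are biased toward a gene's own expression, so a cluster's
score is judged relative to the score-vs-expression trend of all *other*
cells: an ordinary least-squares line of s-bar on q-hat is fitted to the
out-of-cluster cells, a half-normal distribution is fitted to their absolute
residual distances, and the cluster's mean distance is converted to a
z-score and a one-sided upper-tail p-value.  A significant gene is one
whose cluster sits unusually far from the trend — i.e. whose regulatory
association with the LM class cannot be explained by expression alone.

With residual distances d_i and the half-normal scale sigma estimated from
the out-of-cluster residuals (sigma^2 = sum d_i^2 / (n - 2), the residual
degrees of freedom), the half-normal mean and standard deviation are
sigma*sqrt(2/pi) and sigma*sqrt(1 - 2/pi), and the cluster statistic is

    z = (d_cluster_mean - mu_HN) / sqrt(Var),

where by default Var carries both the sampling variance of the cluster mean
(sigma_HN^2 / n_cluster) and a delta-method term for the uncertainty of the
estimated centering mu_HN (sigma^2 (2/pi) / (2 n_out)); in-cluster
distances are additionally shrunk by the regression leverage sqrt(1 + h_i).
Without these corrections (``corrected=False``) the plain
sigma_HN / sqrt(n_cluster) standard error is used.  Benjamini-Hochberg
adjustment is applied within each (cluster, class) family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusterTestResult",
    "cluster_feature_pvalue",
    "adjust_pvalues",
    "cluster_test_table",
    "significant_cluster_genes",
    "rank_delta_tfs",
    "DeltaRanking",
]

_HN_MEAN = math.sqrt(2.0 / math.pi)
_HN_VAR = 1.0 - 2.0 / math.pi


@dataclass(frozen=True)
class ClusterTestResult:
    gene: str
    lm_class: str
    cluster: object
    slope: float
    intercept: float
    mean_distance: float
    z: float
    p: float
    adjusted_p: float | None = None
    degenerate: bool = False


def cluster_feature_pvalue(
    qhat: np.ndarray,
    sbar: np.ndarray,
    in_cluster: np.ndarray,
    gene: str = "",
    lm_class: str = "",
    cluster: object = None,
    corrected: bool = True,
) -> ClusterTestResult:
    """Half-normal cluster test for one gene and one LM class.

    Parameters
    ----------
    qhat, sbar
        Per-sample normalized expression and regulatory score of the gene.
    in_cluster
        Boolean mask of the cluster's samples.  At least one in-cluster and
        three out-of-cluster samples are required.
    corrected
        Use the calibrated statistic (default): residual degrees of
        freedom in the scale estimate, leverage-scaled in-cluster
        distances, and a delta-method variance that accounts for the
        estimated half-normal scale.  With ``corrected=False`` the plain
        standard-error-of-the-mean z-score is used; it is anti-conservative
        when the cluster is not small relative to the background.
    """
    qhat = np.asarray(qhat, dtype=float)
    sbar = np.asarray(sbar, dtype=float)
    mask = np.asarray(in_cluster, dtype=bool)
    if qhat.shape != sbar.shape or qhat.shape != mask.shape:
        raise ValueError("qhat, sbar and cluster mask must be aligned")
    n_in = int(mask.sum())
    n_out = int((~mask).sum())
    if n_in < 1:
        raise ValueError("cluster is empty")
    if n_out < 3:
        raise ValueError("need at least 3 out-of-cluster samples")

    x_out, y_out = qhat[~mask], sbar[~mask]
    degenerate = bool(np.ptp(x_out) == 0.0)
    if degenerate:
        # no expression spread to regress on: flat line through the mean
        slope, intercept = 0.0, float(np.mean(y_out))
        dof = max(n_out - 1, 1)
    else:
        slope, intercept = np.polyfit(x_out, y_out, 1)
        dof = n_out - 2

    dist_out = np.abs(y_out - (intercept + slope * x_out))
    dist_in = np.abs(sbar[mask] - (intercept + slope * qhat[mask]))
    if corrected:
        sigma2 = float(np.sum(dist_out**2) / dof)
        # residuals around an estimated line are inflated by the leverage
        x_bar = float(np.mean(x_out))
        sxx = float(np.sum((x_out - x_bar) ** 2))
        lev = 1.0 / n_out + (
            (qhat[mask] - x_bar) ** 2 / sxx if sxx > 0 else 0.0
        )
        dist_in = dist_in / np.sqrt(1.0 + lev)
    else:
        sigma2 = float(np.mean(dist_out**2))
    d_mean = float(np.mean(dist_in))

    if sigma2 == 0.0:
        # perfect fit outside the cluster: any excess distance is infinitely
        # surprising, none at all is unremarkable
        z = math.inf if d_mean > 0 else 0.0
        p = 0.0 if d_mean > 0 else 0.5
    else:
        sigma = math.sqrt(sigma2)
        mu_hn = sigma * _HN_MEAN
        var_dbar = sigma2 * _HN_VAR / n_in
        if corrected:
            # the centering term sigma-hat * sqrt(2/pi) is itself noisy
            var_dbar += sigma2 * (_HN_MEAN**2) / (2.0 * n_out)
        z = (d_mean - mu_hn) / math.sqrt(var_dbar)
        p = float(sps.norm.sf(z))
    return ClusterTestResult(
        gene=gene,
        lm_class=lm_class,
        cluster=cluster,
        slope=float(slope),
        intercept=float(intercept),
        mean_distance=d_mean,
        z=float(z),
        p=p,
        degenerate=degenerate,
    )


def adjust_pvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cluster_test_table(
    qhat: pd.DataFrame,
    scores: pd.DataFrame,
    clusters: pd.Series,
) -> pd.DataFrame:
    """Run the cluster test for every (gene, class, cluster) combination.

    Parameters
    ----------
    qhat
        Genes x samples normalized expression.
    scores
        Long-format score table with columns sample, gene, class, score.
    clusters
        Sample -> cluster id.

    Returns a tidy frame with BH-adjusted p-values within each
    (cluster, class) family.
    """
    samples = [s for s in qhat.columns if s in set(clusters.index)]
    cluster_ids = sorted(pd.unique(clusters.loc[samples]))
    wide = scores.pivot_table(
        index="gene", columns=["class", "sample"], values="score", fill_value=0.0
    )
    rows: list[ClusterTestResult] = []
    classes = sorted({c for c, _ in wide.columns})
    for cls in classes:
        sub = wide[cls].reindex(columns=samples, fill_value=0.0)
        genes = [g for g in sub.index if g in qhat.index]
        q_mat = qhat.loc[genes, samples].to_numpy()
        s_mat = sub.loc[genes].to_numpy()
        for cid in cluster_ids:
            mask = (clusters.loc[samples] == cid).to_numpy()
            if mask.sum() < 1 or (~mask).sum() < 3:
                continue
            for gi, gene in enumerate(genes):
                rows.append(
                    cluster_feature_pvalue(
                        q_mat[gi], s_mat[gi], mask,
                        gene=gene, lm_class=cls, cluster=cid,
                    )
                )
    table = pd.DataFrame(
        {
            "cluster": [r.cluster for r in rows],
            "class": [r.lm_class for r in rows],
            "gene": [r.gene for r in rows],
            "mean_distance": [r.mean_distance for r in rows],
            "z": [r.z for r in rows],
            "p": [r.p for r in rows],
        }
    )
    if table.empty:
        table["adj_p"] = []
        return table
    table["adj_p"] = (
        table.groupby(["cluster", "class"], group_keys=False)["p"]
        .apply(lambda s: pd.Series(adjust_pvalues(s.to_numpy()), index=s.index))
    )
    return table.sort_values(["cluster", "class", "p", "gene"]).reset_index(
        drop=True
    )


def significant_cluster_genes(
    table: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Genes significant for at least one LM class, per cluster.

    Returns one row per (cluster, gene) with the best (lowest adjusted p)
    class recorded.
    """
    hits = table[table["adj_p"] < alpha]
    if hits.empty:
        return pd.DataFrame(
            columns=["cluster", "gene", "best_class", "best_adj_p"]
        )
    best = hits.sort_values(["adj_p", "class"]).groupby(
        ["cluster", "gene"], as_index=False
    ).first()
    out = best[["cluster", "gene", "class", "adj_p"]].rename(
        columns={"class": "best_class", "adj_p": "best_adj_p"}
    )
    return out.sort_values(["cluster", "best_adj_p", "gene"]).reset_index(
        drop=True
    )


@dataclass
class DeltaRanking:
    """Top regulators by score change between two conditions."""

    lm_class: str
    condition_a: str
    condition_b: str
    ranking: pd.DataFrame  # columns: gene, delta
    k: int

    @property
    def top(self) -> list[str]:
        return self.ranking["gene"].head(self.k).tolist()


def rank_delta_tfs(
    scores_a: pd.Series,
    scores_b: pd.Series,
    lm_class: str = "",
    k: int = 3,
    by_magnitude: bool = False,
    condition_a: str = "A",
    condition_b: str = "B",
) -> DeltaRanking:
    """Regulators with the strongest score change from condition A to B.

    Scores are aligned on the union of gene ids (missing genes score 0) and
    ranked by delta = s_bar(B) - s_bar(A), descending — regulators whose
    topological association *increased* — or by |delta| when
    ``by_magnitude`` is set.  Ties break on gene id.
    """
    if len(scores_a) == 0 and len(scores_b) == 0:
        raise ValueError("no genes to rank")
    genes = scores_a.index.union(scores_b.index)
    if len(genes) == 0:
        raise ValueError("empty gene universe")
    a = scores_a.reindex(genes, fill_value=0.0)
    b = scores_b.reindex(genes, fill_value=0.0)
    delta = (b - a).astype(float)
    key = delta.abs() if by_magnitude else delta
    order = (
        pd.DataFrame({"gene": genes, "delta": delta.to_numpy(), "key": key.to_numpy()})
        .sort_values(["key", "gene"], ascending=[False, True])
        .drop(columns="key")
        .reset_index(drop=True)
    )
    return DeltaRanking(
        lm_class=lm_class,
        condition_a=condition_a,
        condition_b=condition_b,
        ranking=order,
        k=k,
    )
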