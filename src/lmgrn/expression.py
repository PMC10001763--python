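"""Expression matrices: raw read counts and cell-type normalization.

Counts are stored genes x samples.  Normalization divides each gene's counts
by its maximum across samples, yielding the cell-type normalized read count
q-hat in [0, 1]; genes with all-zero counts normalize to zero everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "normalize_expression", "map_identifiers"]

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x samples read counts with optional sample metadata.

    Parameters
    ----------
    counts
        Non-negative raw (library-size normalized) read counts, genes as
        rows, samples as columns.
    metadata
        Optional per-sample annotations (cell type, tissue, stimulus, time
        point), indexed by sample id.
    normalized
        Per-gene max-normalized counts; computed by
        :func:`normalize_expression`.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame | None = None
    normalized: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            raise TypeError("counts must be a pandas DataFrame")
        values = self.counts.to_numpy()
        if not np.isfinite(values).all():
            raise ValueError("counts contain non-finite values")
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in counts")
        if self.metadata is not None:
            missing = self.counts.columns.difference(self.metadata.index)
            if len(missing):
                raise ValueError(f"samples missing from metadata: {list(missing)[:5]}")

    # -- accessors ---------------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def sample_counts(self, sample: str) -> pd.Series:
        if sample not in self.counts.columns:
            raise KeyError(f"unknown sample {sample!r}")
        return self.counts[sample]

    def sample_normalized(self, sample: str) -> pd.Series:
        """q-hat column for one sample (normalizing on first use)."""
        if self.normalized is None:
            self.normalized = _max_normalize(self.counts)
        if sample not in self.normalized.columns:
            raise KeyError(f"unknown sample {sample!r}")
        return self.normalized[sample]


def _max_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    gene_max = counts.max(axis=1)
    # all-zero genes: define q-hat = 0 rather than 0/0
    safe = gene_max.replace(0.0, 1.0)
    return counts.div(safe, axis=0)


def normalize_expression(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each gene's counts by its maximum across all samples.

    Every gene with any expression then peaks at exactly 1 in the sample
    where it is highest; all-zero genes map to zero.
    """
    return ExpressionMatrix(
        counts=expr.counts.copy(),
        metadata=expr.metadata,
        normalized=_max_normalize(expr.counts),
    )


def map_identifiers(
    expr: ExpressionMatrix, mapping: pd.DataFrame | dict[str, str]
) -> ExpressionMatrix:
    """Rename genes through a two-column ortholog/ID mapping table.

    ``mapping`` is either a dict or a two-column DataFrame (source id,
    target id).  Source ids must be unique; several sources may map to the
    same target, in which case their counts are aggregated by the maximum
    (a gene counts as expressed if any of its orthologs is).  Genes without
    a mapping are dropped and the number dropped is logged.
    """
    if isinstance(mapping, dict):
        pairs = pd.DataFrame(
            {"source": list(mapping.keys()), "target": list(mapping.values())}
        )
    else:
        if mapping.shape[1] < 2:
            raise ValueError("mapping table needs two columns")
        pairs = mapping.iloc[:, :2].copy()
        pairs.columns = ["source", "target"]
    if pairs.empty:
        raise ValueError("empty identifier mapping")
    if pairs["source"].duplicated().any():
        raise ValueError("mapping source ids must be unique")

    lut = pairs.set_index("source")["target"]
    mapped = expr.counts.index.intersection(lut.index)
    dropped = len(expr.counts.index) - len(mapped)
    if dropped:
        logger.info("map_identifiers: dropped %d unmapped genes", dropped)

    sub = expr.counts.loc[mapped]
    sub.index = lut.loc[mapped].to_numpy()
    aggregated = sub.groupby(level=0).max()
    return ExpressionMatrix(counts=aggregated, metadata=expr.metadata)
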