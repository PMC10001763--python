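"""De novo lipid mediator synthesis capability calls.

A sample can synthesize an LM class when its precursor fatty acid (AA, DHA
or EPA) is linked to at least one terminal product of the class through a
chain of reactions whose catalyzing enzymes are all expressed (read count at
or above the threshold).  Metabolite intermediates carry no expression and
never gate a route; only enzymes do.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .expression import ExpressionMatrix
from .lipid_classes import LMClassSpec
from .network import EXPRESSION_THRESHOLD, SignedGraph
from .topology import SignedPath, shortest_path

__all__ = ["CapabilityCall", "can_synthesize", "capability_matrix"]


@dataclass(frozen=True)
class CapabilityCall:
    """Outcome of one (sample, class) capability query."""

    capable: bool
    witness: SignedPath | None = None

    def __bool__(self) -> bool:
        return self.capable

    @property
    def witness_enzymes(self) -> tuple[str, ...]:
        if self.witness is None:
            return ()
        return self.witness.vertices


def can_synthesize(
    graph: SignedGraph,
    lm_class: LMClassSpec,
    counts: pd.Series,
    threshold: float = EXPRESSION_THRESHOLD,
) -> CapabilityCall:
    """Is a complete, expressed precursor->product route present?

    ``counts`` is the sample's raw read-count column.  The class submap is
    restricted to expressed enzymes (an enzyme missing from ``counts``
    counts as unexpressed — a route cannot be certified without evidence),
    and a BFS witness path from precursor to the nearest reachable product
    is returned when one exists.
    """
    submap = lm_class.submap(graph)
    if lm_class.precursor not in submap:
        raise ValueError(
            f"precursor {lm_class.precursor!r} of class {lm_class.name!r} "
            "absent from the network"
        )
    expressed = {
        n
        for n in submap.vertices
        if submap.role(n) != "enzyme"
        or (n in counts.index and counts[n] >= threshold)
    }
    filtered = submap.subgraph(expressed)
    products = [p for p in lm_class.products if p in filtered]
    if lm_class.precursor not in filtered or not products:
        return CapabilityCall(False)
    path = shortest_path(filtered, lm_class.precursor, products)
    if path is None:
        return CapabilityCall(False)
    return CapabilityCall(True, witness=path)


def capability_matrix(
    graph: SignedGraph,
    expr: ExpressionMatrix,
    classes: list[LMClassSpec],
    threshold: float = EXPRESSION_THRESHOLD,
) -> pd.DataFrame:
    """Samples x classes boolean capability matrix.

    Each cell holds the :func:`can_synthesize` call for that sample and LM
    class; export with ``df.astype(int).to_csv(...)`` for the 0/1 form.
    """
    data = {
        cls.name: [
            bool(can_synthesize(graph, cls, expr.counts[sample], threshold))
            for sample in expr.samples
        ]
        for cls in classes
    }
    return pd.DataFrame(data, index=expr.samples)
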