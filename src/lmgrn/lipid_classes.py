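"""Lipid mediator classes and their biosynthesis submaps.

A lipid mediator (LM) class — e.g. E-prostaglandins or D-resolvins — is
described by its precursor fatty acid (arachidonic acid AA, docosahexaenoic
acid DHA, or eicosapentaenoic acid EPA), its terminal products, the enzymes
catalysing the route, and any intermediate metabolites.  The class submap is
the induced subgraph of the full network on these members and is expected to
be acyclic (biosynthesis is a directed cascade).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .network import SignedGraph

__all__ = ["LMClassSpec", "PRECURSORS", "CANONICAL_CLASSES"]

#: the three precursor polyunsaturated fatty acids
PRECURSORS = ("AA", "DHA", "EPA")

#: canonical LM classes and their precursors: prostaglandins, thromboxanes
#: and leukotrienes are arachidonic-acid-derived pro-inflammatory mediators;
#: lipoxins (AA), E-resolvins (EPA) and the DHA-derived D-resolvins,
#: protectins and maresins are specialized pro-resolving mediators.
CANONICAL_CLASSES: dict[str, str] = {
    "prostaglandins_d": "AA",
    "prostaglandins_e": "AA",
    "prostaglandins_f": "AA",
    "prostaglandins_i": "AA",
    "thromboxanes": "AA",
    "leukotrienes": "AA",
    "lipoxins": "AA",
    "e_resolvins": "EPA",
    "d_resolvins": "DHA",
    "protectins": "DHA",
    "maresins": "DHA",
}


@dataclass(frozen=True)
class LMClassSpec:
    """One lipid mediator class.

    ``intermediates`` lists metabolite nodes between precursor and products;
    together with precursor, enzymes and products they span the class
    biosynthesis submap.
    """

    name: str
    precursor: str
    products: tuple[str, ...]
    enzymes: tuple[str, ...]
    intermediates: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.enzymes:
            raise ValueError(f"class {self.name!r} has no enzymes")
        if self.precursor in self.products:
            raise ValueError(
                f"class {self.name!r}: precursor cannot be a product"
            )
        object.__setattr__(self, "products", tuple(self.products))
        object.__setattr__(self, "enzymes", tuple(self.enzymes))
        object.__setattr__(self, "intermediates", tuple(self.intermediates))

    @property
    def members(self) -> set[str]:
        return (
            {self.precursor}
            | set(self.products)
            | set(self.enzymes)
            | set(self.intermediates)
        )

    def submap(self, graph: SignedGraph) -> SignedGraph:
        """Induced biosynthesis submap of this class within ``graph``."""
        return graph.subgraph(self.members & graph.vertices)

    def to_dict(self) -> dict:
        return {
            "precursor": self.precursor,
            "products": list(self.products),
            "enzymes": list(self.enzymes),
            "intermediates": list(self.intermediates),
        }

    @classmethod
    def from_dict(cls, name: str, d: dict) -> "LMClassSpec":
        return cls(
            name=name,
            precursor=d["precursor"],
            products=tuple(d["products"]),
            enzymes=tuple(d["enzymes"]),
            intermediates=tuple(d.get("intermediates", ())),
        )
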