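"""Readers and writers for the package's plain-text formats.

Networks travel as tab-separated edge lists (source, relation, target) with
a companion node-roles TSV; relations may be spelled ``+1``/``-1`` or
``activates``/``inhibits``.  Reactions are TSV triples (substrate, enzyme,
product).  Expression is a genes-x-samples TSV/CSV with a header of sample
ids, plus an optional sample-metadata TSV.  LM class specs are YAML.
Networks and core regulatory networks export to GraphML for visualization.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd
import yaml

from .expression import ExpressionMatrix
from .lipid_classes import LMClassSpec
from .network import CatalyticReaction, MalformedInputError, SignedGraph
from .topology import CoreRegulatoryNetwork

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_roles",
    "write_roles",
    "read_network",
    "write_network",
    "read_reactions",
    "read_expression",
    "write_expression",
    "read_metadata",
    "load_class_specs",
    "dump_class_specs",
    "export_graphml",
    "export_crn_graphml",
    "read_score_table",
    "write_score_table",
]

_RELATIONS = {
    "+1": 1, "1": 1, "activates": 1, "activation": 1,
    "-1": -1, "inhibits": -1, "inhibition": -1,
}


def _parse_relation(token: str, default_sign: int | None) -> int:
    token = token.strip()
    if token in _RELATIONS:
        return _RELATIONS[token]
    if token == "" and default_sign is not None:
        return default_sign
    raise MalformedInputError(f"cannot parse relation {token!r}")


def read_edge_list(
    path: str | Path, default_sign: int | None = None
) -> list[tuple[str, int, str]]:
    """Read a signed edge list TSV (source, relation, target).

    Unsigned rows (empty relation column) are accepted only when
    ``default_sign`` is given explicitly.
    """
    edges = []
    for line in Path(path).read_text().splitlines():
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 2 and default_sign is not None:
            s, t = parts
            r = default_sign
        elif len(parts) >= 3:
            s, rel, t = parts[0], parts[1], parts[2]
            r = _parse_relation(rel, default_sign)
        else:
            raise MalformedInputError(f"bad edge-list row: {line!r}")
        edges.append((s.strip(), r, t.strip()))
    return edges


def write_edge_list(path: str | Path, graph: SignedGraph) -> None:
    rows = sorted(graph.edges)
    lines = [f"{s}\t{r:+d}\t{t}" for s, r, t in rows]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_roles(path: str | Path) -> dict[str, str]:
    roles = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        node, role = line.split("\t")[:2]
        roles[node.strip()] = role.strip()
    return roles


def write_roles(path: str | Path, graph: SignedGraph) -> None:
    lines = [f"{n}\t{r}" for n, r in sorted(graph.node_roles.items())]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_network(
    edges_path: str | Path,
    roles_path: str | Path | None = None,
    default_sign: int | None = None,
) -> SignedGraph:
    """Assemble a SignedGraph from an edge-list TSV and a roles TSV."""
    g = SignedGraph()
    roles = read_roles(roles_path) if roles_path else {}
    for node, role in roles.items():
        g.add_node(node, role)
    for s, r, t in read_edge_list(edges_path, default_sign=default_sign):
        g.add_edge(s, r, t)
    return g


def write_network(
    graph: SignedGraph, edges_path: str | Path, roles_path: str | Path
) -> None:
    write_edge_list(edges_path, graph)
    write_roles(roles_path, graph)


def read_reactions(path: str | Path) -> list[CatalyticReaction]:
    """Read reaction triples (substrate, enzyme, product) from TSV."""
    reactions = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) < 3:
            raise MalformedInputError(f"bad reaction row: {line!r}")
        reactions.append(CatalyticReaction(*parts[:3]))
    return reactions


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    counts_path: str | Path, metadata_path: str | Path | None = None
) -> ExpressionMatrix:
    counts_path = Path(counts_path)
    counts = pd.read_csv(counts_path, sep=_sep_for(counts_path), index_col=0)
    meta = read_metadata(metadata_path) if metadata_path else None
    return ExpressionMatrix(counts=counts, metadata=meta)


def write_expression(expr: ExpressionMatrix, counts_path: str | Path,
                     metadata_path: str | Path | None = None) -> None:
    counts_path = Path(counts_path)
    expr.counts.to_csv(counts_path, sep=_sep_for(counts_path))
    if metadata_path is not None and expr.metadata is not None:
        expr.metadata.to_csv(metadata_path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t", index_col=0)


def load_class_specs(path: str | Path) -> list[LMClassSpec]:
    """Load LM class specs from YAML (class -> precursor/products/enzymes)."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or not raw:
        raise ValueError(f"no class definitions in {path}")
    return [LMClassSpec.from_dict(name, d) for name, d in raw.items()]


def dump_class_specs(path: str | Path, classes: list[LMClassSpec]) -> None:
    data = {c.name: c.to_dict() for c in classes}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _as_nx_simple(graph: SignedGraph,
                  node_attrs: Mapping[str, Mapping[str, object]] | None = None
                  ) -> nx.DiGraph:
    # GraphML has no multi-edge keys we care about; contradictory-sign pairs
    # are collapsed to the activating edge with a flag
    g = nx.DiGraph()
    for n, role in graph.node_roles.items():
        g.add_node(n, role=role)
    for u, r, v in sorted(graph.edges):
        if g.has_edge(u, v):
            g[u][v]["ambiguous_sign"] = True
            g[u][v]["relation"] = max(g[u][v]["relation"], r)
        else:
            g.add_edge(u, v, relation=int(r))
    if node_attrs:
        for attr, values in node_attrs.items():
            for n, val in values.items():
                if n in g:
                    g.nodes[n][attr] = val
    return g


def export_graphml(
    graph: SignedGraph,
    path: str | Path,
    node_attrs: Mapping[str, Mapping[str, object]] | None = None,
) -> None:
    nx.write_graphml(_as_nx_simple(graph, node_attrs), str(path))


def export_crn_graphml(
    crn: CoreRegulatoryNetwork,
    path: str | Path,
    qhat: Mapping[str, float] | None = None,
    threshold_flags: Mapping[str, bool] | None = None,
) -> None:
    """GraphML export of a core regulatory network.

    Node attributes carry the regulatory score, the role (rendering shape),
    the normalized read count where available, and a below-threshold flag
    (rendering gray) so downstream viewers can reproduce the CRN figures.
    """
    attrs: dict[str, dict[str, object]] = {
        "score": {n: float(s) for n, s in crn.vertex_scores.items()}
    }
    if qhat is not None:
        attrs["qhat"] = {
            n: float(qhat[n]) for n in crn.graph.vertices if n in qhat
        }
    if threshold_flags is not None:
        attrs["below_threshold"] = {
            n: bool(threshold_flags[n])
            for n in crn.graph.vertices
            if n in threshold_flags
        }
    export_graphml(crn.graph, path, node_attrs=attrs)


def read_score_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t")
    expected = {"sample", "gene", "class", "score"}
    if not expected.issubset(df.columns):
        raise ValueError(f"score table must have columns {sorted(expected)}")
    return df


def write_score_table(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(Path(path), sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))
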