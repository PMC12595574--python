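"""Thresholded causal influence digraph and cause–effect diagram coordinates.

The network keeps every catalog factor as a node (isolated nodes included)
with its (prominence, relation) coordinates — the axes of the cause–effect
diagram — and draws a directed edge i→j whenever the total influence t_ij
exceeds the threshold. Self-loops are never drawn: the diagram shows
inter-factor influence, even though diagonal entries of T participate in
the threshold computation.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import networkx as nx
import numpy as np

from dematelkit.catalog import FactorCatalog
from dematelkit.core import FactorInfluenceProfile, TotalRelationMatrix
from dematelkit.errors import ValidationError

logger = logging.getLogger(__name__)

EdgeRule = Literal["strict", "inclusive"]

EXPORT_FORMATS = ("dot", "graphml", "edgelist")


@dataclass(frozen=True)
class CausalNetwork:
    """Factors as nodes with diagram coordinates; supra-threshold influences as edges."""

    catalog: FactorCatalog
    nodes: tuple[FactorInfluenceProfile, ...]
    edges: tuple[tuple[str, str, float], ...]  # (source, target, t_ij)
    threshold: float
    edge_rule: EdgeRule = "strict"

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.DiGraph:
        """Directed graph with node attributes (label, prominence, relation, group)
        and edge attribute ``weight``."""
        g = nx.DiGraph(threshold=self.threshold)
        for p in self.nodes:
            g.add_node(
                p.factor_id,
                label=p.label,
                prominence=p.prominence,
                relation=p.relation,
                group=p.group,
            )
        for src, tgt, w in self.edges:
            g.add_edge(src, tgt, weight=w)
        return g


def build_network(
    T: TotalRelationMatrix,
    profiles: Sequence[FactorInfluenceProfile],
    threshold: float,
    *,
    edge_rule: EdgeRule = "strict",
) -> CausalNetwork:
    """Build the causal digraph: edge i→j (i≠j) iff t_ij exceeds the threshold.

    ``edge_rule="strict"`` uses t_ij > threshold (default); ``"inclusive"``
    uses t_ij ≥ threshold. A negative threshold is allowed but warned about,
    since the resulting network is near-complete.
    """
    if not np.isfinite(threshold):
        raise ValidationError(f"threshold must be finite, got {threshold!r}")
    if edge_rule not in ("strict", "inclusive"):
        raise ValidationError(
            f"edge_rule must be 'strict' or 'inclusive', got {edge_rule!r}"
        )
    if threshold < 0:
        logger.warning(
            "threshold %g is negative; the network will be near-complete", threshold
        )
    ids = T.catalog.ids
    by_id = {p.factor_id: p for p in profiles}
    if set(by_id) != set(ids) or len(profiles) != len(ids):
        raise ValidationError("profiles do not match the catalog's factor set")
    nodes = tuple(by_id[fid] for fid in ids)  # catalog order

    edges = []
    for i, src in enumerate(ids):
        for j, tgt in enumerate(ids):
            if i == j:
                continue
            t = float(T.values[i, j])
            keep = t > threshold if edge_rule == "strict" else t >= threshold
            if keep:
                edges.append((src, tgt, t))
    return CausalNetwork(
        catalog=T.catalog,
        nodes=nodes,
        edges=tuple(edges),
        threshold=float(threshold),
        edge_rule=edge_rule,
    )


def _dot_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def export_network(net: CausalNetwork, format: str = "dot") -> str:
    """Serialize the network as DOT, GraphML or edge-list CSV text.

    Ordering is deterministic: nodes in catalog order, edges in catalog
    order by source then target. Edge-list CSV has columns
    ``source,target,weight``; DOT and GraphML carry node attributes
    (label, prominence, relation, group) and edge attribute weight.
    """
    if format not in EXPORT_FORMATS:
        raise ValidationError(
            f"unknown format {format!r}; supported: {', '.join(EXPORT_FORMATS)}"
        )
    if format == "edgelist":
        lines = ["source,target,weight"]
        lines += [f"{src},{tgt},{w!r}" for src, tgt, w in net.edges]
        return "\n".join(lines) + "\n"
    if format == "graphml":
        buf = io.BytesIO()
        nx.write_graphml(net.to_networkx(), buf)
        return buf.getvalue().decode("utf-8")
    # DOT, hand-emitted for a dependency-free deterministic dialect
    lines = ["digraph causal_network {"]
    lines.append(f"  graph [threshold={net.threshold!r}];")
    for p in net.nodes:
        lines.append(
            f'  "{_dot_escape(p.factor_id)}" [label="{_dot_escape(p.label)}", '
            f"prominence={p.prominence!r}, relation={p.relation!r}, "
            f'group="{p.group}"];'
        )
    for src, tgt, w in net.edges:
        lines.append(f'  "{_dot_escape(src)}" -> "{_dot_escape(tgt)}" [weight={w!r}];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def parse_edgelist(text: str) -> tuple[tuple[str, str, float], ...]:
    """Parse the edge-list CSV dialect back into (source, target, weight) tuples."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0] != "source,target,weight":
        raise ValidationError("edge-list CSV must start with header 'source,target,weight'")
    edges = []
    for ln in lines[1:]:
        src, tgt, w = ln.split(",")
        edges.append((src, tgt, float(w)))
    return tuple(edges)
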