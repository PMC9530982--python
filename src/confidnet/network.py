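"""Directed network container shared by the tie builder, descriptives and ERGM.

The outcome of interest is the directed indicator ``Y_ij`` over all ordered
pairs of participants: ``Y_ij = 1`` when *i* regards *j* as a confidant.
Ties carry a provenance label telling whether they were identified from
household co-residence or from a matched community nomination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Hashable, Iterable, Mapping, Optional, Set, Tuple

import networkx as nx

NodeId = Hashable
Edge = Tuple[NodeId, NodeId]

PROVENANCE_HOUSEHOLD = "household"
PROVENANCE_COMMUNITY = "community"


@dataclass
class DirectedNetwork:
    """A directed confidant network over a fixed node set.

    Parameters
    ----------
    nodes
        Ordered list of participant ids (the analysis set; isolates included).
    edges
        Set of ordered pairs ``(i, j)`` meaning "i regards j as a confidant".
    node_attributes
        Per-node attribute mapping (covariates and depression scores).
    tie_provenance
        Optional per-edge label, ``"household"`` or ``"community"``.
    """

    nodes: list
    edges: Set[Edge] = field(default_factory=set)
    node_attributes: Dict[NodeId, dict] = field(default_factory=dict)
    tie_provenance: Dict[Edge, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node ids in node list")
        node_set = set(self.nodes)
        for (i, j) in self.edges:
            if i == j:
                raise ValueError(f"self-tie {i!r}->{j!r} not allowed")
            if i not in node_set or j not in node_set:
                raise ValueError(f"edge endpoint not in node set: ({i!r}, {j!r})")

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, i: NodeId, j: NodeId) -> bool:
        return (i, j) in self.edges

    def add_edge(self, i: NodeId, j: NodeId, provenance: Optional[str] = None) -> None:
        if i == j:
            raise ValueError("self-ties are not allowed")
        self.edges.add((i, j))
        if provenance is not None:
            self.tie_provenance[(i, j)] = provenance

    def attribute_vector(self, name: str) -> list:
        """Attribute values aligned with ``nodes``; raises naming the node on a miss."""
        out = []
        for node in self.nodes:
            attrs = self.node_attributes.get(node, {})
            if name not in attrs or attrs[name] is None:
                raise KeyError(f"node {node!r} is missing attribute {name!r}")
            out.append(attrs[name])
        return out

    def to_undirected_collapse(self) -> nx.Graph:
        """Undirected collapse: edge {i, j} iff i->j or j->i (duplicates merged)."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((i, j) for (i, j) in self.edges)
        return g

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for node in self.nodes:
            g.add_node(node, **self.node_attributes.get(node, {}))
        for (i, j) in self.edges:
            g.add_edge(i, j, provenance=self.tie_provenance.get((i, j)))
        return g

    def copy(self) -> "DirectedNetwork":
        return DirectedNetwork(
            nodes=list(self.nodes),
            edges=set(self.edges),
            node_attributes={k: dict(v) for k, v in self.node_attributes.items()},
            tie_provenance=dict(self.tie_provenance),
        )


def from_edge_list(
    nodes: Iterable[NodeId],
    edges: Iterable[Edge],
    node_attributes: Optional[Mapping[NodeId, dict]] = None,
    tie_provenance: Optional[Mapping[Edge, str]] = None,
) -> DirectedNetwork:
    return DirectedNetwork(
        nodes=list(nodes),
        edges=set(tuple(e) for e in edges),
        node_attributes=dict(node_attributes or {}),
        tie_provenance=dict(tie_provenance or {}),
    )
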