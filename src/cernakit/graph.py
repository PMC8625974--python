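"""Typed lncRNA/miRNA/mRNA interaction graph.

Nodes carry a ``node_class`` attribute (one of ``lncRNA``, ``miRNA``,
``mRNA``); edges carry a ``kind`` attribute (``sponge`` for lncRNA-miRNA
edges, ``target`` for miRNA-mRNA edges).  The graph additionally remembers
the list of lncRNA-miRNA-mRNA triplets it was assembled from, because
subnetwork extraction operates on triplets rather than on bare edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .errors import UnknownIdError, ValidationError

NODE_CLASSES = ("lncRNA", "miRNA", "mRNA")
EDGE_KINDS = ("sponge", "target")

# edge kind implied by the unordered pair of endpoint classes
_KIND_BY_CLASSES = {
    frozenset(("lncRNA", "miRNA")): "sponge",
    frozenset(("miRNA", "mRNA")): "target",
}


@dataclass(frozen=True, order=True)
class Triplet:
    """One lncRNA-miRNA-mRNA interaction."""

    lncrna: str
    mirna: str
    mrna: str


@dataclass
class GeneNetwork:
    """Undirected typed graph over lncRNA/miRNA/mRNA nodes.

    Invariants enforced on every mutation: no self loops, no duplicate
    edges, endpoints exist, sponge edges join lncRNA-miRNA and target
    edges join miRNA-mRNA.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    triplets: list[Triplet] = field(default_factory=list)

    # -- construction ------------------------------------------------------

    def add_node(self, node_id: str, node_class: str) -> None:
        if node_class not in NODE_CLASSES:
            raise ValidationError(f"unknown node class {node_class!r} for {node_id!r}")
        existing = self.graph.nodes.get(node_id)
        if existing is not None and existing["node_class"] != node_class:
            raise ValidationError(
                f"node {node_id!r} registered twice with conflicting classes "
                f"({existing['node_class']} vs {node_class})"
            )
        self.graph.add_node(node_id, node_class=node_class)

    def add_edge(self, u: str, v: str, kind: str) -> None:
        if u == v:
            raise ValidationError(f"self loop on {u!r}")
        if kind not in EDGE_KINDS:
            raise ValidationError(f"unknown edge kind {kind!r}")
        for end in (u, v):
            if end not in self.graph:
                raise UnknownIdError(f"edge endpoint {end!r} is not a node")
        classes = frozenset(
            (self.graph.nodes[u]["node_class"], self.graph.nodes[v]["node_class"])
        )
        if _KIND_BY_CLASSES.get(classes) != kind:
            raise ValidationError(
                f"edge {u!r}-{v!r} of kind {kind!r} joins classes {sorted(classes)}"
            )
        self.graph.add_edge(u, v, kind=kind)

    @classmethod
    def from_triplets(cls, triplets: Iterable[Triplet]) -> "GeneNetwork":
        net = cls()
        seen: list[Triplet] = []
        for t in triplets:
            net.add_node(t.lncrna, "lncRNA")
            net.add_node(t.mirna, "miRNA")
            net.add_node(t.mrna, "mRNA")
            net.add_edge(t.lncrna, t.mirna, "sponge")
            net.add_edge(t.mirna, t.mrna, "target")
            seen.append(t)
        net.triplets = sorted(set(seen))
        return net

    # -- queries -----------------------------------------------------------

    def node_class(self, node_id: str) -> str:
        try:
            return self.graph.nodes[node_id]["node_class"]
        except KeyError:
            raise UnknownIdError(f"unknown node {node_id!r}") from None

    def nodes_of_class(self, node_class: str) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["node_class"] == node_class
        )

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[tuple[str, str, str]]:
        """Canonical (sorted-endpoint) edge tuples with kind, for comparisons."""
        return {
            (*sorted((u, v)), d["kind"]) for u, v, d in self.graph.edges(data=True)
        }

    def degrees(self) -> dict[str, int]:
        return {n: d for n, d in self.graph.degree()}
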