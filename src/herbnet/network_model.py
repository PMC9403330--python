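"""Typed storage for the three pharmacological networks and their cross-links.

The pipeline works with three networks: network A (plants, their constituent
compounds, and the proteins those compounds interact with), network B (an
expansion set of compounds structurally similar to A's compounds, with their
own protein interactions), and network C (disease proteins and the compounds
known to interact with them).  All three share one undirected, weighted
adjacency-list representation so that enumerating a node's neighbours costs
O(degree).

Cross-links between the networks come in two flavours: ``compound_similarity``
edges produced by the fingerprint-similarity rules (see :mod:`herbnet.similarity`)
and ``protein_identity`` edges joining the same protein appearing in two
networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator

__all__ = [
    "ValidationError",
    "NodeRef",
    "Edge",
    "TripartiteNetwork",
    "add_edge",
    "link_protein_identity",
    "prune_untraceable",
    "merge_networks",
    "KINDS",
    "NETWORKS",
    "ORIGINS",
]

KINDS = frozenset({"plant", "compound", "protein"})
NETWORKS = frozenset({"A", "B", "C"})
ORIGINS = frozenset(
    {"plant_compound", "compound_protein", "compound_similarity", "protein_identity"}
)
#: Edge origins whose weight is structural (always 1.0), not a similarity score.
UNIT_ORIGINS = frozenset({"plant_compound", "protein_identity"})


class ValidationError(ValueError):
    """Raised when an input violates a structural contract."""


def canonical_id(raw: str) -> str:
    """Collapse internal whitespace and strip the ends of an identifier.

    Identifiers arrive from heterogeneous sources (Latin binomials, PubChem
    CIDs, GI numbers); whitespace is the only normalisation applied so that
    display forms are preserved.  Case-insensitive comparison, where needed,
    happens at link time.
    """
    return " ".join(str(raw).split())


@dataclass(frozen=True)
class NodeRef:
    """A reference to one node: a plant, compound, or protein in one network."""

    kind: str
    id: str
    network: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"unknown node kind {self.kind!r}")
        if self.network not in NETWORKS:
            raise ValidationError(f"unknown network {self.network!r}")
        object.__setattr__(self, "id", canonical_id(self.id))
        if not self.id:
            raise ValidationError("empty node id")


@dataclass(frozen=True)
class Edge:
    """An undirected weighted edge between two nodes.

    ``plant_compound`` and ``protein_identity`` edges always carry weight 1.0;
    ``compound_similarity`` edges carry a Tanimoto score in [0, 1].
    """

    source: NodeRef
    target: NodeRef
    weight: float
    origin: str

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValidationError(f"unknown edge origin {self.origin!r}")
        if not (0.0 <= self.weight <= 1.0):
            raise ValidationError(f"edge weight {self.weight} outside [0, 1]")
        if self.origin in UNIT_ORIGINS and self.weight != 1.0:
            raise ValidationError(f"{self.origin} edges must have weight 1.0")
        if self.source == self.target:
            raise ValidationError("self-loops are not allowed")


class TripartiteNetwork:
    """Undirected adjacency-list store for plant/compound/protein nodes.

    Duplicate edges (same endpoints and origin) are merged keeping the
    maximum weight, matching the keep-max update rule used throughout the
    traversal stage.
    """

    def __init__(self, edges: Iterable[Edge] = ()) -> None:
        # node -> {(neighbor, origin): weight}
        self._adj: dict[NodeRef, dict[tuple[NodeRef, str], float]] = {}
        for e in edges:
            self.add_edge(e)

    # -- construction -----------------------------------------------------

    def add_node(self, node: NodeRef) -> None:
        self._adj.setdefault(node, {})

    def add_edge(self, edge: Edge) -> "TripartiteNetwork":
        """Insert ``edge`` symmetrically; duplicates keep the larger weight."""
        self.add_node(edge.source)
        self.add_node(edge.target)
        for u, v in ((edge.source, edge.target), (edge.target, edge.source)):
            key = (v, edge.origin)
            prev = self._adj[u].get(key)
            if prev is None or edge.weight > prev:
                self._adj[u][key] = edge.weight
        return self

    # -- inspection -------------------------------------------------------

    @property
    def nodes(self) -> set[NodeRef]:
        return set(self._adj)

    def __contains__(self, node: NodeRef) -> bool:
        return node in self._adj

    def __len__(self) -> int:
        return len(self._adj)

    def degree(self, node: NodeRef) -> int:
        return len(self._adj.get(node, {}))

    def neighbors(self, node: NodeRef) -> list[tuple[NodeRef, float, str]]:
        """All (neighbor, weight, origin) triples incident to ``node``."""
        return [(v, w, o) for (v, o), w in self._adj.get(node, {}).items()]

    def edges(self) -> Iterator[Edge]:
        """Each undirected edge exactly once (endpoint order arbitrary)."""
        seen: set[tuple[NodeRef, NodeRef, str]] = set()
        for u, nbrs in self._adj.items():
            for (v, origin), w in nbrs.items():
                if (v, u, origin) in seen:
                    continue
                seen.add((u, v, origin))
                yield Edge(u, v, w, origin)

    def nodes_of_kind(self, kind: str, network: str | None = None) -> list[NodeRef]:
        return sorted(
            (
                n
                for n in self._adj
                if n.kind == kind and (network is None or n.network == network)
            ),
            key=lambda n: (n.network, n.id),
        )

    def edge_count(self) -> int:
        return sum(1 for _ in self.edges())


def add_edge(net: TripartiteNetwork, edge: Edge) -> TripartiteNetwork:
    """Functional alias for :meth:`TripartiteNetwork.add_edge`."""
    return net.add_edge(edge)


def link_protein_identity(
    net_x: TripartiteNetwork, net_y: TripartiteNetwork
) -> list[Edge]:
    """Join identical proteins appearing in two networks with weight-1 edges.

    Protein identifiers are compared case-insensitively after whitespace
    canonicalisation; the stored node ids are untouched.  One edge is created
    per protein id present in both networks.
    """
    def by_key(net: TripartiteNetwork) -> dict[str, NodeRef]:
        return {n.id.casefold(): n for n in net.nodes if n.kind == "protein"}

    px, py = by_key(net_x), by_key(net_y)
    edges = []
    for key in sorted(px.keys() & py.keys()):
        a, b = px[key], py[key]
        if a != b:
            edges.append(Edge(a, b, 1.0, "protein_identity"))
    return edges


def merge_networks(
    *nets: TripartiteNetwork, links: Iterable[Edge] = ()
) -> TripartiteNetwork:
    """Union several networks and cross-link edges into one graph."""
    merged = TripartiteNetwork()
    for net in nets:
        for node in net.nodes:
            merged.add_node(node)
        for edge in net.edges():
            merged.add_edge(edge)
    for edge in links:
        merged.add_edge(edge)
    return merged


def prune_untraceable(
    net: TripartiteNetwork, seeds: set[NodeRef] | Iterable[NodeRef]
) -> TripartiteNetwork:
    """Drop every node (and its edges) unreachable from the seed proteins.

    Components that no disease protein can reach contribute nothing to any
    plant profile, so removing them shrinks the graph before traversal.
    Idempotent; an empty seed set yields an empty network with a warning.
    """
    seeds = {s for s in seeds if s in net}
    if not seeds:
        warnings.warn("prune_untraceable: no seeds present in network; result is empty")
        return TripartiteNetwork()
    reached: set[NodeRef] = set(seeds)
    frontier = list(seeds)
    while frontier:
        nxt = []
        for u in frontier:
            for v, _, _ in net.neighbors(u):
                if v not in reached:
                    reached.add(v)
                    nxt.append(v)
        frontier = nxt
    pruned = TripartiteNetwork()
    for node in reached:
        pruned.add_node(node)
    for edge in net.edges():
        if edge.source in reached and edge.target in reached:
            pruned.add_edge(edge)
    return pruned
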