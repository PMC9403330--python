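"""Trace disease proteins through the linked networks down to plants.

The traversal answers, for every compound and then every plant: which disease
proteins can be reached from it, and how strong is the best route?  Route
strength follows two rules:

* a direct compound-protein interaction contributes weight 1.0;
* crossing a compound-similarity edge multiplies the route weight by that
  edge's Tanimoto score (a single similarity hop therefore contributes the
  score itself; the networks built here never need more than one hop, but
  the product rule extends the semantics conservatively).

Among all routes from a disease protein to a compound the maximum weight is
kept.  Disease-network compounds may act as relays (protein -> disease
compound -> best-match similarity -> network-A compound) but are excluded
from the annotated output, since only network-A compounds can be backtracked
to plants.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

from .network_model import NodeRef, TripartiteNetwork
from .protein_weighting import ProteinWeightTable

__all__ = [
    "CompoundAnnotation",
    "PlantProteinProfile",
    "annotate_compounds",
    "backtrack_to_plants",
]

# Per-protein record: (gene symbol, normalized protein weight, best edge weight)
ProteinRecord = tuple[str, float, float]


@dataclass
class CompoundAnnotation:
    """Disease proteins traceable from one compound, with best route weights."""

    compound_id: str
    proteins: dict[str, ProteinRecord] = field(default_factory=dict)

    @property
    def traced(self) -> set[str]:
        """Protein ids already recorded; guards against double counting."""
        return set(self.proteins)

    def record(self, protein_id: str, gene: str, p_weight: float, e_weight: float) -> None:
        prev = self.proteins.get(protein_id)
        # strict ">": equal-weight routes never overwrite an existing record
        if prev is None or e_weight > prev[2]:
            self.proteins[protein_id] = (gene, p_weight, e_weight)


@dataclass
class PlantProteinProfile:
    """One plant's side of the weighted plant-protein bipartite graph."""

    plant_id: str
    proteins: dict[str, ProteinRecord] = field(default_factory=dict)

    @property
    def total_value(self) -> float:
        """Sum of protein_weight x edge_weight: the plant's standalone score."""
        return sum(pw * ew for (_, pw, ew) in self.proteins.values())

    def record(self, protein_id: str, gene: str, p_weight: float, e_weight: float) -> None:
        prev = self.proteins.get(protein_id)
        if prev is None or e_weight > prev[2]:
            self.proteins[protein_id] = (gene, p_weight, e_weight)


def _identity_closure(net: TripartiteNetwork, seed: NodeRef) -> set[NodeRef]:
    """All protein nodes reachable from ``seed`` via protein_identity edges."""
    closure = {seed}
    frontier = [seed]
    while frontier:
        nxt = []
        for u in frontier:
            for v, _, origin in net.neighbors(u):
                if origin == "protein_identity" and v.kind == "protein" and v not in closure:
                    closure.add(v)
                    nxt.append(v)
        frontier = nxt
    return closure


def _best_route_weights(
    net: TripartiteNetwork, proteins: set[NodeRef]
) -> dict[NodeRef, float]:
    """Max-product route weight from a protein closure to every compound.

    Starts at 1.0 on compounds with a direct interaction to any protein in the
    closure, then relaxes across compound-similarity edges with a max-product
    Dijkstra (edge weights <= 1, so products only shrink and the greedy
    finalization is exact).
    """
    best: dict[NodeRef, float] = {}
    heap: list[tuple[float, int, NodeRef]] = []
    tick = 0
    for p in proteins:
        for v, _, origin in net.neighbors(p):
            if origin == "compound_protein" and v.kind == "compound":
                if best.get(v, 0.0) < 1.0:
                    best[v] = 1.0
                    heapq.heappush(heap, (-1.0, tick, v))
                    tick += 1
    done: set[NodeRef] = set()
    while heap:
        negw, _, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        w = -negw
        for v, sim, origin in net.neighbors(u):
            if origin != "compound_similarity" or v.kind != "compound":
                continue
            cand = w * sim
            if cand > best.get(v, 0.0):
                best[v] = cand
                heapq.heappush(heap, (-cand, tick, v))
                tick += 1
    return best


def annotate_compounds(
    net: TripartiteNetwork,
    seeds: ProteinWeightTable,
    *,
    seed_network: str = "C",
) -> dict[str, CompoundAnnotation]:
    """Per-compound record of traceable disease proteins and route weights.

    ``seeds`` supplies the disease proteins (looked up by protein id in
    ``seed_network``) together with their normalized weights.  Seed proteins
    absent from the network are skipped with a warning.  Compounds belonging
    to the seed network serve only as relays and do not appear in the output.
    """
    annotations: dict[str, CompoundAnnotation] = {}
    for protein_id, gene, p_weight in seeds.items():
        seed = NodeRef("protein", protein_id, seed_network)
        if seed not in net:
            warnings.warn(f"seed protein {protein_id!r} ({gene}) absent from network; skipped")
            continue
        closure = _identity_closure(net, seed)
        for compound, e_weight in _best_route_weights(net, closure).items():
            if compound.network == seed_network:
                continue
            ann = annotations.setdefault(compound.id, CompoundAnnotation(compound.id))
            ann.record(protein_id, gene, p_weight, e_weight)
    return annotations


def backtrack_to_plants(
    annotations: dict[str, CompoundAnnotation],
    net: TripartiteNetwork,
) -> list[PlantProteinProfile]:
    """Merge compound annotations up to plants, keeping per-protein maxima.

    A plant's profile records, for each disease protein hit by any of its
    compounds, the best edge weight seen over those compounds.  Plants whose
    compounds trace no disease protein are omitted.  Profiles are returned
    sorted by plant id.
    """
    profiles: dict[str, PlantProteinProfile] = {}
    for plant in net.nodes_of_kind("plant"):
        prof = PlantProteinProfile(plant.id)
        for v, _, origin in net.neighbors(plant):
            if origin != "plant_compound" or v.kind != "compound":
                continue
            ann = annotations.get(v.id)
            if ann is None:
                continue
            for pid, (gene, pw, ew) in ann.proteins.items():
                prof.record(pid, gene, pw, ew)
        if prof.proteins:
            profiles[plant.id] = prof
    return [profiles[pid] for pid in sorted(profiles)]
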