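"""Seeded generators for every input the pipeline consumes.

Real inputs come from database snapshots of plant-compound, compound-protein
and disease-protein relations.  These generators emulate that structure at
desk scale — a plant-compound-protein network A, an expansion network B whose
compounds include near-duplicates of A's (bit-flip noise calibrated to keep
Tanimoto >= 0.9), and a disease network C with centrality-weighted proteins —
so that the full stack is exercisable and testable with no downloads.  All
randomness flows through one ``numpy`` PCG64 generator seeded from the spec,
so outputs are byte-identical across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .network_model import Edge, NodeRef, TripartiteNetwork, ValidationError
from .protein_weighting import normalize_weights
from .similarity import DEFAULT_FP_LENGTH, Fingerprint
from .traversal import PlantProteinProfile

__all__ = ["SyntheticSpec", "SyntheticNetworks", "generate_networks", "generate_bipartite"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape parameters of a synthetic study instance.

    Defaults describe a desk-scale analogue of a real herbal-medicine
    screen: tens of plants over ~100 compounds targeting 14 disease proteins
    (the number of disease proteins that compound data could actually reach
    in the motivating study), sparse 4860-bit fingerprints at ~2% density
    (substructure fingerprints are sparse), and a two-regime edge-weight
    model — direct interactions weigh 1.0, similarity-mediated ones fall in
    [0.9, 1.0) because only links above the 0.9 threshold exist.
    """

    n_plants: int = 40
    n_compounds: int = 120
    n_proteins: int = 14
    compounds_per_plant: tuple[int, int] = (1, 5)
    proteins_per_compound: tuple[int, int] = (1, 3)
    fingerprint_length: int = DEFAULT_FP_LENGTH
    bit_density: float = 0.02
    similarity_pair_fraction: float = 0.3
    duplicate_noise_bits: int = 4
    direct_interaction_prob: float = 0.5
    #: per-protein inclusion rate of a plant's traced set; 0.15 of 14
    #: proteins gives a mean coverage of ~3, matching the sparsity where
    #: even the best single plant reaches well under half the maximum score
    coverage_density: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_plants, self.n_compounds, self.n_proteins) < 1:
            raise ValidationError("all counts must be >= 1")
        if not (0.0 < self.bit_density < 1.0):
            raise ValidationError("bit_density must lie in (0, 1)")
        if not (0.0 <= self.similarity_pair_fraction <= 1.0):
            raise ValidationError("similarity_pair_fraction must lie in [0, 1]")
        lo, hi = self.compounds_per_plant
        if lo < 1 or hi < lo:
            raise ValidationError("invalid compounds_per_plant range")
        lo, hi = self.proteins_per_compound
        if lo < 0 or hi < lo:
            raise ValidationError("invalid proteins_per_compound range")
        if self.duplicate_noise_bits < 0:
            raise ValidationError("duplicate_noise_bits must be >= 0")
        if not (0.0 < self.coverage_density <= 1.0):
            raise ValidationError("coverage_density must lie in (0, 1]")


class SyntheticNetworks(NamedTuple):
    net_a: TripartiteNetwork
    net_b: TripartiteNetwork
    net_c: TripartiteNetwork
    fingerprints_a: list[Fingerprint]
    fingerprints_b: list[Fingerprint]
    fingerprints_c: list[Fingerprint]
    centralities: list[tuple[str, float, float, str]]
    planted_pairs: list[tuple[str, str]]


def _random_bits(rng: np.random.Generator, length: int, density: float) -> np.ndarray:
    bits = (rng.random(length) < density).astype(np.uint8)
    if not bits.any():
        bits[int(rng.integers(length))] = 1
    return bits


def _noisy_copy(
    rng: np.random.Generator, bits: np.ndarray, n_flips: int
) -> np.ndarray:
    """Copy a fingerprint turning on up to ``n_flips`` extra bits.

    Adding bits (never removing) keeps the Tanimoto of copy vs original at
    p / (p + f), so a small ``n_flips`` relative to the popcount stays above
    the 0.9 linking threshold.
    """
    out = bits.copy()
    zeros = np.flatnonzero(out == 0)
    if n_flips and zeros.size:
        picks = rng.choice(zeros, size=min(n_flips, zeros.size), replace=False)
        out[picks] = 1
    return out


def _centralities(
    rng: np.random.Generator, n: int
) -> list[tuple[str, float, float, str]]:
    """Nondegenerate per-protein (gene, bc, cc, protein_id) draws."""
    bc = rng.uniform(0.0, 0.35, n)
    cc = rng.uniform(0.30, 0.65, n)
    return [
        (f"GENE{i}", float(bc[i]), float(cc[i]), f"P{i:03d}") for i in range(n)
    ]


def generate_networks(spec: SyntheticSpec) -> SyntheticNetworks:
    """Generate networks A, B, C plus fingerprints and a centrality table.

    A fraction ``similarity_pair_fraction`` of A's compounds get a planted
    near-duplicate in network B (reported in ``planted_pairs``); every
    disease compound in C is likewise a near-duplicate of some A compound so
    that the best-match linking rule has true partners to find.
    """
    rng = np.random.default_rng(spec.seed)
    cents = _centralities(rng, spec.n_proteins)
    protein_ids = [pid for (_, _, _, pid) in cents]

    def protein(pid: str, network: str) -> NodeRef:
        return NodeRef("protein", pid, network)

    # --- network A: plants - compounds - proteins -----------------------
    net_a = TripartiteNetwork()
    fps_a = [
        Fingerprint(f"CA{i:04d}", _random_bits(rng, spec.fingerprint_length, spec.bit_density))
        for i in range(spec.n_compounds)
    ]
    lo, hi = spec.compounds_per_plant
    for t in range(spec.n_plants):
        plant = NodeRef("plant", f"Plant{t:03d}", "A")
        m = int(rng.integers(lo, hi + 1))
        for ci in rng.choice(spec.n_compounds, size=min(m, spec.n_compounds), replace=False):
            net_a.add_edge(
                Edge(plant, NodeRef("compound", fps_a[int(ci)].compound_id, "A"), 1.0, "plant_compound")
            )
    plo, phi = spec.proteins_per_compound
    for fp in fps_a:
        if rng.random() < spec.direct_interaction_prob and phi > 0:
            m = int(rng.integers(max(plo, 1), phi + 1))
            for pi in rng.choice(spec.n_proteins, size=min(m, spec.n_proteins), replace=False):
                net_a.add_edge(
                    Edge(
                        NodeRef("compound", fp.compound_id, "A"),
                        protein(protein_ids[int(pi)], "A"),
                        1.0,
                        "compound_protein",
                    )
                )

    # --- network B: expansion compounds, some planted near-duplicates ---
    net_b = TripartiteNetwork()
    fps_b: list[Fingerprint] = []
    planted_pairs: list[tuple[str, str]] = []
    n_dups = int(round(spec.similarity_pair_fraction * spec.n_compounds))
    dup_sources = rng.choice(spec.n_compounds, size=n_dups, replace=False)
    for j, src in enumerate(sorted(int(s) for s in dup_sources)):
        cid = f"CB{j:04d}"
        fps_b.append(
            Fingerprint(cid, _noisy_copy(rng, fps_a[src].bits, spec.duplicate_noise_bits))
        )
        planted_pairs.append((fps_a[src].compound_id, cid))
    for j in range(n_dups, n_dups + spec.n_compounds // 5):
        fps_b.append(
            Fingerprint(f"CB{j:04d}", _random_bits(rng, spec.fingerprint_length, spec.bit_density))
        )
    for fp in fps_b:
        m = int(rng.integers(0, 3))
        for pi in rng.choice(spec.n_proteins, size=min(m, spec.n_proteins), replace=False):
            net_b.add_edge(
                Edge(
                    NodeRef("compound", fp.compound_id, "B"),
                    protein(protein_ids[int(pi)], "B"),
                    1.0,
                    "compound_protein",
                )
            )
        net_b.add_node(NodeRef("compound", fp.compound_id, "B"))

    # --- network C: disease proteins and their interacting compounds ----
    net_c = TripartiteNetwork()
    for pid in protein_ids:
        net_c.add_node(protein(pid, "C"))
    n_cc = max(3, spec.n_compounds // 4)
    cc_sources = rng.integers(0, spec.n_compounds, size=n_cc)
    fps_c = []
    for i in range(n_cc):
        cid = f"CC{i:04d}"
        fps_c.append(
            Fingerprint(cid, _noisy_copy(rng, fps_a[int(cc_sources[i])].bits, spec.duplicate_noise_bits))
        )
        m = int(rng.integers(1, 4))
        for pi in rng.choice(spec.n_proteins, size=min(m, spec.n_proteins), replace=False):
            net_c.add_edge(
                Edge(
                    NodeRef("compound", cid, "C"),
                    protein(protein_ids[int(pi)], "C"),
                    1.0,
                    "compound_protein",
                )
            )

    return SyntheticNetworks(
        net_a, net_b, net_c, fps_a, fps_b, fps_c, cents, planted_pairs
    )


def generate_bipartite(
    spec: SyntheticSpec,
    *,
    planted_k: int | None = None,
    identical_plants: bool = False,
) -> list[PlantProteinProfile]:
    """Directly generate plant-protein profiles (the optimizer's input).

    Edge weights follow the two-regime model: 1.0 with probability
    ``direct_interaction_prob`` (a direct interaction), otherwise uniform on
    [0.9, 1.0) (a similarity-mediated route).  With ``planted_k`` set, the
    first ``planted_k`` plants jointly cover every protein at weight 1.0 and
    each holds an exclusive sentinel protein no other plant touches, so that
    exact k-set is the unique optimum by construction.  With
    ``identical_plants`` every plant carries the same profile (degenerate
    instance: any k-subset is optimal).
    """
    rng = np.random.default_rng(spec.seed)
    cents = _centralities(rng, spec.n_proteins)
    table = normalize_weights(cents)
    records = list(table.items())  # (protein_id, gene, weight)

    def draw_weight() -> float:
        if rng.random() < spec.direct_interaction_prob:
            return 1.0
        return float(rng.uniform(0.9, 1.0))

    profiles: list[PlantProteinProfile] = []

    if identical_plants:
        n_cov = int(rng.integers(1, spec.n_proteins + 1))
        picks = [records[int(i)] for i in rng.choice(spec.n_proteins, size=n_cov, replace=False)]
        weights = [draw_weight() for _ in picks]
        for t in range(spec.n_plants):
            prof = PlantProteinProfile(f"Plant{t:03d}")
            for (pid, gene, pw), ew in zip(picks, weights):
                prof.record(pid, gene, pw, ew)
            profiles.append(prof)
        return profiles

    start = 0
    if planted_k is not None:
        if not (1 <= planted_k <= min(spec.n_plants, spec.n_proteins)):
            raise ValidationError("planted_k must fit within plants and proteins")
        blocks: list[list[int]] = [[j] for j in range(planted_k)]  # sentinel j
        for i in range(planted_k, spec.n_proteins):
            blocks[i % planted_k].append(i)
        for j in range(planted_k):
            prof = PlantProteinProfile(f"Plant{j:03d}")
            for i in blocks[j]:
                pid, gene, pw = records[i]
                prof.record(pid, gene, pw, 1.0)
            profiles.append(prof)
        start = planted_k

    n_free = spec.n_proteins - (planted_k or 0)
    for t in range(start, spec.n_plants):
        prof = PlantProteinProfile(f"Plant{t:03d}")
        if planted_k is not None:
            if n_free == 0:
                # every protein is a sentinel: the plant traces nothing
                continue
            pool = np.arange(planted_k, spec.n_proteins)
        else:
            pool = np.arange(spec.n_proteins)
        # sparse coverage: most plants trace only a few disease proteins
        n_cov = 1 + int(rng.binomial(pool.size - 1, spec.coverage_density))
        for i in rng.choice(pool, size=min(n_cov, pool.size), replace=False):
            pid, gene, pw = records[int(i)]
            prof.record(pid, gene, pw, draw_weight())
        profiles.append(prof)
    return profiles
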