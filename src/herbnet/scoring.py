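"""Formula scoring: how well a set of plants covers the disease proteins.

The score of a plant set S is

    score(S) = sum over covered proteins i of  P_i * W_i(S)

where ``P_i`` is the protein's normalized weight and ``W_i(S)`` is the best
edge weight any member plant achieves on protein i.  Taking the per-protein
maximum (rather than the sum) means a protein hit by several plants is
counted once — the set of traced proteins prevents double counting — which
makes the score monotone and subadditive in S.  Subadditivity is what makes
the optimizer's additive bound valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .network_model import ValidationError
from .traversal import PlantProteinProfile, ProteinRecord

__all__ = [
    "FormulaCandidate",
    "formula_score",
    "plant_total_value",
    "combine_profiles",
    "as_profile_map",
    "make_candidate",
]


@dataclass(frozen=True)
class FormulaCandidate:
    """A scored composition of k plants."""

    plants: tuple[str, ...]
    score: float
    covered: frozenset[str]
    #: per-protein (gene, protein_weight, best member edge weight)
    proteins: dict[str, ProteinRecord] = field(default_factory=dict, compare=False)

    def as_dict(self) -> dict:
        return {
            "plants": list(self.plants),
            "score": self.score,
            "covered": sorted(self.covered),
            "proteins": {
                pid: {"gene": g, "protein_weight": pw, "edge_weight": ew}
                for pid, (g, pw, ew) in sorted(self.proteins.items())
            },
        }


def as_profile_map(
    profiles: Mapping[str, PlantProteinProfile] | Iterable[PlantProteinProfile],
) -> dict[str, PlantProteinProfile]:
    if isinstance(profiles, Mapping):
        return dict(profiles)
    return {p.plant_id: p for p in profiles}


def combine_profiles(
    plants: Iterable[str],
    profiles: Mapping[str, PlantProteinProfile] | Iterable[PlantProteinProfile],
) -> dict[str, ProteinRecord]:
    """Per-protein best (gene, weight, edge weight) over the member plants."""
    pmap = as_profile_map(profiles)
    merged: dict[str, ProteinRecord] = {}
    for plant in plants:
        if plant not in pmap:
            raise ValidationError(f"unknown plant id {plant!r}")
        for pid, rec in pmap[plant].proteins.items():
            prev = merged.get(pid)
            if prev is None or rec[2] > prev[2]:
                merged[pid] = rec
    return merged


def formula_score(
    plants: Iterable[str],
    profiles: Mapping[str, PlantProteinProfile] | Iterable[PlantProteinProfile],
) -> tuple[float, set[str]]:
    """Score a plant set and report which proteins it covers."""
    merged = combine_profiles(plants, profiles)
    score = sum(pw * ew for (_, pw, ew) in merged.values())
    return score, set(merged)


def plant_total_value(profile: PlantProteinProfile) -> float:
    """A single plant's score: the formula score of the singleton set."""
    return profile.total_value


def make_candidate(
    plants: Sequence[str],
    profiles: Mapping[str, PlantProteinProfile] | Iterable[PlantProteinProfile],
) -> FormulaCandidate:
    merged = combine_profiles(plants, profiles)
    score = sum(pw * ew for (_, pw, ew) in merged.values())
    return FormulaCandidate(
        plants=tuple(sorted(plants)),
        score=score,
        covered=frozenset(merged),
        proteins=merged,
    )
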