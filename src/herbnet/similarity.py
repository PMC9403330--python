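"""Tanimoto similarity on binary fingerprints and the two network-linking rules.

Compound structure is encoded as a fixed-length binary substructure
fingerprint (4860 bits for the Klekota-Roth dictionary used by default).
For two fingerprints with ``a`` and ``b`` set bits of which ``c`` are shared,
the Tanimoto coefficient is ``c / (a + b - c)``: 1 for identical structures,
0 for disjoint ones.

Two linking rules are built on the coefficient:

* ``threshold_links`` — connect every pair of compounds across two sets whose
  similarity reaches a threshold (0.9 by default); used to attach the
  expansion compounds of network B to network A.
* ``best_match_links`` — for each disease-network compound, connect it to the
  compound(s) of network A attaining the highest similarity, keeping all
  ties; used to bridge networks C and A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .network_model import Edge, NodeRef, ValidationError

__all__ = [
    "Fingerprint",
    "tanimoto",
    "threshold_links",
    "best_match_links",
    "DEFAULT_FP_LENGTH",
    "DEFAULT_THRESHOLD",
]

DEFAULT_FP_LENGTH = 4860
DEFAULT_THRESHOLD = 0.9


@dataclass(frozen=True)
class Fingerprint:
    """A compound's binary substructure fingerprint."""

    compound_id: str
    bits: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.bits, dtype=np.uint8)
        if arr.ndim != 1:
            raise ValidationError("fingerprint bits must be a 1-D vector")
        if arr.size and arr.max(initial=0) > 1:
            raise ValidationError("fingerprint bits must be 0/1")
        arr.setflags(write=False)
        object.__setattr__(self, "bits", arr)

    def __len__(self) -> int:
        return int(self.bits.size)

    @property
    def popcount(self) -> int:
        return int(np.count_nonzero(self.bits))

    @property
    def on_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    @classmethod
    def from_indices(
        cls, compound_id: str, indices: Iterable[int], length: int = DEFAULT_FP_LENGTH
    ) -> "Fingerprint":
        bits = np.zeros(length, dtype=np.uint8)
        idx = np.asarray(sorted(set(int(i) for i in indices)), dtype=np.intp)
        if idx.size and (idx[0] < 0 or idx[-1] >= length):
            raise ValidationError(
                f"bit index out of range for fingerprint of length {length}"
            )
        bits[idx] = 1
        return cls(compound_id, bits)

    @classmethod
    def from_dense(cls, compound_id: str, dense: str) -> "Fingerprint":
        if set(dense) - {"0", "1"}:
            raise ValidationError("dense fingerprint string must contain only 0/1")
        return cls(compound_id, np.frombuffer(dense.encode(), dtype=np.uint8) - ord("0"))


def tanimoto(fa: Fingerprint, fb: Fingerprint) -> float:
    """Tanimoto coefficient ``c / (a + b - c)`` between two fingerprints.

    Two all-zero fingerprints carry no structural evidence at all; their
    coefficient is defined as 0 (with a warning) rather than 0/0.
    """
    if len(fa) != len(fb):
        raise ValidationError(
            f"fingerprint length mismatch: {len(fa)} vs {len(fb)}"
        )
    a = fa.popcount
    b = fb.popcount
    if a == 0 and b == 0:
        warnings.warn(
            f"tanimoto({fa.compound_id!r}, {fb.compound_id!r}): both fingerprints "
            "empty; similarity defined as 0"
        )
        return 0.0
    c = int(np.count_nonzero(fa.bits & fb.bits))
    return c / (a + b - c)


def _similarity_matrix(
    rows: Sequence[Fingerprint], cols: Sequence[Fingerprint]
) -> np.ndarray:
    """All-pairs Tanimoto matrix (rows x cols); empty-vs-empty pairs score 0."""
    if not rows or not cols:
        return np.zeros((len(rows), len(cols)))
    length = len(rows[0])
    for fp in list(rows) + list(cols):
        if len(fp) != length:
            raise ValidationError("all fingerprints must share one bit length")
    mr = np.stack([fp.bits for fp in rows]).astype(np.int64)
    mc = np.stack([fp.bits for fp in cols]).astype(np.int64)
    inter = mr @ mc.T
    pr = mr.sum(axis=1)[:, None]
    pc = mc.sum(axis=1)[None, :]
    union = pr + pc - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return sim


def threshold_links(
    set_a: Sequence[Fingerprint],
    set_b: Sequence[Fingerprint],
    t: float = DEFAULT_THRESHOLD,
    *,
    network_a: str = "A",
    network_b: str = "B",
) -> list[Edge]:
    """Similarity edges for every cross-set pair with Tanimoto >= ``t``."""
    if not (0.0 <= t <= 1.0):
        raise ValidationError(f"threshold {t} outside [0, 1]")
    sim = _similarity_matrix(set_a, set_b)
    edges = []
    for i, j in zip(*np.nonzero(sim >= t)):
        w = float(sim[i, j])
        edges.append(
            Edge(
                NodeRef("compound", set_a[i].compound_id, network_a),
                NodeRef("compound", set_b[j].compound_id, network_b),
                w,
                "compound_similarity",
            )
        )
    return edges


def best_match_links(
    set_c: Sequence[Fingerprint],
    set_a: Sequence[Fingerprint],
    *,
    floor: float = 0.0,
    network_c: str = "C",
    network_a: str = "A",
) -> list[Edge]:
    """For each compound in ``set_c``, edges to ALL its best matches in ``set_a``.

    Ties at the per-row maximum are all kept.  A best match of score 0 (or
    below ``floor``) creates no edge: a zero-weight similarity edge could
    never contribute to a traversal weight.
    """
    if not set_a:
        raise ValidationError("best_match_links requires a nonempty reference set")
    sim = _similarity_matrix(set_c, set_a)
    edges = []
    for i, fc in enumerate(set_c):
        row = sim[i]
        best = float(row.max())
        if best <= 0.0 or best < floor:
            continue
        for j in np.flatnonzero(row == best):
            edges.append(
                Edge(
                    NodeRef("compound", fc.compound_id, network_c),
                    NodeRef("compound", set_a[int(j)].compound_id, network_a),
                    best,
                    "compound_similarity",
                )
            )
    return edges
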