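"""Normalized protein weights from network-centrality scores.

Each disease protein carries a betweenness centrality (BC) and a closeness
centrality (CC) taken from a prior protein-protein interaction analysis.  The
two are averaged and the averages divided by the largest average, giving a
weight in (0, 1] per protein.  These weights are the P_i terms of the formula
score: a protein that is more central to the disease module contributes more
when a plant set covers it.

The packaged 21-gene type II diabetes mellitus (T2DM) centrality table is the
reference fixture; :func:`load_t2dm_table` returns it ready-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .network_model import ValidationError

__all__ = [
    "ProteinWeightTable",
    "normalize_weights",
    "load_t2dm_table",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (0.0005 -> 0.001), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ProteinWeightTable:
    """Per-gene centralities with their averaged, max-normalized weights.

    Backed by a DataFrame with columns ``protein_id, bc, cc, avg, norm``
    indexed by gene symbol; row order follows the input.
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def norm(self, gene: str) -> float:
        return float(self.table.loc[gene, "norm"])

    def avg(self, gene: str) -> float:
        return float(self.table.loc[gene, "avg"])

    def protein_id(self, gene: str) -> str:
        return str(self.table.loc[gene, "protein_id"])

    def items(self) -> Iterator[tuple[str, str, float]]:
        """Yield (protein_id, gene, normalized_weight) per row."""
        for gene, row in self.table.iterrows():
            yield str(row["protein_id"]), str(gene), float(row["norm"])

    @property
    def total_weight(self) -> float:
        """Sum of all normalized weights: the maximum attainable formula score."""
        return float(self.table["norm"].sum())


def normalize_weights(
    raw: Iterable[Sequence],
) -> ProteinWeightTable:
    """Build a weight table from ``(gene, bc, cc[, protein_id])`` rows.

    ``avg = (bc + cc) / 2`` per gene; ``norm = avg / max(avg)``, so the most
    central protein gets weight exactly 1 and the rest scale proportionally.
    When no protein identifier is supplied the gene symbol doubles as the id.
    """
    genes, bcs, ccs, pids = [], [], [], []
    for row in raw:
        if len(row) not in (3, 4):
            raise ValidationError(f"centrality row must have 3 or 4 fields: {row!r}")
        gene = str(row[0]).strip()
        bc, cc = float(row[1]), float(row[2])
        if bc < 0 or cc < 0:
            raise ValidationError(f"negative centrality for gene {gene!r}")
        genes.append(gene)
        bcs.append(bc)
        ccs.append(cc)
        pids.append(str(row[3]).strip() if len(row) == 4 else gene)
    if not genes:
        raise ValidationError("empty centrality table")
    if len(set(genes)) != len(genes):
        raise ValidationError("duplicate gene symbols in centrality table")
    df = pd.DataFrame(
        {"protein_id": pids, "bc": bcs, "cc": ccs},
        index=pd.Index(genes, name="gene"),
    )
    df["avg"] = (df["bc"] + df["cc"]) / 2.0
    peak = df["avg"].max()
    if peak <= 0:
        raise ValidationError("all centrality averages are zero; cannot normalize")
    df["norm"] = df["avg"] / peak
    return ProteinWeightTable(df)


def load_t2dm_table() -> ProteinWeightTable:
    """The packaged 21-protein T2DM centrality table, normalized."""
    path = resources.files("herbnet.data").joinpath("t2dm_centrality.tsv")
    with path.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, sep="\t")
    return normalize_weights(df[["gene", "bc", "cc"]].itertuples(index=False))
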