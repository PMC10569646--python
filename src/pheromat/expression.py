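"""RPKM expression values and mating-type-dependent expression calls.

RPKM (reads per kilobase of transcript per million mapped reads) is
``count · 10⁹ / (library_size · gene_length_bp)``.  Read mapping itself
is out of scope: counts, gene lengths and library sizes arrive as a
table.  The mating-dependence test asks whether a pheromone gene is
expressed (RPKM at or above a threshold, default 1.0) exclusively in
samples of one pure mating type; mixed-culture samples are excluded from
the exclusivity test but reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

MATING_TYPES = ("MAT1-1", "MAT1-2", "mixed")

#: required columns of the long-format count table
COUNT_COLUMNS = ("gene_id", "gene_length_bp", "sample_id", "mating_type", "library_size", "count")


@dataclass
class CountTable:
    """Long-format read-count table with per-sample metadata."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(COUNT_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"count table missing columns: {sorted(missing)}")
        if (self.data["gene_length_bp"] <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (self.data["count"] < 0).any():
            raise ValueError("counts must be non-negative")
        bad = ~self.data["mating_type"].isin(MATING_TYPES)
        if bad.any():
            raise ValueError(f"unknown mating types: {sorted(self.data.loc[bad, 'mating_type'].unique())}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        return cls(pd.read_csv(path, sep="\t"))

    def with_rpkm(self) -> pd.DataFrame:
        df = self.data.copy()
        df["rpkm"] = [
            rpkm(int(c), int(l), int(n))
            for c, l, n in zip(df["count"], df["gene_length_bp"], df["library_size"])
        ]
        return df


def rpkm(count: int, gene_length_bp: int, library_size: int) -> float:
    """RPKM = count × 10⁹ / (library_size × gene_length_bp)."""
    if gene_length_bp <= 0:
        raise ValueError("gene length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return count * 1e9 / (library_size * gene_length_bp)


def mating_dependence(
    table: CountTable, gene_id: str, threshold_on: float = 1.0
) -> str:
    """Mating-type exclusivity verdict for one gene.

    ``MAT1_1_exclusive``: expressed (RPKM ≥ threshold) in at least one
    MAT1-1 sample and below threshold in every MAT1-2 sample (and vice
    versa); ``both`` when both pure types express it; ``neither``
    otherwise.  Mixed samples do not participate.
    """
    df = table.with_rpkm()
    sub = df[df["gene_id"] == gene_id]
    if sub.empty:
        raise KeyError(f"gene {gene_id!r} not in count table")
    pure = sub[sub["mating_type"] != "mixed"]
    if pure.empty:
        raise ValueError(f"gene {gene_id!r}: no samples of known mating type")
    on_11 = (pure.loc[pure["mating_type"] == "MAT1-1", "rpkm"] >= threshold_on).any()
    on_12 = (pure.loc[pure["mating_type"] == "MAT1-2", "rpkm"] >= threshold_on).any()
    if on_11 and on_12:
        return "both"
    if on_11:
        return "MAT1_1_exclusive"
    if on_12:
        return "MAT1_2_exclusive"
    return "neither"


def rpkm_table_tsv(table: CountTable) -> str:
    """RPKM per gene × sample as TSV."""
    return table.with_rpkm().to_csv(sep="\t", index=False)
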