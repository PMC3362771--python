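"""Core in-memory containers shared across the pipeline.

Expression values are log2-scale throughout. Marker tracks hold aCGH
log2 ratios (sample vs diploid reference) at ordered genomic positions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ROLES = ("TM", "CM", "metastasis")

#: Columns of a segment table (one row per segment, tiling each chromosome).
#: ``start``/``end`` are 0-based half-open marker indices; ``start_bp``/
#: ``end_bp`` are the genomic positions of the first/last marker (used for
#: SEG output, 1-based inclusive); ``cover_start``/``cover_end`` are the
#: half-open bp interval the segment is taken to cover for gene overlap
#: (boundaries at midpoints between flanking markers, so segments tile the
#: chromosome in bp as well as in marker index).
SEGMENT_COLUMNS = [
    "sample", "chrom", "start", "end", "n_markers", "mean_log2", "state",
    "start_bp", "end_bp", "cover_start", "cover_end",
]

STATES = ("amplified", "deleted", "unchanged")


@dataclass
class ExpressionMatrix:
    """Log2 expression, genes x samples, with a sample role and optional
    TM<->CM pairing.

    Parameters
    ----------
    values : DataFrame
        Genes in rows (unique index), samples in columns.
    role : str
        One of ``TM``, ``CM`` or ``metastasis``.
    pairing : DataFrame, optional
        Columns ``tm`` and ``cm`` giving autologous pairs; each row is one
        patient. Only meaningful for TM/CM matrices.
    """

    values: pd.DataFrame
    role: str
    pairing: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene IDs: {list(dups[:5])}")
        if self.pairing is not None:
            missing = set(self.pairing["tm" if self.role == "TM" else "cm"])
            missing -= set(self.values.columns)
            if missing and self.role in ("TM", "CM"):
                raise ValueError(
                    f"pairing references unknown {self.role} samples: "
                    f"{sorted(missing)[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def paired_columns(self, other: "ExpressionMatrix") -> tuple[list, list]:
        """Return (self columns, other columns) ordered by shared pairing."""
        pairing = self.pairing if self.pairing is not None else other.pairing
        if pairing is None:
            raise ValueError("no pairing map available")
        key_self = "tm" if self.role == "TM" else "cm"
        key_other = "tm" if other.role == "TM" else "cm"
        return list(pairing[key_self]), list(pairing[key_other])


@dataclass
class MarkerTrack:
    """Ordered genomic markers with per-sample log2 ratios.

    ``table`` has columns ``chrom``, ``position`` then one column per
    sample; rows are sorted by (chrom, position) with strictly increasing
    positions within each chromosome.
    """

    table: pd.DataFrame
    dropped_markers: int = 0

    def __post_init__(self) -> None:
        t = self.table
        if list(t.columns[:2]) != ["chrom", "position"]:
            raise ValueError("marker table must start with chrom, position")
        for chrom, sub in t.groupby("chrom", sort=False):
            pos = sub["position"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on {chrom}")
        vals = t[self.samples]
        if not np.isfinite(vals.to_numpy(float)).all():
            raise ValueError("marker values must be finite; drop missing "
                             "markers at load time")

    @property
    def samples(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("chrom", "position")]

    @property
    def chromosomes(self) -> list:
        return list(pd.unique(self.table["chrom"]))

    def chromosome(self, chrom) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]


def empty_segment_table() -> pd.DataFrame:
    return pd.DataFrame(columns=SEGMENT_COLUMNS)
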