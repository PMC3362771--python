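"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: tab-delimited matrices (first column gene ID,
header row of sample IDs), tab-delimited marker tracks (chrom, position,
one column per sample), BED gene annotations (0-based half-open), SEG
segment tables (1-based inclusive genomic coordinates, Broad
convention) and YAML/JSON run configuration.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ExpressionMatrix, MarkerTrack, SEGMENT_COLUMNS

logger = logging.getLogger(__name__)

SEG_HEADER = ["ID", "chrom", "loc.start", "loc.end", "num.mark",
              "seg.mean", "state"]


class InputError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------- expression

def read_expression(path, role: str = "metastasis",
                    pairing: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Read a tab-delimited log2 expression matrix.

    First column gene IDs, header row of sample IDs. Duplicate gene IDs
    and non-numeric cells are rejected with descriptive errors; a value
    above 30 triggers a warning that the matrix may not be log2 scale.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise InputError(f"duplicate gene ID {dup!r} in {path}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise InputError(
                f"non-numeric value {bad.iloc[0]!r} at gene "
                f"{bad.index[0]!r}, column {col!r} in {path}")
    if np.nanmax(df.to_numpy(float), initial=0.0) > 30:
        logger.warning("%s: values above 30; expected log2 scale", path)
    return ExpressionMatrix(df, role=role, pairing=pairing)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_pairing(path) -> pd.DataFrame:
    """Two-column TSV (TM sample, CM sample), with or without header."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["tm", "cm"]:
        df = pd.read_csv(path, sep="\t", header=None, names=["tm", "cm"])
    if df.shape[1] < 2:
        raise InputError(f"pairing file {path} needs two columns")
    return df[["tm", "cm"]]


def write_pairing(pairing: pd.DataFrame, path) -> None:
    pairing[["tm", "cm"]].to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------- marker track

def read_marker_track(path) -> MarkerTrack:
    """Read a tab-delimited marker track (chrom, position, samples...).

    Markers with any missing value are dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["chrom", "position"]:
        raise InputError(
            f"{path}: first two columns must be chrom, position")
    sample_cols = list(df.columns[2:])
    before = len(df)
    df = df.dropna(subset=sample_cols).reset_index(drop=True)
    dropped = before - len(df)
    if dropped:
        logger.info("%s: dropped %d markers with missing values", path,
                    dropped)
    df = df.sort_values(["chrom", "position"],
                        kind="mergesort").reset_index(drop=True)
    return MarkerTrack(df, dropped_markers=dropped)


def write_marker_track(track: MarkerTrack, path) -> None:
    track.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


# --------------------------------------------------------------------- BED

def read_bed(path) -> pd.DataFrame:
    """Gene annotations as BED (chrom, start, end, name); 0-based
    half-open. Returns a DataFrame indexed by gene name."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3],
                     names=["chrom", "start", "end", "gene"])
    bad = df[df["end"] <= df["start"]]
    if len(bad):
        row = bad.iloc[0]
        raise InputError(
            f"{path}: malformed BED record {row['gene']!r} "
            f"({row['chrom']}:{row['start']}-{row['end']})")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise InputError(f"{path}: duplicate gene name {dup!r}")
    return df.set_index("gene")


def write_bed(genes: pd.DataFrame, path) -> None:
    out = genes.reset_index()[["chrom", "start", "end", "gene"]]
    out.to_csv(path, sep="\t", index=False, header=False)


# --------------------------------------------------------------------- SEG

def write_seg(segments: pd.DataFrame, path) -> None:
    """Write called segments in SEG format with a state column.

    Coordinates are 1-based inclusive marker positions (Broad SEG
    convention); seg.mean is written to 4 decimals.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(SEG_HEADER) + "\n")
        for _, row in segments.iterrows():
            fh.write("\t".join([
                str(row["sample"]), str(row["chrom"]),
                str(int(row["start_bp"])), str(int(row["end_bp"])),
                str(int(row["n_markers"])),
                f"{row['mean_log2']:.4f}", str(row["state"]),
            ]) + "\n")


def read_seg(path) -> pd.DataFrame:
    """Read a SEG file written by :func:`write_seg`."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != SEG_HEADER:
        raise InputError(f"{path}: unexpected SEG header {list(df.columns)}")
    return df.rename(columns={"ID": "sample", "loc.start": "start_bp",
                              "loc.end": "end_bp", "num.mark": "n_markers",
                              "seg.mean": "mean_log2"})


# ------------------------------------------------------------- gene CN, misc

def write_gene_cn(per_sample: dict[str, pd.DataFrame], path) -> None:
    """Tab-delimited gene-level CN with composition fractions."""
    frames = []
    for sample, tab in per_sample.items():
        t = tab.copy()
        if "sample" not in t:
            t.insert(0, "sample", sample)
        frames.append(t.reset_index(names="gene"))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False,
                                                float_format="%.10g")


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(str(g) for g in genes) + "\n")


# ------------------------------------------------------------------- config

@dataclasses.dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Thresholds mirror the statistical defaults of the analysis: the
    SNR/marker-count segmentation rule, strict amplification/deletion
    thresholds, the screen p cutoffs, the delegate significance level,
    the class-comparison cutoff and the top-discriminant count.
    """

    out_dir: str = "taraclass_out"
    markers_path: str | None = None
    genes_path: str | None = None
    tm_path: str | None = None
    cm_path: str | None = None
    pairing_path: str | None = None
    cohort_path: str | None = None
    batch_path: str | None = None
    simulate: bool = True
    min_markers: int = 10
    snr: float = 2.0
    amp_threshold: float = 0.15
    del_threshold: float = -0.3
    p_stable: float = 0.05
    p_stable_strict: float = 0.01
    delegate_alpha: float = 0.05
    de_cutoff: float = 0.001
    top_n: int = 100
    k_classes: int = 3
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.min_markers < 1:
            raise ValueError("min_markers must be >= 1")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.amp_threshold <= self.del_threshold:
            raise ValueError("amp_threshold must exceed del_threshold")
        for name in ("p_stable", "p_stable_strict", "delegate_alpha",
                     "de_cutoff"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.top_n < 1 or self.k_classes < 2:
            raise ValueError("top_n >= 1 and k_classes >= 2 required")


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config),
                                         sort_keys=False))


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise InputError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))
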