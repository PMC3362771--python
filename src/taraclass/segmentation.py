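"""aCGH segmentation, state calling and gene-level copy number.

The segmentation model is recursive binary splitting with a merge
pass. The split search maximises the normalised mean difference
|mean_left - mean_right| / sqrt(1/n_left + 1/n_right) — the two-sample
change-point statistic, which stays sensitive to events embedded deep
inside a long chromosome, where the raw mean difference is diluted
away. A candidate split is accepted when that statistic exceeds a
conservative multiple-testing-aware bar (``split_t`` noise SDs) and
both children keep at least ``min_markers`` markers. The final merge
pass then enforces the segment definition itself: adjacent segments
must differ in mean log2 ratio by at least ``snr`` (default 2) local
noise SDs — segments that differ from their neighboring regions by at
least 2 signal-to-noise ratios, in at least ``min_markers`` markers.

Amplification/deletion states are called on segment means with strict
thresholds (> 0.15 / < -0.3 by default). Gene-level copy number
summarises the segments overlapping each gene as a bp-weighted mean
log2 ratio plus the fractional state composition of the gene span,
which captures mixed intra-genic states (e.g. a gene 38% unchanged /
62% deleted).
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import MarkerTrack, SEGMENT_COLUMNS

logger = logging.getLogger(__name__)

NOISE_FLOOR = 1e-6
STATE_PRIORITY = ("unchanged", "amplified", "deleted")  # tie-break order


def estimate_noise_sd(values, floor: float = NOISE_FLOOR) -> float:
    """Robust marker-noise SD from first differences.

    Uses 1.4826 * median(|diff|) / sqrt(2): the MAD of successive
    differences is insensitive to a small number of true copy-number
    steps, unlike the naive SD which they inflate.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 markers to estimate noise")
    sd = 1.4826 * np.median(np.abs(np.diff(v))) / np.sqrt(2.0)
    return float(max(sd, floor))


def _best_split(cumsum: np.ndarray, i: int, j: int, min_markers: int):
    """Best single split of marker interval [i, j).

    Maximises the normalised mean difference
    |mean_left - mean_right| / sqrt(1/n_left + 1/n_right)
    over splits leaving >= min_markers on each side, leftmost on ties.
    Returns (split_index, statistic); (None, 0.0) when no admissible
    split exists. ``cumsum`` is the prefix sum with
    cumsum[k] = sum(values[:k]).
    """
    lo, hi = i + min_markers, j - min_markers
    if hi < lo:
        return None, 0.0
    s = np.arange(lo, hi + 1)
    nl = s - i
    nr = j - s
    left = (cumsum[s] - cumsum[i]) / nl
    right = (cumsum[j] - cumsum[s]) / nr
    stats_ = np.abs(left - right) / np.sqrt(1.0 / nl + 1.0 / nr)
    k = int(np.argmax(stats_))  # argmax returns first (leftmost) maximum
    return int(s[k]), float(stats_[k])


def _split_recursive(cumsum, i, j, min_markers, threshold, out):
    split, stat = _best_split(cumsum, i, j, min_markers)
    if split is None or stat < threshold:
        out.append((i, j))
        return
    _split_recursive(cumsum, i, split, min_markers, threshold, out)
    _split_recursive(cumsum, split, j, min_markers, threshold, out)


def _merge_pass(bounds: list[tuple[int, int]], cumsum, threshold):
    """Iteratively merge the adjacent pair with the smallest mean
    difference while that difference is below threshold."""
    bounds = list(bounds)

    def mean(b):
        return (cumsum[b[1]] - cumsum[b[0]]) / (b[1] - b[0])

    while len(bounds) > 1:
        means = [mean(b) for b in bounds]
        diffs = np.abs(np.diff(means))
        k = int(np.argmin(diffs))
        if diffs[k] >= threshold:
            break
        bounds[k] = (bounds[k][0], bounds[k + 1][1])
        del bounds[k + 1]
    return bounds


def _cover_edges(positions: np.ndarray) -> np.ndarray:
    """Half-open bp cover boundaries for each marker interval: midpoints
    between adjacent markers, extended half a spacing at both ends."""
    pos = positions.astype(float)
    if pos.size == 1:
        return np.array([pos[0] - 0.5, pos[0] + 0.5])
    mids = (pos[:-1] + pos[1:]) / 2.0
    first = pos[0] - (pos[1] - pos[0]) / 2.0
    last = pos[-1] + (pos[-1] - pos[-2]) / 2.0
    return np.concatenate([[max(first, 0.0)], mids, [last]])


def segment_profile(track: MarkerTrack, sample: str,
                    min_markers: int = 10, snr: float = 2.0,
                    split_t: float = 4.0) -> pd.DataFrame:
    """Segment one sample's marker profile per chromosome.

    Noise is estimated per chromosome (robust MAD-of-differences). The
    recursive split search uses the normalised change-point statistic
    with an acceptance bar of ``split_t`` noise SDs (conservative
    against the multiplicity of candidate splits); both children must
    keep >= min_markers markers, which enforces the minimum-size rule
    for every reported region. The merge pass then re-joins adjacent
    segments whose mean log2 ratios differ by less than
    ``snr * noise_sd``, so every reported boundary separates neighboring
    regions by at least ``snr`` signal-to-noise ratios. Returns a
    segment table (see ``containers.SEGMENT_COLUMNS``) tiling each
    chromosome; states are unset until :func:`call_states`.
    """
    if sample not in track.samples:
        raise KeyError(f"unknown sample {sample!r}")
    rows = []
    for chrom in track.chromosomes:
        sub = track.chromosome(chrom)
        values = sub[sample].to_numpy(float)
        positions = sub["position"].to_numpy()
        n = values.size
        cumsum = np.concatenate([[0.0], np.cumsum(values)])
        if n >= 3:
            noise_sd = estimate_noise_sd(values)
        else:
            noise_sd = np.inf
        bounds: list[tuple[int, int]] = []
        if n < 2 * min_markers:
            bounds = [(0, n)]
        else:
            _split_recursive(cumsum, 0, n, min_markers,
                             split_t * noise_sd, bounds)
            bounds = _merge_pass(bounds, cumsum, snr * noise_sd)
        edges = _cover_edges(positions)
        for (i, j) in bounds:
            mean = (cumsum[j] - cumsum[i]) / (j - i)
            rows.append((sample, chrom, i, j, j - i, mean, None,
                         int(positions[i]), int(positions[j - 1]),
                         float(edges[i]), float(edges[j])))
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def call_states(segments: pd.DataFrame, amp_threshold: float = 0.15,
                del_threshold: float = -0.3) -> pd.DataFrame:
    """Assign amplified/deleted/unchanged states to segment means.

    Thresholds are strict: a mean of exactly ``amp_threshold`` is
    unchanged.
    """
    if amp_threshold <= del_threshold:
        raise ValueError("amp_threshold must exceed del_threshold")
    mean = segments["mean_log2"].to_numpy(float)
    if not np.isfinite(mean).all():
        raise ValueError("segment means must be finite")
    state = np.where(mean > amp_threshold, "amplified",
                     np.where(mean < del_threshold, "deleted", "unchanged"))
    out = segments.copy()
    out["state"] = state
    return out


def gene_copy_number(segments: pd.DataFrame, genes: pd.DataFrame,
                     sample: str | None = None) -> pd.DataFrame:
    """Gene-level copy number from called segments.

    Parameters
    ----------
    segments : DataFrame
        Called segment table for one sample (or filtered with
        ``sample``). Cover intervals (``cover_start``/``cover_end``)
        define the bp extent of each segment.
    genes : DataFrame
        BED-like records with columns ``chrom``, ``start``, ``end``
        (0-based half-open) indexed by gene ID.

    Returns
    -------
    DataFrame indexed by gene: ``weighted_log2`` (bp-weighted mean of
    overlapping segment means), ``frac_amplified``, ``frac_deleted``,
    ``frac_unchanged`` (fractions of the gene span, summing to 1; any
    uncovered part of the span counts as unchanged), ``dominant_state``
    (largest fraction, ties broken toward unchanged, then amplified) and
    ``no_coverage`` for genes with no overlapping segment.
    """
    bad = genes[genes["end"] <= genes["start"]]
    if len(bad):
        raise ValueError(
            f"malformed BED record (end <= start): {bad.index[0]!r}")
    if sample is not None:
        segments = segments[segments["sample"] == sample]
    if segments["state"].isna().any():
        raise ValueError("segments must be state-called first")

    n = len(genes)
    frac = {s: np.zeros(n) for s in ("amplified", "deleted", "unchanged")}
    wsum = np.zeros(n)
    cover = np.zeros(n)
    glen = (genes["end"] - genes["start"]).to_numpy(float)

    for chrom, seg_sub in segments.groupby("chrom", sort=False):
        gmask = (genes["chrom"] == chrom).to_numpy()
        if not gmask.any():
            continue
        ga = genes.loc[gmask, "start"].to_numpy(float)
        gb = genes.loc[gmask, "end"].to_numpy(float)
        for _, seg in seg_sub.iterrows():
            ov = np.clip(np.minimum(gb, seg["cover_end"])
                         - np.maximum(ga, seg["cover_start"]), 0.0, None)
            frac[seg["state"]][gmask] += ov
            wsum[gmask] += ov * seg["mean_log2"]
            cover[gmask] += ov

    no_coverage = cover <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        weighted = np.where(no_coverage, 0.0, wsum / np.where(cover > 0,
                                                              cover, 1.0))
    for s in frac:
        frac[s] = frac[s] / glen
    # uncovered span counts as unchanged; no-coverage genes are fully so
    frac["unchanged"] = frac["unchanged"] + np.clip(
        1.0 - (frac["amplified"] + frac["deleted"] + frac["unchanged"]),
        0.0, None)

    stacked = np.vstack([frac[s] for s in STATE_PRIORITY])
    dominant = np.array(STATE_PRIORITY)[np.argmax(stacked, axis=0)]

    out = pd.DataFrame({
        "weighted_log2": weighted,
        "frac_amplified": frac["amplified"],
        "frac_deleted": frac["deleted"],
        "frac_unchanged": frac["unchanged"],
        "dominant_state": dominant,
        "no_coverage": no_coverage,
    }, index=genes.index)
    if sample is not None:
        out.insert(0, "sample", sample)
    return out


def gene_copy_number_matrix(segments: pd.DataFrame, genes: pd.DataFrame
                            ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Run :func:`gene_copy_number` for every sample in a segment table.

    Returns ``(weighted_log2 matrix genes x samples, per-sample tables)``.
    """
    samples = list(pd.unique(segments["sample"]))
    per_sample = {}
    mat = pd.DataFrame(index=genes.index, columns=samples, dtype=float)
    for s in samples:
        tab = gene_copy_number(segments, genes, s)
        per_sample[s] = tab
        mat[s] = tab["weighted_log2"]
    return mat, per_sample
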