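"""Synthetic paired tumor / cell-line cohort with planted ground truth.

Emulates the study design the pipeline targets: 15 autologous tumor
(TM) / cell-line (CM) pairs with aCGH profiles of the cell lines, plus an
independent metastasis cohort carrying a two-polar-classes-plus-
intermediate structure and additive batch effects. Every downstream
stage (segmentation, stable-gene screen, delegate discovery, TARA
classification) can be validated against the planted truth.

Gene population structure
-------------------------
Four planted categories, assigned at random gene positions:

* ``dosage_driven`` — tumor-intrinsic expression tracks the gene's DNA
  log2 ratio with a per-gene slope drawn around ``dosage_slope``;
* ``stable_nondosage`` — a patient-level intrinsic signal shared by TM
  and CM but independent of copy number;
* ``stromal`` — a TM-only microenvironment signal with near-constant CM
  values (these decorrelate TM from CM);
* the remainder — pure measurement noise around a gene baseline.

Class structure is carried by the dosage-driven genes (one quarter up
in class A, one quarter up in class B), so that clustering the
metastasis cohort on recovered delegate genes can rediscover the
planted classes. The intermediate class C draws half-effect shifts on
both polar marker sets plus a weak C-specific signature on a third
(reserved) quarter of the dosage genes: a purely intermediate profile
coincides with the cohort mean after centering and is therefore
invisible to correlation-distance clustering, whereas real intermediate
subclusters are coherent enough to be drawn as a group.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, MarkerTrack

# rng domain codes: keep generate_cgh_profile(config, i) reproducible on
# its own and identical to what generate_cohort uses internally.
_DOM_LAYOUT = 0
_DOM_CGH = 1
_DOM_EXPR = 2
_DOM_MET = 3


class ConfigurationError(ValueError):
    """Invalid simulation configuration; message names the field."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    All expression quantities are log2 units. ``seed`` fully determines
    every output.
    """

    n_pairs: int = 15
    n_metastases: int = 112
    n_genes: int = 5000
    n_markers_per_chrom: int = 500
    n_chromosomes: int = 4
    frac_dosage: float = 0.08
    frac_stromal: float = 0.10
    frac_stable_nondosage: float = 0.12
    dosage_slope: float = 1.5
    #: per-gene slope = dosage_slope * U(1 - jitter, 1 + jitter)
    dosage_slope_jitter: float = 1.0 / 3.0
    stable_signal_sd: float = 1.0
    noise_sd_expr: float = 0.2
    noise_sd_cgh: float = 0.1
    #: expected copy-number events per chromosome per sample
    segment_event_rate: float = 3.0
    min_event_markers: int = 30
    max_event_markers: int = 120
    gain_levels: tuple = (0.3, 0.45, 0.6, 1.0)
    loss_levels: tuple = (-0.5, -0.7, -1.0)
    p_gain: float = 0.55
    class_effect: float = 1.5
    frac_class_c: float = 0.2
    n_batches: int = 3
    batch_sd: float = 0.15
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    marker_spacing_bp: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_pairs", "n_metastases", "n_genes",
                     "n_markers_per_chrom", "n_chromosomes", "n_batches"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        fracs = {}
        for name in ("frac_dosage", "frac_stromal", "frac_stable_nondosage",
                     "frac_class_c"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
            fracs[name] = v
        if (self.frac_dosage + self.frac_stromal
                + self.frac_stable_nondosage) > 1.0 + 1e-12:
            raise ConfigurationError(
                "frac_dosage + frac_stromal + frac_stable_nondosage "
                "must be <= 1")
        for name in ("noise_sd_expr", "noise_sd_cgh", "stable_signal_sd",
                     "batch_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.min_event_markers < 1:
            raise ConfigurationError("min_event_markers must be >= 1")
        if self.max_event_markers < self.min_event_markers:
            raise ConfigurationError(
                "max_event_markers must be >= min_event_markers")
        if not 0.0 <= self.p_gain <= 1.0:
            raise ConfigurationError("p_gain must be in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gain_levels"] = list(self.gain_levels)
        d["loss_levels"] = list(self.loss_levels)
        return d

    @classmethod
    def null(cls, **overrides) -> "SimulationConfig":
        """Configuration with no planted signal of any kind."""
        base = dict(frac_dosage=0.0, frac_stromal=0.0,
                    frac_stable_nondosage=0.0, class_effect=0.0)
        base.update(overrides)
        return cls(**base)


@dataclass
class SyntheticTruth:
    """Planted ground truth for a generated cohort.

    Attributes
    ----------
    genes : DataFrame
        Indexed by gene ID with columns ``chrom``, ``start``, ``end``
        (0-based half-open bp), the boolean category flags, the realized
        per-gene ``dosage_slope`` and the expression ``baseline``.
    sample_class : Series
        True class (``A``/``B``/``C``) per metastasis sample.
    batch : Series
        Batch label per metastasis sample.
    segments : DataFrame
        True piecewise-constant copy-number structure per cell-line
        sample: columns ``sample``, ``chrom``, ``start``, ``end``
        (0-based half-open marker indices) and ``mean_log2``.
    gene_cn : DataFrame
        True bp-weighted gene-level log2 ratio, genes x cell-line
        samples.
    """

    genes: pd.DataFrame
    sample_class: pd.Series
    batch: pd.Series
    segments: pd.DataFrame
    gene_cn: pd.DataFrame

    def breakpoints(self, sample: str, chrom: str) -> np.ndarray:
        """Interior true breakpoint marker indices for one chromosome."""
        seg = self.segments
        sel = seg[(seg["sample"] == sample) & (seg["chrom"] == chrom)]
        starts = np.sort(sel["start"].to_numpy())
        return starts[starts > 0]


def _rng(config: SimulationConfig, domain: int, index: int = 0):
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed,
                               spawn_key=(domain, index)))


def _chrom_names(config: SimulationConfig) -> list[str]:
    return [f"chr{i + 1}" for i in range(config.n_chromosomes)]


def _marker_positions(config: SimulationConfig) -> np.ndarray:
    """Marker i is taken to cover bp tile [i*s, (i+1)*s); its reported
    position is the tile midpoint, so segment cover boundaries computed
    from midpoints between markers fall exactly on tile edges."""
    s = config.marker_spacing_bp
    return np.arange(config.n_markers_per_chrom) * s + s // 2


def gene_layout(config: SimulationConfig) -> pd.DataFrame:
    """Contiguous non-overlapping gene spans tiling each chromosome (bp).

    Genes are laid out in genome order; the gene grid is finer than the
    marker grid when n_genes exceeds the marker count.
    """
    chroms = _chrom_names(config)
    L = config.n_markers_per_chrom * config.marker_spacing_bp
    per = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per[i] += 1
    rows = []
    gid = 0
    for chrom, n in zip(chroms, per):
        bounds = np.linspace(0, L, n + 1).astype(np.int64)
        for k in range(n):
            gid += 1
            rows.append((f"G{gid:05d}", chrom,
                         int(bounds[k]), int(bounds[k + 1])))
    df = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])
    return df.set_index("gene")


def _plant_events(rng, config: SimulationConfig) -> list[tuple[int, int, float]]:
    """Non-overlapping (start, end, mean) copy-number events on one
    chromosome, each flanked by >= 10 background markers so that every
    resulting true segment has >= 10 markers (unless the configuration
    requests shorter events)."""
    n = config.n_markers_per_chrom
    gap = min(10, config.min_event_markers)
    n_events = rng.poisson(config.segment_event_rate)
    placed: list[tuple[int, int, float]] = []
    for _ in range(n_events):
        for _attempt in range(100):
            length = int(rng.integers(config.min_event_markers,
                                      config.max_event_markers + 1))
            if length > n - 2 * gap:
                continue
            start = int(rng.integers(gap, n - gap - length + 1))
            end = start + length
            if all(end + gap <= s or e + gap <= start
                   for s, e, _ in placed):
                if rng.random() < config.p_gain:
                    mean = float(rng.choice(config.gain_levels))
                else:
                    mean = float(rng.choice(config.loss_levels))
                placed.append((start, end, mean))
                break
    return sorted(placed)


def _tile_segments(events, n_markers) -> list[tuple[int, int, float]]:
    """Complete the event list into a tiling of [0, n_markers)."""
    segs = []
    cursor = 0
    for start, end, mean in events:
        if start > cursor:
            segs.append((cursor, start, 0.0))
        segs.append((start, end, mean))
        cursor = end
    if cursor < n_markers:
        segs.append((cursor, n_markers, 0.0))
    return segs


def generate_cgh_profile(config: SimulationConfig, sample_index: int
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Marker log2 ratios plus true segment structure for one cell line.

    Returns
    -------
    profile : DataFrame
        Columns ``chrom``, ``position``, ``value``.
    true_segments : DataFrame
        Columns ``chrom``, ``start``, ``end`` (marker indices, half-open)
        and ``mean_log2``; segments tile each chromosome.
    """
    config.validate()
    if not 0 <= sample_index < config.n_pairs:
        raise IndexError(
            f"sample_index {sample_index} out of range [0, {config.n_pairs})")
    rng = _rng(config, _DOM_CGH, sample_index)
    positions = _marker_positions(config)
    prof_rows, seg_rows = [], []
    for chrom in _chrom_names(config):
        events = _plant_events(rng, config)
        segs = _tile_segments(events, config.n_markers_per_chrom)
        truth = np.zeros(config.n_markers_per_chrom)
        for start, end, mean in segs:
            truth[start:end] = mean
            seg_rows.append((chrom, start, end, mean))
        noise = rng.standard_normal(config.n_markers_per_chrom)
        values = truth + config.noise_sd_cgh * noise
        prof_rows.append(pd.DataFrame(
            {"chrom": chrom, "position": positions, "value": values}))
    profile = pd.concat(prof_rows, ignore_index=True)
    true_segments = pd.DataFrame(
        seg_rows, columns=["chrom", "start", "end", "mean_log2"])
    return profile, true_segments


def _true_gene_cn(config, genes: pd.DataFrame,
                  true_segments: pd.DataFrame) -> np.ndarray:
    """bp-weighted true log2 ratio per gene for one sample."""
    s = config.marker_spacing_bp
    out = np.zeros(len(genes))
    for chrom, seg_sub in true_segments.groupby("chrom", sort=False):
        mask = (genes["chrom"] == chrom).to_numpy()
        ga = genes.loc[mask, "start"].to_numpy(float)
        gb = genes.loc[mask, "end"].to_numpy(float)
        acc = np.zeros(mask.sum())
        for _, row in seg_sub.iterrows():
            lo, hi = row["start"] * s, row["end"] * s
            ov = np.clip(np.minimum(gb, hi) - np.maximum(ga, lo), 0, None)
            acc += ov * row["mean_log2"]
        out[mask] = acc / (gb - ga)
    return out


def generate_cohort(config: SimulationConfig
                    ) -> tuple[ExpressionMatrix, ExpressionMatrix,
                               ExpressionMatrix, MarkerTrack, SyntheticTruth]:
    """Generate the full synthetic study.

    Returns ``(tm, cm, metastases, marker_track, truth)``. The marker
    track columns are the CM sample names (aCGH is run on the cell
    lines). Identical config and seed give byte-identical outputs.
    """
    config.validate()
    rng = _rng(config, _DOM_LAYOUT)
    genes = gene_layout(config)
    n_genes = config.n_genes

    # --- category flags
    n_dos = round(config.frac_dosage * n_genes)
    n_str = round(config.frac_stromal * n_genes)
    n_snd = round(config.frac_stable_nondosage * n_genes)
    order = rng.permutation(n_genes)
    idx_dos = order[:n_dos]
    idx_str = order[n_dos:n_dos + n_str]
    idx_snd = order[n_dos + n_str:n_dos + n_str + n_snd]
    flags = pd.DataFrame(False, index=genes.index,
                         columns=["dosage_driven", "stromal",
                                  "stable_nondosage", "class_marker_A",
                                  "class_marker_B", "class_marker_C"])
    flags.iloc[idx_dos, 0] = True
    flags.iloc[idx_str, 1] = True
    flags.iloc[idx_snd, 2] = True
    n_class = n_dos // 4
    flags.iloc[idx_dos[:n_class], 3] = True
    flags.iloc[idx_dos[n_class:2 * n_class], 4] = True
    flags.iloc[idx_dos[2 * n_class:3 * n_class], 5] = True

    baseline = config.baseline_mean + config.baseline_sd * \
        rng.standard_normal(n_genes)
    slope = np.zeros(n_genes)
    j = config.dosage_slope_jitter
    slope[idx_dos] = config.dosage_slope * rng.uniform(1 - j, 1 + j, n_dos)

    # --- sample naming
    patients = [f"P{i + 1:02d}" for i in range(config.n_pairs)]
    tm_names = [f"{p}_TM" for p in patients]
    cm_names = [f"{p}_CM" for p in patients]
    met_names = [f"M{i + 1:03d}" for i in range(config.n_metastases)]
    pairing = pd.DataFrame({"tm": tm_names, "cm": cm_names},
                           index=pd.Index(patients, name="patient"))

    # --- aCGH profiles and true gene-level CN
    marker_cols, seg_frames = {}, []
    gene_cn = np.zeros((n_genes, config.n_pairs))
    positions = _marker_positions(config)
    for i, name in enumerate(cm_names):
        profile, true_segments = generate_cgh_profile(config, i)
        marker_cols[name] = profile["value"].to_numpy()
        ts = true_segments.copy()
        ts.insert(0, "sample", name)
        seg_frames.append(ts)
        gene_cn[:, i] = _true_gene_cn(config, genes, true_segments)
    chrom_col = np.repeat(_chrom_names(config), config.n_markers_per_chrom)
    track_table = pd.DataFrame({"chrom": chrom_col,
                                "position": np.tile(positions,
                                                    config.n_chromosomes)})
    for name in cm_names:
        track_table[name] = marker_cols[name]
    track = MarkerTrack(track_table)
    true_segments_all = pd.concat(seg_frames, ignore_index=True)
    gene_cn_df = pd.DataFrame(gene_cn, index=genes.index, columns=cm_names)

    # --- paired TM/CM expression
    erng = _rng(config, _DOM_EXPR)
    n, p = n_genes, config.n_pairs
    intrinsic = baseline[:, None] + slope[:, None] * gene_cn
    z = np.zeros((n, p))
    z[idx_snd] = config.stable_signal_sd * \
        erng.standard_normal((len(idx_snd), p))
    intrinsic = intrinsic + z
    cm_vals = intrinsic + config.noise_sd_expr * erng.standard_normal((n, p))
    tm_vals = intrinsic + config.noise_sd_expr * erng.standard_normal((n, p))
    # stromal: independent TM-only signal; near-constant CM
    stromal_sig = config.stable_signal_sd * \
        erng.standard_normal((len(idx_str), p))
    tm_vals[idx_str] = (baseline[idx_str, None] + stromal_sig
                        + config.noise_sd_expr
                        * erng.standard_normal((len(idx_str), p)))
    cm_vals[idx_str] = (baseline[idx_str, None]
                        + 0.25 * config.noise_sd_expr
                        * erng.standard_normal((len(idx_str), p)))

    tm = ExpressionMatrix(pd.DataFrame(tm_vals, index=genes.index,
                                       columns=tm_names), "TM", pairing)
    cm = ExpressionMatrix(pd.DataFrame(cm_vals, index=genes.index,
                                       columns=cm_names), "CM", pairing)

    # --- metastasis cohort with class and batch structure
    mrng = _rng(config, _DOM_MET)
    m = config.n_metastases
    u = mrng.random(m)
    classes = np.where(u < config.frac_class_c, "C",
                       np.where(mrng.random(m) < 0.5, "A", "B"))
    batches = mrng.integers(config.n_batches, size=m)
    e = config.class_effect
    shift = np.zeros((n, m))
    a_mask = flags["class_marker_A"].to_numpy()
    b_mask = flags["class_marker_B"].to_numpy()
    c_mask = flags["class_marker_C"].to_numpy()
    for si, cls in enumerate(classes):
        if cls == "A":
            shift[a_mask, si] = e
        elif cls == "B":
            shift[b_mask, si] = e
        else:
            # intermediate: half of both polar programs, plus a weak
            # C-specific signature that makes the subcluster coherent
            shift[a_mask, si] = e / 2.0
            shift[b_mask, si] = e / 2.0
            shift[c_mask, si] = e / 2.0
    batch_effect = config.batch_sd * \
        mrng.standard_normal((n, config.n_batches))
    met_vals = (baseline[:, None] + shift + batch_effect[:, batches]
                + config.noise_sd_expr * mrng.standard_normal((n, m)))
    # metastases are tissues: stromal genes vary there as in TMs
    met_vals[idx_str] += config.stable_signal_sd * \
        mrng.standard_normal((len(idx_str), m))
    mets = ExpressionMatrix(pd.DataFrame(met_vals, index=genes.index,
                                         columns=met_names), "metastasis")

    truth_genes = pd.concat([genes, flags], axis=1)
    truth_genes["dosage_slope"] = slope
    truth_genes["baseline"] = baseline
    truth = SyntheticTruth(
        genes=truth_genes,
        sample_class=pd.Series(classes, index=met_names, name="class"),
        batch=pd.Series([f"B{b + 1}" for b in batches], index=met_names,
                        name="batch"),
        segments=true_segments_all,
        gene_cn=gene_cn_df,
    )
    return tm, cm, mets, track, truth
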