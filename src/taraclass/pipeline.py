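"""End-to-end pipeline orchestration.

Stage order follows the analysis narrative: TM/CM stable-gene screen,
aCGH segmentation and gene-level copy number of the cell lines,
delegate discovery by copy-number/expression concordance, then
unsupervised classification of the metastasis cohort on the delegates.
Every intermediate artifact is written in a re-readable text format and
a machine-readable summary JSON closes the run.
"""
from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import io as tio
from .classify import (adjusted_rand_index, class_de, cluster_cohort,
                       pca_embed, top_discriminants)
from .containers import ExpressionMatrix
from .delegates import (cn_expression_correlation, concordance_by_bin,
                        define_delegates, modal_cn_category)
from .screen import (pairwise_gene_correlation, select_stable,
                     stable_set_summary)
from .segmentation import (call_states, gene_copy_number_matrix,
                           segment_profile)
from .synthetic import SimulationConfig, generate_cohort

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage and cause."""


def write_cohort(out_dir, tm, cm, mets, track, truth, sim_config) -> None:
    """Write a generated cohort and its truth tables as text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tio.write_expression(tm, out / "tm_expression.tsv")
    tio.write_expression(cm, out / "cm_expression.tsv")
    tio.write_expression(mets, out / "metastasis_expression.tsv")
    tio.write_pairing(tm.pairing, out / "pairing.tsv")
    tio.write_marker_track(track, out / "markers.tsv")
    tio.write_bed(truth.genes[["chrom", "start", "end"]],
                  out / "genes.bed")
    truth.genes.reset_index(names="gene").to_csv(
        out / "truth_genes.tsv", sep="\t", index=False)
    truth.segments.to_csv(out / "truth_segments.tsv", sep="\t", index=False)
    pd.DataFrame({"class": truth.sample_class,
                  "batch": truth.batch}).reset_index(names="sample").to_csv(
        out / "truth_samples.tsv", sep="\t", index=False)
    tio.write_json(sim_config.to_dict(), out / "sim_config.json")


def run_pipeline(config: tio.RunConfig,
                 sim_config: SimulationConfig | None = None) -> dict:
    """Execute the full pipeline and return the summary dict.

    With ``config.simulate`` (the default) a synthetic cohort is
    generated first and recovery metrics against the planted truth are
    included in the summary; otherwise the configured input paths are
    loaded. The run is fully reproducible given the seed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed,
                     "thresholds": {
                         "min_markers": config.min_markers,
                         "snr": config.snr,
                         "amp_threshold": config.amp_threshold,
                         "del_threshold": config.del_threshold,
                         "p_stable": config.p_stable,
                         "p_stable_strict": config.p_stable_strict,
                         "delegate_alpha": config.delegate_alpha,
                         "de_cutoff": config.de_cutoff,
                         "top_n": config.top_n,
                         "k_classes": config.k_classes,
                     }}
    logger.info("thresholds: %s", summary["thresholds"])

    truth = None
    try:
        if config.simulate:
            sim = sim_config or SimulationConfig(seed=config.seed)
            tm, cm, mets, track, truth = generate_cohort(sim)
            write_cohort(out / "cohort", tm, cm, mets, track, truth, sim)
            genes = truth.genes[["chrom", "start", "end"]]
            batch = truth.batch
        else:
            pairing = tio.read_pairing(config.pairing_path)
            tm = tio.read_expression(config.tm_path, "TM", pairing)
            cm = tio.read_expression(config.cm_path, "CM", pairing)
            mets = tio.read_expression(config.cohort_path, "metastasis")
            track = tio.read_marker_track(config.markers_path)
            genes = tio.read_bed(config.genes_path)
            batch = None
            if config.batch_path:
                b = pd.read_csv(config.batch_path, sep="\t")
                batch = pd.Series(b.iloc[:, 1].to_numpy(),
                                  index=b.iloc[:, 0], name="batch")
    except Exception as exc:
        raise StageError(f"input stage failed: {exc}") from exc

    # --- stable-gene screen
    try:
        records = pairwise_gene_correlation(tm, cm)
        stable = select_stable(records, config.p_stable)
        stable_strict = select_stable(records, config.p_stable_strict)
        records.reset_index(names="gene").to_csv(
            out / "tmcm_correlations.tsv", sep="\t", index=False)
        tio.write_gene_list(stable, out / "stable_genes.tsv")
        tio.write_gene_list(stable_strict, out / "stable_genes_strict.tsv")
        summary["n_stable"] = int(len(stable))
        summary["n_stable_strict"] = int(len(stable_strict))
        summary["stable_min_r"] = stable_set_summary(records,
                                                     stable)["min_r"]
    except Exception as exc:
        raise StageError(f"screen stage failed: {exc}") from exc

    # --- segmentation and gene-level CN
    try:
        seg_frames = []
        for sample in track.samples:
            seg = segment_profile(track, sample, config.min_markers,
                                  config.snr)
            seg_frames.append(call_states(seg, config.amp_threshold,
                                          config.del_threshold))
        segments = pd.concat(seg_frames, ignore_index=True)
        tio.write_seg(segments, out / "segments.seg")
        cn_matrix, per_sample_cn = gene_copy_number_matrix(segments, genes)
        tio.write_gene_cn(per_sample_cn, out / "gene_cn.tsv")
        summary["n_segments"] = int(len(segments))
    except Exception as exc:
        raise StageError(f"segmentation stage failed: {exc}") from exc

    # --- delegate discovery
    try:
        cn_records = cn_expression_correlation(cm, cn_matrix)
        category = modal_cn_category(per_sample_cn)
        rec, del_summary = define_delegates(
            stable, cn_records, tmcm_records=records,
            cn_category=category, alpha=config.delegate_alpha)
        bins, trend = concordance_by_bin(rec)
        delegates = rec.index[rec["is_delegate"]]
        rec.reset_index(names="gene").to_csv(out / "delegate_records.tsv",
                                             sep="\t", index=False)
        bins.to_csv(out / "concordance_bins.tsv", sep="\t", index=False)
        tio.write_gene_list(delegates, out / "delegate_genes.tsv")
        summary["delegates"] = del_summary
        summary["concordance_trend"] = None if pd.isna(trend) else \
            float(trend)
    except Exception as exc:
        raise StageError(f"delegate stage failed: {exc}") from exc

    # --- classification
    try:
        assignment, _ = cluster_cohort(mets, delegates, config.k_classes)
        assignment.reset_index(names="sample").to_csv(
            out / "tara_assignments.tsv", sep="\t", index=False)
        comparisons = class_de(mets, assignment, batch, config.de_cutoff)
        comparisons.reset_index(names="gene").to_csv(
            out / "class_comparisons.tsv", sep="\t", index=False)
        top = top_discriminants(comparisons, config.top_n)
        tio.write_gene_list(top, out / "top_discriminants.tsv")
        reshuffled, _ = cluster_cohort(mets, top, config.k_classes)
        coords, evr = pca_embed(mets)
        coords.reset_index(names="sample").to_csv(
            out / "pca_coordinates.tsv", sep="\t", index=False)
        sizes = assignment["tara_class"].value_counts().to_dict()
        summary["class_sizes"] = {k: int(v) for k, v in sizes.items()}
        summary["n_de_significant"] = int(comparisons["significant"].sum())
        summary["pca_explained_variance"] = [float(v) for v in evr]
    except Exception as exc:
        raise StageError(f"classification stage failed: {exc}") from exc

    # --- recovery metrics when truth is available
    if truth is not None:
        g = truth.genes
        planted_stable = g.index[g["dosage_driven"] | g["stable_nondosage"]]
        planted_delegate = g.index[g["dosage_driven"]]
        summary["recovery"] = {
            "stable_recall": _recall(stable, planted_stable),
            "stable_precision": _precision(stable, planted_stable),
            "delegate_recall": _recall(delegates, planted_delegate),
            "delegate_precision": _precision(delegates, planted_delegate),
            "tara_ari": adjusted_rand_index(
                truth.sample_class, assignment["tara_class"]),
            "tara_ari_top_discriminants": adjusted_rand_index(
                truth.sample_class, reshuffled["tara_class"]),
        }

    tio.write_json(summary, out / "summary.json")
    logger.info("pipeline complete; summary written to %s",
                out / "summary.json")
    return summary


def _recall(found, planted) -> float:
    planted = set(planted)
    if not planted:
        return float("nan")
    return len(set(found) & planted) / len(planted)


def _precision(found, planted) -> float:
    found = set(found)
    if not found:
        return float("nan")
    return len(found & set(planted)) / len(found)
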