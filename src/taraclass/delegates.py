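"""Genomic-delegate discovery: copy-number/expression concordance.

A "genomic delegate" is a gene that (a) is stably expressed between
tumors and their derived cell lines and (b) whose cell-line expression
correlates positively and significantly with its own gene-level DNA
log2 ratio across the cell lines — the transcriptional footprint of the
genome. The module also produces the concordance-vs-stability curve:
genes are ranked into 0.1-wide intervals of TM/CM correlation (top
interval [0.5, 1.0] pooled) and, following the sequential-subset
construction, the percent of copy-number-concordant genes is reported
both per interval and cumulatively from the most stable set downward.
The trend statistic is the gene-count-weighted Pearson correlation
between set rank and the cumulative percentage: high stability
predicting high concordance gives a trend near 1 with a plateau at the
top, while the percentage declines gradually for lower-ranking sets.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .screen import _pearson_rows, correlation_pvalue

CN_CATEGORIES = ("gain", "deletion", "unchanged")
_STATE_TO_CATEGORY = {"amplified": "gain", "deleted": "deletion",
                      "unchanged": "unchanged"}


def cn_expression_correlation(cm: ExpressionMatrix,
                              gene_cn: pd.DataFrame) -> pd.DataFrame:
    """Per-gene Pearson correlation of CM expression with gene-level CN.

    ``gene_cn`` is the weighted-log2 matrix (genes x cell-line samples).
    Samples are aligned by name; genes present in the expression matrix
    but absent from the CN table are flagged in the reconciliation
    column ``in_cn_table`` and get undefined r. Genes whose CN never
    varies across samples (never imbalanced) have undefined r and count
    as non-concordant.
    """
    samples = [s for s in cm.samples if s in gene_cn.columns]
    if len(samples) < 3:
        raise ValueError(
            f"need >= 3 samples with both expression and CN, "
            f"got {len(samples)}")
    common = cm.genes.intersection(gene_cn.index)
    expr = cm.values.loc[:, samples].to_numpy(float)
    cn = np.full(expr.shape, np.nan)
    locs = cm.genes.get_indexer(common)
    cn[locs] = gene_cn.loc[common, samples].to_numpy(float)
    r, n = _pearson_rows(expr, cn)
    p = correlation_pvalue(r, n)
    out = pd.DataFrame({"r_cn": r, "p_cn": p, "n_cn": n,
                        "cn_defined": ~np.isnan(r)}, index=cm.genes)
    out["in_cn_table"] = cm.genes.isin(gene_cn.index)
    return out


def modal_cn_category(per_sample_cn: dict[str, pd.DataFrame]) -> pd.Series:
    """Modal called state per gene across samples, as a CN category.

    Uses the per-gene dominant state of each sample; ties between
    categories are broken gain > deletion > unchanged.
    """
    counts = None
    for tab in per_sample_cn.values():
        dom = tab["dominant_state"].map(_STATE_TO_CATEGORY)
        oh = pd.get_dummies(dom).reindex(columns=CN_CATEGORIES,
                                         fill_value=0).astype(int)
        counts = oh if counts is None else counts + oh
    arr = counts[list(CN_CATEGORIES)].to_numpy()
    modal = np.array(CN_CATEGORIES)[np.argmax(arr, axis=1)]
    return pd.Series(modal, index=counts.index, name="cn_category")


def define_delegates(stable: pd.Index | set,
                     cn_records: pd.DataFrame,
                     tmcm_records: pd.DataFrame | None = None,
                     cn_category: pd.Series | None = None,
                     alpha: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Intersect the stable set with the CN-concordant set.

    Returns the per-gene delegate record table and a summary dict with
    the delegate count, stable count, percentage (rounded to the nearest
    integer) and the delegate composition by CN category.
    """
    records = cn_records.copy()
    stable = pd.Index(stable)
    records["is_stable"] = records.index.isin(stable)
    records["is_concordant"] = (records["cn_defined"]
                                & (records["r_cn"] > 0)
                                & (records["p_cn"] < alpha)).fillna(False)
    records["is_delegate"] = records["is_stable"] & records["is_concordant"]
    if tmcm_records is not None:
        records["r_tmcm"] = tmcm_records["r"].reindex(records.index)
        records["tmcm_defined"] = tmcm_records["defined"].reindex(
            records.index).fillna(False)
    if cn_category is not None:
        records["cn_category"] = cn_category.reindex(records.index)

    n_del = int(records["is_delegate"].sum())
    n_stable = int(records["is_stable"].sum())
    pct = round(100.0 * n_del / n_stable) if n_stable else 0
    summary = {"n_delegates": n_del, "n_stable": n_stable,
               "pct_of_stable": int(pct)}
    if cn_category is not None and n_del:
        summary["cn_composition"] = delegate_cn_composition(records)
    summary["reconciliation"] = reconciliation(records)
    return records, summary


def reconciliation(records: pd.DataFrame) -> dict:
    """Partition the gene universe into delegate / stable-only /
    concordant-only / neither / undefined (each gene exactly once)."""
    undefined = ~records["cn_defined"] & ~records["is_stable"]
    delegate = records["is_delegate"]
    stable_only = records["is_stable"] & ~records["is_concordant"]
    concordant_only = records["is_concordant"] & ~records["is_stable"]
    neither = ~(delegate | stable_only | concordant_only | undefined)
    out = {"delegate": int(delegate.sum()),
           "stable_only": int(stable_only.sum()),
           "concordant_only": int(concordant_only.sum()),
           "neither": int(neither.sum()),
           "undefined": int(undefined.sum())}
    assert sum(out.values()) == len(records)
    return out


def _bin_edges(bin_width: float = 0.1) -> np.ndarray:
    """Half-open edges partitioning [-1, 1] with the top [0.5, 1] pooled."""
    edges = np.arange(-1.0, 0.5 + bin_width / 2, bin_width)
    return np.append(edges, 1.0 + 1e-9)


def _weighted_pearson(x, y, w) -> float:
    x, y, w = (np.asarray(v, float) for v in (x, y, w))
    mx = np.average(x, weights=w)
    my = np.average(y, weights=w)
    cov = np.average((x - mx) * (y - my), weights=w)
    vx = np.average((x - mx) ** 2, weights=w)
    vy = np.average((y - my) ** 2, weights=w)
    if vx <= 0 or vy <= 0:
        return np.nan
    return float(cov / np.sqrt(vx * vy))


def concordance_by_bin(records: pd.DataFrame, bin_width: float = 0.1,
                       alpha: float | None = None
                       ) -> tuple[pd.DataFrame, float]:
    """Concordance-vs-stability curve over 0.1-wide TM/CM correlation
    intervals.

    ``records`` must carry ``r_tmcm`` and ``is_concordant`` (genes with
    undefined CN correlation stay in denominators as non-concordant;
    genes with undefined r_tmcm are excluded). Returns the interval
    table — per-interval gene and concordant counts and percentage, plus
    the cumulative-from-top set size and percentage — and the trend
    statistic: the Pearson correlation between set rank and cumulative
    percent concordant across non-empty intervals, weighted by the
    number of genes each interval contributes. NaN when fewer than two
    non-empty intervals or the percentages have zero variance.
    """
    if "r_tmcm" not in records:
        raise ValueError("records must carry r_tmcm (pass tmcm_records "
                         "to define_delegates)")
    ok = records["r_tmcm"].notna()
    r = records.loc[ok, "r_tmcm"].to_numpy(float)
    conc = records.loc[ok, "is_concordant"].to_numpy(bool)
    edges = _bin_edges(bin_width)
    idx = np.clip(np.digitize(r, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 2, -1, -1):  # top set first
        m = idx == b
        rows.append({
            "bin_low": edges[b],
            "bin_high": min(edges[b + 1], 1.0),
            "rank": b + 1,
            "n_genes": int(m.sum()),
            "n_concordant": int(conc[m].sum()),
        })
    table = pd.DataFrame(rows)
    with np.errstate(invalid="ignore", divide="ignore"):
        table["pct_concordant"] = np.where(
            table["n_genes"] > 0,
            100.0 * table["n_concordant"] / table["n_genes"].replace(0, 1),
            np.nan)
    table["cum_n_genes"] = table["n_genes"].cumsum()
    table["cum_pct_concordant"] = np.where(
        table["cum_n_genes"] > 0,
        100.0 * table["n_concordant"].cumsum()
        / table["cum_n_genes"].replace(0, 1), np.nan)
    table = table.sort_values("rank", ignore_index=True)

    nonempty = table[table["n_genes"] > 0]
    if len(nonempty) < 2:
        trend = np.nan
    else:
        trend = _weighted_pearson(nonempty["rank"],
                                  nonempty["cum_pct_concordant"],
                                  nonempty["n_genes"])
    return table, trend


def largest_remainder_percents(counts) -> list[int]:
    """Integer percentages summing to exactly 100 (largest-remainder)."""
    counts = np.asarray(counts, float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    exact = 100.0 * counts / total
    floors = np.floor(exact).astype(int)
    short = 100 - floors.sum()
    order = np.argsort(-(exact - floors), kind="stable")
    floors[order[:short]] += 1
    return [int(v) for v in floors]


def delegate_cn_composition(records: pd.DataFrame) -> dict[str, int]:
    """Integer-percent composition of delegates by CN category
    (gain/deletion/unchanged), largest-remainder rounded to sum 100."""
    dele = records[records["is_delegate"]]
    if "cn_category" not in dele:
        raise ValueError("records must carry cn_category")
    counts = [int((dele["cn_category"] == c).sum()) for c in CN_CATEGORIES]
    if sum(counts) == 0:
        return {c: 0 for c in CN_CATEGORIES}
    pcts = largest_remainder_percents(counts)
    return dict(zip(CN_CATEGORIES, pcts))
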