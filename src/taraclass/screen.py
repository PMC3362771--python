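"""Gene-wise TM/CM concordance screening and stable-set extraction.

For each gene the Pearson correlation r between its expression in the
tumor metastases (TM) and the autologous cell lines (CM) across patient
pairs is computed, with a two-sided p-value from the exact t transform
t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom (at n = 15 pairs,
r ~ 0.514 corresponds to p ~ 0.05). "Stable" genes are those with
p below a cutoff AND r > 0 — a significantly negative TM/CM correlation
is not concordant expression. A seeded random non-correlated control set
(r < 0.1) and a reference-list enrichment ratio (the housekeeping check)
complete the screen.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix


def _pearson_rows(a: np.ndarray, b: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r and per-row pair count, NaN-aware
    (complete-pair deletion)."""
    ok = np.isfinite(a) & np.isfinite(b)
    n = ok.sum(axis=1)
    a = np.where(ok, a, 0.0)
    b = np.where(ok, b, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = a.sum(1) / n
        mb = b.sum(1) / n
        ac = np.where(ok, a - ma[:, None], 0.0)
        bc = np.where(ok, b - mb[:, None], 0.0)
        cov = (ac * bc).sum(1)
        va = (ac * ac).sum(1)
        vb = (bc * bc).sum(1)
        # zero-variance genes: compare against the rms scale so values
        # constant up to float rounding are still flagged undefined
        va = np.where(va <= 1e-20 * (a * a).sum(1), 0.0, va)
        vb = np.where(vb <= 1e-20 * (b * b).sum(1), 0.0, vb)
        den = np.sqrt(va * vb)
        r = np.where(den > 0, cov / den, np.nan)
    r = np.where(n >= 3, r, np.nan)
    return r, n


def correlation_pvalue(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p from the exact t transform with n-2 df."""
    r = np.asarray(r, float)
    n = np.asarray(n, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.clip(1.0 - r * r, 1e-300, None)
        t = r * np.sqrt((n - 2) / denom)
        p = 2.0 * stats.t.sf(np.abs(t), np.clip(n - 2, 1, None))
    return np.where(np.isnan(r), np.nan, np.clip(p, 0.0, 1.0))


def pairwise_gene_correlation(tm: ExpressionMatrix, cm: ExpressionMatrix,
                              pairing: pd.DataFrame | None = None
                              ) -> pd.DataFrame:
    """Per-gene Pearson concordance between paired TM and CM expression.

    Returns a DataFrame indexed by gene with columns ``r``, ``p``, ``n``
    and ``defined`` (False for genes with zero variance in either
    vector, whose r is undefined and which are excluded from
    selections).
    """
    if pairing is None:
        pairing = tm.pairing if tm.pairing is not None else cm.pairing
    if pairing is None:
        raise ValueError("a TM<->CM pairing map is required")
    if not tm.genes.equals(cm.genes):
        raise ValueError("TM and CM matrices must share an identical "
                         "gene index")
    if len(pairing) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(pairing)}")
    a = tm.values[list(pairing["tm"])].to_numpy(float)
    b = cm.values[list(pairing["cm"])].to_numpy(float)
    r, n = _pearson_rows(a, b)
    p = correlation_pvalue(r, n)
    return pd.DataFrame({"r": r, "p": p, "n": n,
                         "defined": ~np.isnan(r)}, index=tm.genes)


def select_stable(records: pd.DataFrame, p_cutoff: float = 0.05
                  ) -> pd.Index:
    """Genes with defined r, p < p_cutoff and r > 0 (direction rule)."""
    if not 0.0 < p_cutoff < 1.0:
        raise ValueError("p_cutoff must be in (0, 1)")
    sel = records["defined"] & (records["p"] < p_cutoff) & (records["r"] > 0)
    return records.index[sel.fillna(False)]


def stable_set_summary(records: pd.DataFrame, selected: pd.Index) -> dict:
    """Size of a stable set and the implied minimal r among its genes."""
    out = {"n": int(len(selected))}
    out["min_r"] = (float(records.loc[selected, "r"].min())
                    if len(selected) else None)
    return out


def select_noncorrelated_control(records: pd.DataFrame,
                                 r_max: float = 0.1, n: int = 3000,
                                 seed: int = 0) -> pd.Index:
    """Seeded uniform sample of ``n`` genes with defined r < r_max."""
    eligible = records.index[(records["defined"]
                              & (records["r"] < r_max)).fillna(False)]
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} eligible genes (r < {r_max}), "
            f"cannot sample {n}")
    rng = np.random.default_rng(seed)
    take = rng.choice(len(eligible), size=n, replace=False)
    return eligible[np.sort(take)]


def enrichment_ratio(selected, reference, universe) -> dict:
    """Reference-list enrichment of a selected gene set vs the universe.

    Gene IDs are matched case-insensitively. Returns counts, the
    percentage of the selected set (and of the universe) that is in the
    reference list (one-decimal rounding for reporting), and their
    ratio (None when the universe percentage is zero).
    """
    selected = list(selected)
    universe = list(universe)
    if not selected or not universe:
        raise ValueError("selected and universe must be non-empty")
    ref = {str(g).lower() for g in reference}
    sel_hit = sum(1 for g in selected if str(g).lower() in ref)
    uni_hit = sum(1 for g in universe if str(g).lower() in ref)
    pct_sel = 100.0 * sel_hit / len(selected)
    pct_uni = 100.0 * uni_hit / len(universe)
    ratio = (pct_sel / pct_uni) if pct_uni > 0 else None
    return {
        "count_in_selected": sel_hit,
        "count_in_universe": uni_hit,
        "pct_of_selected": round(pct_sel, 1),
        "pct_of_universe": round(pct_uni, 1),
        "ratio": ratio,
        "n_selected": len(selected),
        "n_universe": len(universe),
    }


def reporting_percentage(count: int, denominator: int) -> float:
    """Percentage at one-decimal reporting precision.

    The denominator is the set size actually used, stated explicitly:
    e.g. 19 reference genes in a 1,006-gene set reports 1.9.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * count / denominator, 1)
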