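"""Unsupervised TARA classification of the metastasis cohort.

The cohort is clustered on the delegate genes with average-linkage
agglomerative clustering on a correlation distance (1 - Pearson between
samples over per-gene z-scored expression) and the tree is cut at k
clusters. The two clusters whose centroids are furthest apart become
the polar classes A and B; everything else is the intermediate class C.
Class comparison fits, per gene, a linear model with a class indicator
plus additive batch terms (two-sided t test on the class coefficient,
significant at p < 0.001); with a single batch this reduces exactly to
the classic equal-variance two-sample t test. Top discriminant
selection, PCA embedding for confirmation and generic signature scoring
complete the module.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)


def _zscore_genes(values: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score across samples; zero-variance genes dropped."""
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d zero-variance genes", dropped)
    v = values.loc[keep]
    return v.sub(v.mean(axis=1), axis=0).div(sd[keep], axis=0)


def cluster_cohort(metastases: ExpressionMatrix, genes, k: int = 3
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    """Cluster the cohort on a gene set and assign TARA classes.

    Parameters
    ----------
    metastases : ExpressionMatrix
        Cohort matrix.
    genes : sequence
        Gene set to cluster on (e.g. the delegates); genes missing from
        the matrix are logged and dropped.
    k : int
        Number of clusters to cut; with k = 3 the two most separated
        clusters are labelled A and B and the remainder C.

    Returns
    -------
    (assignment, linkage) where ``assignment`` is a DataFrame indexed by
    sample with columns ``cluster``, ``tara_class``, ``linkage_order``
    and ``silhouette``, and ``linkage`` is the scipy linkage matrix.
    """
    genes = pd.Index(genes)
    present = genes.intersection(metastases.genes)
    missing = len(genes) - len(present)
    if missing:
        logger.warning("%d requested genes absent from cohort matrix",
                       missing)
    if len(present) == 0:
        raise ValueError("none of the requested genes are present")
    n_samples = len(metastases.samples)
    if k > n_samples:
        raise ValueError(f"k={k} exceeds {n_samples} samples")

    z = _zscore_genes(metastases.values.loc[present])
    x = z.to_numpy(float).T                      # samples x genes
    corr = np.corrcoef(x)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False),
                             method="average")
    clusters = hierarchy.fcluster(link, t=k, criterion="maxclust")
    order = hierarchy.leaves_list(link)
    leaf_rank = np.empty(n_samples, int)
    leaf_rank[order] = np.arange(n_samples)

    # polar labels: the two clusters with maximal inter-centroid distance
    ids = np.unique(clusters)
    centroids = {c: x[clusters == c].mean(axis=0) for c in ids}
    best, best_d = None, -1.0
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ca, cb = centroids[a], centroids[b]
            num = np.dot(ca - ca.mean(), cb - cb.mean())
            den = (np.linalg.norm(ca - ca.mean())
                   * np.linalg.norm(cb - cb.mean()))
            d = 1.0 - (num / den if den > 0 else 0.0)
            if d > best_d + 1e-12:
                best, best_d = (a, b), d
    labels = {}
    if best is not None:
        # polarity is arbitrary; fix it independent of sample order:
        # A = the larger polar cluster, ties by smallest member name
        a, b = best
        sample_names = np.asarray(metastases.samples)

        def _key(c):
            members = sample_names[clusters == c]
            return (-len(members), min(members))

        if _key(b) < _key(a):
            a, b = b, a
        labels[a], labels[b] = "A", "B"
    tara = np.array([labels.get(c, "C") for c in clusters])

    sil = _silhouette(dist, clusters)
    assignment = pd.DataFrame({
        "cluster": clusters,
        "tara_class": tara,
        "linkage_order": leaf_rank,
        "silhouette": sil,
    }, index=metastases.samples)
    return assignment, link


def _silhouette(dist: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Silhouette values from a precomputed distance matrix."""
    n = len(labels)
    out = np.zeros(n)
    ids = np.unique(labels)
    if len(ids) < 2:
        return out
    for i in range(n):
        own = labels[i]
        a_mask = (labels == own)
        n_own = a_mask.sum()
        if n_own <= 1:
            out[i] = 0.0
            continue
        a = dist[i, a_mask].sum() / (n_own - 1)
        b = min(dist[i, labels == c].mean() for c in ids if c != own)
        out[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return out


def class_de(metastases: ExpressionMatrix, assignment: pd.DataFrame,
             batch: pd.Series | None = None, p_cutoff: float = 0.001,
             classes: tuple[str, str] = ("A", "B")) -> pd.DataFrame:
    """Per-gene class comparison with additive batch adjustment.

    Fits, for every gene, expression ~ intercept + class + batch
    (fixed-effects dummies) over the samples of the two compared
    classes, and tests the class coefficient with a two-sided t test.
    With a single batch this is exactly the equal-variance two-sample
    t test. A batch entirely contained in one class is confounded; a
    warning is logged and the table carries a ``confounded`` flag.
    """
    cls = assignment["tara_class"]
    use = cls.index[cls.isin(classes)]
    if len(use) < 4 or min((cls.loc[use] == c).sum() for c in classes) < 2:
        raise ValueError("each compared class needs >= 2 samples")
    y = metastases.values[list(use)].to_numpy(float)
    group = (cls.loc[use] == classes[1]).to_numpy(float)

    cols = [np.ones(len(use)), group]
    confounded = False
    if batch is not None:
        b = batch.reindex(use)
        if b.isna().any():
            raise ValueError("batch labels must cover all compared samples")
        levels = list(pd.unique(b))
        for lev in levels[1:]:                 # first level is reference
            cols.append((b == lev).to_numpy(float))
        for lev in levels:
            in_batch = (b == lev).to_numpy()
            if len(set(group[in_batch])) < 2:
                confounded = True
        if confounded:
            logger.warning("batch structure confounded with class; "
                           "estimates may be unstable")
    x = np.column_stack(cols)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError("design matrix is rank deficient (batch fully "
                         "confounded with class)")

    # shared design across genes: solve once via pseudo-inverse
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = y @ (xtx_inv @ x.T).T               # genes x coefficients
    resid = y - beta @ x.T
    df = x.shape[0] - x.shape[1]
    if df < 1:
        raise ValueError("not enough samples for the batch-adjusted model")
    sigma2 = (resid * resid).sum(axis=1) / df
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, beta[:, 1] / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    out = pd.DataFrame({"t_statistic": t, "p": p,
                        "significant": p < p_cutoff},
                       index=metastases.genes)
    out.attrs["confounded"] = confounded
    out.attrs["df"] = int(df)
    return out


def top_discriminants(comparisons: pd.DataFrame, n: int = 100) -> list[str]:
    """The n smallest class-comparison p-values.

    Ties are broken by |t| descending, then gene ID; deterministic for
    identical inputs. Requesting more genes than were tested returns the
    full ordered list with a logged warning.
    """
    if n > len(comparisons):
        logger.warning("requested %d genes but only %d tested", n,
                       len(comparisons))
        n = len(comparisons)
    ordered = comparisons.assign(
        _abs_t=comparisons["t_statistic"].abs(),
        _gene=comparisons.index.astype(str))
    ordered = ordered.sort_values(["p", "_abs_t", "_gene"],
                                  ascending=[True, False, True],
                                  kind="mergesort")
    return list(ordered.index[:n])


def pca_embed(matrix: ExpressionMatrix, n_components: int = 3
              ) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on per-gene mean-centered expression.

    Returns per-sample coordinates and explained-variance ratios. The
    sign of each component is fixed so its largest-magnitude gene
    loading is positive. Degenerate rank yields fewer components with a
    logged warning.
    """
    from sklearn.decomposition import PCA

    n_samples = len(matrix.samples)
    if n_samples < n_components:
        raise ValueError(f"need >= {n_components} samples")
    centered = matrix.values.sub(matrix.values.mean(axis=1), axis=0)
    x = centered.to_numpy(float).T             # samples x genes
    rank = min(x.shape[0] - 1, x.shape[1])
    k = min(n_components, rank)
    if k < n_components:
        logger.warning("rank %d < %d requested components", rank,
                       n_components)
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(x)
    for j in range(k):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] *= -1.0
    cols = [f"PC{j + 1}" for j in range(k)]
    return (pd.DataFrame(coords, index=matrix.samples, columns=cols),
            pca.explained_variance_ratio_)


def signature_score(matrix: ExpressionMatrix, gene_list) -> pd.Series:
    """Mean per-gene z-score over the listed genes present in the matrix.

    Gene IDs match case-insensitively; the number of missing genes is
    recorded in ``.attrs['n_missing']``. Raises when no listed gene is
    present.
    """
    lower = {str(g).lower(): g for g in matrix.genes}
    present = [lower[str(g).lower()] for g in gene_list
               if str(g).lower() in lower]
    n_missing = len(list(gene_list)) - len(present)
    if not present:
        raise ValueError("no listed gene present in the matrix")
    sub = matrix.values.loc[present]
    sd = sub.std(axis=1, ddof=1).replace(0, np.nan)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    score = z.mean(axis=0, skipna=True)
    score.name = "signature_score"
    score.attrs["n_missing"] = n_missing
    return score


def adjusted_rand_index(labels_true, labels_pred) -> float:
    """Chance-corrected agreement between two labelings."""
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(list(labels_true), list(labels_pred)))
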