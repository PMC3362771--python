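"""TARA classification: clustering behavior, batch-adjusted class
comparison (with the textbook two-sample t test as internal oracle),
top discriminants, PCA and signature scoring."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from taraclass import (ExpressionMatrix, adjusted_rand_index, class_de,
                       cluster_cohort, pca_embed, signature_score,
                       top_discriminants)


def cohort_matrix(values, samples=None, genes=None):
    samples = samples or [f"M{i:03d}" for i in range(values.shape[1])]
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes,
                                         columns=samples), "metastasis")


def two_class_cohort(rng, n_per=10, n_genes=60, effect=2.0):
    a = rng.normal(0, 0.3, (n_genes, n_per))
    b = rng.normal(0, 0.3, (n_genes, n_per))
    a[: n_genes // 3] += effect
    b[n_genes // 3: 2 * n_genes // 3] += effect
    return cohort_matrix(np.hstack([a, b]))


def assignment_from_labels(samples, labels):
    return pd.DataFrame({"tara_class": list(labels)},
                        index=pd.Index(samples))


# ----------------------------------------------------------- clustering

def test_duplicated_sample_stays_with_its_copy(rng):
    mets = two_class_cohort(rng)
    vals = mets.values.copy()
    vals["DUP"] = vals[vals.columns[0]]
    dup = cohort_matrix(vals.to_numpy(), samples=list(vals.columns))
    for k in (2, 3, 4):
        assign, _ = cluster_cohort(dup, dup.genes, k)
        assert (assign.loc["DUP", "cluster"]
                == assign.loc[vals.columns[0], "cluster"])


def test_two_clear_classes_recovered(rng):
    mets = two_class_cohort(rng)
    assign, link = cluster_cohort(mets, mets.genes, 2)
    truth = ["A"] * 10 + ["B"] * 10
    assert adjusted_rand_index(truth, assign["tara_class"]) == 1.0
    assert link.shape == (19, 4)


def test_polar_labels_and_intermediate(default_cohort):
    _, _, mets, _, truth = default_cohort
    genes = truth.genes.index[truth.genes["dosage_driven"]]
    assign, _ = cluster_cohort(mets, genes, 3)
    ct = pd.crosstab(assign["tara_class"], truth.sample_class)
    # polar labels map to the planted polar classes; C to the rest
    assert set(assign["tara_class"]) == {"A", "B", "C"}
    polar = ct.loc[["A", "B"], ["A", "B"]].to_numpy()
    assert polar.max(axis=1).sum() >= 0.95 * ct.loc[["A", "B"]].sum().sum()


def test_sample_order_permutation_invariance(rng):
    mets = two_class_cohort(rng)
    perm = rng.permutation(mets.values.shape[1])
    shuffled = cohort_matrix(mets.values.to_numpy()[:, perm],
                             samples=[mets.samples[i] for i in perm])
    a1, _ = cluster_cohort(mets, mets.genes, 2)
    a2, _ = cluster_cohort(shuffled, shuffled.genes, 2)
    joined = a1["tara_class"].to_frame("orig").join(a2["tara_class"]
                                                    .rename("perm"))
    assert (joined["orig"] == joined["perm"]).all()


def test_k_larger_than_cohort_rejected(rng):
    mets = two_class_cohort(rng, n_per=2)
    with pytest.raises(ValueError):
        cluster_cohort(mets, mets.genes, 5)


def test_missing_genes_dropped_not_fatal(rng):
    mets = two_class_cohort(rng)
    genes = list(mets.genes[:10]) + ["ABSENT1", "ABSENT2"]
    assign, _ = cluster_cohort(mets, genes, 2)
    assert len(assign) == 20
    with pytest.raises(ValueError):
        cluster_cohort(mets, ["ABSENT1"], 2)


# --------------------------------------------------------------- class DE

def test_single_batch_reduces_to_two_sample_t(rng):
    vals = rng.normal(7, 1, (200, 24))
    mets = cohort_matrix(vals)
    labels = ["A"] * 12 + ["B"] * 12
    assign = assignment_from_labels(mets.samples, labels)
    batch = pd.Series(["B1"] * 24, index=mets.samples)
    res = class_de(mets, assign, batch)
    res_nobatch = class_de(mets, assign, None)
    t_ref, p_ref = stats.ttest_ind(vals[:, 12:], vals[:, :12], axis=1)
    np.testing.assert_allclose(res["p"], p_ref, atol=1e-12)
    np.testing.assert_allclose(np.abs(res["t_statistic"]), np.abs(t_ref),
                               atol=1e-12)
    np.testing.assert_allclose(res_nobatch["p"], p_ref, atol=1e-12)


def test_batch_adjustment_removes_confounded_shift(rng):
    # identical class means within batch; batches imbalanced across
    # classes -> unadjusted test is fooled, adjusted one is not
    n = 20
    labels = ["A"] * 10 + ["B"] * 10
    batch = ["B1"] * 9 + ["B2"] * 1 + ["B1"] * 1 + ["B2"] * 9
    base = rng.normal(0, 0.1, (50, n))
    shift = np.where(np.array(batch) == "B2", 2.0, 0.0)
    mets = cohort_matrix(base + shift)
    assign = assignment_from_labels(mets.samples, labels)
    bser = pd.Series(batch, index=mets.samples)
    adj = class_de(mets, assign, bser)
    unadj = class_de(mets, assign, None)
    assert (unadj["p"] < 0.001).mean() > 0.9      # fooled without adjustment
    # adjusted test is calibrated: p-values roughly uniform, no signal
    assert (adj["p"] < 0.001).mean() < 0.1
    assert adj["p"].median() > 0.1
    assert not adj.attrs["confounded"]


def test_fully_confounded_batch_raises(rng):
    labels = ["A"] * 6 + ["B"] * 6
    batch = ["B1"] * 6 + ["B2"] * 6
    mets = cohort_matrix(rng.normal(0, 1, (10, 12)))
    assign = assignment_from_labels(mets.samples, labels)
    with pytest.raises(ValueError, match="confounded"):
        class_de(mets, assign, pd.Series(batch, index=mets.samples))


def test_null_de_calibration(rng):
    vals = rng.normal(0, 1, (10_000, 40))
    mets = cohort_matrix(vals)
    assign = assignment_from_labels(mets.samples, ["A"] * 20 + ["B"] * 20)
    res = class_de(mets, assign)
    n_sig = int(res["significant"].sum())
    # expect ~10 of 10,000 at p < 0.001; generous binomial band
    assert n_sig <= 25


def test_tiny_classes_rejected(rng):
    mets = cohort_matrix(rng.normal(0, 1, (5, 3)))
    assign = assignment_from_labels(mets.samples, ["A", "A", "B"])
    with pytest.raises(ValueError):
        class_de(mets, assign)


# ------------------------------------------------------ top discriminants

def test_top_discriminants_ordering_and_determinism(rng):
    comp = pd.DataFrame({
        "t_statistic": [5.0, -6.0, 1.0, -1.0],
        "p": [0.001, 0.001, 0.5, 0.5],
    }, index=["g1", "g2", "g3", "g4"])
    top = top_discriminants(comp, 4)
    assert top == ["g2", "g1", "g3", "g4"]      # |t| breaks the p tie
    assert top == top_discriminants(comp, 4)
    assert top_discriminants(comp, 10) == top   # truncated with warning


def test_top_discriminants_find_planted_markers(default_cohort):
    _, _, mets, _, truth = default_cohort
    assign = assignment_from_labels(truth.sample_class.index,
                                    truth.sample_class)
    res = class_de(mets, assign, truth.batch)
    top = set(top_discriminants(res, 100))
    g = truth.genes
    planted = set(g.index[g["class_marker_A"] | g["class_marker_B"]])
    assert len(top & planted) >= 90


# ------------------------------------------------------------------- PCA

def test_planar_data_third_component_vanishes(rng):
    u = rng.normal(0, 1, (50, 1)) @ rng.normal(0, 1, (1, 30))
    v = rng.normal(0, 1, (50, 1)) @ rng.normal(0, 1, (1, 30))
    mets = cohort_matrix((u + v).T)             # genes x samples, rank 2
    coords, evr = pca_embed(mets, 3)
    assert evr[2] == pytest.approx(0.0, abs=1e-12)
    assert list(coords.columns) == ["PC1", "PC2", "PC3"]


def test_explained_variance_monotone_and_bounded(rng):
    mets = cohort_matrix(rng.normal(0, 1, (100, 20)))
    _, evr = pca_embed(mets, 3)
    assert evr.sum() <= 1.0 + 1e-12
    assert (np.diff(evr) <= 1e-12).all()


def test_pca_separates_planted_classes(default_cohort):
    _, _, mets, _, truth = default_cohort
    coords, _ = pca_embed(mets, 3)
    from sklearn.metrics import silhouette_score
    s = silhouette_score(coords.to_numpy(), truth.sample_class.to_numpy())
    assert s > 0.25


def test_pca_sign_convention_deterministic(rng):
    mets = cohort_matrix(rng.normal(0, 1, (40, 15)))
    c1, _ = pca_embed(mets, 2)
    c2, _ = pca_embed(mets, 2)
    pd.testing.assert_frame_equal(c1, c2)


# -------------------------------------------------------------- signature

def test_single_gene_signature_equals_its_zscore(rng):
    mets = cohort_matrix(rng.normal(5, 2, (10, 12)))
    g = mets.genes[3]
    score = signature_score(mets, [g])
    row = mets.values.loc[g]
    z = (row - row.mean()) / row.std(ddof=1)
    np.testing.assert_allclose(score, z)


def test_signature_cohort_mean_is_zero(rng):
    mets = cohort_matrix(rng.normal(5, 2, (30, 12)))
    score = signature_score(mets, list(mets.genes[:10]))
    assert score.mean() == pytest.approx(0.0, abs=1e-12)


def test_signature_missing_genes_counted(rng):
    mets = cohort_matrix(rng.normal(5, 2, (10, 8)))
    score = signature_score(mets, [mets.genes[0], "NOPE"])
    assert score.attrs["n_missing"] == 1
    with pytest.raises(ValueError):
        signature_score(mets, ["NOPE"])


def test_class_a_signature_separates_classes(default_cohort):
    _, _, mets, _, truth = default_cohort
    g = truth.genes
    score = signature_score(mets, list(g.index[g["class_marker_A"]]))
    cls = truth.sample_class
    a = score[cls.index[cls == "A"]]
    b = score[cls.index[cls == "B"]]
    t, p = stats.ttest_ind(a, b, alternative="greater")
    assert p < 0.01
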