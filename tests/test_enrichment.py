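"""Representation, CV enrichment, chi-squared z, KLD, K-means, PCA."""

import numpy as np
import pandas as pd
import pytest

import screenfate as sf
from screenfate.enrichment import chi2_guide_test, kld_cv_test


# --- representation ---------------------------------------------------------

def test_representation_direct_ratios(toy_assignments):
    assignments, clusters = toy_assignments
    table = sf.representation(assignments, clusters)
    assert table.r.loc["g1", "x"] == pytest.approx(0.4)  # 2 of 5
    assert table.r.loc["g2", "y"] == pytest.approx(0.6)  # 3 of 5
    assert table.r.loc["g2", "x"] == 0.0
    assert table.counts.loc["scr"].sum() == 2


def test_representation_full_cluster_is_one(single_guide_library):
    umis = pd.DataFrame(
        {"g1": [50, 50, 50]}, index=["a", "b", "c"]
    )
    assignments = sf.filter_ambient(umis, single_guide_library)
    clusters = pd.Series(["only"] * 3, index=["a", "b", "c"])
    table = sf.representation(assignments, clusters)
    assert table.r.loc["g1", "only"] == 1.0


@pytest.mark.parametrize("seed", range(3))
def test_representation_matches_double_loop_oracle(seed):
    rng = np.random.default_rng(seed)
    library = sf.GuideLibrary.design(5, guides_per_gene=1, n_scramble=0)
    n_cells = 40
    umis = (rng.uniform(size=(n_cells, 5)) < 0.3).astype(int) * 50
    assignments = sf.filter_ambient(umis, library)
    clusters = pd.Series(
        rng.choice(["a", "b", "c"], n_cells),
        index=[f"cell_{i}" for i in range(n_cells)],
    )
    table = sf.representation(assignments, clusters)
    for g_idx, guide in enumerate(library.guide_ids):
        for label in ["a", "b", "c"]:
            expected = sum(
                1
                for i in range(n_cells)
                if umis[i, g_idx] > 0 and clusters.iloc[i] == label
            )
            assert table.counts.loc[guide, label] == expected
            assert table.r.loc[guide, label] == pytest.approx(
                expected / (clusters == label).sum()
            )


def test_representation_unlabeled_cell_is_error(toy_assignments):
    assignments, clusters = toy_assignments
    with pytest.raises(ValueError, match="c0"):
        sf.representation(assignments, clusters.drop(index="c0"))


# --- CV enrichment ----------------------------------------------------------

def test_single_fold_equals_whole_data_log_ratio(toy_assignments):
    assignments, clusters = toy_assignments
    enr, sd = sf.cv_enrichment(assignments, clusters, n_folds=1, seed=0)
    table = sf.representation(assignments, clusters)
    eps = 1.0 / (table.cluster_sizes.to_numpy(float) + 1.0)
    scr = table.r.loc[["scr"]].mean(axis=0).to_numpy()
    expected = np.log2((table.r.to_numpy() + eps) / (scr + eps))
    assert np.allclose(enr.to_numpy(), expected)
    assert (sd == 0).all().all()


def test_guide_duplicating_scramble_cells_scores_zero():
    # a guide present in exactly the scramble cells has enrichment 0
    library = sf.GuideLibrary(
        pd.DataFrame(
            {
                "guide_id": ["twin", "scr"],
                "target_gene": ["A", None],
                "scramble": [False, True],
            }
        )
    )
    rng = np.random.default_rng(1)
    cells = [f"c{i}" for i in range(60)]
    mask = rng.uniform(size=60) < 0.4
    umis = pd.DataFrame(
        {"twin": mask.astype(int) * 30, "scr": mask.astype(int) * 30}, index=cells
    )
    assignments = sf.filter_ambient(umis, library)
    clusters = pd.Series(rng.choice(["x", "y", "z"], 60), index=cells)
    enr, _ = sf.cv_enrichment(assignments, clusters, n_folds=5, seed=2)
    assert np.allclose(enr.loc["twin"].to_numpy(), 0.0, atol=1e-12)


def test_cv_requires_scramble():
    library = sf.GuideLibrary.design(2, guides_per_gene=1, n_scramble=0)
    umis = np.full((6, 2), 10)
    assignments = sf.filter_ambient(umis, library)
    clusters = pd.Series(["a"] * 6, index=[f"cell_{i}" for i in range(6)])
    with pytest.raises(ValueError, match="scramble reference"):
        sf.cv_enrichment(assignments, clusters)


# --- chi-squared ------------------------------------------------------------

def test_chi2_proportional_rows_give_zero():
    result = chi2_guide_test(
        pd.Series([10, 20, 30]), pd.Series([20.0, 40.0, 60.0])
    )
    assert result.chi2_stat == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(result.z.to_numpy(), 0.0, atol=1e-8)


def test_chi2_two_cluster_worked_example():
    # guide (10, 30) vs reference (30, 30): E = (16, 24),
    # adjusted denominators sqrt(16*0.6*0.6) = sqrt(24*0.6*0.4) = 2.4
    result = chi2_guide_test(pd.Series([10, 30]), pd.Series([30, 30]))
    assert result.z.iloc[0] == pytest.approx(-2.5)
    assert result.z.iloc[1] == pytest.approx(2.5)
    assert abs(result.z.iloc[0]) == pytest.approx(abs(result.z.iloc[1]))


@pytest.mark.parametrize("seed", range(10))
def test_chi2_and_residuals_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    k = rng.integers(2, 8)
    guide = rng.integers(5, 50, size=k).astype(float)
    ref = rng.integers(5, 50, size=k).astype(float)
    result = chi2_guide_test(pd.Series(guide), pd.Series(ref))
    table = np.vstack([guide, ref])
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    chi2 = ((table - expected) ** 2 / expected).sum()
    assert result.chi2_stat == pytest.approx(chi2)
    row_tot = table.sum(axis=1)
    col_tot = table.sum(axis=0)
    denom = np.sqrt(
        expected[0] * (1 - row_tot[0] / n) * (1 - col_tot / n)
    )
    z = (table[0] - expected[0]) / denom
    assert np.allclose(result.z.to_numpy(), z)


def test_chi2_all_zero_guide_untestable():
    result = chi2_guide_test(pd.Series([0, 0, 0]), pd.Series([5, 5, 5]))
    assert not result.testable
    assert np.isnan(result.chi2_stat)


def test_chi2_pools_tiny_expected_clusters():
    guide = pd.Series([50, 50, 0], index=["a", "b", "c"])
    ref = pd.Series([50.0, 50.0, 1.0], index=["a", "b", "c"])
    result = chi2_guide_test(guide, ref)
    assert result.pooled_clusters == ["c"]
    assert np.isnan(result.z["c"])
    assert np.isfinite(result.z["a"])


# --- KLD --------------------------------------------------------------------

def test_kld_identical_distributions_zero():
    assert sf.kl_divergence([0.2, 0.3, 0.5], [0.2, 0.3, 0.5]) == pytest.approx(0.0)


def test_kld_closed_form_example():
    expected = 0.5 * np.log(25 / 9)
    assert sf.kl_divergence([0.5, 0.5], [0.9, 0.1]) == pytest.approx(expected)


def test_kld_nonnegative_and_zero_iff_equal_after_smoothing():
    rng = np.random.default_rng(2)
    for _ in range(20):
        p = rng.dirichlet(np.ones(5))
        q = rng.dirichlet(np.ones(5))
        d = sf.kl_divergence(p, q, smooth_k=5)
        assert d >= 0
    assert sf.kl_divergence([1, 0, 0], [1, 0, 0], smooth_k=3) == pytest.approx(0.0)


def test_kld_cv_indeterminate_below_fold_count():
    result = kld_cv_test([0, 1], [0, 1, 2, 0], n_clusters=3, n_folds=5, seed=0)
    assert result.indeterminate
    assert np.isnan(result.p_value)


def test_kld_cv_detects_shifted_distribution():
    rng = np.random.default_rng(3)
    guide = rng.choice(3, size=200, p=[0.8, 0.1, 0.1])
    scramble = rng.choice(3, size=300, p=[0.3, 0.4, 0.3])
    result = kld_cv_test(guide, scramble, n_clusters=3, n_permutations=199, seed=4)
    assert result.p_value < 0.05
    assert result.kld > 0


def test_kld_cv_null_is_insignificant():
    rng = np.random.default_rng(5)
    guide = rng.choice(3, size=150, p=[0.3, 0.4, 0.3])
    scramble = rng.choice(3, size=250, p=[0.3, 0.4, 0.3])
    result = kld_cv_test(guide, scramble, n_clusters=3, n_permutations=199, seed=6)
    assert result.p_value > 0.05


# --- K-means and PCA --------------------------------------------------------

def test_kmeans_identical_rows_fall_back_to_one():
    matrix = pd.DataFrame(np.ones((6, 4)), index=[f"g{i}" for i in range(6)])
    labels, k = sf.kmeans_enrichment_patterns(matrix, k_max=5, seed=0)
    assert k == 1
    assert labels.nunique() == 1


def test_kmeans_recovers_two_planted_groups():
    rng = np.random.default_rng(8)
    group_a = np.tile([5.0, 0.0, 0.0], (6, 1)) + rng.normal(0, 0.1, (6, 3))
    group_b = np.tile([0.0, 5.0, 0.0], (6, 1)) + rng.normal(0, 0.1, (6, 3))
    matrix = pd.DataFrame(
        np.vstack([group_a, group_b]), index=[f"g{i}" for i in range(12)]
    )
    labels, k = sf.kmeans_enrichment_patterns(matrix, k_max=8, seed=0)
    assert k == 2
    from sklearn.metrics import adjusted_rand_score

    planted = [0] * 6 + [1] * 6
    assert adjusted_rand_score(planted, labels.to_numpy()) == 1.0


def test_kmeans_k_max_capped_with_warning():
    matrix = pd.DataFrame(np.eye(3), index=list("abc"))
    with pytest.warns(UserWarning, match="capped"):
        _, k = sf.kmeans_enrichment_patterns(matrix, k_max=10, seed=0)
    assert k <= 3


def test_pca_rank_one_explains_everything():
    matrix = pd.DataFrame(np.outer([1.0, 2, 3, 4], [1.0, 0, 2]))
    result = sf.pca_enrichment(matrix)
    assert result.explained_variance_ratio[0] == pytest.approx(1.0)
    assert np.all(np.diff(result.explained_variance_ratio) <= 1e-12)


def test_pca_matches_covariance_eigendecomposition():
    rng = np.random.default_rng(10)
    matrix = pd.DataFrame(rng.normal(size=(6, 4)))
    result = sf.pca_enrichment(matrix)
    x = matrix.to_numpy() - matrix.to_numpy().mean(axis=0)
    cov = x.T @ x / (len(matrix) - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    ncomp = result.loadings.shape[1]
    assert np.allclose(
        result.explained_variance_ratio, (eigval / eigval.sum())[:ncomp]
    )
    for i in range(ncomp):
        got = result.loadings.iloc[:, i].to_numpy()
        want = eigvec[:, i]
        assert np.allclose(np.abs(got @ want), 1.0)  # up to sign


def test_pca_constant_matrix_empty_components():
    matrix = pd.DataFrame(np.full((5, 3), 2.0))
    result = sf.pca_enrichment(matrix)
    assert result.scores.shape[1] == 0


# --- orchestration ----------------------------------------------------------

def test_analyze_enrichment_fields_consistent(small_null_screen, null_assignments):
    _, dataset, _ = small_null_screen
    result = sf.analyze_enrichment(
        null_assignments, dataset.clusters, n_permutations=49, seed=0
    )
    n_guides = len(dataset.library)
    assert result.enrichment.shape[0] == n_guides
    assert result.z.shape == result.enrichment.shape
    assert set(result.calls.to_numpy().ravel()) <= {"enriched", "depleted", "none"}
    # calls match the z cutoff exactly
    z = result.z.to_numpy()
    calls = result.calls.to_numpy()
    assert ((z > 2) == (calls == "enriched"))[np.isfinite(z)].all()
    assert ((z < -2) == (calls == "depleted"))[np.isfinite(z)].all()
    long = result.long_format()
    assert len(long) == n_guides * dataset.clusters.nunique()


def test_scramble_vs_scramble_symmetry(small_null_screen, null_assignments):
    # the two scrambles are generatively identical: their mutual KLD test
    # should be non-significant on this null screen
    _, dataset, _ = small_null_screen
    clusters = dataset.clusters
    level_index = {c: i for i, c in enumerate(sorted(clusters.unique()))}
    s1 = sorted(sf.cells_with_guide(null_assignments, "scramble_1"))
    s2 = sorted(sf.cells_with_guide(null_assignments, "scramble_2"))
    labels1 = np.array([level_index[clusters[c]] for c in s1])
    labels2 = np.array([level_index[clusters[c]] for c in s2])
    result = kld_cv_test(
        labels2, labels1, n_clusters=len(level_index), n_permutations=199, seed=0
    )
    assert result.p_value > 0.05


def test_gene_cluster_counts_pools_guides(toy_assignments):
    assignments, clusters = toy_assignments
    counts = sf.gene_cluster_counts(assignments, clusters, "A")
    assert counts["x"] == 2
    assert counts["y"] == 0
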