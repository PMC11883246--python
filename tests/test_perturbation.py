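"""LR perturbation scoring, Jaccard matrices, Fisher ORA, comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import screenfate as sf


def cells(n):
    return [f"c{i}" for i in range(n)]


def test_ols_closed_form_two_by_two():
    # guide cells' scaled expression {1, 3}, scramble {5, 7}:
    # intercept 6, guide coefficient -4
    expr = pd.DataFrame({"gene": [1.0, 3.0, 5.0, 7.0]}, index=cells(4))
    design = pd.DataFrame({"g1": [1.0, 1.0, 0.0, 0.0]}, index=cells(4))
    signature = sf.lr_scores(expr, design, ridge_penalty=0.0, n_permutations=0)
    assert signature.lr_score.loc["g1", "gene"] == pytest.approx(-4.0)


def test_zero_penalty_single_guide_equals_group_mean_difference():
    rng = np.random.default_rng(0)
    n = 30
    labels = rng.uniform(size=n) < 0.5
    y = rng.normal(size=n) + labels * 1.5
    expr = pd.DataFrame({"gene": y}, index=cells(n))
    design = pd.DataFrame({"g1": labels.astype(float)}, index=cells(n))
    signature = sf.lr_scores(expr, design, ridge_penalty=0.0, n_permutations=0)
    diff = y[labels].mean() - y[~labels].mean()
    assert signature.lr_score.loc["g1", "gene"] == pytest.approx(diff)


def test_dominating_statistic_gives_p_one_percent():
    rng = np.random.default_rng(1)
    y = np.concatenate([np.full(20, 5.0), np.zeros(20)]) + rng.normal(0, 0.05, 40)
    expr = pd.DataFrame({"gene": y}, index=cells(40))
    design = pd.DataFrame(
        {"g1": np.concatenate([np.ones(20), np.zeros(20)])}, index=cells(40)
    )
    signature = sf.lr_scores(expr, design, ridge_penalty=0.0, n_permutations=99, seed=2)
    assert signature.p.loc["g1", "gene"] == pytest.approx(1 / 100)


def test_singular_design_zero_penalty_advises_ridge():
    expr = pd.DataFrame({"gene": [1.0, 2.0, 3.0]}, index=cells(3))
    # duplicate columns: singular at penalty 0
    design = pd.DataFrame(
        {"g1": [1.0, 0.0, 1.0], "g2": [1.0, 0.0, 1.0]}, index=cells(3)
    )
    with pytest.raises(ValueError, match="ridge"):
        sf.lr_scores(expr, design, ridge_penalty=0.0, n_permutations=0)
    # a positive penalty solves it
    signature = sf.lr_scores(expr, design, ridge_penalty=0.5, n_permutations=0)
    assert np.isfinite(signature.lr_score.to_numpy()).all()


def test_permutation_p_location_invariant():
    rng = np.random.default_rng(3)
    y = rng.normal(size=24)
    design = pd.DataFrame(
        {"g1": (rng.uniform(size=24) < 0.5).astype(float)}, index=cells(24)
    )
    expr1 = pd.DataFrame({"gene": y}, index=cells(24))
    expr2 = pd.DataFrame({"gene": y + 100.0}, index=cells(24))
    p1 = sf.lr_scores(expr1, design, 0.0, n_permutations=49, seed=4).p
    p2 = sf.lr_scores(expr2, design, 0.0, n_permutations=49, seed=4).p
    assert p1.loc["g1", "gene"] == p2.loc["g1", "gene"]


def test_null_permutation_p_approximately_uniform():
    rng = np.random.default_rng(5)
    n_genes = 200
    expr = pd.DataFrame(
        rng.normal(size=(60, n_genes)),
        index=cells(60),
        columns=[f"gene{i}" for i in range(n_genes)],
    )
    design = pd.DataFrame(
        {"g1": (rng.uniform(size=60) < 0.5).astype(float)}, index=cells(60)
    )
    signature = sf.lr_scores(expr, design, 0.0, n_permutations=99, seed=6)
    pvals = np.sort(signature.p.loc["g1"].to_numpy())
    ks = np.max(np.abs(pvals - np.arange(1, n_genes + 1) / n_genes))
    assert ks < 0.1


def test_feature_list_restricts_and_warns():
    expr = pd.DataFrame(
        np.ones((4, 3)), index=cells(4), columns=["a", "b", "c"]
    )
    design = pd.DataFrame({"g1": [1.0, 0, 0, 1]}, index=cells(4))
    with pytest.warns(UserWarning, match="dropped"):
        signature = sf.lr_scores(
            expr, design, 0.5, n_permutations=0, feature_list=["a", "zzz"]
        )
    assert signature.feature_list == ["a"]


# --- Jaccard ----------------------------------------------------------------

def test_jaccard_worked_examples():
    matrix = sf.jaccard_matrix(
        {"i": {"a", "b", "c"}, "j": {"b", "c", "d"}, "k": {"x"}}
    )
    assert matrix.loc["i", "j"] == pytest.approx(0.5)
    assert matrix.loc["i", "k"] == 0.0
    assert matrix.loc["i", "i"] == 1.0
    assert np.allclose(matrix.to_numpy(), matrix.to_numpy().T)


def test_jaccard_empty_vs_empty_is_zero_with_warning():
    with pytest.warns(UserWarning, match="empty"):
        matrix = sf.jaccard_matrix({"i": set(), "j": set()})
    assert matrix.loc["i", "j"] == 0.0


# --- Fisher ORA -------------------------------------------------------------

def exhaustive_hypergeom_p(universe_n, annotated_n, query_n, overlap):
    """P(X >= overlap) by direct summation of hypergeometric masses."""
    total = 0.0
    for k in range(overlap, min(annotated_n, query_n) + 1):
        total += hypergeom.pmf(k, universe_n, annotated_n, query_n)
    return total


@pytest.mark.parametrize("seed", range(5))
def test_fisher_ora_matches_exhaustive_hypergeometric(seed):
    rng = np.random.default_rng(seed)
    universe = {f"u{i}" for i in range(rng.integers(15, 30))}
    genes = sorted(universe)
    annotation = {
        "T1": set(rng.choice(genes, size=8, replace=False)),
        "T2": set(rng.choice(genes, size=5, replace=False)),
    }
    query = set(rng.choice(genes, size=10, replace=False))
    result = sf.fisher_ora(query, annotation, universe).set_index("term")
    for term, annotated in annotation.items():
        overlap = len(query & annotated)
        expected = exhaustive_hypergeom_p(
            len(universe), len(annotated), len(query), overlap
        )
        assert result.loc[term, "p_value"] == pytest.approx(expected, rel=1e-9)


def test_fisher_ora_zero_overlap_not_enriched():
    universe = {f"u{i}" for i in range(20)}
    annotation = {"T": {"u0", "u1"}}
    query = {"u5", "u6", "u7"}
    result = sf.fisher_ora(query, annotation, universe)
    assert result["p_value"].iloc[0] == pytest.approx(1.0)


def test_fisher_ora_empty_universe_rejected():
    with pytest.raises(ValueError, match="universe"):
        sf.fisher_ora({"a"}, {"T": {"a"}}, set())


def test_gmt_roundtrip(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("T1\tdesc\tg1\tg2\ng3\nT2\tdesc\tg4\n".replace("\ng3", "\tg3"))
    annotation = sf.read_gmt(path)
    assert annotation == {"T1": {"g1", "g2", "g3"}, "T2": {"g4"}}


# --- compare_perturbations --------------------------------------------------

def _signature_from_sets(sets):
    guides = list(sets)
    genes = sorted(set().union(*sets.values()) | {"pad1", "pad2"})
    lr = pd.DataFrame(0.0, index=guides, columns=genes)
    p = pd.DataFrame(1.0, index=guides, columns=genes)
    for g, s in sets.items():
        p.loc[g, sorted(s)] = 0.01
    return sf.PerturbationSignature(lr, p, p.copy(), sets, genes)


def test_identical_effects_score_near_max_jaccard():
    sets = {
        "g1": {"a", "b", "c", "d"},
        "g2": {"a", "b", "c", "d"},
        "g3": {"x", "y"},
        "g4": {"p", "q", "r"},
    }
    comparison = sf.compare_perturbations(_signature_from_sets(sets), k_max=3)
    matrix = comparison.gene_jaccard
    off_diag = matrix.where(~np.eye(len(matrix), dtype=bool))
    assert matrix.loc["g1", "g2"] == off_diag.max().max() == 1.0
    assert np.allclose(np.diag(matrix), 1.0)


def test_empty_sets_excluded_and_all_empty_errors():
    sets = {"g1": {"a", "b"}, "g2": {"b", "c"}, "g3": set()}
    with pytest.warns(UserWarning, match="empty"):
        comparison = sf.compare_perturbations(_signature_from_sets(sets), k_max=2)
    assert "g3" not in comparison.gene_jaccard.index
    assert set(comparison.dendrogram_order) == {"g1", "g2"}
    with pytest.raises(ValueError, match="no signal"):
        sf.compare_perturbations(
            _signature_from_sets({"g1": set(), "g2": set()})
        )


def test_term_jaccard_built_from_significant_terms():
    sets = {"g1": {"a", "b", "c"}, "g2": {"a", "b", "c"}, "g3": {"x", "y", "z"}}
    annotation = {"TERM_AB": {"a", "b", "c"}, "TERM_XY": {"x", "y", "z"}}
    universe = {"a", "b", "c", "x", "y", "z", "m", "n", "o", "p", "q", "r"}
    comparison = sf.compare_perturbations(
        _signature_from_sets(sets), annotation=annotation, universe=universe, k_max=2
    )
    assert comparison.term_jaccard.loc["g1", "g2"] == 1.0
    assert comparison.term_jaccard.loc["g1", "g3"] == 0.0
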