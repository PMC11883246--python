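"""Perturbation expression signatures and their comparison.

Scores each guide's transcriptome-wide effect against the scramble control
by regularized linear regression: scaled expression of each gene is
regressed on guide-indicator columns (scramble cells are the all-zero
reference), and the guide coefficient — the "lr score" — is a corrected
readout of differential expression that accounts for cells carrying several
guides at once. Significance comes from permuting the cell-to-guide labels.
Genes with permutation p < 0.05 form a guide's misregulated set; sets are
compared across guides with Jaccard similarity and local Fisher
over-representation against a user-supplied GMT annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .enrichment import kmeans_enrichment_patterns
from .guide_calling import GuideAssignmentSet

__all__ = [
    "PerturbationSignature",
    "scale_expression",
    "build_guide_design",
    "lr_scores",
    "jaccard_matrix",
    "read_gmt",
    "fisher_ora",
    "compare_perturbations",
]


@dataclass
class PerturbationSignature:
    """Per-guide regression scores, permutation p-values and gene sets."""

    lr_score: pd.DataFrame  # guides x genes
    p: pd.DataFrame  # guides x genes, permutation p in (0, 1]
    fdr_q: pd.DataFrame  # guides x genes, BH across genes within guide
    misregulated: dict[str, set[str]]  # guide -> genes with p < alpha
    feature_list: list[str]

    def long_format(self) -> pd.DataFrame:
        rows = []
        for g in self.lr_score.index:
            for gene in self.lr_score.columns:
                rows.append(
                    {
                        "guide_id": g,
                        "gene": gene,
                        "lr_score": self.lr_score.loc[g, gene],
                        "p_value": self.p.loc[g, gene],
                        "fdr_q": self.fdr_q.loc[g, gene],
                    }
                )
        return pd.DataFrame(rows)


def scale_expression(normalized: pd.DataFrame) -> pd.DataFrame:
    """Center each gene and scale to unit variance; constant genes -> 0."""
    x = normalized.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return pd.DataFrame(
        (x - mu) / sd_safe, index=normalized.index, columns=normalized.columns
    )


def build_guide_design(
    assignments: GuideAssignmentSet, cells: list | None = None
) -> pd.DataFrame:
    """Cells x targeting-guides indicator matrix, scramble as reference.

    A cell with several guides carries 1 in each of their columns; cells
    with only scramble guides are all-zero rows (the reference level). By
    default the matrix covers every cell with at least one retained guide.
    """
    targeting = assignments.library.targeting_guides
    if cells is None:
        cells = sorted(assignments.cells())
    design = pd.DataFrame(0, index=list(cells), columns=targeting, dtype=float)
    frame = assignments.assignments
    mask = frame["guide_id"].isin(targeting) & frame["cell_id"].isin(set(cells))
    for cell, guide in zip(frame.loc[mask, "cell_id"], frame.loc[mask, "guide_id"]):
        design.loc[cell, guide] = 1.0
    return design


def _ridge_solve(
    x: np.ndarray, y: np.ndarray, penalty: float
) -> np.ndarray:
    """Solve the ridge normal equations; the intercept is unpenalized."""
    xtx = x.T @ x
    reg = np.eye(x.shape[1]) * penalty
    reg[0, 0] = 0.0  # never shrink the intercept
    a = xtx + reg
    if penalty == 0.0:
        if np.linalg.matrix_rank(xtx) < xtx.shape[0]:
            raise np.linalg.LinAlgError(
                "design matrix is singular; use a positive ridge penalty"
            )
    return np.linalg.solve(a, x.T @ y)


def lr_scores(
    expression: pd.DataFrame,
    guide_design: pd.DataFrame,
    ridge_penalty: float = 0.1,
    n_permutations: int = 999,
    seed: int = 0,
    feature_list: list[str] | None = None,
    alpha: float = 0.05,
) -> PerturbationSignature:
    """Regress scaled expression on guide indicators; permutation p-values.

    Parameters
    ----------
    expression
        cells x genes matrix of scaled (per-gene standardized) expression,
        restricted to the analysis feature list. Index must match
        ``guide_design``.
    guide_design
        cells x guides indicator matrix from :func:`build_guide_design`.
    ridge_penalty
        L2 penalty on guide coefficients (intercept unpenalized). A small
        positive value keeps overlapping multi-guide designs solvable.
    n_permutations
        Label permutations for the two-sided p-value
        p = (1 + #{|coef_perm| >= |coef_obs|}) / (n_permutations + 1).
    feature_list
        Optional restriction of the gene universe; unknown names are
        dropped with a warning.
    alpha
        Raw-p cutoff defining each guide's misregulated gene set (BH q is
        reported alongside but the set uses raw p, matching the screen's
        gene-level rule).
    """
    if ridge_penalty < 0:
        raise ValueError("ridge_penalty must be >= 0")
    if not expression.index.equals(guide_design.index):
        guide_design = guide_design.reindex(expression.index)
        if guide_design.isna().any().any():
            raise ValueError("expression and guide_design cover different cells")
    if feature_list is not None:
        known = [f for f in feature_list if f in expression.columns]
        unknown = sorted(set(feature_list) - set(known))
        if unknown:
            warnings.warn(
                f"{len(unknown)} features not in expression matrix; dropped",
                stacklevel=2,
            )
        expression = expression[known]

    genes = list(expression.columns)
    guides = list(guide_design.columns)
    y = expression.to_numpy(dtype=float)
    d = guide_design.to_numpy(dtype=float)
    n = y.shape[0]
    x = np.column_stack([np.ones(n), d])
    try:
        beta = _ridge_solve(x, y, ridge_penalty)
    except np.linalg.LinAlgError as err:
        raise ValueError(str(err)) from None
    coef = beta[1:]  # guides x genes

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(coef)
    abs_obs = np.abs(coef)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        x_perm = np.column_stack([np.ones(n), d[perm]])
        beta_perm = _ridge_solve(x_perm, y, ridge_penalty)
        exceed += np.abs(beta_perm[1:]) >= abs_obs
    p = (1.0 + exceed) / (n_permutations + 1.0)

    q = np.ones_like(p)
    for i in range(len(guides)):
        _, q[i], _, _ = multipletests(p[i], method="fdr_bh")

    lr = pd.DataFrame(coef, index=guides, columns=genes)
    p_frame = pd.DataFrame(p, index=guides, columns=genes)
    q_frame = pd.DataFrame(q, index=guides, columns=genes)
    misregulated = {
        g: set(p_frame.columns[p_frame.loc[g] < alpha]) for g in guides
    }
    return PerturbationSignature(lr, p_frame, q_frame, misregulated, genes)


def jaccard_matrix(sets: dict[str, set]) -> pd.DataFrame:
    """Pairwise Jaccard overlap |A n B| / |A u B| between labelled sets.

    The reported number is the overlap fraction (1 = identical sets).
    Empty-vs-empty pairs are defined as 0 with a warning.
    """
    labels = list(sets)
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    warned = False
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if j < i:
                continue
            union = sets[a] | sets[b]
            if not union:
                if not warned:
                    warnings.warn("empty-vs-empty Jaccard defined as 0", stacklevel=2)
                    warned = True
                val = 0.0
            else:
                val = len(sets[a] & sets[b]) / len(union)
            out.iloc[i, j] = out.iloc[j, i] = val
    return out


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT annotation file: term, description, genes...

    Returns term -> gene set; the description column is discarded.
    """
    annotation: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        annotation[parts[0]] = set(parts[2:])
    return annotation


def fisher_ora(
    gene_set: set[str],
    annotation: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher over-representation of a gene set in each term.

    Each term's genes are intersected with the universe; the 2x2 table
    (in gene_set / not x annotated / not) is tested for enrichment
    (alternative='greater') and BH-adjusted across terms. ``significant``
    marks adjusted p < alpha.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    stray = gene_set - universe
    if stray:
        warnings.warn(
            f"{len(stray)} query genes outside the universe; dropped", stacklevel=2
        )
    query = gene_set & universe
    rows = []
    for term, genes in annotation.items():
        annotated = genes & universe
        k = len(query & annotated)
        table = [
            [k, len(query) - k],
            [len(annotated) - k, len(universe) - len(annotated) - len(query) + k],
        ]
        odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append(
            {
                "term": term,
                "n_overlap": k,
                "n_annotated": len(annotated),
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    result = pd.DataFrame(
        rows, columns=["term", "n_overlap", "n_annotated", "odds_ratio", "p_value"]
    )
    if len(result):
        _, q, _, _ = multipletests(result["p_value"], method="fdr_bh")
        result["adjusted_p"] = q
        result["significant"] = result["adjusted_p"] < alpha
    else:
        result["adjusted_p"] = []
        result["significant"] = []
    return result.sort_values("p_value", kind="stable").reset_index(drop=True)


@dataclass
class PerturbationComparison:
    gene_jaccard: pd.DataFrame
    term_jaccard: pd.DataFrame | None
    pattern_labels: pd.Series
    chosen_k: int
    dendrogram_order: list[str]


def compare_perturbations(
    signature: PerturbationSignature,
    annotation: dict[str, set[str]] | None = None,
    universe: set[str] | None = None,
    alpha: float = 0.05,
    k_max: int = 10,
    seed: int = 0,
) -> PerturbationComparison:
    """Compare perturbations by their misregulated-gene (and term) sets.

    Builds the gene-set Jaccard matrix, optionally a term-set Jaccard
    matrix from per-guide significant ORA terms, groups guides by
    elbow-selected K-means on the Jaccard rows, and exports an
    average-linkage hierarchical leaf order for heatmaps.
    """
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    sets = dict(signature.misregulated)
    empty = [g for g, s in sets.items() if not s]
    for g in empty:
        warnings.warn(f"guide {g} has an empty misregulated set; excluded",
                      stacklevel=2)
        del sets[g]
    if len(sets) < 2:
        raise ValueError("no signal to compare: need >= 2 nonempty gene sets")

    gene_j = jaccard_matrix(sets)

    term_j = None
    if annotation is not None:
        if universe is None:
            universe = set(signature.feature_list)
        term_sets = {}
        for g, s in sets.items():
            ora = fisher_ora(s, annotation, universe, alpha=alpha)
            term_sets[g] = set(ora.loc[ora["significant"], "term"])
        term_j = jaccard_matrix(term_sets)

    labels, chosen_k = kmeans_enrichment_patterns(gene_j, k_max=k_max, seed=seed)
    dist = 1.0 - gene_j.to_numpy()
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [gene_j.index[i] for i in hierarchy.leaves_list(link)]
    return PerturbationComparison(gene_j, term_j, labels, chosen_k, order)
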