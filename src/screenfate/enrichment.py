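"""Per-guide, per-cluster fate enrichment and depletion statistics.

The central readout of a pooled fate screen: does a guide's cell population
sit in the fate clusters where scramble-control cells sit, or has the
perturbation shifted it? Quantities computed here:

* guide representation r[g, c] — cells with guide g in cluster c divided by
  the total cells in cluster c;
* cross-validated enrichment scores — log2 ratio of a guide's representation
  to the scramble-average representation, mean and SD over stratified folds;
* chi-squared tests of a guide's cluster counts against a reference row
  (scramble guide 1 and the all-guide average), with per-cluster adjusted
  standardized residuals as z-scores; |z| > 2 classifies a (guide, cluster)
  cell as enriched or depleted;
* Kullback-Leibler divergence of the guide's cluster distribution from the
  scramble average, averaged over folds, with a label-permutation p-value;
* K-means grouping of enrichment patterns with elbow-selected K, and PCA of
  the enrichment matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .guide_calling import GuideAssignmentSet

__all__ = [
    "RepresentationTable",
    "Chi2GuideResult",
    "KLDResult",
    "EnrichmentResult",
    "representation",
    "stratified_folds",
    "cv_enrichment",
    "chi2_guide_test",
    "gene_cluster_counts",
    "kl_divergence",
    "kld_cv_test",
    "kmeans_enrichment_patterns",
    "pca_enrichment",
    "analyze_enrichment",
]


@dataclass
class RepresentationTable:
    """Guide x cluster occupancy: raw counts and per-cluster fractions."""

    counts: pd.DataFrame  # guides x clusters, int
    r: pd.DataFrame  # guides x clusters, counts / cluster size
    cluster_sizes: pd.Series  # cluster -> total cells


@dataclass
class Chi2GuideResult:
    """One guide's 2 x K contingency test against a reference row."""

    chi2_stat: float
    p_value: float
    z: pd.Series  # per-cluster adjusted standardized residual (NaN if pooled)
    testable: bool
    pooled_clusters: list = field(default_factory=list)


@dataclass
class KLDResult:
    """Cross-validated KL divergence of guide vs scramble cluster use."""

    kld: float  # mean over folds, nats
    p_value: float
    n_cells: int
    indeterminate: bool


@dataclass
class EnrichmentResult:
    """All per-guide fate statistics of one screen."""

    representation: RepresentationTable
    enrichment: pd.DataFrame  # guides x clusters, CV-mean log2 ratio
    cv_sd: pd.DataFrame  # guides x clusters, SD over folds
    z: pd.DataFrame  # guides x clusters, adjusted standardized residuals
    chi2: pd.DataFrame  # per guide: stat/p vs scramble1 and vs average
    kld: pd.DataFrame  # per guide: kld, p, n_cells, indeterminate
    calls: pd.DataFrame  # guides x clusters: enriched / depleted / none

    def long_format(self) -> pd.DataFrame:
        """One row per (guide, cluster) with every statistic, for export."""
        rows = []
        for g in self.enrichment.index:
            for c in self.enrichment.columns:
                rows.append(
                    {
                        "guide_id": g,
                        "cluster": c,
                        "count": self.representation.counts.loc[g, c],
                        "representation": self.representation.r.loc[g, c],
                        "enrichment": self.enrichment.loc[g, c],
                        "cv_sd": self.cv_sd.loc[g, c],
                        "z": self.z.loc[g, c],
                        "call": self.calls.loc[g, c],
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# representation
# ---------------------------------------------------------------------------

def representation(
    assignments: GuideAssignmentSet, clusters: pd.Series
) -> RepresentationTable:
    """Fraction of each cluster's cells that carry each guide.

    ``clusters`` maps every cell id to its fate-cluster label and defines
    both the cluster universe and the cluster sizes (denominators). Every
    assigned cell must be labelled.
    """
    labelled = set(clusters.index)
    assigned = set(assignments.assignments["cell_id"])
    missing = assigned - labelled
    if missing:
        raise ValueError(
            f"assigned cells without cluster label: {sorted(missing)[:5]}"
        )
    cluster_levels = sorted(pd.unique(clusters))
    sizes = clusters.value_counts().reindex(cluster_levels, fill_value=0)
    guides = assignments.library.guide_ids
    counts = pd.DataFrame(0, index=guides, columns=cluster_levels, dtype=int)
    frame = assignments.assignments
    if len(frame):
        cl = clusters.loc[frame["cell_id"]].to_numpy()
        tab = pd.crosstab(frame["guide_id"].to_numpy(), cl)
        counts.loc[tab.index, tab.columns] = tab
    r = counts.div(sizes.replace(0, np.nan), axis=1).fillna(0.0)
    return RepresentationTable(
        counts=counts, r=r, cluster_sizes=sizes.rename("n_cells")
    )


# ---------------------------------------------------------------------------
# cross-validated enrichment scores
# ---------------------------------------------------------------------------

def stratified_folds(
    clusters: pd.Series, n_folds: int, rng: np.random.Generator
) -> list[list]:
    """Partition cells into folds stratified by cluster, seeded."""
    folds: list[list] = [[] for _ in range(n_folds)]
    for _, grp in clusters.groupby(clusters, sort=True):
        cells = np.array(sorted(grp.index))
        rng.shuffle(cells)
        for i, cell in enumerate(cells):
            folds[i % n_folds].append(cell)
    return folds


def cv_enrichment(
    assignments: GuideAssignmentSet,
    clusters: pd.Series,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scramble-referenced enrichment scores, cross-validated.

    Cells are split into ``n_folds`` cluster-stratified folds. Within each
    fold, enrichment[g, c] = log2((r_fold[g, c] + eps) / (scramble-average
    r_fold + eps)) with eps = 1 / (fold cluster size + 1). Returns the mean
    and sample SD over folds. With ``n_folds=1`` this is the whole-data
    log-ratio.
    """
    scrambles = assignments.library.scramble_guides
    if not scrambles:
        raise ValueError("scramble reference required")
    if n_folds < 1:
        raise ValueError("n_folds must be >= 1")
    if n_folds > len(clusters):
        raise ValueError("more folds than cells")
    rng = np.random.default_rng(seed)
    folds = stratified_folds(clusters, n_folds, rng)
    guides = assignments.library.guide_ids
    cluster_levels = sorted(pd.unique(clusters))
    per_fold = []
    frame = assignments.assignments
    for fold_cells in folds:
        fold_set = set(fold_cells)
        sub = frame[frame["cell_id"].isin(fold_set)]
        sizes = clusters.loc[list(fold_set)].value_counts().reindex(
            cluster_levels, fill_value=0
        )
        counts = pd.DataFrame(0, index=guides, columns=cluster_levels, dtype=int)
        if len(sub):
            cl = clusters.loc[sub["cell_id"]].to_numpy()
            tab = pd.crosstab(sub["guide_id"].to_numpy(), cl)
            counts.loc[tab.index, tab.columns] = tab
        r_fold = counts.div(sizes.replace(0, np.nan), axis=1).fillna(0.0)
        eps = 1.0 / (sizes.to_numpy(dtype=float) + 1.0)
        scr = r_fold.loc[scrambles].mean(axis=0).to_numpy()
        enr = np.log2((r_fold.to_numpy() + eps) / (scr + eps))
        per_fold.append(enr)
    stack = np.stack(per_fold)  # folds x guides x clusters
    mean = pd.DataFrame(stack.mean(axis=0), index=guides, columns=cluster_levels)
    if n_folds > 1:
        sd = pd.DataFrame(
            stack.std(axis=0, ddof=1), index=guides, columns=cluster_levels
        )
    else:
        sd = pd.DataFrame(0.0, index=guides, columns=cluster_levels)
    return mean, sd


# ---------------------------------------------------------------------------
# chi-squared tests with adjusted standardized residuals
# ---------------------------------------------------------------------------

def chi2_guide_test(
    guide_counts: pd.Series,
    reference_counts: pd.Series,
    pool_expected_below: float = 1.0,
    residual: str = "adjusted",
) -> Chi2GuideResult:
    """Pearson chi-squared of one guide's cluster counts vs a reference row.

    The 2 x K contingency table stacks the guide's per-cluster cell counts
    on a reference row (scramble-1 counts, or the average counts across all
    guides — fractional reference rows are accepted). Per-cluster z-scores
    are adjusted standardized residuals of the guide row,

        z = (O - E) / sqrt(E (1 - row_tot/N) (1 - col_tot/N)),

    standard normal under independence, so |z| > 2 classifies enrichment or
    depletion. Clusters whose expected count falls below
    ``pool_expected_below`` are pooled into a remainder category that enters
    the statistic but gets no per-cluster call. ``residual="pearson"`` gives
    the plain (O - E)/sqrt(E) residual instead.
    """
    if residual not in ("adjusted", "pearson"):
        raise ValueError("residual must be 'adjusted' or 'pearson'")
    guide_counts, reference_counts = guide_counts.align(reference_counts)
    if guide_counts.isna().any() or reference_counts.isna().any():
        raise ValueError("guide and reference counts must cover the same clusters")
    clusters = list(guide_counts.index)
    obs = np.vstack([guide_counts.to_numpy(float), reference_counts.to_numpy(float)])
    if np.any(obs < 0):
        raise ValueError("counts must be nonnegative")
    if obs[0].sum() == 0 or obs[1].sum() == 0:
        return Chi2GuideResult(
            np.nan, np.nan,
            pd.Series(np.nan, index=clusters, name="z"), False,
        )

    def expected(table: np.ndarray) -> np.ndarray:
        rt = table.sum(axis=1, keepdims=True)
        ct = table.sum(axis=0, keepdims=True)
        return rt * ct / table.sum()

    exp = expected(obs)
    pool_mask = exp.min(axis=0) < pool_expected_below
    pooled = [c for c, m in zip(clusters, pool_mask) if m]
    kept = [c for c, m in zip(clusters, pool_mask) if not m]
    if pool_mask.any():
        table = np.column_stack(
            [obs[:, ~pool_mask], obs[:, pool_mask].sum(axis=1)]
        )
    else:
        table = obs[:, ~pool_mask] if pool_mask.any() else obs
    # drop all-zero columns (possible after pooling nothing into an empty one)
    nz = table.sum(axis=0) > 0
    table = table[:, nz]
    if table.shape[1] < 2:
        return Chi2GuideResult(
            np.nan, np.nan,
            pd.Series(np.nan, index=clusters, name="z"), False, pooled,
        )
    chi2, p, _, exp_t = stats.chi2_contingency(table, correction=False)
    n = table.sum()
    row_tot = table.sum(axis=1)
    col_tot = table.sum(axis=0)
    resid = table[0] - exp_t[0]
    if residual == "adjusted":
        denom = np.sqrt(exp_t[0] * (1 - row_tot[0] / n) * (1 - col_tot / n))
    else:
        denom = np.sqrt(exp_t[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        z_vals = np.where(denom > 0, resid / denom, 0.0)
    z = pd.Series(np.nan, index=clusters, name="z", dtype=float)
    kept_nz = [c for c, keep in zip(kept, nz[: len(kept)]) if keep]
    for c, zv in zip(kept_nz, z_vals):
        z[c] = zv
    return Chi2GuideResult(float(chi2), float(p), z, True, pooled)


def gene_cluster_counts(
    assignments: GuideAssignmentSet, clusters: pd.Series, gene: str
) -> pd.Series:
    """Cluster counts of cells carrying any guide against ``gene``.

    Pools the gene's guides into one row — the gene-level comparison unit
    for :func:`chi2_guide_test` (a gene's fate shift is shared by all its
    guides, so pooling their cells gives the most powerful contrast).
    """
    cells = assignments.cells_with_gene_guide(gene)
    levels = sorted(pd.unique(clusters))
    if not cells:
        return pd.Series(0, index=levels, name=gene)
    labels = clusters.loc[sorted(cells)]
    return labels.value_counts().reindex(levels, fill_value=0).rename(gene)


# ---------------------------------------------------------------------------
# Kullback-Leibler divergence with permutation significance
# ---------------------------------------------------------------------------

def kl_divergence(p, q, smooth_k: int | None = None) -> float:
    """D_KL(p || q) in nats, optionally smoothing both by +1/K then renorm."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if smooth_k is not None:
        p = (p / p.sum() + 1.0 / smooth_k)
        p = p / p.sum()
        q = (q / q.sum() + 1.0 / smooth_k)
        q = q / q.sum()
    mask = p > 0
    if np.any(q[mask] <= 0):
        return float("inf")
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def _fold_distributions(
    labels: np.ndarray, n_folds: int, k: int
) -> np.ndarray:
    """Smoothed cluster distributions of ``labels`` split into folds.

    Returns an (n_folds, k) array; folds follow the order of ``labels``.
    """
    out = np.empty((n_folds, k))
    for i, chunk in enumerate(np.array_split(labels, n_folds)):
        counts = np.bincount(chunk, minlength=k).astype(float)
        p = counts / counts.sum() + 1.0 / k
        out[i] = p / p.sum()
    return out


def kld_cv_test(
    guide_labels,
    scramble_labels,
    n_clusters: int,
    n_folds: int = 5,
    n_permutations: int = 999,
    seed: int = 0,
) -> KLDResult:
    """Cross-validated KL divergence of guide vs scramble cluster use.

    ``guide_labels`` / ``scramble_labels`` are integer cluster labels (in
    ``0..n_clusters-1``) of the guide-bearing and scramble-bearing cells.
    The guide cells are shuffled and split into folds; each fold's smoothed
    cluster distribution is compared to the smoothed scramble distribution
    and the fold KLDs averaged. Significance comes from permuting the
    guide/scramble group labels and recomputing the mean-fold KLD:

        p = (1 + #{perm >= observed}) / (n_permutations + 1).

    Guides with fewer cells than folds are reported indeterminate.
    """
    rng = np.random.default_rng(seed)
    g = np.asarray(guide_labels, dtype=int)
    s = np.asarray(scramble_labels, dtype=int)
    k = n_clusters
    if g.size < n_folds or s.size == 0:
        return KLDResult(np.nan, np.nan, int(g.size), True)

    def mean_fold_kld(guide_part: np.ndarray, scr_part: np.ndarray) -> float:
        scr_counts = np.bincount(scr_part, minlength=k).astype(float)
        q = scr_counts / scr_counts.sum() + 1.0 / k
        q = q / q.sum()
        dists = _fold_distributions(guide_part, n_folds, k)
        return float(np.mean(np.sum(dists * np.log(dists / q), axis=1)))

    g_shuf = g.copy()
    rng.shuffle(g_shuf)
    observed = mean_fold_kld(g_shuf, s)

    if n_permutations <= 0:
        return KLDResult(observed, np.nan, int(g.size), False)

    pool = np.concatenate([g, s])
    m, n_g = pool.size, g.size
    b = n_permutations
    # vectorized permutations: argsort of random keys gives row permutations
    keys = rng.random((b, m))
    order = np.argsort(keys, axis=1)
    perm_labels = pool[order]  # b x m
    guide_part = perm_labels[:, :n_g]
    scr_part = perm_labels[:, n_g:]
    scr_counts = np.stack(
        [
            np.bincount(
                (np.arange(b)[:, None] * k + scr_part).ravel(), minlength=b * k
            ).reshape(b, k)
        ]
    )[0].astype(float)
    q = scr_counts / scr_counts.sum(axis=1, keepdims=True) + 1.0 / k
    q = q / q.sum(axis=1, keepdims=True)
    fold_klds = np.zeros(b)
    start = 0
    for chunk_len in [len(c) for c in np.array_split(np.arange(n_g), n_folds)]:
        chunk = guide_part[:, start : start + chunk_len]
        start += chunk_len
        counts = np.bincount(
            (np.arange(b)[:, None] * k + chunk).ravel(), minlength=b * k
        ).reshape(b, k).astype(float)
        p = counts / counts.sum(axis=1, keepdims=True) + 1.0 / k
        p = p / p.sum(axis=1, keepdims=True)
        fold_klds += np.sum(p * np.log(p / q), axis=1)
    fold_klds /= n_folds
    p_value = (1.0 + np.sum(fold_klds >= observed)) / (n_permutations + 1.0)
    return KLDResult(observed, float(p_value), int(g.size), False)


# ---------------------------------------------------------------------------
# pattern grouping and PCA
# ---------------------------------------------------------------------------

def kmeans_enrichment_patterns(
    enrichment: pd.DataFrame, k_max: int = 10, seed: int = 0
) -> tuple[pd.Series, int]:
    """Group guides by enrichment pattern; K chosen by the elbow rule.

    Runs K-means for k = 1..k_max (10 restarts, seeded) and picks the k
    maximizing the second difference of the total within-cluster distance —
    the sharpest bend of the elbow plot. Degenerate inputs (identical rows)
    fall back to k = 1.
    """
    if len(enrichment) < 2:
        raise ValueError("need at least 2 guides to group")
    x = enrichment.to_numpy(dtype=float)
    n = len(enrichment)
    if k_max > n:
        warnings.warn(f"k_max {k_max} capped at the number of guides {n}", stacklevel=2)
        k_max = n
    km1 = KMeans(n_clusters=1, n_init=10, random_state=seed)
    labels_by_k: dict[int, np.ndarray] = {1: km1.fit_predict(x)}
    inertias: dict[int, float] = {1: float(km1.inertia_)}
    if inertias[1] <= 1e-12:  # identical rows: no structure
        return (
            pd.Series(labels_by_k[1], index=enrichment.index, name="pattern"),
            1,
        )
    for k in range(2, k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels_by_k[k] = km.fit_predict(x)
        inertias[k] = float(km.inertia_)
    if k_max < 3:
        chosen = k_max
    else:
        second_diff = {
            k: inertias[k - 1] - 2 * inertias[k] + inertias[k + 1]
            for k in range(2, k_max)
        }
        chosen = max(second_diff, key=second_diff.get)
    labels = pd.Series(labels_by_k[chosen], index=enrichment.index, name="pattern")
    return labels, chosen


@dataclass
class PCAResult:
    scores: pd.DataFrame  # guides x components
    loadings: pd.DataFrame  # clusters x components
    explained_variance_ratio: np.ndarray


def pca_enrichment(enrichment: pd.DataFrame) -> PCAResult:
    """Column-centered PCA of the guide x cluster enrichment matrix.

    Loadings expose which clusters drive each component; components with
    numerically zero variance are dropped (a constant matrix yields an
    empty component set).
    """
    if enrichment.shape[0] < 2 or enrichment.shape[1] < 2:
        raise ValueError("need >= 2 guides and >= 2 clusters")
    x = enrichment.to_numpy(dtype=float)
    if np.allclose(x, x.mean(axis=0), atol=1e-12):  # constant columns
        empty = pd.DataFrame(index=enrichment.index)
        return PCAResult(
            scores=empty,
            loadings=pd.DataFrame(index=enrichment.columns),
            explained_variance_ratio=np.array([]),
        )
    n_comp = min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(x)
    keep = pca.explained_variance_ > 1e-12
    comp_names = [f"PC{i + 1}" for i in range(int(keep.sum()))]
    return PCAResult(
        scores=pd.DataFrame(
            scores[:, keep], index=enrichment.index, columns=comp_names
        ),
        loadings=pd.DataFrame(
            pca.components_[keep].T, index=enrichment.columns, columns=comp_names
        ),
        explained_variance_ratio=pca.explained_variance_ratio_[keep],
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def analyze_enrichment(
    assignments: GuideAssignmentSet,
    clusters: pd.Series,
    n_folds: int = 5,
    n_permutations: int = 999,
    seed: int = 0,
    z_reference: str = "average",
    z_cutoff: float = 2.0,
) -> EnrichmentResult:
    """Run the full enrichment stage for every guide.

    ``z_reference`` selects the reference row behind the per-cluster calls:
    ``"average"`` (mean counts across all guides) or ``"scramble1"`` (the
    first scramble guide's counts). Chi-squared statistics against both
    references are always reported.
    """
    if z_reference not in ("average", "scramble1"):
        raise ValueError("z_reference must be 'average' or 'scramble1'")
    scrambles = assignments.library.scramble_guides
    if not scrambles:
        raise ValueError("scramble reference required")
    rep = representation(assignments, clusters)
    enr, sd = cv_enrichment(assignments, clusters, n_folds=n_folds, seed=seed)

    avg_ref = rep.counts.mean(axis=0)
    scr1_ref = rep.counts.loc[scrambles[0]].astype(float)
    guides = assignments.library.guide_ids
    z = pd.DataFrame(np.nan, index=guides, columns=rep.counts.columns)
    chi2_rows = []
    for guide in guides:
        row = rep.counts.loc[guide]
        res_avg = chi2_guide_test(row, avg_ref)
        res_s1 = chi2_guide_test(row, scr1_ref)
        chosen = res_avg if z_reference == "average" else res_s1
        if chosen.testable:
            z.loc[guide] = chosen.z
        chi2_rows.append(
            {
                "guide_id": guide,
                "chi2_scramble1": res_s1.chi2_stat,
                "p_scramble1": res_s1.p_value,
                "chi2_average": res_avg.chi2_stat,
                "p_average": res_avg.p_value,
                "testable": chosen.testable,
            }
        )
    chi2_frame = pd.DataFrame(chi2_rows).set_index("guide_id")

    cluster_levels = list(rep.counts.columns)
    level_index = {c: i for i, c in enumerate(cluster_levels)}
    scr_cells = sorted(assignments.scramble_cells())
    scr_labels = np.array([level_index[clusters[c]] for c in scr_cells], dtype=int)
    kld_rows = []
    ss = np.random.SeedSequence(seed)
    guide_seeds = ss.generate_state(len(guides))
    for guide, gseed in zip(guides, guide_seeds):
        cells = sorted(
            set(
                assignments.assignments.loc[
                    assignments.assignments["guide_id"] == guide, "cell_id"
                ]
            )
        )
        labels = np.array([level_index[clusters[c]] for c in cells], dtype=int)
        res = kld_cv_test(
            labels, scr_labels, len(cluster_levels),
            n_folds=n_folds, n_permutations=n_permutations,
            seed=int(gseed % (2**31)),
        )
        kld_rows.append(
            {
                "guide_id": guide,
                "kld": res.kld,
                "p_value": res.p_value,
                "n_cells": res.n_cells,
                "indeterminate": res.indeterminate,
            }
        )
    kld_frame = pd.DataFrame(kld_rows).set_index("guide_id")

    calls = pd.DataFrame("none", index=guides, columns=cluster_levels, dtype=object)
    calls = calls.mask(z > z_cutoff, "enriched").mask(z < -z_cutoff, "depleted")
    return EnrichmentResult(
        representation=rep,
        enrichment=enr,
        cv_sd=sd,
        z=z,
        chi2=chi2_frame,
        kld=kld_frame,
        calls=calls,
    )
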