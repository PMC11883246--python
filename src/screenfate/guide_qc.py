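"""Knockdown QC: which guides actually reduced their target's expression.

A guide is "successful" when cells carrying it express the targeted gene at
a lower level than a comparator population — by default cells carrying a
scramble (non-targeting) control guide — at a Benjamini-Hochberg FDR below
the threshold. Expression is library-size normalized and log1p-transformed
first; the test is a two-sided Wilcoxon rank-sum on the target gene.

Two comparator conventions exist in the field and both are offered:
``"scramble"`` (cells with a scramble guide and no guide against the same
target) and ``"without_target"`` (all cells lacking a guide against the
target). Cells bearing both a target guide and a scramble count in the
target group only, since any target guide may perturb the gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .guide_calling import GuideAssignmentSet
from .synthetic import ScreenDataset

__all__ = [
    "GuideSuccessRecord",
    "normalize_expression",
    "test_guide_success",
    "run_guide_qc",
    "summarize_success",
]

#: group sizes at or below which the exact rank-sum null is enumerated
EXACT_MAX_N = 8


@dataclass
class GuideSuccessRecord:
    """Outcome of one guide's knockdown test.

    ``successful`` is None (indeterminate) when either group is below the
    minimum cell count.
    """

    guide_id: str
    target_gene: str
    log_fold_change: float
    p_value: float
    fdr_q: float
    n_guide_cells: int
    n_comparator_cells: int
    successful: bool | None


def normalize_expression(counts, scale: float = 1e4):
    """Library-size normalize to a common total, then log1p.

    Each cell's counts are scaled so they sum to ``scale``, then
    log1p-transformed — the standard shift-log normalization for UMI count
    matrices. Cells with zero total counts map to all-zero rows (with a
    warning) rather than NaN.
    """
    frame = isinstance(counts, pd.DataFrame)
    arr = np.asarray(counts, dtype=float)
    if np.any(arr < 0):
        raise ValueError("expression counts must be nonnegative")
    totals = arr.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} cells have zero total counts; left all-zero",
            stacklevel=2,
        )
    safe = np.where(totals == 0, 1.0, totals)
    out = np.log1p(arr / safe * scale)
    if frame:
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p; exact null when min(n) is small."""
    method = "exact" if min(len(x), len(y)) <= EXACT_MAX_N else "asymptotic"
    try:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    except ValueError:
        # exact method refuses ties in some scipy versions; fall back
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def _log2_fold_change(guide_vals: np.ndarray, comp_vals: np.ndarray) -> float:
    # means on the de-logged scale, pseudocount 1
    g = np.expm1(guide_vals).mean()
    c = np.expm1(comp_vals).mean()
    return float(np.log2((g + 1.0) / (c + 1.0)))


def _comparator_cells(
    assignments: GuideAssignmentSet, target_gene: str, comparator: str, all_cells
) -> set[str]:
    with_target = assignments.cells_with_gene_guide(target_gene)
    if comparator == "scramble":
        return assignments.scramble_cells() - with_target
    if comparator == "without_target":
        return set(all_cells) - with_target
    raise ValueError(
        f"comparator must be 'scramble' or 'without_target', got {comparator!r}"
    )


def test_guide_success(
    dataset: ScreenDataset,
    assignments: GuideAssignmentSet,
    guide_id: str,
    comparator: str = "scramble",
    fdr_threshold: float = 0.05,
    min_cells: int = 3,
    normalized: pd.DataFrame | None = None,
) -> GuideSuccessRecord:
    """Test one guide's knockdown against the comparator population.

    ``fdr_q`` equals the raw p here (single-test family); use
    :func:`run_guide_qc` to adjust across all guides of a run.
    """
    target = assignments.library.target_of(guide_id)
    if target is None:
        raise ValueError(f"scramble guides have no target: {guide_id}")
    if target not in dataset.gene_names:
        raise ValueError(f"target gene {target} not in expression matrix")
    if normalized is None:
        normalized = normalize_expression(dataset.counts_frame())

    guide_cells = sorted(
        {c for c, g in assignments.retained_pairs() if g == guide_id}
    )
    comp_cells = sorted(
        _comparator_cells(assignments, target, comparator, dataset.cell_ids)
    )
    n_g, n_c = len(guide_cells), len(comp_cells)
    if n_g < min_cells or n_c < min_cells:
        return GuideSuccessRecord(
            guide_id, target, np.nan, np.nan, np.nan, n_g, n_c, None
        )
    gv = normalized.loc[guide_cells, target].to_numpy()
    cv = normalized.loc[comp_cells, target].to_numpy()
    p = _rank_sum_p(gv, cv)
    lfc = _log2_fold_change(gv, cv)
    return GuideSuccessRecord(
        guide_id, target, lfc, p, p, n_g, n_c,
        bool(lfc < 0 and p < fdr_threshold),
    )


def run_guide_qc(
    dataset: ScreenDataset,
    assignments: GuideAssignmentSet,
    comparator: str = "scramble",
    fdr_threshold: float = 0.05,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Test every targeting guide; BH-adjust q across the whole run.

    Returns one row per targeting guide with the fields of
    :class:`GuideSuccessRecord`.
    """
    normalized = normalize_expression(dataset.counts_frame())
    records = [
        test_guide_success(
            dataset, assignments, guide, comparator, fdr_threshold, min_cells,
            normalized=normalized,
        )
        for guide in assignments.library.targeting_guides
    ]
    frame = pd.DataFrame([vars(r) for r in records])
    testable = frame["p_value"].notna()
    if testable.any():
        _, q, _, _ = multipletests(
            frame.loc[testable, "p_value"], method="fdr_bh"
        )
        frame.loc[testable, "fdr_q"] = q
        frame.loc[testable, "successful"] = (
            (frame.loc[testable, "log_fold_change"] < 0)
            & (frame.loc[testable, "fdr_q"] < fdr_threshold)
        )
    return frame


def summarize_success(records: pd.DataFrame) -> pd.DataFrame:
    """Per-gene counts of successful / failed / indeterminate guides.

    Genes with zero successful guides are flagged ``excluded`` — they carry
    no evidence of on-target perturbation and should be dropped from
    downstream fate analysis.
    """
    if len(records) == 0:
        return pd.DataFrame(
            columns=["target_gene", "successful", "failed", "indeterminate", "excluded"]
        ).set_index("target_gene")
    rows = []
    for gene, grp in records.groupby("target_gene", sort=True):
        succ = int((grp["successful"] == True).sum())  # noqa: E712
        indet = int(grp["successful"].isna().sum())
        rows.append(
            {
                "target_gene": gene,
                "successful": succ,
                "failed": len(grp) - succ - indet,
                "indeterminate": indet,
                "excluded": succ == 0,
            }
        )
    return pd.DataFrame(rows).set_index("target_gene")
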