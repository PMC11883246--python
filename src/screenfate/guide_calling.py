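"""Guide-capture parsing and ambient-contamination filtering.

Pooled screens read out which guide(s) each cell received through a capture
sequence in the gRNA scaffold, yielding a cells x guides UMI count matrix.
True uptake produces high UMI counts; ambient plasmid or lysed-cell debris
produces sporadic low counts. Assignments are filtered per guide by the
log10-UMI rule: an assignment is kept iff

    log10(umi) >= mean(log10(umi)) - sd_multiplier * sd(log10(umi))

where mean and SD are taken over that guide's cells with at least one UMI
(sample SD, ddof=1). Assignments below the threshold are discarded as
ambient amplification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GuideLibrary",
    "GuideAssignmentSet",
    "filter_ambient",
    "guides_per_cell",
    "cells_with_guide",
]


class GuideLibrary:
    """The guide <-> target-gene map of a pooled screen.

    Wraps a table with columns ``guide_id``, ``target_gene`` and ``scramble``.
    Scramble (non-targeting control) guides carry ``target_gene = None``.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"guide_id", "target_gene", "scramble"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"guide library missing columns: {sorted(missing)}")
        table = table.copy()
        table["target_gene"] = table["target_gene"].where(
            ~table["scramble"].astype(bool), None
        )
        table["target_gene"] = table["target_gene"].replace({np.nan: None, "": None})
        if table["guide_id"].duplicated().any():
            dups = table.loc[table["guide_id"].duplicated(), "guide_id"].tolist()
            raise ValueError(f"duplicate guide ids: {dups}")
        bad = table[~table["scramble"].astype(bool) & table["target_gene"].isna()]
        if len(bad):
            raise ValueError(
                f"targeting guides without a target gene: {bad['guide_id'].tolist()}"
            )
        self.table = table.reset_index(drop=True)

    @classmethod
    def design(
        cls,
        target_genes: list[str] | int,
        guides_per_gene: int = 4,
        n_scramble: int = 2,
    ) -> "GuideLibrary":
        """Build a library from a gene list (or gene count): per-gene guides
        named ``<gene>_g<i>`` plus ``scramble_<j>`` controls."""
        if isinstance(target_genes, int):
            width = max(2, len(str(target_genes)))
            target_genes = [f"GENE{i + 1:0{width}d}" for i in range(target_genes)]
        rows = [
            {"guide_id": f"{g}_g{i + 1}", "target_gene": g, "scramble": False}
            for g in target_genes
            for i in range(guides_per_gene)
        ]
        rows += [
            {"guide_id": f"scramble_{j + 1}", "target_gene": None, "scramble": True}
            for j in range(n_scramble)
        ]
        return cls(pd.DataFrame(rows))

    @property
    def guide_ids(self) -> list[str]:
        return self.table["guide_id"].tolist()

    @property
    def scramble_guides(self) -> list[str]:
        return self.table.loc[self.table["scramble"].astype(bool), "guide_id"].tolist()

    @property
    def targeting_guides(self) -> list[str]:
        return self.table.loc[~self.table["scramble"].astype(bool), "guide_id"].tolist()

    @property
    def target_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.table["target_gene"]:
            if g is not None:
                seen.setdefault(g, None)
        return list(seen)

    def target_of(self, guide_id: str) -> str | None:
        row = self.table.loc[self.table["guide_id"] == guide_id]
        if row.empty:
            raise KeyError(f"unknown guide: {guide_id}")
        return row["target_gene"].iloc[0]

    def guides_for_gene(self, gene: str) -> list[str]:
        return self.table.loc[self.table["target_gene"] == gene, "guide_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def __repr__(self) -> str:
        return (
            f"GuideLibrary({len(self)} guides: {len(self.targeting_guides)} targeting "
            f"{len(self.target_genes)} genes, {len(self.scramble_guides)} scramble)"
        )


@dataclass
class GuideAssignmentSet:
    """Retained and discarded (cell, guide, umi) assignments after ambient
    filtering, with the per-guide log10-UMI threshold that produced them.

    ``thresholds`` maps guide_id -> log10-UMI cutoff; guides never seen with a
    nonzero count have no defined threshold and are listed in ``undetected``.
    """

    assignments: pd.DataFrame  # columns: cell_id, guide_id, umi
    discarded: pd.DataFrame  # same columns
    thresholds: pd.Series  # guide_id -> log10 threshold (NaN if undetected)
    library: GuideLibrary
    undetected: list[str] = field(default_factory=list)

    def retained_pairs(self) -> set[tuple[str, str]]:
        return set(
            zip(self.assignments["cell_id"], self.assignments["guide_id"])
        )

    def cells(self) -> list[str]:
        """Cells carrying at least one retained guide."""
        return self.assignments["cell_id"].unique().tolist()

    def guide_sets_by_cell(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for cell, guide in zip(self.assignments["cell_id"], self.assignments["guide_id"]):
            out.setdefault(cell, set()).add(guide)
        return out

    def cells_with_gene_guide(self, gene: str) -> set[str]:
        """Cells bearing any retained guide that targets ``gene``."""
        guides = set(self.library.guides_for_gene(gene))
        mask = self.assignments["guide_id"].isin(guides)
        return set(self.assignments.loc[mask, "cell_id"])

    def scramble_cells(self) -> set[str]:
        mask = self.assignments["guide_id"].isin(self.library.scramble_guides)
        return set(self.assignments.loc[mask, "cell_id"])


def _as_umi_frame(umi_matrix, library: GuideLibrary, cell_ids) -> pd.DataFrame:
    if isinstance(umi_matrix, pd.DataFrame):
        frame = umi_matrix
        extra = set(frame.columns) - set(library.guide_ids)
        if extra:
            raise ValueError(f"UMI matrix columns not in library: {sorted(extra)}")
        return frame
    arr = np.asarray(umi_matrix)
    if arr.ndim != 2 or arr.shape[1] != len(library):
        raise ValueError(
            f"UMI matrix shape {arr.shape} does not match library size {len(library)}"
        )
    if cell_ids is None:
        cell_ids = [f"cell_{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=list(cell_ids), columns=library.guide_ids)


def filter_ambient(
    umi_matrix,
    library: GuideLibrary,
    sd_multiplier: float = 2.0,
    cell_ids=None,
    pooled: bool = False,
) -> GuideAssignmentSet:
    """Remove ambient guide assignments by the per-guide log10-UMI rule.

    Parameters
    ----------
    umi_matrix
        cells x guides nonnegative integer matrix; a DataFrame indexed by
        cell id with guide-id columns, or an array (then ``cell_ids`` names
        rows and columns follow library order).
    library
        The guide library naming the columns.
    sd_multiplier
        How many sample SDs below the mean log10 UMI the cutoff sits
        (default 2).
    pooled
        If True, compute one mean/SD over all guides' nonzero counts instead
        of per guide. The per-guide statistic is the default because ambient
        background scales with each guide's plasmid abundance.

    Notes
    -----
    Single-pass contract: thresholds are computed once from the input matrix.
    Re-running the filter on the retained assignments recomputes thresholds
    on the already-truncated distribution and may discard more.
    """
    if sd_multiplier < 0:
        raise ValueError("sd_multiplier must be >= 0")
    frame = _as_umi_frame(umi_matrix, library, cell_ids)
    values = frame.to_numpy()
    if np.any(values < 0):
        raise ValueError("guide UMI matrix contains negative counts")

    log_all = None
    if pooled:
        nz = values[values >= 1]
        if nz.size:
            logs = np.log10(nz)
            pooled_mean = logs.mean()
            pooled_sd = logs.std(ddof=1) if logs.size > 1 else 0.0
            log_all = pooled_mean - sd_multiplier * pooled_sd

    kept_rows, drop_rows = [], []
    thresholds: dict[str, float] = {}
    undetected: list[str] = []
    cells = np.asarray(frame.index)
    for guide in library.guide_ids:
        if guide not in frame.columns:
            thresholds[guide] = np.nan
            undetected.append(guide)
            continue
        col = frame[guide].to_numpy()
        nz_mask = col >= 1
        if not nz_mask.any():
            thresholds[guide] = np.nan
            undetected.append(guide)
            continue
        logs = np.log10(col[nz_mask])
        if pooled:
            thr = log_all
        else:
            m = logs.mean()
            s = logs.std(ddof=1) if logs.size > 1 else 0.0
            thr = m - sd_multiplier * s
        thresholds[guide] = thr
        keep = logs >= thr
        nz_cells = cells[nz_mask]
        nz_counts = col[nz_mask]
        for cell, umi, ok in zip(nz_cells, nz_counts, keep):
            (kept_rows if ok else drop_rows).append(
                {"cell_id": cell, "guide_id": guide, "umi": int(umi)}
            )

    cols = ["cell_id", "guide_id", "umi"]
    assignments = pd.DataFrame(kept_rows, columns=cols)
    discarded = pd.DataFrame(drop_rows, columns=cols)
    return GuideAssignmentSet(
        assignments=assignments,
        discarded=discarded,
        thresholds=pd.Series(thresholds, name="log10_threshold"),
        library=library,
        undetected=undetected,
    )


def guides_per_cell(assignments: GuideAssignmentSet, all_cells=None) -> pd.Series:
    """Number of distinct retained guides per cell.

    ``all_cells`` optionally supplies the full cell universe so that cells
    with no retained guide are reported as 0.
    """
    counts = (
        assignments.assignments.groupby("cell_id")["guide_id"].nunique()
        if len(assignments.assignments)
        else pd.Series(dtype=int)
    )
    if all_cells is not None:
        counts = counts.reindex(list(all_cells), fill_value=0)
    return counts.astype(int).rename("n_guides")


def cells_with_guide(assignments: GuideAssignmentSet, guide_id: str) -> set[str]:
    """Retained cells for one guide; raises on a guide not in the library."""
    if guide_id not in assignments.library.guide_ids:
        raise KeyError(f"unknown guide: {guide_id}")
    mask = assignments.assignments["guide_id"] == guide_id
    return set(assignments.assignments.loc[mask, "cell_id"])
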