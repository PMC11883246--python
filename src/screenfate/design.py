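"""Screen design: cells needed per guide and guides per embryo.

A pooled in-vivo screen is capacity-limited: the electroporatable target
tissue holds a few thousand progenitor cells, and every guide must land in
enough cells to detect a shift in its detection count. The two-sample
difference-of-means sample size

    n = (Z_{1-alpha/2} + Z_power)^2 (sigma^2 + sigma_avg^2) / delta^2

gives the cells required per guide to detect a difference of ``delta``
cells in guide detection, where ``sigma`` is the per-gene SD of guide
detection and ``sigma_avg`` the average SD across target genes (two
variance terms because the compared populations are unequal). Dividing the
accessible tissue (tissue size x electroporation efficacy) by that number
bounds how many guides one embryo can host.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

__all__ = [
    "PowerDesign",
    "CapacityEstimate",
    "cells_per_guide",
    "guide_capacity",
    "guide_detection_sd",
]


@dataclass
class PowerDesign:
    """Inputs and result of the cells-per-guide power calculation."""

    alpha: float
    power: float
    delta: float
    sigma: float
    sigma_avg: float
    z_alpha: float
    z_power: float
    n_per_guide: float
    n_rounded: int


@dataclass
class CapacityEstimate:
    """How many guides one embryo's target tissue can host."""

    tissue_cells: int
    efficacy: float
    cells_per_guide: int
    max_guides: int


def cells_per_guide(
    alpha: float = 0.05,
    power: float = 0.8,
    delta: float = 50.0,
    sigma: float = 100.0,
    sigma_avg: float = 100.0,
) -> PowerDesign:
    """Cells required per guide for a detectable detection-count shift.

    ``delta`` is the difference in guide-detection cells to resolve;
    ``sigma`` / ``sigma_avg`` are the per-gene and gene-averaged SDs of
    guide detection. Returns both the real-valued n and its nearest-integer
    rounding.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if not 0.0 < power < 1.0:
        raise ValueError("power must be in (0, 1)")
    if delta <= 0:
        raise ValueError("delta must be > 0 (a zero difference is undetectable)")
    if sigma < 0 or sigma_avg < 0:
        raise ValueError("standard deviations must be >= 0")
    z_alpha = stats.norm.ppf(1.0 - alpha / 2.0)
    z_power = stats.norm.ppf(power)
    n = (z_alpha + z_power) ** 2 * (sigma**2 + sigma_avg**2) / delta**2
    return PowerDesign(
        alpha=alpha,
        power=power,
        delta=delta,
        sigma=sigma,
        sigma_avg=sigma_avg,
        z_alpha=float(z_alpha),
        z_power=float(z_power),
        n_per_guide=float(n),
        n_rounded=int(round(n)),
    )


def guide_capacity(
    tissue_cells: int, efficacy: float, cells_per_guide: int
) -> CapacityEstimate:
    """Guides electroporatable per embryo: floor(tissue x efficacy / n).

    The floor reflects that a fractional guide cannot be delivered.
    """
    if tissue_cells <= 0:
        raise ValueError("tissue_cells must be > 0")
    if not 0.0 < efficacy <= 1.0:
        raise ValueError("efficacy must be in (0, 1]")
    if cells_per_guide <= 0:
        raise ValueError("cells_per_guide must be > 0")
    max_guides = math.floor(tissue_cells * efficacy / cells_per_guide)
    return CapacityEstimate(
        tissue_cells=int(tissue_cells),
        efficacy=float(efficacy),
        cells_per_guide=int(cells_per_guide),
        max_guides=int(max_guides),
    )


def guide_detection_sd(assignments, clusters=None) -> pd.Series:
    """Per-gene SD of guide-detection counts, for pilot-based sigma.

    For each target gene, the SD (ddof=1) across its guides of the number
    of cells each guide was detected in. Genes with a single guide get SD 0.
    """
    counts = assignments.assignments.groupby("guide_id")["cell_id"].nunique()
    lib = assignments.library.table
    rows = {}
    for gene, grp in lib[~lib["scramble"].astype(bool)].groupby("target_gene"):
        vals = counts.reindex(grp["guide_id"], fill_value=0).astype(float)
        rows[gene] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return pd.Series(rows, name="detection_sd").sort_index()
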