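"""Per-cell HCR quantification: positivity, classes, co-expression, shape.

Works on per-cell measurement tables (cell centres plus nuclear / hood /
cytoplasm channel averages, where the "hood" is a slight dilation of the
nuclear mask used as a proxy for total transcript per cell). Hood averages
are first normalized to DAPI to cancel imaging artefacts; a cell is called
positive for a channel when its normalized value exceeds the sample mean of
that channel's distribution. TBXT gets a three-way expression-level class
(high > 0.4 marks notochord, medium > 0.3 marks CLE/primitive streak,
else negative). Region masks are scored by tortuosity = perimeter / area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = [
    "PositivityCalls",
    "normalize_to_dapi",
    "call_positive",
    "classify_tbxt",
    "quantify_hcr",
    "coexpression_overlap",
    "cluster_profiles",
    "mask_tortuosity",
    "positive_fraction_in_mask",
]

TBXT_HIGH = 0.4  # normalized level above which a cell is notochord-like
TBXT_MEDIUM = 0.3  # above this (and <= high) marks CLE / primitive streak


@dataclass
class PositivityCalls:
    """DAPI-normalized values, boolean positivity, optional TBXT classes."""

    normalized: pd.DataFrame  # cells x channels
    positive: pd.DataFrame  # cells x channels, bool
    tbxt_class: pd.Series | None = None  # high / medium / negative


def _channels_of(table: pd.DataFrame) -> list[str]:
    return [c[: -len("_hood")] for c in table.columns if c.endswith("_hood")]


def normalize_to_dapi(
    table: pd.DataFrame, channels: list[str] | None = None
) -> pd.DataFrame:
    """Hood average / DAPI per cell and channel.

    ``table`` needs a ``dapi`` column plus ``<channel>_hood`` columns (a
    ``cell_id`` column, if present, becomes the index). DAPI must be
    strictly positive; offending cells are named in the error.
    """
    if "cell_id" in table.columns:
        table = table.set_index("cell_id")
    if "dapi" not in table.columns:
        raise ValueError("table has no 'dapi' column")
    bad = table.index[table["dapi"] <= 0]
    if len(bad):
        raise ValueError(f"nonpositive DAPI for cells: {list(bad[:5])}")
    if channels is None:
        channels = _channels_of(table)
    out = {}
    for ch in channels:
        col = f"{ch}_hood"
        if col not in table.columns:
            raise ValueError(f"missing hood column for channel {ch}")
        out[ch] = table[col] / table["dapi"]
    return pd.DataFrame(out, index=table.index)


def call_positive(normalized, channel: str | None = None) -> pd.Series:
    """Positive iff strictly above the within-channel sample mean.

    Accepts a Series (one channel) or a DataFrame plus ``channel``. With
    all values equal, nothing exceeds the mean, so all calls are False.
    """
    values = normalized[channel] if channel is not None else normalized
    if not isinstance(values, pd.Series):
        raise ValueError("pass a Series, or a DataFrame with channel=")
    if len(values) < 2:
        raise ValueError("need >= 2 cells to threshold on the sample mean")
    return (values > values.mean()).rename(values.name)


def classify_tbxt(
    normalized: pd.Series, high: float = TBXT_HIGH, medium: float = TBXT_MEDIUM
) -> pd.Series:
    """Three-way TBXT level: high (> 0.4), medium (> 0.3), else negative.

    Both cutoffs are strict, so exactly 0.4 is medium and exactly 0.3 is
    negative.
    """
    out = pd.Series("negative", index=normalized.index, dtype=object)
    out[normalized > medium] = "medium"
    out[normalized > high] = "high"
    return out.rename("tbxt_class")


def quantify_hcr(
    table: pd.DataFrame,
    channels: list[str] | None = None,
    tbxt_channel: str | None = None,
) -> PositivityCalls:
    """Normalize, threshold and (optionally) class a measurement table."""
    normalized = normalize_to_dapi(table, channels)
    positive = pd.DataFrame(
        {ch: call_positive(normalized[ch]) for ch in normalized.columns}
    )
    tbxt = None
    if tbxt_channel is not None:
        if tbxt_channel not in normalized.columns:
            raise ValueError(f"channel {tbxt_channel} not in table")
        tbxt = classify_tbxt(normalized[tbxt_channel])
    return PositivityCalls(normalized, positive, tbxt)


def coexpression_overlap(
    denominator_cells,
    other_cells,
    coordinates: pd.DataFrame | None = None,
) -> tuple[float, pd.DataFrame | None]:
    """Fraction of a reference population co-positive for a second marker.

    ``denominator_cells`` is the reference set A (e.g. the cells of one
    TBXT level class); ``other_cells`` the comparison set B. Returns
    |A n B| / |A| and, when cell-centre ``coordinates`` are supplied, the
    co-positive cells with their coordinates for map export. An empty
    denominator yields NaN (reported missing, not an error).
    """
    a = set(denominator_cells)
    b = set(other_cells)
    if not a:
        return float("nan"), None
    co = sorted(a & b)
    fraction = len(co) / len(a)
    co_table = None
    if coordinates is not None:
        co_table = coordinates.loc[coordinates.index.intersection(co)].copy()
    return fraction, co_table


def cluster_profiles(
    normalized: pd.DataFrame,
    n_groups: int | None = None,
    cut_height: float | None = None,
) -> tuple[list, pd.Series]:
    """Average-linkage hierarchical clustering of per-cell channel profiles.

    Returns the dendrogram leaf order and a flat grouping, cut either into
    ``n_groups`` clusters or at ``cut_height`` (Euclidean distance).
    Rows are pre-sorted by cell id so that ties resolve deterministically.
    """
    if len(normalized) < 2:
        raise ValueError("need >= 2 cells to cluster")
    ordered = normalized.sort_index(kind="stable")
    link = hierarchy.linkage(ordered.to_numpy(float), method="average",
                             metric="euclidean")
    leaf_order = [ordered.index[i] for i in hierarchy.leaves_list(link)]
    if n_groups is not None:
        flat = hierarchy.fcluster(link, t=n_groups, criterion="maxclust")
    elif cut_height is not None:
        flat = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    else:
        flat = np.ones(len(ordered), dtype=int)
    groups = pd.Series(flat, index=ordered.index, name="group")
    return leaf_order, groups.reindex(normalized.index)


def mask_tortuosity(mask) -> float:
    """Perimeter / area of a binary region mask.

    Area is the foreground pixel count; perimeter counts foreground pixel
    edges adjacent to background or to the grid boundary (4-connectivity
    edge count), so a solid k x k square scores 4k / k^2 = 4/k.
    """
    m = np.asarray(mask).astype(bool)
    if m.ndim != 2:
        raise ValueError("mask must be a 2-D grid")
    area = int(m.sum())
    if area == 0:
        raise ValueError("empty mask")
    padded = np.pad(m, 1, constant_values=False)
    perimeter = 0
    for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neighbour = np.roll(padded, shift, axis=(0, 1))
        perimeter += int(np.sum(padded & ~neighbour))
    return perimeter / area


def positive_fraction_in_mask(
    positive: pd.Series, in_mask: pd.Series
) -> float:
    """Fraction of in-mask cells called positive (e.g. Pax6+ in neural tube)."""
    positive, in_mask = positive.align(in_mask)
    member = in_mask.fillna(False).astype(bool)
    n = int(member.sum())
    if n == 0:
        raise ValueError("no cells fall inside the mask")
    return float(positive[member].fillna(False).astype(bool).sum() / n)
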