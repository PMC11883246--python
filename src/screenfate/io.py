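"""Reading screens back from the 10x-style plain-text export."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

from .guide_calling import GuideLibrary
from .synthetic import GroundTruth, ScreenDataset

__all__ = ["read_screen", "read_guide_umis_csv"]


def read_screen(indir: str | Path) -> tuple[ScreenDataset, GroundTruth | None]:
    """Load a screen directory written by :func:`screenfate.write_screen`.

    Expects ``matrix.mtx`` (genes x cells), ``barcodes.tsv``,
    ``features.tsv``, ``guide_umis.mtx`` (cells x guides), ``guides.csv``
    and ``clusters.csv``; ``ground_truth.json`` is loaded when present.
    """
    indir = Path(indir)
    cell_ids = (indir / "barcodes.tsv").read_text().split()
    gene_names = (indir / "features.tsv").read_text().split()
    counts = np.asarray(mmread(indir / "matrix.mtx").todense()).T.astype(int)
    guide_umis = np.asarray(mmread(indir / "guide_umis.mtx").todense()).astype(int)
    library = GuideLibrary(pd.read_csv(indir / "guides.csv"))
    clusters = pd.read_csv(indir / "clusters.csv", index_col="cell_id")["cluster"]
    truth = None
    truth_path = indir / "ground_truth.json"
    if truth_path.exists():
        truth = GroundTruth.from_json(truth_path.read_text())
    dataset = ScreenDataset(
        counts=counts,
        gene_names=gene_names,
        cell_ids=cell_ids,
        guide_umis=guide_umis,
        library=library,
        clusters=clusters,
    )
    return dataset, truth


def read_guide_umis_csv(path: str | Path, library: GuideLibrary) -> pd.DataFrame:
    """Long-format guide UMIs (cell_id, guide_id, umi) -> cells x guides."""
    long = pd.read_csv(path)
    required = {"cell_id", "guide_id", "umi"}
    if not required <= set(long.columns):
        raise ValueError(f"CSV must have columns {sorted(required)}")
    wide = long.pivot_table(
        index="cell_id", columns="guide_id", values="umi",
        aggfunc="sum", fill_value=0,
    )
    return wide.reindex(columns=library.guide_ids, fill_value=0).astype(int)
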