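"""Seeded synthetic pooled-screen generator with planted ground truth.

Emulates the statistical structure of a pooled in-vivo CRISPR screen read
out by droplet scRNA-seq with guide capture:

* ~14 fate clusters with uneven proportions;
* a 25-gene x 4-guide library plus 2 scramble controls (102 guides);
* multi-guide cells (electroporation delivers several plasmids per cell;
  guides per cell modelled as a zero-inflated zero-truncated Poisson capped
  at a maximum);
* high-UMI true guide capture vs low-UMI ambient contamination;
* target-gene knockdown in guide-bearing cells (negative-binomial counts
  with the target mean scaled by a knockdown fraction);
* fate-shift effects: a multiplicative tilt on a perturbed cell's
  cluster-probability vector, renormalized.

Every planted effect is recorded in a :class:`GroundTruth` so downstream
stages can be scored against truth. All randomness flows through one
``numpy.random.Generator`` seeded from the config: identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.io import mmwrite

from .guide_calling import GuideLibrary

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ScreenDataset",
    "simulate_screen",
    "simulate_hcr_table",
    "write_screen",
]


def _default_proportions(k: int) -> np.ndarray:
    # uneven cluster sizes: harmonic decay, largest cluster dominant
    p = 1.0 / np.arange(1, k + 1)
    return p / p.sum()


@dataclass
class SimulationConfig:
    """Generative parameters of a synthetic screen.

    Defaults mirror the screen design being emulated: 25 target genes x 4
    guides + 2 scrambles (102 guides), 14 uneven fate clusters, several
    guides per cell, strong (80%) knockdown of targeted genes, and sparse
    low-UMI ambient contamination well separated from true capture.
    """

    n_cells: int = 3000
    n_clusters: int = 14
    cluster_proportions: np.ndarray | None = None
    n_target_genes: int = 25
    guides_per_gene: int = 4
    n_scramble: int = 2
    guides_per_cell_mean: float = 3.0
    guides_per_cell_max: int = 29
    zero_guide_fraction: float = 0.15
    ambient_rate: float = 0.5  # expected ambient assignments per cell
    true_guide_umi_mean: float = 50.0
    ambient_umi_mean: float = 1.0
    knockdown_fraction: float | dict[str, float] = 0.2  # remaining expression
    fate_effect: dict[tuple[str, int], float] = field(default_factory=dict)
    n_background_genes: int = 100
    target_gene_mean: float = 5.0
    background_log_mean: float = 0.5
    background_log_sd: float = 1.0
    dispersion: float = 0.5  # NB: var = mu + dispersion * mu^2
    baseline_expression: pd.DataFrame | None = None  # genes x clusters means
    seed: int = 0

    def proportions(self) -> np.ndarray:
        if self.cluster_proportions is None:
            return _default_proportions(self.n_clusters)
        p = np.asarray(self.cluster_proportions, dtype=float)
        return p

    def validate(self) -> None:
        p = self.proportions()
        if len(p) != self.n_clusters:
            raise ValueError(
                f"cluster_proportions has length {len(p)}, expected {self.n_clusters}"
            )
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("cluster_proportions must be nonnegative and sum to 1")
        for name, v in [
            ("guides_per_cell_mean", self.guides_per_cell_mean),
            ("true_guide_umi_mean", self.true_guide_umi_mean),
            ("ambient_umi_mean", self.ambient_umi_mean),
            ("target_gene_mean", self.target_gene_mean),
            ("dispersion", self.dispersion),
        ]:
            if v <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.ambient_umi_mean >= self.true_guide_umi_mean:
            raise ValueError("ambient_umi_mean must be well below true_guide_umi_mean")
        if not 0.0 <= self.zero_guide_fraction <= 1.0:
            raise ValueError("zero_guide_fraction must be in [0, 1]")
        if self.ambient_rate < 0:
            raise ValueError("ambient_rate must be >= 0")
        kf = self.knockdown_fraction
        fracs = kf.values() if isinstance(kf, dict) else [kf]
        for f in fracs:
            if not 0.0 <= f <= 1.0:
                raise ValueError("knockdown_fraction must be in [0, 1]")
        genes = self.target_gene_names()
        for (gene, cluster), factor in self.fate_effect.items():
            if gene not in genes:
                raise ValueError(f"fate_effect references unknown gene: {gene}")
            if not 0 <= cluster < self.n_clusters:
                raise ValueError(f"fate_effect references unknown cluster: {cluster}")
            if factor < 0:
                raise ValueError("fate_effect factors must be >= 0")

    def target_gene_names(self) -> list[str]:
        width = max(2, len(str(self.n_target_genes)))
        return [f"GENE{i + 1:0{width}d}" for i in range(self.n_target_genes)]

    def gene_names(self) -> list[str]:
        width = max(3, len(str(self.n_background_genes)))
        bg = [f"BG{i + 1:0{width}d}" for i in range(self.n_background_genes)]
        return self.target_gene_names() + bg

    def knockdown_for(self, gene: str) -> float:
        if isinstance(self.knockdown_fraction, dict):
            return self.knockdown_fraction.get(gene, 1.0)
        return self.knockdown_fraction


@dataclass
class GroundTruth:
    """Planted effects of one simulated screen."""

    true_assignments: set[tuple[str, str]]
    ambient_assignments: set[tuple[str, str]]
    planted_fate_effects: list[tuple[str, int, float]]
    planted_knockdowns: list[tuple[str, float]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "true_assignments": sorted(self.true_assignments),
                "ambient_assignments": sorted(self.ambient_assignments),
                "planted_fate_effects": self.planted_fate_effects,
                "planted_knockdowns": self.planted_knockdowns,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            true_assignments={tuple(t) for t in d["true_assignments"]},
            ambient_assignments={tuple(t) for t in d["ambient_assignments"]},
            planted_fate_effects=[tuple(t) for t in d["planted_fate_effects"]],
            planted_knockdowns=[tuple(t) for t in d["planted_knockdowns"]],
        )


@dataclass
class ScreenDataset:
    """One screen: expression counts, guide-capture UMIs, cluster labels."""

    counts: np.ndarray  # cells x genes, integer
    gene_names: list[str]
    cell_ids: list[str]
    guide_umis: np.ndarray  # cells x guides, integer
    library: GuideLibrary
    clusters: pd.Series  # cell_id -> cluster label (int)

    def guide_umi_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.guide_umis, index=self.cell_ids, columns=self.library.guide_ids
        )

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.cell_ids, columns=self.gene_names)

    def to_anndata(self):
        import anndata as ad

        adata = ad.AnnData(
            X=sparse.csr_matrix(self.counts),
            obs=pd.DataFrame(
                {"cluster": self.clusters.reindex(self.cell_ids).to_numpy()},
                index=self.cell_ids,
            ),
            var=pd.DataFrame(index=self.gene_names),
        )
        adata.obsm["guide_umis"] = self.guide_umis
        adata.uns["guide_library"] = self.library.table
        return adata


def _zero_truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Poisson(lam) conditioned on >= 1, by inverse transform."""
    p0 = np.exp(-lam)
    u = rng.uniform(p0, 1.0, size=size)
    return stats.poisson.ppf(u, lam).astype(int)


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean mu and var mu + dispersion*mu^2."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=int)
    pos = mu > 0
    if pos.any():
        r = 1.0 / dispersion
        p = r / (r + mu[pos])
        out[pos] = rng.negative_binomial(r, p)
    return out


def simulate_screen(config: SimulationConfig) -> tuple[ScreenDataset, GroundTruth]:
    """Generate one seeded screen and its planted ground truth.

    The generative order is: guide uptake per cell -> fate-cluster label
    (tilted by any fate effect of the cell's target genes) -> expression
    counts (target means scaled by the knockdown fraction in perturbed
    cells) -> guide-capture UMIs (high-mean for true assignments, sparse
    low-mean truncated-Poisson ambient elsewhere).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    library = GuideLibrary.design(
        config.target_gene_names(), config.guides_per_gene, config.n_scramble
    )
    guide_ids = library.guide_ids
    n_guides = len(guide_ids)
    n_cells = config.n_cells
    cell_ids = [f"cell_{i:05d}" for i in range(n_cells)]
    target_of = dict(zip(library.table["guide_id"], library.table["target_gene"]))

    # --- guide uptake -----------------------------------------------------
    has_guides = rng.uniform(size=n_cells) >= config.zero_guide_fraction
    k = np.zeros(n_cells, dtype=int)
    idx = np.flatnonzero(has_guides)
    k[idx] = _zero_truncated_poisson(rng, config.guides_per_cell_mean, idx.size)
    k = np.minimum(k, min(config.guides_per_cell_max, n_guides))

    cell_guides: list[list[int]] = []
    for i in range(n_cells):
        if k[i] == 0:
            cell_guides.append([])
        else:
            cell_guides.append(list(rng.choice(n_guides, size=k[i], replace=False)))

    # --- fate-cluster labels ---------------------------------------------
    base_p = config.proportions()
    effects_by_gene: dict[str, list[tuple[int, float]]] = {}
    for (gene, cluster), factor in config.fate_effect.items():
        effects_by_gene.setdefault(gene, []).append((cluster, factor))

    labels = np.empty(n_cells, dtype=int)
    for i in range(n_cells):
        genes_here = {
            target_of[guide_ids[j]]
            for j in cell_guides[i]
            if target_of[guide_ids[j]] is not None
        }
        tilted = [g for g in genes_here if g in effects_by_gene]
        if tilted:
            p = base_p.copy()
            for g in tilted:
                for cluster, factor in effects_by_gene[g]:
                    p[cluster] *= factor
            total = p.sum()
            if total <= 0:
                raise ValueError("fate_effect factors drove all cluster mass to zero")
            p = p / total
            labels[i] = rng.choice(config.n_clusters, p=p)
        else:
            labels[i] = rng.choice(config.n_clusters, p=base_p)

    # --- expression counts -------------------------------------------------
    gene_names = config.gene_names()
    target_genes = config.target_gene_names()
    if config.baseline_expression is not None:
        base_means = config.baseline_expression.reindex(gene_names)
        if base_means.isna().any().any():
            raise ValueError("baseline_expression missing genes or has NaNs")
        mean_matrix = base_means.to_numpy()[:, labels].T  # cells x genes
    else:
        gene_mu = np.empty(len(gene_names))
        gene_mu[: len(target_genes)] = config.target_gene_mean
        gene_mu[len(target_genes):] = rng.lognormal(
            config.background_log_mean, config.background_log_sd,
            size=config.n_background_genes,
        )
        mean_matrix = np.tile(gene_mu, (n_cells, 1))

    gene_index = {g: i for i, g in enumerate(gene_names)}
    knockdowns: list[tuple[str, float]] = [
        (g, config.knockdown_for(g)) for g in target_genes
    ]
    for i in range(n_cells):
        for j in cell_guides[i]:
            gene = target_of[guide_ids[j]]
            if gene is not None:
                mean_matrix[i, gene_index[gene]] *= config.knockdown_for(gene)

    counts = _nb_sample(rng, mean_matrix, config.dispersion)

    # --- guide-capture UMIs -------------------------------------------------
    umis = np.zeros((n_cells, n_guides), dtype=int)
    true_pairs: set[tuple[str, str]] = set()
    for i in range(n_cells):
        for j in cell_guides[i]:
            umis[i, j] = max(1, rng.poisson(config.true_guide_umi_mean))
            true_pairs.add((cell_ids[i], guide_ids[j]))

    ambient_pairs: set[tuple[str, str]] = set()
    if config.ambient_rate > 0:
        p_amb = min(1.0, config.ambient_rate / n_guides)
        amb = rng.uniform(size=(n_cells, n_guides)) < p_amb
        amb &= umis == 0  # ambient cannot overwrite a true assignment
        rows, cols = np.nonzero(amb)
        if rows.size:
            umis[rows, cols] = _zero_truncated_poisson(
                rng, config.ambient_umi_mean, rows.size
            )
            ambient_pairs = {
                (cell_ids[r], guide_ids[c]) for r, c in zip(rows, cols)
            }

    dataset = ScreenDataset(
        counts=counts,
        gene_names=gene_names,
        cell_ids=cell_ids,
        guide_umis=umis,
        library=library,
        clusters=pd.Series(labels, index=cell_ids, name="cluster"),
    )
    truth = GroundTruth(
        true_assignments=true_pairs,
        ambient_assignments=ambient_pairs,
        planted_fate_effects=[
            (gene, cluster, factor)
            for (gene, cluster), factor in sorted(config.fate_effect.items())
        ],
        planted_knockdowns=knockdowns,
    )
    return dataset, truth


def simulate_hcr_table(
    n_cells: int,
    channel_means: dict[str, float],
    positive_fraction: dict[str, float],
    seed: int = 0,
    negative_level: float = 0.2,
    log_sd: float = 0.25,
    dapi_mean: float = 1.0,
    dapi_log_sd: float = 0.1,
    domain: tuple[float, float] = (500.0, 500.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a per-cell HCR measurement table with planted positives.

    Each channel's hood average is lognormal around ``channel_means[ch]`` for
    planted-positive cells and around ``negative_level * channel_means[ch]``
    otherwise; DAPI is lognormal around ``dapi_mean`` and strictly positive.
    Cell centres are uniform on a 2-D rectangle.

    Returns
    -------
    (table, truth)
        ``table`` has columns ``cell_id, x, y, dapi, <ch>_nuclear, <ch>_hood,
        <ch>_cyto`` per channel; ``truth`` holds the planted boolean positive
        label per channel.
    """
    rng = np.random.default_rng(seed)
    for ch, mu in channel_means.items():
        if mu <= 0:
            raise ValueError(f"channel mean for {ch} must be positive")
    for ch, frac in positive_fraction.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"positive_fraction for {ch} must be in [0, 1]")

    cell_ids = [f"cell_{i:04d}" for i in range(n_cells)]
    table = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "x": rng.uniform(0, domain[0], n_cells),
            "y": rng.uniform(0, domain[1], n_cells),
            "dapi": rng.lognormal(np.log(dapi_mean), dapi_log_sd, n_cells),
        }
    )
    truth = pd.DataFrame({"cell_id": cell_ids})
    for ch, mu in channel_means.items():
        frac = positive_fraction.get(ch, 0.0)
        positive = rng.uniform(size=n_cells) < frac
        level = np.where(positive, mu, negative_level * mu)
        hood = rng.lognormal(np.log(level), log_sd)
        table[f"{ch}_hood"] = hood
        table[f"{ch}_nuclear"] = hood * rng.lognormal(0.0, 0.1, n_cells)
        table[f"{ch}_cyto"] = 0.5 * hood * rng.lognormal(0.0, 0.1, n_cells)
        truth[f"{ch}_positive"] = positive
    return table, truth


def write_screen(
    dataset: ScreenDataset,
    truth: GroundTruth | None,
    outdir: str | Path,
    hcr_table: pd.DataFrame | None = None,
) -> None:
    """Export a screen in 10x-style plain-text form.

    Writes ``matrix.mtx`` (genes x cells), ``barcodes.tsv``, ``features.tsv``,
    ``guide_umis.mtx`` (cells x guides), ``guides.csv``, ``clusters.csv``,
    ``ground_truth.json`` and, if given, ``hcr_cells.csv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(dataset.counts.T))
    (outdir / "barcodes.tsv").write_text("\n".join(dataset.cell_ids) + "\n")
    (outdir / "features.tsv").write_text("\n".join(dataset.gene_names) + "\n")
    mmwrite(outdir / "guide_umis.mtx", sparse.csr_matrix(dataset.guide_umis))
    dataset.library.table.to_csv(outdir / "guides.csv", index=False)
    dataset.clusters.rename_axis("cell_id").to_frame().to_csv(outdir / "clusters.csv")
    if truth is not None:
        (outdir / "ground_truth.json").write_text(truth.to_json())
    if hcr_table is not None:
        hcr_table.to_csv(outdir / "hcr_cells.csv", index=False)
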