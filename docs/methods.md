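# Methods

## Scope and data model

The package analyses pooled CRISPR fate screens in which each sequenced
cell carries (i) an expression profile already assigned to a fate cluster,
and (ii) a guide-capture UMI count vector over the library. Clustering,
alignment and feature selection are upstream concerns: cluster labels and
the restricted analysis gene list arrive as inputs. The library must
contain at least one scramble (non-targeting) guide; scramble cells define
the null fate distribution throughout.

## Ambient guide filtering

Droplet guide capture mixes true uptake (tens of UMIs) with ambient
contamination (1–3 UMIs). For each guide, over its cells with ≥1 UMI, we
compute the mean m and sample SD s (ddof = 1) of log10(UMI) and retain an
assignment iff log10(UMI) ≥ m − k·s, default k = 2. Conventions fixed
here:

- **Per-guide statistics** by default: ambient background scales with each
  guide's plasmid abundance. A `pooled=True` flag computes one mean/SD over
  all guides' nonzero counts instead.
- **Sample SD**, because per-guide cell numbers are small; a guide seen in
  a single cell gets s = 0 and is retained.
- **Boundary**: values exactly at the threshold are retained (≥); only
  strictly lower values are discarded.
- Guides never detected (no nonzero cell) have no defined threshold; they
  are flagged `undetected`, not an error — guide dropout is expected.
- Single-pass contract: thresholds come from the input matrix once.
  Re-filtering the retained set recomputes thresholds on a truncated
  distribution and may discard more; callers should filter raw counts.

## Knockdown QC

A guide's cells are compared to a comparator population on the target
gene's normalized expression (counts scaled per cell to 10,000 and
log1p-transformed; zero-total cells stay zero with a warning). The test is
a two-sided Wilcoxon rank-sum: exact null when the smaller group has ≤ 8
cells, normal approximation with tie correction otherwise. Log2 fold
changes use group means on the de-logged scale with pseudocount 1. BH
adjustment runs across all guides of one run; `successful` requires
negative fold change and q below the FDR threshold (default 5%). Groups
below `min_cells` (default 3) give an indeterminate record rather than an
exception.

Two comparator conventions circulate for this design and both are
implemented: `"scramble"` (default) — cells bearing a scramble guide and
no guide against the same target — and `"without_target"` — every cell
lacking a guide against the target. Cells carrying both a target guide and
a scramble count in the target group only, since any target guide may
perturb the gene. Genes with zero successful guides are flagged for
exclusion from fate analysis.

## Fate enrichment

Representation r(g,c) is the fraction of cluster c's cells carrying guide
g; cells with several guides count once per guide, so rows are not
disjoint.

**Cross-validated scores.** Cells are split into n_folds = 5 folds,
stratified by cluster (seeded shuffle, round-robin). Per fold,
enrichment(g,c) = log2((r_fold(g,c)+ε)/(mean over scramble guides of
r_fold+ε)) with ε = 1/(fold cluster size + 1); we report mean and sample
SD over folds. The ε choice keeps log-ratios finite for empty cells while
shrinking with cluster size; with one fold the score is the whole-data
log-ratio exactly.

**χ² tests and z-scores.** Each guide's cluster count vector is stacked on
a reference row into a 2×K table — reference either scramble-1's counts or
the average counts across all guides (fractional rows are fine for the
Pearson statistic); both are always reported, and the per-cluster calls
default to the all-guide average. The per-cluster "z-score" is the
adjusted standardized residual

    z = (O − E) / sqrt(E (1 − row_tot/N)(1 − col_tot/N)),

which is standard normal under independence, making the ±2 call threshold
meaningful; the plain Pearson residual (O−E)/√E is available by flag.
Clusters with expected count < 1 are pooled into a remainder category that
enters the statistic but receives no per-cluster call. All-zero guide rows
are flagged untestable. Because a gene's fate shift is shared by its
guides, `gene_cluster_counts` pools a gene's guide-bearing cells into one
row for the gene-level version of the same test — the most powerful unit
for planted-effect recovery, and the unit used by the acceptance checks.

**KLD cross-validation test.** The guide's cells are shuffled and split
into 5 folds; each fold's cluster distribution and the scramble-cell
distribution are smoothed by adding 1/K per cluster and renormalizing, and
D_KL(fold‖scramble) in nats is averaged over folds. The base of the
logarithm is e (configurable via `kl_divergence`). Significance comes from
an assumption-free permutation null: guide and scramble cells are pooled,
group labels permuted (vectorized over permutations), and
p = (1 + #{perm ≥ observed})/(n_permutations + 1), so p ∈ (0,1] and the
test is exact-level. Guides with fewer cells than folds are indeterminate.

**Pattern grouping and PCA.** K-means (10 restarts, seeded) runs for
k = 1..k_max; the chosen k maximizes the second difference of the
within-cluster distance curve (the sharpest elbow), falling back to k = 1
when rows are identical. PCA is column-centered; components with
numerically zero variance are dropped, so a constant matrix yields an
empty component set.

## Perturbation signatures

Per-gene standardized expression is regressed on
[intercept | guide indicators] with an L2 penalty on guide coefficients
only (default 0.1; zero is allowed and raises a clear error if the design
is singular). Scramble cells are the all-zero reference row; multi-guide
cells carry 1 in each of their guides' columns, which is what makes the
coefficient a "corrected" readout relative to naive group means. p-values
permute the cell→guide label rows jointly,
p = (1 + #{|coef_perm| ≥ |coef_obs|})/(B + 1). Gene-level significance
uses raw p < 0.05 for the misregulated sets while BH q is exported
alongside; term-level ORA significance uses adjusted p < 0.05. That
asymmetry is deliberate and mirrors common screen practice at these two
levels.

Over-representation is a local one-sided Fisher exact test of the
misregulated set against each GMT term (terms intersected with the
supplied universe), BH-adjusted across terms — no live annotation
services. Guide similarity uses Jaccard overlap |A∩B|/|A∪B| (1 =
identical; empty-vs-empty defined as 0 with a warning) on gene sets and on
significant-term sets, with elbow-selected K-means groups and an
average-linkage leaf order on 1 − Jaccard for heatmap export.

## Screen design

The cells-per-guide formula is the standard two-sample difference-of-means
sample size n = (Z₁₋α/₂ + Z_power)²(σ² + σ_AVG²)/Δ² — reconstructed from
its named terms (significance α, power, detectable difference Δ in
guide-detection cells, per-gene SD σ and gene-averaged SD σ_AVG of guide
detection, the two variance terms reflecting unequal populations). Both
the real value and its nearest-integer rounding are returned; embryo
capacity is floor(tissue_cells × efficacy / cells_per_guide) because a
fractional guide cannot be delivered. `guide_detection_sd` estimates
per-gene σ from a pilot screen's assignment counts.

## HCR quantification

Hood averages (dilated nuclear neighborhoods, a proxy for per-cell
transcript) are divided by DAPI to cancel imaging artefacts; positivity
then compares the normalized value strictly to the channel's sample mean,
computed per table (a per-image flag would be the alternative when pooling
embryos; per-table is the default). TBXT classes use strict cutoffs: high
> 0.4, medium > 0.3, so exactly 0.4 is medium. Co-expression overlap
divides by the reference class set and returns co-positive cells with
coordinates for spatial back-mapping; an empty denominator reports NaN.
Profile clustering is average-linkage Euclidean with rows pre-sorted by
cell id for deterministic tie-breaks. Mask tortuosity = perimeter/area
with perimeter the 4-connectivity boundary-edge count (image tools differ
in perimeter conventions; this one is fixed and tested — a solid k×k
square scores exactly 4/k).

## Synthetic screens

The generator emulates the screen the pipeline targets: 14 uneven fate
clusters (default proportions ∝ 1/rank), a 25-gene × 4-guide + 2-scramble
library (102 guides), multi-guide cells, strong knockdown, and sparse
low-UMI ambient contamination.

- **Guides per cell**: zero-inflated (default 15% guide-free) zero-truncated
  Poisson (mean 3) capped at 29 — one-knob overdispersed electroporation
  uptake.
- **Expression**: negative binomial per gene with var = μ + 0.5μ²; target
  genes at mean 5 counts, background genes lognormal. Knockdown multiplies
  a perturbed cell's target mean by `knockdown_fraction` (0.2 default =
  80% knockdown; 1.0 = null screen).
- **Fate effects**: multiplicative tilt of the cell's cluster-probability
  vector followed by renormalization — valid probabilities for any factor
  ≥ 0; factor 0.2 in a cluster of baseline mass 0.20 moves occupancy to
  ≈ 0.049.
- **Guide UMIs**: true assignments Poisson(50) (floored at 1); ambient
  assignments independent Bernoulli per (cell, guide) at rate
  ambient_rate/n_guides with zero-truncated Poisson(1) counts.
- All randomness flows through one `numpy.random.Generator`; identical
  seeds give bit-identical datasets, and ground truth records every
  planted pair and effect.

The generator does **not** model doublets, batch effects, read-level
noise, cluster-specific expression programs beyond the supplied baseline
matrix, or spatial gradients. Passing calibration/recovery tests therefore
demonstrates the statistics behave correctly under the stated generative
assumptions — not that real screens meet those assumptions.

## Calibration and problem sizes

The test suite and acceptance script use scaled-down screens chosen to
keep per-guide cell numbers at realistic working points: null calibration
uses 50 screens of 500 cells, 10 guides and 6 clusters (~100 cells/guide);
knockdown power uses 20 screens of the same shape at 80% knockdown (arm
sizes ≥ 50); fate-shift recovery uses 20 screens of 1000 cells (~225
cells/guide, above the 200 floor the recovery claim assumes) with a 5-fold
depletion planted in the second-largest cluster (baseline occupancy ~0.20)
and evaluates the gene-level pooled z against the all-guide average
reference. KLD permutation tests use 199 permutations in these loops (999
remains the library default). Measured on these conditions: null
guide-success rate ~0%, null |z|>2 call rate ≪ 5% (the average-reference
residuals are conservative because each guide contributes to its own
reference), null KLD rejection ~1%, recovery rates at or near 100%.

## Known limitations

- The χ² machinery treats each guide row as independent of the reference;
  with few guides, the all-guide average contains the tested guide, which
  deflates |z| slightly (conservative).
- Permutation p-values are granular at 1/(B+1); with 199 permutations the
  smallest achievable p is 0.005.
- The elbow rule needs k_max ≥ 3 to express a second difference; below
  that the largest k is returned (or 1 for degenerate input).
- `filter_ambient` loops per guide in Python over nonzero entries; fine up
  to ~10⁶ nonzeros, not tuned beyond.
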