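# Methods

This note documents the models, numerical choices and synthetic-data
design behind `neoclust`, and what the test suite does and does not
establish about real data.

## Candidate epitopes from SNVs

A coding SNV producing one amino-acid substitution is represented by a
21-mer context peptide: ten flanking residues on each side of the mutated
position, with the alternate residue substituted. Near protein termini
the context is truncated, never padded — padding would fabricate sequence
that affinity predictors would score. Contexts shorter than 8 residues
yield no candidates (logged, not fatal). Candidate epitopes are all
k-mer windows, k ∈ {8..11}, that cover the mutated position: a full
21-mer yields Σ_{k=8..11} k = 38 candidates. Duplicate k-mers arising
from repetitive sequence are retained with their distinct start offsets;
affinity prediction is position-independent but provenance is not.
Protein positions are 1-based in input tables, windows 0-based half-open
internally.

## Representative peptides, scaling, DAI

One affinity pair (IC50_mut, IC50_wt) represents each SNV: a verified
precise epitope when flagged, otherwise the minimum mutant IC50 over all
alleles and windows, with ties broken lexicographically by
(allele, peptide) so results never depend on input order. Whether the
minimum should instead be taken per allele first is not specified
anywhere we know of; the overall minimum is used.

Scaling is per-column centering and division by the sample (n−1)
standard deviation, on raw nM values. The raw scale (rather than a log
transform) mirrors the original analysis; an optional log10 pre-transform
is available (`fit_scaling(..., log10=True)`) and recorded inside the
`ScalingParams` so projection can never mix scales. DAI is defined on the
scaled coordinates as y − x (WT minus mutant): zero on the diagonal,
positive above it where the mutant binds better than its unmutated
counterpart. The binding-class boundary is 500 nM, with "weak" meaning
strictly greater.

## Parameterized Gaussian mixtures

Clustering uses finite Gaussian mixtures with the axis-aligned
(orientation = identity) covariance decompositions
Σ_k = λ_k·diag(A_k), det(A_k) = 1:

| model | volume | shape | covariance dof (d = 2) |
|-------|--------|-------|------------------------|
| EII | equal | spherical | 1 |
| VII | variable | spherical | G |
| EEI | equal | equal | 2 |
| VEI | variable | equal | G + 1 |
| EVI | equal | variable | G + 1 |
| VVI | variable | variable | 2G |

Rotated-ellipse (full-covariance) families are intentionally out of
scope. The M-step for VEI alternates the per-component volumes λ_k and
the shared shape A to a fixed point (≤ 50 inner iterations, tolerance
1e-12); all other models have closed-form M-steps.

**Initialization.** Each fit is the best of `n_restarts` EM runs
(default 10) by final log-likelihood. The first two restarts are
deterministic hierarchical cuts: Ward on the coordinates, and Ward on
per-column normal scores (rank-based inverse-normal transform). The
second matters when components have very different spreads — raw
Euclidean agglomeration happily splits a diffuse cluster while merging a
tight one into its neighbor, whereas the normal-scores transform
equalizes density before cutting. Remaining restarts use k-means++
seeding. This portfolio plays the role that likelihood-aware hierarchical
agglomeration plays in classical model-based-clustering software.

**Degeneracy.** Component variances are floored at 1e-6 (squared scaled
units); a fit that touches the floor is flagged `variance_floored`. Such
fits are singular solutions — typically a near-singleton component whose
collapsing variance inflates the log-likelihood without bound — so
`em_fit` prefers non-floored restarts, and `select_model` excludes
floored fits from BIC ranking unless every fit in the grid is floored.
This mirrors the convention of reporting no BIC for singular solutions.

**Selection.** BIC = 2·ℓ − m·log n with the larger-is-better sign
convention; m counts weights (G−1), means (Gd) and the covariance dof
above. The default grid is all six models × G ∈ 1..9. Cells with
n < 2G observations are skipped.

**Membership.** Posteriors come from the weighted component densities.
*Forced* membership is the MAP component; *strict* membership
additionally requires the squared Mahalanobis distance to the MAP
component to be within the χ²(2) quantile at `conf_level` (default 0.95;
the level of the original plots is not stated, so it is configurable).
Projection of an external tumor reuses the training column means/SDs and
mixture parameters verbatim; the serialized model JSON carries both so a
projection is reproducible bit-for-bit.

## Enrichment reports

Per-cluster TRMN/non-TRMN tallies exclude unlabeled points; percentages
are rounded half-up to integers (all eight percentages printed in the
motivating study are consistent with this rule); an empty cluster reports
NA rather than 0%. The density-position report fits a Gaussian KDE with
Scott's-rule bandwidth to the scaled mutant IC50 values and reports
density(cluster mean)/max density, quantifying how far a cluster sits
from the global affinity mode.

## Pooled-screen simulator

`design_pools` partitions n peptides into the minimum number of pools of
size 4–5, preferring 5s (279 → 55×5 + 1×4 = 56 pools), randomized by
seed. Counts not expressible as 4a+5b (n < 4, or 6, 7, 11) fall back to
near-equal pools with a warning.

The tumor control index of the original screen is defined in prior work
that this package does not restate; the default scorer here is a
documented surrogate honoring its qualitative contract (higher = better
control): TCI = 100·(1 − AUC(curve)/mean AUC(controls)), trapezoidal AUC
after linear interpolation of all curves onto the union of measurement
days within the common time span, clipped below at −100. A curve
identical to the controls scores 0; complete rejection scores 100.
Alternative scorers can be registered by name.

A pool is *positive* when its cohort's mean TCI exceeds 0 (median
optional); every peptide of a positive pool is tested individually, and
individually positive peptides advance to a confirmation stage —
statistical-significance gating is deliberately absent at the pool and
individual stages, matching the screen being simulated. Growth cohorts
follow V(t) = V0·exp(r·(1−e)·t) with per-measurement lognormal noise
(defaults V0 = 50 mm³, r = 0.25/day, measurements every 3 days to day
21); e is the immunization effect fraction, and for e ≥ 0.8 a mouse
rejects its tumor outright with configurable probability. With zero
noise the funnel recovers a planted active set exactly; the acceptance
suite asserts sensitivity = specificity = 1 across seeds.

ELISpot responses are rated on the ordinal scale 5–10 (+), 11–20 (++),
21–50 (+++), 51–100 (++++), > 100 (+++++); below 5 is negative.

## Single-cell stage

QC applies cell filters first — gene-count range [500, 6000], then
mitochondrial fraction ≤ 30%, then ribosomal fraction ≥ 5%, all computed
on the unfiltered gene set — and then removes genes supported by fewer
than 10 surviving cells. Because the gene filter depends only on
surviving cells, one pass is a fixed point, and re-running QC on its own
output removes nothing. Mito/ribo genes are flagged by configurable
prefix rules (defaults `mt-` and `Rps|Rpl`).

TF-IDF treats cells as documents and genes as terms:
TF(g,c) = count/total(c), IDF(g) = log(N/(1 + n_expressing)), gene score
= mean over cells of TF·IDF. Ubiquitously expressed genes get negative
IDF and sink. The exact TF-IDF variant of the upstream single-cell
service is not restated anywhere public; this classic form is isolated
behind one function so an alternative can be swapped in. The top-n
cutoff defaults to 500 (the original gene count is unstated).

Clustering is agglomerative Ward on Euclidean distances over the
selected genes' log2(x+1) expression, cut at k clusters (default 8, the
study's cluster count; automatic k selection is out of scope).
Differential expression is a one-vs-rest Welch t-test per cluster and
gene on log-transformed values, log2FC = difference of means, significant
iff |log2FC| ≥ 2 and p < 0.01; zero variance on both sides with equal
means yields p = 1 by convention. The Dunn index is the minimum
single-linkage inter-cluster distance divided by the maximum
intra-cluster diameter (singletons have diameter 0; an all-singleton
partition is undefined and raises). The separation matrix holds pairwise
minimum inter-cluster distances. TF-IDF, Dunn and the separation matrix
each have an independent brute-force oracle implementation that lives
only in the test suite.

## Synthetic data: what it emulates, and what it does not

`gen_landscape` draws (IC50_mut, IC50_wt) pairs from a mixture of
bivariate components, each `normal` (in nM, truncated below 0.01 nM by
rejection) or `lognormal`, with per-component TRMN label probabilities
and the ground-truth component retained for recovery tests. The shipped
`fabf_like_spec` mirrors the study geometry: a dominant near-diagonal
mid-affinity cloud (weight 91/145, mean 1400 nM both axes, SD 680 nM,
4% TRMN), a high-affinity component whose WT counterparts bind poorly
(13/145, mutant 80 ± 39 nM, WT 9000 ± 2000 nM, 14% TRMN), and a
low-affinity TRMN-enriched component (41/145, 28 800 ± 5400 nM both
axes, 55% TRMN). Means sit at the centers of the study's printed
per-cluster IC50 ranges with the extremes at ±2σ; weights and TRMN
probabilities follow the printed forced totals and strict percentages.
The WT location of the high-affinity component is printed nowhere and
was fixed once at a plausibly poor-binding value.

Truncated-normal components are the default because the clustering stage
fits axis-aligned Gaussians to centered/scaled *raw* nM values: planted
components that are Gaussian on that scale make the planted structure
identifiable by the model family that must recover it. Strongly
log-normal components on the raw scale are skewed, curved clouds that a
diagonal-Gaussian mixture correctly tiles with extra components — a
model-mismatch statement, not an implementation defect — so they are
available (`dist="lognormal"`) but not the default for recovery testing.
Correlated near-diagonal "bands" have the same caveat: symmetric scatter
about the diagonal is achieved with equal marginals, not with high ρ,
because a tilted elongated Gaussian is outside the axis-aligned family.

Consequently, passing recovery tests show that the pipeline finds planted
axis-aligned Gaussian structure at realistic sizes (n = 145, three
components, 4–55% label enrichment); they do not show that real affinity
landscapes are Gaussian on the raw scale, that three clusters is the
right description of any particular tumor, or anything about affinity
prediction quality. `gen_counts` similarly plants negative-binomial
(gamma-Poisson, dispersion 0.5) clusters with multiplicative marker
shifts and flags mito/ribo genes so every QC path is exercised; it makes
no claim of realistic library-size variation, dropout structure or
batch effects.

## Problem sizes and determinism

All generators and fits are pure functions of their seed; identical
seeds reproduce outputs bit-for-bit. The acceptance suite uses n = 300
three-component Gaussian landscapes over 50 seeds for EM/BIC recovery,
25 seeds of the default 145-point landscape for end-to-end recovery, 20
zero-noise screens of 100 peptides for funnel deconvolution, and ≤ 50
cells/genes for the brute-force metric oracles; `scripts/acceptance.py`
re-runs the landscape pipeline over 10 seeds and 5 screens. These sizes
keep the full suite in single-digit minutes on one CPU while leaving the
recovery statistics far from their decision thresholds.

## Known limitations

- The TCI surrogate is not the published index; only its qualitative
  contract is honored.
- Diagonal-only mixtures cannot represent correlated (tilted) clusters;
  data with strong mutant–WT correlation within a cluster will be tiled
  by several components.
- The BIC values, Dunn index and cluster structure printed in the
  motivating study depend on its unpublished peptide-level tables and
  external affinity predictions and are not reproduced here.
- QC order (cells before genes) matters in corner cases; both orders are
  defensible and only this one is implemented as the default contract.
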