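# Methods

## Data model and quantification

Abundances live in a samples × assays matrix of log₁₀ gene copies g⁻¹ soil.
The Ct→copies chain is the standard qPCR one: copies per reaction
= 10^((Ct − intercept)/slope) from a per-assay linear standard curve
(slope in Ct per log₁₀ copies, necessarily negative), scaled by
elution/template volumes, dilution factor and soil mass.  Reactions at or
above a configured limit-of-detection Ct are non-detects.

Non-detects and missing wells are **masked, not zero-filled**.  Zero-filling
would create a block of tied ranks at the bottom of every assay and inflate
rank correlations between assays that merely share detection failures;
masking keeps each pairwise test on its complete observations.  The cost is
a per-pair sample size n_pairs, tracked explicitly; pairs with fewer than
`min_pairs` (default 10) complete observations are never edges.

Panel cleaning is a detection-fraction filter (default: assay retained when
unmasked in ≥ 50% of samples) plus removal of assays whose standard curve is
flagged as failed in the assay metadata (`standard_curve_ok` column).  Both
knobs are exposed because panel-cleaning conventions vary between labs.

## Correlation and thresholding

Spearman's ρ uses mid-ranks for ties.  Significance comes from the two-sided
t approximation t = ρ√((n−2)/(1−ρ²)) on n−2 df — standard for the per-cell
n ≈ 28 of the default design; an exact permutation test would change nothing
at these sample sizes and costs far more.  A constant assay column within a
pair's complete observations makes ρ undefined; such pairs are masked with a
logged warning rather than raising, because a constant column in one cell
should not abort a 12-cell analysis.

Benjamini–Hochberg runs within each grouping cell, over that cell's
unmasked upper-triangle tests only, because each cell's network is an
independent analysis; pooling across cells would couple the cells' FDR and
change edge sets when cells are added or dropped.  The edge criterion
applies the significance level to the **BH-adjusted** p by default — the
conservative reading when a threshold and an FDR correction are specified
together — with `p_kind="raw"` kept for sensitivity analysis.  Both
thresholds are strict inequalities (|ρ| > 0.75, p < 0.01).  The criterion is
two-sided (|ρ|); in positively co-varying data like block-correlated gene
abundances no negative edges survive it, and a signed mode
(`use_absolute=False`) is available.

## Graph operations

Networks are simple undirected networkx graphs keyed by assay id, with edge
attributes ρ, p_raw, p_adj, sign and graph-level provenance.  Simplification
removes self-loops and isolated nodes and is idempotent.  Intersection
keeps nodes and edges present in both parents, with edge identity the
unordered node pair only — parents' ρ values differ by construction, so
intersection edges carry the flat list of ancestor ρ values and their mean.
Carrying the flat list (rather than a mean-of-means) makes k-way
intersection associative and order-independent.  The displayed ρ on a
consensus edge is this package's convention (mean of parents); no standard
exists.

The default workflow is 12 per-cell networks → 6 per-timepoint
location-intersections → 1 global consensus, expressed as configuration
defaults, not hard-coded.

## Network statistics

* **Density** m / C(n, 2) over the network's own node set (n ≥ 2 required).
* **Clustering coefficient** is global transitivity,
  3 · triangles / Σ_v C(deg v, 2), zero when no connected triple exists.
* **Average path length** averages over mutually *reachable* unordered
  pairs; unreachable pairs are excluded rather than imputed at n.  This is
  the default of the common graph toolchains and keeps L finite for the
  disconnected consensus networks the pipeline routinely produces.  For a
  connected graph with density p and diameter ≤ 2, L = 2 − p exactly — a
  relation the dense dry-season-like networks and their nulls both satisfy,
  used as a consistency check in the tests.
* **Betweenness** is the raw (unnormalized) Brandes count; **closeness** is
  1 / Σ d(v, u) over u in v's connected component.  Both conventions are
  documented prominently because keystone ranking consumes them; within a
  component the within-component closeness preserves ranks, and the
  magnitudes match what practitioners report for networks of this size.
* **Normalized degree** divides by n − 1, the simple-graph maximum.  A
  divisor of n appears in some descriptions; the constant cancels in
  rankings, which is all the keystone rule uses.
* **Modules**: Girvan–Newman divisive clustering, removing the edge of
  maximal betweenness repeatedly and cutting the dendrogram at the partition
  maximizing Newman–Girvan modularity on the original graph.  When several
  edges tie for maximal betweenness (common in the symmetric block networks
  this pipeline sees), the lexicographically smallest endpoint pair is
  removed first, making the result deterministic; modularity ties resolve to
  the coarsest partition.  Module blocks never span connected components.

## Null model and response ratios

The null is G(n, m) — fixed node *and edge* count, matching the observed
network's size exactly — sampled as m distinct pairs uniform without
replacement.  G(n, p) would let edge counts fluctuate and blur C in small
networks.  Default 1000 replicates; the seed is recorded in every output.
Ensemble spreads are sample standard deviations.

RR = C_obs / C_random-mean and LRR = ln RR.  RR is undefined (and flagged,
not fabricated) when the null mean transitivity is zero, which genuinely
happens for very sparse networks (e.g. n = 4, m = 2).  Significance of the
departure from randomness is read from the empirical two-sided band: the
network is random-like when the fraction of replicates with C ≤ C_obs lies
in [0.025, 0.975].  An empirical band was chosen because no parametric test
applies to an ensemble statistic of this kind at these sizes.

## Keystone identification

Within each pathway (default: nitrification and denitrification, the
pathways whose genes occupy central network positions), restricted to that
pathway's nodes present in the network, the maximizer sets of betweenness,
closeness and normalized degree are formed with ties inclusive; a node in at
least two of the three sets is a keystone, reported with the measures it
topped.  The rule is rank-based, hence invariant to rescaling any measure.
Keystones are evaluated on the per-timepoint location-intersection networks
by default (configurable to per-cell networks).  The betweenness timeline
marks an assay absent from a network as missing, never zero — absence and
peripheral presence are different observations.

## Synthetic data generator

The generator emulates the motivating study design: 2 locations × 6
timepoints × 28 samples (336 total) over a 21-assay N-cycle panel
(7 nitrification, 9 denitrification, 2 DNRA, 2 fixation, 1 anammox target,
with realistic redundancy groups such as paired bacterial *nirK* assays).

Latent vectors are multivariate normal with correlation `r_within` = 0.9
inside ground-truth blocks and `r_between` = 0 across; abundances are the
latent variables placed on normal margins with mean 6.0 and sd 0.5 log₁₀
copies g⁻¹ (a Gaussian copula; for normal margins the map is affine).  The
margins match typical soil functional-gene loads (~10⁴–10⁸ copies g⁻¹);
since inference is rank-based, only the copula matters for recovery and the
population Spearman inside a block is (6/π)·arcsin(r/2) ≈ 0.89.  2% of
cells are masked as non-detects.  Blocks follow a deterministic seasonal
schedule — three blocks covering 17 assays at timepoint 1 shrinking to two
blocks of 3+2 by timepoint 6 — emulating the dense-dry/sparse-rainy density
trend; the second location omits one member of the leading block so that
location-intersections genuinely differ from per-cell truth.  The implied
correlation matrix is eigenvalue-checked and non-PSD block specifications
are rejected by name.

What the generator does **not** emulate: compositionality, spatial
autocorrelation between plots, detection limits correlated with abundance,
inter-chip batch effects, or mechanistic N-process dynamics.  Passing
recovery tests therefore demonstrate that the inference chain recovers
block-structured rank dependence at the study's sample sizes — not that
field co-occurrences are estimated without bias from those unmodelled
features.

## Problem sizes and determinism

Defaults throughout are the study conditions: 28 samples/cell, 21 assays,
|ρ| > 0.75, BH-adjusted p < 0.01, 1000 null replicates.  Recovery checks
average 20 generator seeds (12 cells each); null calibration averages 50
seeds of a reduced uncorrelated layout (the per-cell false-edge rate does
not depend on how many cells each seed contributes).  Every stochastic step
is seeded: the pipeline derives per-network null seeds deterministically
from the single configured seed, and a rerun with identical configuration is
byte-identical in all outputs (the manifest contains no timestamps).

## Known limitations

* Spearman co-occurrence is association, not interaction; indirect
  correlations (A–B and B–C inducing A–C) are not deconvolved — partial
  correlation and compositional methods are out of scope by design.
* The t approximation is slightly anticonservative below n ≈ 10; `min_pairs`
  guards the floor but users with very sparse detection should raise it.
* Girvan–Newman is O(m²n)-ish and intended for the ≤ ~40-node networks this
  domain produces, not for large graphs.
* RR is reported without an analytic standard error; the empirical
  c-quantile is the only calibrated uncertainty statement.
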