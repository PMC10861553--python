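# Methods

This note records the models, numerical choices and design decisions behind
the package, and what the synthetic-data conditions do and do not show about
real data.

## Gene-content clustering

Isolates are described by binary KO presence/absence vectors. The cleaning
order is fixed: zero-variance columns are removed first (they cannot affect
any pairwise distance), then columns with identical presence/absence
patterns are collapsed to their first-in-file representative, and distances
are computed on the collapsed matrix. Collapsing before the distance step
means a block of perfectly co-occurring KOs counts once, not once per copy —
distances then measure distinct gene-content patterns rather than raw gene
counts. Duplicate membership is retained so enrichment scores can be
propagated back to every collapsed KO.

Distances are Manhattan, which on binary data equals the Hamming distance
(number of differing KO columns; computed exactly in integer arithmetic via
the identity |x−y| = x + y − 2xy). Linkage is complete (inter-cluster
distance = maximum pairwise distance), implemented in-package with a
deterministic tie-break — at equal merge heights the lexicographically
smallest pair of node indices merges first — so dendrograms are
bit-reproducible across platforms. scipy's linkage is used only as an
independent cross-check in tests, because its tie order is unspecified.

### Adaptive tree cut

Clusters are extracted from the dendrogram without a single fixed cut
height. Each branch is inspected for a significant gap in its internal
merge heights; the branch is cut in the widest gap when two conditions hold:

1. the gap spans at least a fraction `tau_gap` of the branch's merge-height
   range, and
2. the merges above the gap sit at least `tau_ratio` times higher than the
   merges below it.

Both thresholds come from the `deep_split` level (0 conservative … 4
aggressive; default 2 → `tau_gap` 0.30, `tau_ratio` 1.20). The procedure
recurses into the resulting branches; components smaller than
`min_cluster_size` (default 3, appropriate for a ~126-isolate collection)
are attached to the nearest detected cluster by average distance when that
distance lies within the cut height, and otherwise receive the unassigned
label 0. Labels are numbered 1… by decreasing cluster size. The two-part
criterion is what stops homogeneous branches from splitting on the random
fluctuations of their merge heights (condition 2 rejects cuts whose "gap"
is small relative to the absolute height), while still cutting star-like
topologies where many clusters join in a narrow height band.

This cut is this package's own variant of adaptive branch detection; it is
not a reimplementation of any particular published tree-cut code, though it
follows the same idea (adaptive branch cutting plus rescue assignment of
small branches).

A curated split of one cluster into two — in airway collections typically a
Streptococcus cluster split on external 16S evidence — is supported as an
explicit partition operation that leaves all other labels untouched.

### Enrichment scoring

Per cluster and KO the 2×2 table (a, b, c, d) is scored by OR = ad/bc with
0.5 substituted into cells that are exactly zero. This "zero cells only"
form is the package default; the classical variant that adds 0.5 to all
four cells whenever any is zero is available (`correction="all-cells"`).
log10(OR) is a descriptive ranking statistic; no p-values or multiple
-testing corrections are attached, and ranking runs over the full signed
range (over- and under-representation). Unassigned isolates are excluded
from both margins. Duplicate KOs inherit their representative's score; if a
member column is still present in the scored matrix it is annotated rather
than emitted twice.

## Community preparation

OTU filtering removes an OTU when its total reads fall below 20 **or** it
occurs in fewer than 2% of samples (the two published rules are conflated
in their source; the OR of both is the default and each threshold is
configurable).

Contaminant flagging computes, per OTU, the Spearman correlation between
per-sample relative abundance and qPCR biomass, adjusts p-values with
Benjamini–Hochberg across OTUs, and flags OTUs with adjusted p < 0.05 and
ρ ≤ −0.2. The negative direction is deliberate: a reagent contaminant
contributes a roughly constant absolute input, so its relative share falls
as true biomass rises. A two-sided mode exists for exploratory use. At
least 10 biomass-bearing samples are required; constant biomass is an
error, not a silent pass.

Rarefaction draws each sample once from the multivariate hypergeometric
distribution (subsampling without replacement) at a common depth — the
smallest retained sample by default, after discarding samples under
`min_sample_reads` (default 1000; the source protocol never states its
cutoff, so it is exposed). Seeded and reproducible.

Alpha diversity uses natural-log Shannon entropy (the ecology default; base
configurable), richness as the non-zero OTU count, and Pielou evenness
J = H/ln S, undefined for S ≤ 1. Bray–Curtis is computed on relative
abundances by default; note it is a dissimilarity, not a metric — the
triangle inequality can fail, which is why ordination goes through PCoA
rather than any metric-assuming embedding. PCoA reports all eigenvalues of
the double-centred matrix but returns coordinates only for positive ones.

PERMANOVA uses the standard distance-based pseudo-F (among/within sums of
squared distances) with label permutations and p = (1 + #{F* ≥ F})/(1 +
n_perm), so p is never 0 and its minimum is 1/(n_perm+1); default n_perm =
999, seeded. The statistic matches scikit-bio's implementation exactly
(checked in tests); the in-package version exists so the permutation stream
is seedable and the p-value formula explicit.

## Dirichlet-multinomial mixture typing

Community types are fitted on genus-binned **counts**, not proportions: the
DM likelihood is defined on counts, and binning to genus level is done by
summing OTU counts per genus. The likelihood is evaluated entirely in
log-gamma space; depths up to 1e6 are safe.

EM details: responsibilities are initialised from a seeded k-means on the
proportion vectors (90% soft mass on the assigned component, 10% spread
over the rest, so even degenerate data gives every component enough mass to
fit); the M-step updates π in closed form and each α_k by L-BFGS-B on
log α (bounds 1e-8…1e8) with the analytic digamma gradient, warm-started at
the current value — if the optimizer fails to improve, the warm start is
kept, which preserves the EM guarantee that the log-likelihood never
decreases (asserted each iteration). Convergence is a log-likelihood gain
below 1e-6; default 5 restarts keep the best run. A component whose
responsibility mass falls below half a sample equivalent aborts the restart.
Components are reported in decreasing-weight order.

Model selection minimises a Laplace approximation to the negative log model
evidence. Two choices matter:

* a weak Gaussian prior on log α (sd 3, i.e. α within ≈[1e-4, 8e3] at 3σ).
  Under a flat improper prior the evidence is ill-defined and
  near-duplicate or diverging components sit on likelihood ridges that a
  Laplace approximation cannot penalise; the log-scale prior is
  scale-robust (its penalty grows only quadratically in log α, so even a
  component driven toward the α bound on degenerate data is penalised
  deterministically).
* the Hessian is evaluated block-diagonally per component in log-α space.
  Each block has the rank-one structure diag + u·11ᵀ, giving a closed-form
  log determinant; cross-component curvature is omitted, and blocks that
  are not positive definite at the (bounded) optimum fall back to a
  BIC-style contribution. Mixture weights contribute (k−1)/2·ln S.

BIC and AIC are always reported alongside, and the full criterion curve is
returned so an elbow can be inspected. The congruence test is a plain
Pearson χ² (no continuity correction) on the factor-level × type table.

## 16S identity mapping

Alignment is semi-global (terminal gaps free; match +1, mismatch −1, gap
−2) via Biopython's pairwise aligner, so a ~250 nt amplicon aligns inside a
full-length 16S gene without end-gap penalties. Identity = matches /
alignment columns of the aligned core (terminal overhangs excluded);
ambiguous N bases never count as matches, including N–N. Published
e-value thresholds are engine-specific and are replaced by the minimum
aligned-length filter (default 206 columns). Bins are half-open:
[95,97) / [97,99) / [99,100]; the ≥99 class generalises an exact-match
display convention and strict-100 filtering remains available through
`min_identity=100`. All hits above threshold are kept — the OTU↔isolate
relation is many-to-many because taxa carry multiple divergent 16S copies,
and the row pattern of bins (the "barcode") is what discriminates close
relatives such as streptococci.

## Functional projection

An OTU's relative abundance is split equally among its admissible isolate
hits (admissibility = bin ≥ a configurable floor, default the ≥99 class);
identity-proportional weighting is available. How to aggregate multiple
isolates matching one OTU is genuinely underdetermined, so the equal-split
rule is an explicit, documented assumption. Abundance with no admissible
hit is reported as an unmapped fraction and never renormalised, keeping
F = A·K comparable across samples; consequently each F entry lies in [0, 1]
when A rows are relative abundances.

## Synthetic-data conditions

All generators are pure functions of (parameters, seed); one user seed fans
out to per-generator substreams keyed on the generator name, so adding a
generator never shifts another's stream.

* **Planted KO matrices**: background KOs present with probability 0.5 iid,
  disjoint signature blocks per cluster, iid cell flips. With zero flip
  noise the signature columns of a cluster are identical indicator
  patterns, and the pipeline's duplicate collapse would reduce them to one
  column each — real annotations are never this clean, and the CLI's
  simulate scenario therefore defaults to 5% flip noise.
* **Collection-scale matrix**: 126 isolates in 15 planted clusters (sizes
  25, 24, 10, 9, 9, 8, 6, 6, 6, 5, 5, 4, 3, 3, 3 — a realistic genus census
  for a cultured airway collection with its large Streptococcus group in
  two blocks), 5531 KO columns of which 254 are constant and 2313 exact
  duplicates of other columns; the 2964 distinct informative columns
  comprise 150 signature KOs per cluster (present with p=0.98 inside,
  0.005 outside) plus 0.5-background. These rates were chosen so that
  between-cluster complete-linkage heights exceed within-cluster heights
  by ≈1.5×, comfortably inside the adaptive cut's detection regime, while
  distinctness of informative columns is enforced by redrawing collisions
  so the planted filter counts are exact.
* **Cohort**: 888 samples from a two-component DM mixture over 25 genera
  (weights 410/888 and 478/888; one type led by Streptococcus/Veillonella/
  Prevotella, the other by Streptococcus/Veillonella/Haemophilus;
  precision θ = 40, rarefaction-like fixed depth 1000).
* **Contamination**: log-uniform 100-fold biomass gradient over 60 samples,
  true reads Poisson-proportional to biomass, one contaminant with constant
  Poisson input of 500 reads.
* **Mutants**: exactly n distinct substituted positions, so identity is
  (L−n)/L by construction.

What passing these conditions shows — and does not. The planted scenarios
verify that each algorithm recovers truth when its generative assumptions
hold and the signal is at the stated strength; they do not establish
robustness to phylogenetic correlation between KO columns, compositional
biases of amplicon PCR, chimeras, or taxa absent from the isolate
collection (unmapped abundance is reported, not resolved). The cohort
generator draws iid samples; real repeated sampling of donors induces
dependence that the congruence test measures but the fit ignores.

## Problem sizes

Tests and the acceptance script run the collection-scale matrix at its full
126 × 5531 size, the cohort at 888 samples, DM recovery at 200 samples ×
20 taxa × depth 1000, and null calibrations at 500 simulations with 99
permutations each; the whole suite completes in about a minute on one CPU.
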