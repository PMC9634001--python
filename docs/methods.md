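# Methods

This note documents the statistical and numerical choices behind
`protraits`: what each estimator computes, the defaults and why, what the
synthetic-data generators emulate, and the known limits of both.

## Trait definitions

Traits are computed per genome and aggregated to species by arithmetic
means (missing values ignored; a species value is missing only when all
members are missing). Habitat labels aggregate by majority, ties resolved
to `unclassified`.

- **genome_size** — sum of contig lengths (bp).
- **pct_gc** — 100·(G+C)/(A+C+G+T) over all contigs; ambiguous bases are
  excluded from numerator and denominator; all-ambiguous input gives a
  missing value.
- **gene_richness / gene_duplication** — number of distinct gene families
  among CDS, and CDS count divided by that number. Family assignment
  precedence: explicit `family` attribute > `ortholog` attribute >
  normalized product string > a singleton per gene. Duplication is ≥ 1 by
  construction and richness is bounded by the CDS count.
- **pct_tf** — percentage of CDS flagged as regulatory. The flag is rule
  based (upstream annotation pipelines do not publish a single canonical
  rule): case-insensitive product keywords
  {"transcriptional regulator", "transcription factor", "sigma factor"} or
  a configurable list of `regulatory_family` attribute values. Whether
  sigma factors belong in the count is a genuine judgment call; they are
  included by default and removable through the keyword list.
- **rrn** — by default the genus-level mean of a curated reference table of
  rRNA operon copy numbers (annotation-derived 16S counts in draft genomes
  are unreliable, mostly downward); `rrn_source="annotated"` switches to
  counting features whose product contains "16S". Other rRNAs are stored
  but never counted.
- **pct_hgt, prophages** — ingested from external annotation statistics,
  never computed: calling prophages or horizontal transfer is out of scope.
- **generation_time** — `d = exp(a + b·F)` hours with configurable
  coefficients (defaults a = 1.5, b = −6.0 are calibration-flavored
  placeholders in the spirit of published CUB-growth regressions, not
  estimates made by this package; no test or reported number depends on
  them). Estimates above 5 h are flagged unreliable — beyond that range
  CUB-based prediction is qualitative only.

## Codon usage bias (ENC′ and F)

For each amino acid with k ≥ 2 synonymous codons and n ≥ 2 observations,
with observed family frequencies p and background family frequencies e:

```
chi2 = n * sum_i (p_i − e_i)^2 / e_i
F'   = (chi2 + n − k) / (k (n − 1))
ENC' = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6     (class means, clamped to [20, 61])
```

The background is estimated from position-specific nucleotide frequencies
of the pooled counts of all CDS, multiplied across the three codon
positions and renormalized within each synonymous family. This removes
composition-driven (GC-driven) bias from the statistic — necessary here
because %GC is a separate trait.

Numerical choices:

- Gene filters: codons are pooled over CDS with ≥ 80 body codons after
  removing start and stop; codons containing ambiguous bases and in-frame
  stops are skipped. Pooled counts (not per-gene averages) are used for
  both the whole-genome and the highly expressed set — the pooled route is
  stabler on the short ribosomal-protein genes.
- Fallbacks: a missing 3-fold class mean is imputed as the mean of the 2-
  and 4-fold means (the classical treatment); a missing 6-fold mean falls
  back to the 4-fold mean (nearest redundancy); a missing 2- or 4-fold
  mean, or fewer than 100 total codons, makes ENC′ missing. Amino acids
  with non-positive corrected homozygosity (possible only when n < k) are
  dropped as uninformative.
- F requires ≥ 10 ribosomal-protein CDS (configurable); fewer gives a
  missing F with a logged reason.

Closed-form anchors used in tests: one codon per family gives F′ = 1 per
family and ENC′ = 20 for any n; observed = background gives chi2 = 0 and
ENC′ → 61 as n grows.

## Species units and habitat

Genomes with a species-level taxonomy label share a unit; the rest form
single-linkage connected components of the ANI graph at > 94 % — the
minimal closure consistent with "same species above the threshold", and the
variant that is directly checkable against a brute-force
connected-components oracle. Raising the threshold can only refine the
partition. Missing ANI for an unlabeled pair is treated as no edge.

The built-in ANI estimator is a Mash-style k-mer statistic
(ANI = 100·(1 + ln(2J/(1+J))/k) on canonical k-mer Jaccard similarity,
k = 16, optional seeded bottom-s sketch). It is a stand-in so the pipeline
runs without an external aligner, adequate for clustering decisions near
the species threshold, not a replacement for alignment-based ANI.

Habitat classification is a case-insensitive substring search over rule
groups tested in a fixed order — soil {soil, rhizosphere}, aquatic
{aquatic, marine, water}, digestive tract {oral, stomach, gut, intestinal,
feces} — first match wins, no match is `unclassified`. Precedence between
groups is not defined by any upstream convention; the listing order above
is the package's choice and a string like "waterlogged soil" is therefore
soil.

## Covariation analysis

- **Transforms**: %HGT → ln(x + 0.001) (handles exact zeros), generation
  time → ln(x); RRN and prophage counts stay raw (no transform improves
  their fit to normality). A table records its transform state and refuses
  double transformation.
- **PCA** runs on z-standardized complete cases; loadings are reported as
  variable–component correlations (eigenvector times square root of the
  correlation-matrix eigenvalue), so they are bounded in [−1, 1] and
  reproduce `corr(trait, score)` to numerical precision. Component signs
  are fixed deterministically by making each component's largest-magnitude
  loading positive. Loading significance comes from independently permuting
  each column, re-running the PCA, and counting `|loading|` exceedances
  with the (1 + #)/(1 + n_perm) estimator (default 100 permutations).
- **Spearman matrices** use pairwise-complete observations (maximizing n
  per pair), average-rank ties and the t-approximation p-value; Bonferroni
  multiplies by the number of pairs actually tested in the calling context,
  never a hard-coded constant. Pairs with < 4 complete rows, or a constant
  margin, yield missing cells and do not count toward m.
- **Loess** is local linear with a tricube kernel over the f-fraction
  nearest neighbors and bisquare robustness reweighting; defaults f = 2/3
  and 3 iterations. Local linear fits reproduce straight lines exactly,
  which the tests assert at 1e-6.
- **Stratified correlations** contrast genome_size < 4 Mbp against
  > 5 Mbp — rows in the 4–5 Mbp band belong to no size stratum, which is
  what makes the sign flip of the size–CUB relationship detectable — and/or
  habitat labels, for six named resistance × resilience pairs
  (size/duplication/%TF against CUB/RRN) by default.

## Phylogenetic signal

- **Blomberg's K** follows the standard construction: the ratio of the
  observed to phylogenetically corrected mean squared error, scaled by its
  Brownian expectation `(tr V − n/(1'V⁻¹1))/(n−1)`. On a star tree the
  scaling collapses and K = 1 identically, which the tests assert exactly.
  The permutation test shuffles trait values across tips and counts
  corrected MSEs at or below the observed (999 permutations by default).
- **Pagel's λ** multiplies the off-diagonal of V by λ and maximizes the
  profile likelihood of the one-mean Brownian model over λ ∈ [0, 1]
  (V(λ) is provably positive definite on that interval as a convex
  combination of V with its positive diagonal; a `lambda_max` argument
  exposes wider bounds). Optimization is bounded scalar search with
  1e-8 tolerance plus explicit endpoint evaluation, so the reported
  likelihood dominates both λ = 0 and λ = 1. The p-value is a boundary
  likelihood-ratio test against λ = 0 with the ½χ²₀ + ½χ²₁ mixture.
  Both statistics are affine-invariant in the trait, checked numerically.
- **Mantel correlograms** tile (0, 3] in 0.5-wide classes (lower-open,
  upper-closed). Per class, the statistic is the Pearson correlation
  between the class-membership indicator and the trait distance matrix
  over unordered pairs, **negated** so that positive r means within-class
  trait distances are smaller than average — i.e., positive phylogenetic
  autocorrelation at that distance. Conventions differ between
  implementations; this one makes "significant positive correlation at
  short distances" the signature of phylogenetic signal. Permutation p
  (200 by default) is two-sided on |r| under simultaneous row/column
  permutation; Bonferroni m counts non-empty classes only; a class is
  significant when r > 0 and Padj < 0.1. The summary `max_pd` is the
  largest class upper bound up to which every class (with no skipped class
  in between) is significant — the operational radius within which
  marker-gene-based trait prediction is supported.
- **Hidden-state prediction** is generalized-least-squares Brownian
  interpolation, `x̂_q = μ + c'C⁻¹(x − μ1)` with μ the GLS mean of
  observed tips. A query coincident with an observed tip returns that value
  exactly; a star-tree query returns the unweighted mean. Predictions whose
  nearest observed tip is farther than a per-trait `max_pd` are flagged
  unreliable.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of configuration plus seed.

- **Trees**: Yule (birth rate 1, stopped at n tips and extended by the
  waiting time to the next event, so terminal branches are positive and V
  is well conditioned) or a Kingman coalescent.
- **Brownian traits**: per-trait λ transform of V, cross-trait covariance
  through a Cholesky factor of Σ applied to tip innovations. With a common
  λ the tip × trait covariance is exactly V(λ) ⊗ Σ; with per-trait λ the
  cross-trait block is an approximation (adequate for the rank-based
  analyses it feeds).
- **Regime tables** draw genome sizes from a two-component lognormal
  mixture (means ~3 and ~6.5 Mbp, the aquatic-like and soil-like modes seen
  across habitats; the 4–5 Mbp band stays populated — the analytic gap is
  a binning choice, not a biological absence). Within components the
  (size, CUB) correlation is ±0.5 by default, giving the hump-shaped pooled
  relationship; duplication, richness and %TF co-increase with size, RRN
  tracks CUB, habitats are drawn with component-specific preferences
  (small → aquatic-biased, large → soil-biased). Only this qualitative
  structure is planted; no attempt is made to clone the marginals of any
  real compilation, so quantitative agreement with published coefficients
  is out of reach of the simulator by design — tests assert signs,
  orderings and calibrations instead.
- **Toy genomes** place one sequence per gene family (copies identical,
  which is the duplication semantics), ribosomal-protein genes drawn from a
  θ-sharpened within-family codon distribution and everything else from a
  GC-consistent background, so θ = 0 yields F ≈ 0 *by construction*
  (the generator's codon background matches the ENC′ background estimator)
  and F is strictly increasing in θ. Genome size, family count, rRNA count
  and TF fraction are hit exactly (TF to within one gene); intergenic
  filler GC is solved so the whole contig meets the GC target. Real
  genomes differ in every way that does not matter to these statistics:
  no operons, no intergenic structure, no amino-acid realism.

Passing tests on these generators therefore demonstrate estimator
correctness and pipeline integrity under known truth — not that any
particular biological dataset will reproduce a given coefficient.

## Problem sizes

The test suite and the acceptance script use desk-scale sizes chosen to
keep runs in the minutes range while leaving comfortable statistical
margins: cohorts of 80 (tests) and 200 (acceptance script) synthesized
genomes of realistic 2–9 Mbp length, 100–200-tip trees with 50–200
replicate simulations for K and λ recovery, 2,000-row regime tables for
stratified correlations, and 500-replicate calibrations of the permutation
p-values (100 PCA permutations, 200 Mantel permutations, matching the
defaults).

## Known limitations

- The ANI estimator is k-mer based; alignment ANI can differ by a few
  tenths of a percent near the species threshold.
- ML estimates of λ are mildly biased downward at intermediate truth
  (≈ 0.43–0.46 recovered at true 0.5 on 200-tip Yule trees); the
  acceptance band accounts for this.
- The generation-time map is a placeholder regression, not a fitted model.
- Mantel class p-values are exchangeable-permutation approximations; with
  very few pairs in a class the discrete p floor (1/(n_perm+1)) limits
  attainable significance.
- `%HGT` and prophage counts are only as good as the upstream annotation
  that supplies them.
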