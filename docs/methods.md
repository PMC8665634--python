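# Methods

## Count model and differential expression

Counts are modeled negative binomial with the mean–variance relation
var(y) = μ + φμ²; φ is called "the dispersion" everywhere in this package.
The DE workflow per timepoint is:

1. **Filtering.** Genes with CPM < 1 in more than *n* − `min_samples`
   samples are removed; `min_samples` defaults to the smallest
   (genotype, treatment, timepoint) group size, on the argument that a DE
   gene must be expressed in at least one complete replicate group. CPM for
   filtering uses raw column sums (filtering precedes normalization), and
   library sizes are never recomputed after filtering.
2. **Normalization.** Trimmed mean of M-values (TMM): the reference sample
   is the one whose 75th-percentile CPM is closest to the mean of those;
   per sample, genes zero in either sample are excluded, M- and A-values
   are double-trimmed (30% per M tail, 5% per A tail, rank-based), and the
   factor is 2^(weighted mean M) with inverse-variance binomial weights.
   Factors are rescaled to geometric mean 1, so CPM is scale-invariant.
   Normalization and filtering run independently within each timepoint.
3. **Dispersion.** A pooled method of moments with shrinkage. Counts are
   first equalized to the geometric-mean effective depth. Within each
   replicate group the moment estimate is (v − m)/(m² − v/n); the
   denominator is the unbiased moment estimate of μ² — dividing by m²
   overestimates μ² by var(m) and biases φ low, which measurably inflates
   the null tail of the downstream tests at n = 3. Per-gene estimates pool
   across groups with residual-df weights. The common dispersion φ₀ is a
   ratio of sums over all genes and groups (numerator and denominator
   pooled separately), avoiding the upward Jensen bias of averaging
   per-gene ratios. Tagwise values shrink the clipped gene estimate toward
   φ₀ with weights (residual df) : (prior df), prior df = 10, floored at
   1e-6. This is deliberately a transparent moment/shrinkage scheme, not a
   re-derivation of any specific empirical-Bayes package; its guarantees
   are the calibration properties the test suite checks, not numerical
   equality with other tools.
4. **Testing.** Counts are scaled to the common depth ("pseudo-counts",
   rounded group totals) and a two-sided exact conditional NB test is run:
   group totals are NB with mean n·μ₀ and dispersion φ/n; conditional on
   the pooled total, the p-value sums the probabilities of all splits no
   more likely than the observed one (ties included). At φ = 0 this reduces
   to the exact binomial split test. Pooled totals above 10,000 switch to a
   Wald z-test on the log scale (the `method` column records the path);
   at that depth the two agree to numerical noise and enumeration cost is
   the only difference.
5. **Effect size.** log2FC = log2((CPM_A + 0.5)/(CPM_B + 0.5)) with the
   0.5 prior in CPM units avoiding infinite fold changes at zero counts;
   positive means higher in the first-named group (aphid, for
   aphid-vs-mock: induced). The SE comes from the delta method,
   var(ln mean) ≈ (1/μ + φ)/n per group, summed across groups, and is then
   inflated by √(k/(k−2)) with k = residual df + prior df of the dispersion
   estimate (k = 26 in the default design). The inflation is the t-type
   correction for squaring deviations against an estimated variance
   (E[1/v̂] = k/(k−2) · 1/v): without it the downstream standardized
   additivity statistic runs ~5% hot and over-rejects on genuinely
   additive data. The exact/Wald p-values are not affected by this
   correction.
6. **FDR.** Benjamini–Hochberg step-up q-values; DE is called at q < 0.05.

## Synergy analysis

At each timepoint the four per-genotype DE sets are partitioned into their
15 disjoint Venn regions; the **synergy set** is the region unique to the
pyramid. The **strict** subset additionally requires both monogenic
q-values to clear a relaxed cutoff: strict ⇔ q_pyr < 0.05 and q_R1 > 0.25
and q_R2 > 0.25, all strict inequalities exactly as the thresholds read.
Genes with a missing q are "untestable" and excluded from denominators.

The **additive expectation** is d_exp = d_R1 + d_R2. Departure is tested in
aggregate two ways, both reported as (T, df, p):

* **standardized** (default): T = Σ_g (d_obs − d_exp)²/(se²_obs + se²_R1 +
  se²_R2), df = number of genes, upper-tail χ². The three SEs are treated
  as independent because the three contrasts use disjoint samples.
* **binned**: Pearson χ² comparing the histogram of d_obs against that of
  d_exp over 20 shared equal-width bins (df = occupied bins − 1).

Both constructions are plausible readings of "compared using a χ² test" in
this kind of analysis; the ambiguity is intentional and the method used is
recorded in every output. The test runs on the full synergy set and on the
induced (d_obs > 0) and repressed (d_obs < 0) subsets; d_obs = 0 genes are
flagged and belong to neither subset.

Timepoint dynamics: per genotype, the overlap of DE sets at the two
timepoints, each overlapping gene labeled same/opposite by log2FC sign
concordance, plus the count of early synergy genes not DE anywhere at the
later timepoint (the transience measure).

## Clustering

Rows are genes DE in ≥ 1 aphid-vs-mock contrast; values are per-gene
z-scored log2FCs across the 8 contrasts (sample SD, n−1). Constant rows
are kept as zeros and flagged (default) and dropped before clustering.
Distance is 1 − Pearson r; linkage is complete. Rows are pre-sorted by
gene ID before agglomeration so ties break deterministically and the tree
is invariant to input row order. Cutting applies the first n−k merges,
guaranteeing exactly k clusters with labels numbered by first member.
An option to cluster z-scored log-CPM across samples instead of contrast
log2FCs is deliberately *not* asserted as "the" published choice — both
matrices are defensible readings of the published clustering description;
this package defaults to the contrast matrix because the figures it feeds
are contrast-shaped. Defaults: k = 6 globally, k = 2 for the synergy set.

## Enrichment

One-sided overrepresentation only (the stated goal is overrepresented
processes): p = P[X ≥ k], X ~ Hypergeom(N, K, n) with the background
defaulting to all annotated genes. Bonferroni multiplies by the number of
terms actually tested (terms hitting ≥ 1 DE gene); a flag switches to all
background terms. The GO map is taken as already propagated — no ancestor
closure is applied. The TF-family rule flags families where the fraction
of pyramid-DE TFs that are synergy genes is ≥ 0.5 (inclusive); flags are
computed on exact fractions, rounding is display-only.

## Locus scanning

Interval membership is any ≥ 1 bp overlap (not containment): gene models
straddling mapped boundaries should surface for review. Strand is ignored.
The per-locus grid shows log2FC where q < 0.05 and "n.s." otherwise (in
the human-readable report only; machine tables use empty cells), across
six comparisons (two timepoints × three genotype contrasts involving the
carrier). Candidates rank by (tier: all-significant-signs in the expected
direction first) then number of significant comparisons, then minimum
|log2FC|, both descending. Fold changes are always 2^d — repressed genes
show FC < 1, never "negative fold change". Genes significant in ≥ 1
configured comparison are included; the inclusion rule is per-gene, not
per-subset.

## Synthetic data generator

The generator emulates the study design: 4 genotypes × 2 treatments ×
2 timepoints × `replicates_per_cell` (default 3, per-cell overrides allow
the unbalanced 2-replicate pyramid cells), lognormal depths (log-mean 16.8
≈ 20M reads, log-sd 0.2 — the magnitude is irrelevant to the math, only
the spread matters), and per-gene NB counts
y ~ NB(depth × baseline × 2^effect, φ).

Effect classes and their aphid-vs-mock log2FC patterns:

* `null` — zero everywhere.
* `shared_all` — one effect shared by all four genotypes.
* `r1_only` / `r2_only` — an effect in that monogenic genotype only. This
  is the literal Venn reading; it keeps the pyramid-unique region free of
  monogenic signal by construction.
* `additive` — independent magnitudes in R1 and R2 with one shared sign
  per gene (so the pyramid sum stays in [2, 6] in absolute value and the
  class remains detectable); pyramid effect = the sum.
* `synergistic` — an effect in the pyramid only; monogenic effects are
  exactly zero, or bounded by `monogenic_subthreshold` in the optional
  sub-threshold variant used to probe the relaxed-cutoff rule.

Defaults: |log2FC| ~ U(1, 3); induced with probability 0.5; baseline mean
~ U(50, 500) counts at reference depth; φ ~ Gamma(shape 4, mean 0.1),
typical of between-replicate biological variability in plant RNA-seq, with
`dispersion_shape=None` planting the constant φ = 0.1 used by the
calibration and recovery checks; effects planted at 6 h only (the
transient early response). Class counts follow largest-remainder
apportionment with ties broken by class order, so they are deterministic.

What the generator does **not** emulate: GC/length bias, batch effects,
correlated genes, read-level error, or heavy-tailed outlier samples.
Passing the recovery tests therefore demonstrates that the pipeline's
logic and calibration are sound under the stated model — not that real
tissue data will yield the same sensitivity.

## Calibration notes

* With constant planted φ, all-null raw exact-test p-values are
  KS-uniform and BH at q < 0.05 calls essentially nothing. With a
  continuous φ mixture, plug-in-dispersion p-values are intrinsically
  non-uniform under the null (conservative center, inflated extreme tail)
  no matter how good the estimator — a property of the plug-in approach,
  shared by all dispersion-shrinkage DE methods, worth remembering when
  interpreting marginal q-values near the cutoff on real data.
* Under the standardized additivity null with correct SEs, T/df → 1
  (checked at 2000 genes); through the full count pipeline at n = 3 the
  statistic is approximately calibrated (mean T/df ≈ 0.95 across seeds)
  after the SE df-correction described above.
* Strict-synergy recovery at the default planted conditions (constant
  φ = 0.1, baseline ≥ 50, |log2FC| ∈ [1, 3], n = 3): sensitivity ~0.8,
  precision ~0.82–0.89. The residual false entries are BH-level false
  positives of the pyramid contrast that survive the monogenic filters —
  the price any FDR-controlled Venn construction pays. Planted additive
  genes essentially never enter the strict set (≤ 1%); the acceptance
  check allows ≤ 10%, i.e. twice a 5% type-II allowance at the relaxed
  cutoff (the threshold's operationalisation is this package's own).

## Degenerate inputs and tie-breaks

Empty synergy sets produce empty reports with NaN aggregates rather than
errors; empty enrichment tables are returned when no term hits a DE gene;
clustering requires ≥ 2 non-constant rows; exact-test totals of zero give
p = 1; TMM falls back to factor 1 when the trimmed set is empty or has
zero weight. All orderings that could tie (cluster labels, candidate
ranks, apportionment remainders) have documented deterministic tie-breaks.

## Known limitations

* Two-group exact contrasts only — no GLM design matrices, quasi-likelihood
  F-tests, or voom-style precision weights.
* The dispersion estimator is a moment/shrinkage approximation; per-gene
  estimates are noisier than likelihood-based ones at n = 3, which is the
  main driver of the remaining FDR excess in high-signal contrasts.
* The χ² additivity test assumes independent, correctly specified SEs;
  shared normalization noise across contrasts is ignored (it is second
  order at these depths).
* GO enrichment does not propagate ancestors; supply a propagated map.
* Network analysis annotates and prunes a supplied interaction edge list;
  it infers nothing.
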