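# Methods

## Scope and data model

`vmrkit` analyses window-level methylomes derived from reduced
representation bisulfite sequencing (RRBS). The unit of analysis is a
non-overlapping 100-bp genomic tile; a CpG at 1-based position p
belongs to the tile `[((p-1)//100)*100, +100)`. Per-tile methylation is
the *weighted methylation level* — summed methylated counts over summed
total counts across the tile's CpGs — never a mean of per-site
proportions, so deeply covered CpGs carry proportionally more weight.
Tiling is non-overlapping (step = window size): downstream overlap
counting and region totals treat windows as distinct units, which an
overlapping tiling would break.

Coordinates are 0-based half-open internally and in every BED written;
cytosine reports and coverage files are 1-based and converted at the
boundary. CpG dyads are not merged across strands by default
(`merge_cpg_dyads` is available when a destranded analysis is wanted).

The cross-sample container (`MethylationMatrix`) keeps only windows
covered in **all** samples of a comparison (intersection universe).
Every overlap statistic is computed inside that explicitly derived
universe, and the universe size is always reported with the result
rather than assumed.

## Coverage filtering and normalization

Cells (window × sample) with total coverage below 10× are removed, as
are cells above the per-sample 99.9th coverage percentile — a guard
against PCR-duplicated or collapsed-repeat pileups. Whether the
percentile cap should be per sample or global is genuinely open; per
sample is used because coverage distributions differ between libraries.
A site-level variant (`filter_sites`) applies the same rules per CpG
before tiling and is what the pipeline runs on parsed reports.

Coverage normalization scales each sample's counts by
(median of per-sample median coverages) / (that sample's median),
rounding to the nearest integer with ties to even for determinism.
Methylated counts are re-derived from the sample's methylation level
after scaling, so 0 ≤ m ≤ 1 survives rounding and the level moves by
less than one read's worth per cell.

## VMR calling

For a chosen group, each window's inter-individual variance of the
weighted methylation level is computed on the proportion scale with the
unbiased (n−1) denominator (the estimator is unstated in most
descriptions of the approach; n−1 is the conventional choice).
Variances are ranked in descending order and the VMR threshold is the
*knee* of the ranked curve: rank and variance are each min–max
normalized to [0, 1] (making the cut scale-free — multiplying all
variances by a constant cannot change the VMR set) and the threshold is
the variance at the rank with maximum perpendicular distance below the
chord joining the curve's endpoints. Ties break toward the higher
variance, i.e. fewer VMRs. A window is a VMR iff its variance is
strictly above the threshold. Degenerate geometry (a near-linear ranked
curve) is answered with a warning and the tie-break rank; all-equal
variances are an error.

This rule presumes what it is meant to exploit: a biphasic variance
distribution with a large low-variance bulk and a small high-variance
tail. No smoothing is applied to the ranked curve by default; light
moving-average smoothing was evaluated and does not improve the cut
(the knee's placement error is driven by the gradual tail–bulk blend,
not by order-statistic spikes), so the option was dropped rather than
shipped as dead configuration.

## DMR testing

Each window is tested by binomial logistic regression of per-sample
(methylated, total) counts on a group indicator. With one binary
covariate the maximum-likelihood fit is closed-form — fitted
proportions are the per-group pooled methylation levels — so the 1-df
likelihood-ratio chi-square is computed vectorized across windows; the
same fit via an iterative GLM is used as an independent cross-check in
the test suite. Complete separation (one group all-0, the other all-1)
is not an error: `x·log(x)` terms at the boundary are zero and the
deviance is finite. `meth_diff` is the difference of pooled
(coverage-weighted) group levels in percentage points; the
mean-of-sample-proportions contrast is reported alongside since either
convention is defensible.

P-values are Benjamini–Hochberg adjusted (`q`), and windows with
q < 0.05 are DMRs. BH replaces spline-based π₀-estimating FDR variants:
it is simpler, reproducible to the digit, and conservative relative to
them, and no conclusion here depends on the adjustment flavor.

No overdispersion correction is applied. Consequences, measured in this
package's test suite: under pure binomial sampling with non-extreme
means the test is calibrated (type-I error 0.048–0.058 at α = 0.05 on
2,000 null windows, 8 + 8 samples); with beta-binomial dispersion the
test is anticonservative even when the groups are exchangeable, and
with strongly bimodal means near the 0/1 boundary it turns conservative
(≈ 0.02) because the counts are nearly degenerate. The type-I
calibration suite therefore runs on an explicit null methylome
(`generate_null_truth`: uniform means on [0.1, 0.9], zero dispersion) —
the regime where the chi-square reference actually applies. Ranking by
methylation change breaks ties by genomic coordinate so the order is a
deterministic total order.

## Overlap and enrichment statistics

Two framings are deliberately kept side by side, because window-based
studies mix them:

* **Window-set overlap** in a shared universe of N windows: expected
  overlap under independence is E = n_A·n_B/N; the signed fold is O/E
  when O ≥ E and −E/O otherwise; significance is Fisher's exact test,
  computed from the hypergeometric distribution in log space
  (`logsf`/`logpmf` + log-sum-exp) so that tables whose p-value
  underflows double precision still report a finite log10(p). The
  two-sided test sums probabilities of tables no more likely than the
  observed one; the one-sided (enrichment) tail is used for directional
  claims.
* **Interval overlap** against external BED tracks: a region counts as
  overlapping if it intersects any track interval by ≥ 1 bp under
  half-open coordinates (touching end-to-start is not overlap).
  `signed_fold` converts two overlap percentages into the
  ±fold-enrichment/depletion convention.

Positional enrichment of a member set (e.g. VMRs) along a ranked window
list (e.g. by methylation change) uses the classic unweighted GSEA
running sum: +1/|hits| on members, −1/|misses| on non-members; the
enrichment score is the extreme deviation, with an empirical p-value
from seeded membership permutations. The weighting exponent is 0
because the purpose is to *localize* members in the ranking, not to
score a correlation. Because variance-driven changes put interesting
windows at **both** ends of a signed ranking — where a single ES is an
understatement — a two-extremes statistic is also computed: the
fraction of members inside the top-k and bottom-k ranks (k = 5% of the
list per end by default) with a p-value from the same permutations.

Feature distribution against a labelled annotation reports both
multi-assignment fractions (a region counts under every label it
touches; fractions may exceed 1 in total) and an exclusive
priority-order assignment, with an optional "intergenic" fallback for
regions touching nothing.

## The variance-shift model

Methylation of a CpG in one cell is binary, so a region's methylation
level in an individual is an average of Bernoulli states across cells.
The model formalizes stress as movement of the cell-level Bernoulli
parameter from the initial mean m₀ along the path toward 0.5,
parameterized by the achieved across-cell variance p'(1−p') (capped at
0.25, the Bernoulli maximum). The expected shift of the region average
is then 100·(p'−m₀) percentage points:

* starting from an extreme (m₀ ∈ {0, 1}) with variance maxed out, the
  expected shift is **50 points** — variance inflation alone can never
  move a region average past the midpoint;
* a coordinated change (every cell switches state, implemented as a
  deterministic parameter step toward the opposite extreme) reaches
  **100 points**.

The bound is stated and tested as the expectation under maximal
across-cell variance (the maximum-entropy reading); per-realization
averages fluctuate around it by O(1/√(cells·individuals)). The shift is
antisymmetric about m₀ = 0.5 and vanishes there; its magnitude
increases strictly with the variance target once the target exceeds the
starting variance (below that the path does not move — a no-op, not an
error). Individuals are i.i.d.; there is no individual-level random
effect. `asymmetry_stat` provides the corresponding diagnostics on
paired young/old methylation levels: the fraction of changed regions
moving toward 0.5 (NA when nothing changed) and the least-squares slope
of old on young (slope < 1 = compression toward the middle).

## The synthetic methylome generator

The generator is first-class, tested code; it defines the study
conditions under which every emergent property is demonstrated.

* **Baseline means.** Bulk (non-VMR) windows draw from an equal mixture
  of Beta(0.01, 20) and its mirror: almost all mass within a percent of
  0 or 1, the strongly bimodal profile of sperm RRBS windows
  (unmethylated CpG-island-like tiles and fully methylated tiles). VMR
  means draw from the mirrored Beta(2.5, 10) mixture — hypo- or
  hypermethylated but *not* boundary-pinned, because a region whose
  methylation varies across individuals cannot have its population
  mean locked at an extreme; a mean pinned at 0/1 forces near-zero
  variance at any dispersion, which would make the truth labels
  unrecoverable in principle, not just in noise. A `poised_frac` = 0.1
  minority of VMRs instead draws from the extreme Beta(0.3, 12)
  mixture: indistinguishable from bulk at baseline, variable only once
  dispersion is inflated — these are what makes the callable VMR count
  grow in the stressed group.
* **Dispersion.** Beta-binomial with (mean, ρ) parameterization — the
  standard overdispersed model for bisulfite counts; one window-level
  proportion per individual shared by the window's CpGs. Bulk
  ρ ~ U(0.01, 0.02); VMR windows multiply ρ by a contrast drawn from
  U(2.5, 10) per window (heterogeneous variability is the realistic
  default; a scalar contrast — e.g. exactly 5 — can be requested for
  controlled experiments, and every VMR is then still strictly more
  dispersed than every non-VMR).
* **Coverage.** Negative-binomial per CpG (mean 30×, shape 5), five
  CpGs per 100-bp window: a right-skewed coverage distribution in which
  the 10× filter removes a realistic minority of cells.
* **Group effect.** One knob: a dispersion inflation factor
  f = inflation_factor × group_effect applied to VMR windows in group
  B (clamped below ρ = 1 with a warning). Because of the bounded
  cell-state mechanics above, inflating across-cell variance from an
  extreme start necessarily drags the mean toward 0.5; the generator
  realizes this consequence by displacing group B's window mean by the
  fraction `coupling·(1−1/f)` of the remaining distance to 0.5
  (coupling = 0.5). At f = 1 the groups are exchangeable in law; at
  m₀ = 0.5 only the variance grows; the displacement → coupling/2 of
  the distance as f → ∞. Dispersion remains the single experimental
  knob — the mean shift is its modeled consequence, not an independent
  effect — and a mean-preserving variant (coupling = 0) is one argument
  away. The canonical aged/stressed condition used in tests and
  examples is group_effect = 3.
* **What is not emulated.** Read-level sequence, bisulfite-conversion
  failure, alignment artifacts, chromosome structure, spatial
  correlation between neighboring windows, and single-cell
  heterogeneity within an individual. The variance modeled is
  *inter-individual* (computed across animals); the per-cell model
  lives separately in the shift module. Passing tests demonstrate the
  pipeline's behavior under beta-binomial dispersion structure — not
  robustness to alignment or conversion artifacts in real libraries.

Measured under these defaults (20 seeds, 2,000 windows, 8 + 8): VMR
recovery at a fixed 5× contrast reaches precision 0.93 / recall 0.91;
with group_effect = 3 the aged group calls at least as many VMRs in
20/20 seeds; called DMRs move toward 50% methylation in ≥ 90% of cases
with an old~young slope ≈ 0.65; and young-group VMRs concentrate in the
two 5% extremes of the methylation-change ranking (permutation
p < 0.01) in 20/20 seeds. All of these are recomputed by the test
suite, not quoted.

## Problem sizes and numerical choices

Property suites run at 2,000 windows × 16 samples with 20 seeds and
finish in seconds; the shift-model simulations use 10,000 cells × 8
individuals, where the Monte-Carlo standard error of the population
mean is 0.18 percentage points. GSEA permutation counts default to
999 in the pipeline (199–499 in tests; empirical p-value floors of
1/(n_perm+1) remain below the thresholds being tested). All random
draws flow through `numpy.random.default_rng` with explicit seeds;
reruns of the pipeline with the same config are byte-identical, and the
provenance manifest records config, seeds, and SHA-256 hashes of every
output. Proportions entering beta parameterizations are clipped to
[1e-6, 1−1e-6]; LRT statistics are floored at 0; extreme Fisher tails
are reported as log10(p) beside the (possibly underflowed) p.

## Known limitations

* The DMR test ignores biological overdispersion by design; its
  q-values on dispersed data overstate confidence and should be read as
  a screening ranking (this mirrors common practice in window-based
  RRBS pipelines).
* The knee threshold has no uncertainty attached; near-degenerate
  ranked curves produce warnings, not intervals.
* Windows are treated as exchangeable units; no spatial merging of
  adjacent significant windows into larger regions is performed.
* The generator's group effect targets VMR windows only; global
  age-related drift of the bulk is not modeled.
* Interval overlap is binary (≥ 1 bp); no reciprocal-fraction or
  base-pair-weighted overlap modes are provided.
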