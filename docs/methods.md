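# Methods

## Relative expression orderings

All discrimination in this package rests on within-sample orderings: for
genes A and B and one sample, either A > B, A < B, or the values tie.
Orderings are invariant under any strictly increasing per-sample transform
of the expression values, so the method applies unchanged to counts, FPKM
or microarray intensities and needs no cross-sample normalization. Ties
are treated as uninformative: they are excluded from the sample count *n*
of the stability test and never contribute a high-risk vote.

## Stability test

For a pair observed with a given ordering in *m* of *n* tie-free samples,
the stability p-value is the upper binomial tail P(X ≥ m) with
X ~ Bin(n, ½), evaluated through the survival function (stable for
n ≥ 10,000; exactness against direct pmf enumeration is asserted for all
n ≤ 25 in the tests). The tested ordering is the majority direction; an
exact split has no direction and is never significant. Multiple-testing
adjustment is applied within each cohort's family of all tested pairs.
Benjamini–Hochberg is the default with Bonferroni available: the choice of
adjustment was genuinely open, and BH was picked as the standard
false-discovery-rate control for large screening families (all C(k, 2)
candidate pairs are tested). Significance uses adjusted p < 0.01.

The direction-concordance assessment between two training sets uses the
same binomial tail: of k pairs discovered in both sets, the number c with
identical per-group direction assignments is scored as P(X ≥ c),
X ~ Bin(k, ½) — the null being that each shared pair agrees by coin flip.
k = 0 returns p = 1 by convention.

## DEG screen

Genes with zero median across the pooled samples of a training set are
excluded before ranking (the median is taken over both groups together).
Ranks are ascending (1 = lowest) with average ranks on ties, so rank sums
are preserved; only rank differences matter downstream. Selection takes
the k genes per direction with the largest difference in group-median
rank; equal differences at the selection boundary are broken by
lexicographic gene id so runs are deterministic across platforms. Median
rank uses the midpoint convention for even sample counts.

## Matching reduction

Reversal pairs shared by the training sets form a graph whose vertices are
genes; a maximum-cardinality matching (blossom algorithm via networkx)
extracts the largest gene-disjoint subset. Cardinality is the sole
optimality criterion; among multiple maximum matchings, edges with smaller
worst-case adjusted p (ties: lexicographic gene order) are preferred via
distinct edge weights, which fixes the output deterministically. Retained
pairs are oriented so gene_a > gene_b is the ordering observed in the
GBM-like cohort (the high-risk pattern), and the vote threshold defaults
to ⌊pairs/2⌋, generalizing the more-than-10-of-21 rule.

## Classification

A sample is high-risk iff strictly more than `threshold` signature pairs
show gene_a > gene_b. Ties within a pair count against the high-risk
pattern (conservative toward low risk); a policy that instead drops tied
pairs from the evaluable count is available but does not change the vote
rule. Missing signature genes are an error by default; lenient mode drops
the affected pairs and rescales the threshold to ⌊usable/2⌋ with a
warning, since a fixed threshold presumes full evaluability.

## Survival conventions

Kaplan–Meier estimation, the two-group log-rank test and Cox
proportional-hazards fitting are delegated to lifelines; tests verify them
against hand-written product-limit, observed-minus-expected and
simulation oracles. Conventions fixed here: median survival is the first
time with S(t) ≤ 0.5 (infinite if never reached); Cox ties use the Efron
approximation with Wald confidence intervals, constant covariates are
rejected, and non-convergence is reported as an explicit failure status
rather than an exception. Categorical covariates are encoded so the
reported hazard ratio compares high-risk vs low-risk and, for *IDH*,
wildtype vs mutant. The horizon-anchored AUC (default 36 months) takes
death before the horizon as positive reference, follow-up beyond it as
negative, and excludes samples censored earlier — the simplest binary
reading of 3-year survival; time-dependent AUC estimators are out of
scope.

## Synthetic cohort generator

The generator emulates the statistical structure the discovery pipeline
assumes, not real glioma data. Log-scale means are arranged in layers:

* each planted reversal pair straddles its own baseline rung at ±δ, with
  the offsets swapped between groups; δ = noise_sd · Φ⁻¹(s)/√2 makes the
  per-sample probability of the planted ordering equal the target
  stability s (δ = 1 when noise_sd = 0, giving deterministic orderings);
* rungs are spaced 2δ + 2·noise_sd + 0.1 apart, so genes of different
  pairs never systematically reverse;
* background and differential genes share a band strictly above every
  rung's window (width 4 log-units), so no gene reverses against a pair
  gene; planted differential genes shift by `deg_rank_shift` (default 1.5,
  three noise standard deviations) in one group, crossing interleaved
  background genes and acquiring large median-rank differences. Genes they
  cross do reverse against them — the same phenomenon that makes pairs of
  oppositely shifted genes discriminative in real data.

Values are exp(mean + noise) with i.i.d. Gaussian noise, hence positive
and finite. The planted layout (which genes pair up, orderings per group,
differential directions) is a deterministic function of the config
dimensions, so simulations at different seeds share ground truth and act
as twin training sets from "different platforms".

The generator's contract guarantees each planted pair an empirical
within-group stability of at least s − 0.03. Binomial sampling alone
leaves a non-trivial chance of dipping below that floor, so pairs that
miss it have their two noise rows redrawn until it holds (conditional
sampling, deterministic given the seed). This biases realized stability
slightly upward; the mean across pairs stays within ±0.03 of the target
and is asserted in the tests.

Survival times are exponential: the low-risk class has median
`baseline_median_os_months` (default 60) and the high-risk hazard is
multiplied by `hazard_ratio_high_vs_low` (default 4, in the range seen
between indolent and aggressive glioma). Censoring is an independent
uniform administrative time whose upper bound is solved numerically so the
expected censored fraction matches `censor_fraction`; it is independent of
class. Mutation labels are Bernoulli with class-conditional frequencies
(defaults: *IDH* mutant 0.85 low / 0.15 high, *TERT*-p mutant 0.80 / 0.85,
echoing the frequency contrast between *IDH*-mutant low-grade and
*IDH*-wildtype high-grade disease in published training-cohort
descriptives); grade, age and sex are likewise class-correlated. One
global seed feeds a named sub-stream per component (expression, survival,
censoring, labels), so adding or resampling one component never perturbs
another.

What the generator does **not** emulate: realistic expression magnitudes
or library-size effects, batch structure, probe-level artifacts,
correlated co-expression modules, or non-proportional hazards. Passing
tests therefore demonstrate correctness of the algorithms under the
model's assumptions, not performance on real cohorts.

Because planted pair genes swap ranks only with their partner, their
median-rank difference is ±1 and a tight DEG filter would discard them;
in planted-recovery scenarios the filter is run permissively
(k = genes/2), leaving discrimination to the pair-stability stage. With
planted differential genes (the default config) the filter is informative
and recovers ≥ 90% of them at k = planted count.

## Problem sizes

Test and acceptance runs use cohorts of 100–200 genes and 40–150 samples
per group (500/group for the Cox hazard-ratio check, 2000/class for
estimator-bias checks), 15 planted pairs at stability 0.98, and 20-seed
replications for stochastic claims — sizes at which every stochastic
tolerance in the suite is comfortably stable while the full suite runs in
about a minute.

## Known limitations

* Gene identifiers are matched case-insensitively after trimming; no
  alias or annotation lookup is attempted, so cross-platform harmonization
  beyond exact symbols is the caller's responsibility.
* Duplicate gene rows are collapsed by per-sample median — robust and
  order-preserving, but any probe-selection scheme (e.g. highest-IQR
  probe) will yield different orderings for affected genes.
* The discovery step tests all candidate pairs exhaustively; beyond a few
  hundred candidates the quadratic pair family becomes the dominant cost.
* Heavily discretized data with many within-pair ties reduce the
  informative sample count n and, in classification, push votes toward
  low risk by construction.
* No competing risks, time-dependent covariates or proportionality
  diagnostics; the Cox model is taken at face value.
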