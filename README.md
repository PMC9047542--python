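# reosig

Reversal gene-pair signatures from relative expression orderings (REOs),
with majority-vote risk classification and survival evaluation.

## The problem

Bulk and single-cell expression measurements are hard to compare across
platforms, batches and normalization pipelines — but the *ordering* of two
genes within one sample (is gene A expressed above gene B?) is invariant to
any per-sample monotone transform. Signatures built from such within-sample
orderings transfer between RNA-seq and microarray cohorts without
renormalization. The motivating application is diffuse glioma: some tumours
histologically graded as low-grade glioma (LGG) behave like glioblastoma
(GBM) and carry its dismal prognosis. A rank-based gene-pair signature can
flag these GBM-like patients from a single expression profile, where
single-marker classifications (e.g. *IDH* or *TERT*-promoter mutation
status) are confounded by tumour heterogeneity.

## The method

Given two labelled training cohorts (an LGG-like low-risk group and a
GBM-like high-risk group):

1. **Rank-based DEG screen.** Genes with zero median expression in a
   training set are excluded; the remaining genes are ranked within each
   sample (ascending, average ranks on ties). The k genes per direction
   with the largest between-group difference in median rank are the
   differential candidates; candidates shared by both training sets with
   the same direction are kept.
2. **Stable and reversely stable pairs.** For a candidate pair observed
   with the same ordering in *m* of *n* informative samples of a cohort,
   the chance probability is the binomial tail

   p = 1 − Σ_{i=0}^{m−1} C(n, i) P₀^i (1 − P₀)^{n−i},  P₀ = ½.

   A pair with Benjamini–Hochberg-adjusted p < 0.01 is *stable*; a pair
   stable in both groups with opposite orderings is a *reversal pair* —
   the discriminative unit of the signature. Reversal pairs found in both
   training sets with concordant directions are retained, and the
   concordance itself is scored with the same binomial tail.
3. **Redundancy removal.** A maximum-cardinality matching on the graph
   (genes = vertices, reversal pairs = edges) yields the largest
   gene-disjoint subset; each retained pair is stored oriented so that
   gene_a > gene_b is the high-risk (GBM-like) ordering, with vote
   threshold ⌊pairs/2⌋.
4. **Majority-vote classification.** A new sample is high-risk iff
   strictly more than `threshold` signature pairs show their high-risk
   ordering (for a 21-pair signature with threshold 10: ≥ 11 pairs).
5. **Survival evaluation.** Risk groups are compared with Kaplan–Meier
   curves, the log-rank test, univariate/multivariate Cox
   proportional-hazards models, and the ROC AUC anchored at 3-year
   survival (death before 36 months = positive reference; samples censored
   earlier are excluded).

A synthetic two-cohort generator with planted reversal pairs, planted
rank-shifted differential genes, class-dependent exponential survival and
correlated mutation labels makes every stage testable without external
data (see `docs/methods.md`).

## Worked example

Discover a signature from twin synthetic training cohorts (15 planted
reversal pairs, 60 samples per group) and apply it to a third cohort:

```python
from reosig import (PipelineConfig, SimulationConfig, run_apply,
                    run_discovery, simulate_study)

sim = dict(n_genes=200, n_samples_per_group=60, n_planted_reversal_pairs=15,
           reversal_stability=0.98, n_planted_degs=0)

train1 = simulate_study(SimulationConfig(**sim, seed=1))
train2 = simulate_study(SimulationConfig(**sim, seed=2))
signature, report = run_discovery([train1[:2], train2[:2]], PipelineConfig())
print("signature pairs:", len(signature), "| vote threshold:", signature.threshold)

expr, pheno, truth = simulate_study(SimulationConfig(**sim, seed=3))
votes, ev = run_apply(expr, pheno, signature, PipelineConfig())
```

Output:

```
signature pairs: 15 | vote threshold: 7
direction consistency: 15/15 concordant, p = 3.05e-05
high-risk calls: 60/120 | agreement with truth: 100.0%
log-rank chi2 = 42.0, p = 9.25e-11
Cox HR (high vs low) = 4.48
3-year AUC of the vote score = 0.798
```

Discovery recovered exactly the 15 planted pairs (15/15 concordant
between the training sets; a concordance that extreme arises by chance
with p ≈ 3e-5). On the held-out cohort every sample is classified
correctly, the predicted risk groups separate survival sharply (log-rank
p ≈ 1e-10), and the high-risk hazard is ~4.5-fold — close to the
simulated class hazard ratio of 4.

The same pipeline is available from the shell:

```sh
reosig simulate --seed 1 --out-dir d1
reosig simulate --seed 2 --out-dir d2
reosig discover --expr1 d1/expression.tsv --pheno1 d1/pheno.tsv \
                --expr2 d2/expression.tsv --pheno2 d2/pheno.tsv --out-dir disc
reosig classify --expr d1/expression.tsv --signature disc/signature.tsv --out votes.tsv
reosig evaluate --votes votes.tsv --pheno d1/pheno.tsv --out-dir report
```

(`reosig run-all` chains all of the above.) Real cohorts are supplied as
tab-separated genes × samples expression matrices plus a phenotype table;
an existing signature file can be applied directly with `classify`.

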