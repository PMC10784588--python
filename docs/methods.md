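# Methods

This note records the statistical models flyspan implements, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## Extreme-phenotype association

Lines are split on one diet into an in-case and a non-case group. Two
dichotomization modes exist because either reading of the design is
defensible: `top_k` (default, k = 25 — the k longest-lived lines are
in-case) and `threshold` (in-case iff median lifespan strictly exceeds a
cutoff, default 41 d). `top_k` is the default; `threshold` is retained for
sensitivity analysis. Ties at the k-th lifespan are broken by ascending
line id so the assignment is a pure function of the phenotype table.

Each marker's table counts **lines**, not allele copies: the two allele
copies of a fully inbred line are not independent observations, so counting
them twice would overstate evidence. Missing calls drop out of the table
per marker (rather than dropping the line globally), which keeps counts
maximal and matches standard GWAS practice; lines genotyped but not
phenotyped (or vice versa) are excluded with a logged count.

The two-sided Fisher p uses the minimum-likelihood rule — the sum of
hypergeometric point probabilities not exceeding the observed table's,
with a 1e-7 relative tie tolerance — i.e. exactly the convention of
`scipy.stats.fisher_exact`, which the implementation wraps (behind an LRU
cache, since permutation scans revisit the same tables heavily). An
exhaustive sweep over all 2×2 tables with margins ≤ 12 against a
rational-arithmetic enumeration oracle is part of the test suite.

## Permutation FDR

For permutation i, the analyzed diet's lifespans are shuffled across line
ids (other diets untouched), cases are **re-assigned on the shuffled
phenotypes**, and the full scan is re-run. This propagates the selection of
extremes into the null distribution; permuting labels without re-assigning
would understate the null discovery count. FDR(t) is the ratio of the mean
permuted discovery count to the real count at threshold t, capped at 1,
and left undefined (not 0) where the real scan calls nothing — 0/0 is not
evidence of control. Defaults: 10 permutations; threshold grid
{1e-6, 1e-5, 1e-4, 1e-3, 0.01, 0.05}. Per-permutation seeds derive from
the master seed by counter (`SeedSequence([seed, i])`), so runs are
deterministic and parallelizable. No monotonization across t is applied by
default; `monotonize_fdr` (running minimum from large t) is provided and
off.

Markers are called at `fdr_max` by taking t\* = the largest grid threshold
with defined FDR ≤ fdr_max and returning markers with p ≤ t\*.

Two properties of this estimator are worth knowing. First, at sparse
thresholds (where the real scan typically calls 0–1 markers) the estimate
is noisy and conditionally biased downward: a replicate only *has* a
discovery there via an upward fluctuation of the real scan, while the
10-permutation mean stays near its expectation, so the ratio concentrates
well below 1 even under a global null. At thresholds with a handful of
real calls (0.01, 0.05) the null median is 1, as it should be. Second,
the coarse default grid leaves a gap between 1e-4 and 1e-3; signals whose
p lands in that gap are only called if FDR(1e-3) clears `fdr_max`, which
costs a few percent of power for planted markers at the low end of the
common-MAF range. Both behaviours are quantified by the acceptance tests.

## Survival statistics

Kaplan–Meier product-limit estimation with deaths pooled by recorded day
(the 2-day check grid makes ties the norm); right-censored records leave
the risk set without an event, and censoring at a death time is processed
after the deaths. The median is the first event time with S(t) ≤ 0.5, not
interpolated — interpolation on a 2-day grid would be spurious. The
log-rank test is the Mantel–Cox form with the hypergeometric
tied-data variance; times with one subject at risk contribute zero
variance, and a zero total variance yields an undefined statistic with
p = 1 and a warning. The χ² p-value comes from `scipy.stats.chi2.sf`
(regularized upper incomplete gamma). Both routines are cross-checked
against lifelines and against a direct per-event-time summation oracle.

## Omics statistics

Abundances are log2 scale throughout; a feature's fold-change is the mean
of its per-pair treated-minus-control differences, pairing naturally with
the paired t-test. Welch's form is used for unpaired two-sample
comparisons. Zero-variance inputs are degenerate by convention (p = 1 when
the mean difference is 0, else p = 0, logged).

Storey q-values: π̂₀ is estimated on the λ grid 0, 0.05, …, 0.90 as
#{p > λ}/(m(1−λ)), smoothed with a cubic smoothing spline at three
effective degrees of freedom (penalty calibrated by bisection on the trace
of the smoother matrix), evaluated at the largest λ and clamped to (0, 1].
The spline, rather than an unpenalized cubic polynomial, keeps the
boundary variance small enough that uniform-null estimates stay near 1.
q-values are the step-up monotone minimum of π̂₀·m·p\_(j)/j; with π̂₀ = 1
the procedure reduces exactly to Benjamini–Hochberg, which the tests
verify.

The DE filter keeps features with ≥ 2 unique peptides, q strictly below
0.05 and |log2FC| strictly above 0.58 — the inequalities are strict
exactly as conventionally printed. The Spearman screen uses average ranks
for ties and pairwise-complete samples, keeps ρ strictly above 0.30
(one-sided positive), and skips features with fewer than 3 overlapping
samples. The overlap test requires an explicit universe (no default is
assumed), computes the upper-tail hypergeometric P(X ≥ k), and reports
fold enrichment k/(|A||B|/N).

## The synthetic generator

What it emulates: (a) fully homozygous biallelic genotypes with per-marker
alt frequency drawn uniformly from `maf_range` and independent per-call
missingness; (b) per-fly lifespans from a Gompertz law (hazard a·e^{bt}),
sampled by inverse CDF, with the causal alt allele multiplying the
baseline hazard by `effect_dr` under DR and `effect_al` under AL, and
death times rounded **up** to the next 2-day check (flies are found dead
at the next transfer); (c) paired log2 abundance matrices with planted
shifts and Gaussian noise, plus unique-peptide counts with a configurable
single-peptide fraction; (d) gene lists with an exactly planted overlap.

Defaults are the study conditions: 100-line panels, 100 flies per line per
diet, 2-day checks, `maf_range = (0.25, 0.5)` (the post-filter regime of a
≥ 25 % MAF scan — the minor allele should be carried by many lines),
missing rate 0.02, Gompertz a = 1.2e-4/day and b = 0.15/day giving a
median lifespan of ≈ 45 d, in the range of DR-fed lines. A single global
seed expands into independent substreams per component so each dataset
piece can be regenerated alone.

What it does not emulate — and hence what passing tests do not show about
real data: linkage disequilibrium and population structure (markers are
independent), inter-line frailty beyond finite-sample median noise (no
line-level hazard variance term; real panels vary genetically at many
loci), polygenic architecture (at most one causal marker), diet-dependent
baseline mortality (AL and DR share a baseline; only the causal allele is
diet-specific), and realistic proteome abundance/missingness structure.
Because the latent allele frequency is drawn in [0.25, 0.5], realized
sample frequencies can fall slightly below 0.25; pipeline stages that
re-filter on realized MAF will occasionally drop a planted marker at the
boundary.

## Problem sizes and runtime

The test suite and the acceptance script size their simulations to desk
scale: 100 replicates of 100 × 300–500 panels for FDR calibration and
recovery, 1000 log-rank simulations at n = 100/arm, 10⁴ random p-vectors
for the BH reduction, and 50 uniform-null vectors of m = 2000 for π̂₀.
The full suite runs in about a minute; `scripts/acceptance.py` in about
half a minute.

## Known limitations

* The FDR threshold grid is fixed and coarse by default; analyses hunting
  signals near a specific p should densify it (`thresholds=` argument).
* `assign_cases` treats the phenotype table as exact; measurement error in
  line medians is not modeled.
* VCF input reads GT only (no INFO/structural records); multi-allelic
  records are skipped with a warning rather than decomposed.
* The overlap test treats gene ids as opaque strings; identifier-mapping
  (symbol vs accession) is the caller's responsibility.
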