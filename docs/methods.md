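# Methods

This note documents the models behind `vagsig`, the parameters that matter,
what the synthetic generators do and do not emulate, and the numerical
choices made where the design was open.

## Differential expression and the selection rule

Each cancer's paired cohort is analyzed on the log2 scale with a two-sided
paired t-test per gene: t = mean(d)/(sd(d)/√n) on the within-patient tumor −
normal differences d, df = n − 1. P-values are Benjamini–Hochberg adjusted
**within each cancer** (the per-dataset testing structure; a pooled scope
would change the signature size and is left to the caller by adjusting the
long results table directly). Fold change is 2^mean(d) — the geometric-mean
ratio, consistent with testing on log2 values; a linear-mean ratio is not
offered because it mixes scales.

A gene is selected when some direction (up/down) is significant at adjusted
P < `alpha` (default 0.05) in at least `min_cancers` (default 4) cancers.
"Accordant" is read as a constraint on the qualifying count only: a gene
significant up in four cancers and down in one still qualifies by default,
because the rule asks for four accordant cancers, not for unanimity. The
stricter reading is available (`SelectionRule(forbid_discordant=True)`).
Genes with t = 0 exactly count for neither direction.

Term enrichment is the one-sided (greater) Fisher's exact test on the 2×2
in-set × in-term table over a caller-supplied universe, BH-adjusted across
terms. Term databases are inputs, never fetched.

## Risk scoring

Per signature gene, a univariate Cox proportional-hazards model of
recurrence-free survival on expression is fit on the training cohort
(partial likelihood, Efron tie handling; Breslow available). The Wald
statistic Z_i = β_i/se_i weights the gene in

S = Σ_i Z_i (e_i − μ_i)/τ_i,

with μ_i, τ_i the mean and SD (ddof = 1) of gene i over all training
samples. Design choices where the procedure is ambiguous:

* **Scaling scope.** μ and τ are frozen from training by default (the
  literal "scoring system … fixed on the training cohorts").
  `restandardize_per_cohort=True` recomputes them on the scored cohort — the
  pragmatic choice when training and validation come from different
  platforms. Both modes are tested.
* **Threshold.** The positive/negative split always uses the scored
  cohort's own median ("the group median"), strictly-greater-than; ties at
  the median are negative, so the positive group can be the smaller one.
* **Missing genes** are dropped from the sum without reweighting (the score
  is a sum and no renormalization is defined); the count is reported on the
  `RiskAssignment`. More than 50% missing at training time is an error.
* Constant-expression genes are dropped with a warning; a model with no
  fittable gene is an error.

### The Cox core

`vagsig.cox.cox_fit_many` maximizes the univariate partial likelihood by
Newton–Raphson, vectorized across covariate columns that share one
(time, event) vector — the resampling tests refit ~45 gene models per random
signature, thousands of times, so per-fit overhead dominates everything
else. Efron's tie correction is computed per multiplicity layer; for untied
data it collapses to cumulative-sum expressions with no per-event Python
loop. Covariates are centered before exponentiation; steps are clipped at
±2 to survive monotone-likelihood edge cases (e.g. near-perfect separation);
convergence is |step| < 1e-10·(1 + |β|). The implementation agrees with
lifelines to that library's own convergence slack (~1e-4) and with a
brute-force partial-likelihood oracle to ~1e-8; columns with zero variance
return NaN rather than raising, so bulk fits skip degenerate genes.

Multivariate fits, Kaplan–Meier curves and log-rank tests are delegated to
lifelines. Categorical covariates require an explicitly declared reference
level — no silent alphabetical defaults — and rank-deficient designs raise
an error naming a culprit column. Stratified analyses reuse the
cohort-level dichotomization (patients are stratified, scoring is not
redone); strata with fewer than two events or a single risk group are
skipped with a warning. Evaluation P-values are two-sided throughout; the
one-tailed tests live in the resampling module only.

## Resampling nulls

All three tests share one machinery: compute the observed statistic for the
signature, recompute it for `n_resamples` uniform same-size draws from an
explicit gene pool, and report the right-tail add-one empirical P,
(1 + #{null ≥ observed})/(1 + N) — never exactly zero, standard permutation
practice. The pool is always an argument: the whole measured universe for
the prognostic test, a curated "cancer-related but outside the signature's
interaction universe" pool for the pooled sum-of-z test. Each resample
re-runs the entire train → score → dichotomize → Cox pipeline; cached
weights would not answer the question "is *this* signature better than a
random one of identical size". Degenerate resamples (constant scores, no
events in a group) are skipped and counted; a skip fraction above 5% aborts
the run rather than silently reporting a P on a truncated null.

## Network coherence

The co-expression statistic follows the GENIE3 procedure: for each target
gene, a random-forest regression of the target's unit-variance-standardized
expression on all other genes; the directed weight w_ij is regulator i's
total impurity (variance) reduction averaged over trees, **not**
renormalized, so each target's incoming weights sum to the ensemble's
explained-variance mass and are comparable across targets. The coherence
statistic is the sum of all weights. Defaults: 100 trees, √(n−1) candidate
regulators per split, minimum leaf size 5 (the classic regression-forest
default). The leaf size is load-bearing: fully grown trees explain
essentially all in-sample variance of any target — noise included — which
flattens the adjacency sum; with leaf size 5 a mutually predictable gene set
scores far above independent noise. Per-target forest seeds are derived
from (seed, gene id) and genes are ordered canonically inside the function,
so the adjacency is exactly equivariant under permutations of the input
rows. Constant genes get zero rows/columns with a warning.

## Synthetic data

Expression is simulated directly on the log2 scale as Gaussian, matching
log2-transformed microarray intensities; probe-level effects, batch and
platform differences, and competing risks are deliberately out of scope, so
green tests say the *statistics* behave as designed, not that the pipeline
is robust to real-data artifacts like normalization failures or annotation
drift.

**Paired cohorts.** value = baseline (8.0) + per-patient-per-gene random
effect (SD 0.5) + signed DE effect (tumor only) + residual noise (SD 0.5).
The shared patient effect is the simplest mechanism that makes the paired
t-test strictly more powerful than an unpaired one. DE genes carry either a
single signed log2 effect applied in `accordant_in` randomly chosen cancers
(accordant genes) or an explicit per-cancer effect map (used to plant
discordant decoys). Ground truth is always returned.

**Survival cohorts.** Signature genes follow a one-latent-factor model,
x = baseline + λF + √(1−λ²)ε with unit marginal variance, giving pairwise
correlation λ²; other genes are independent. Event times are exponential
with rate h₀·exp(Σβ_g(x_g − baseline)); censoring is the minimum of an
independent exponential and an administrative cut-off. Unit-exponential
draws are scaled by the rates, so at fixed seed the censoring fraction is
monotone in the censoring rate. Default h₀ = 0.05/time-unit and censoring
rate 0.02 give roughly 30% censoring under a null signature with a 100-unit
administrative cap.

Default study conditions (used by the pipeline and the acceptance script):
1,000-gene universe; six paired cohorts of 30 patients with 50 accordant DE
genes at effect 1.0 log2 in 5 of 6 cancers; 300/300-sample training and
validation cohorts in which 10 signature genes carry log HR 0.4 with
loading 0.5. The 1,000-gene universe matters for the resampling null:
random same-size signatures must be mostly free of true hazard signal, as
they would be on a genome-scale array. Under these conditions the planted
effects are strong — validation hazard ratios around 5–8 — which keeps the
recovery checks about correctness rather than borderline power.

## Problem sizes in the test suite

The statistical acceptance checks run at reduced but fully powered scale,
chosen as ordinary desk-scale experiments: 50-seed recovery runs at
n = 1,000 (Cox) and 300/300 (end-to-end); 200 replicates × 200 resamples
for null calibration on 120-sample cohorts over a 60-gene pool; 20 seeds ×
100 resamples for the coherence test (10-gene sets, 60 samples, 10 trees);
1,000 replicates for log-rank calibration. Empirical error-rate assertions
use bands wide enough for binomial noise at those sizes.

## Pipeline and reproducibility

`run_pipeline` executes simulate → signature → train → evaluate → resample →
network, writing TSV/JSON artifacts and a manifest with per-output SHA-256
checksums, per-stage seeds and timings. One run seed fans out to per-stage
seeds through a fixed SHA-256-based rule, so stages are independently
reproducible; two runs with the same config produce identical outputs
(manifest timings aside). Stage requirements missing from both memory and
the output directory raise a dependency error naming the stage. The CLI is
a thin wrapper; exit codes: 1 validation, 2 dependency, 3 numerical.

## Known limitations

* The detection filter's presence predicate ("value above a floor",
  defaulting to the cohort 10th percentile) is a value-level stand-in for
  platform detection calls; with real array data prefer passing a predicate
  built from actual detection flags.
* Univariate Cox assumes proportional hazards; no diagnostics (Schoenfeld
  residuals, time-varying effects) are provided.
* The coherence statistic uses in-sample importances, inheriting the
  overfit bias of the underlying forests; it is only meaningful relative to
  its resampling null, never as an absolute quantity.
* Cross-platform gene reconciliation is reduced to "intersect universes and
  log the losses"; probe re-annotation is out of scope.
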