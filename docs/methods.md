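# Methods

This note documents the statistical machinery, the defaults and the design
choices made where the procedure left room for interpretation, plus known
limitations. It describes what the code does; every number quoted here is
computed by the test suite or `scripts/acceptance.py` at run time.

## Phenotypes and cohort

Five patient-reported neuropathy symptoms (numbness in feet, tingling in feet,
cramps in feet, difficulty opening a jar, difficulty climbing stairs) are
scored on the four-level scale *not at all / a little / quite a bit / very
much* and dichotomized: the upper two levels count as moderate–severe (y = 1),
the lower two as none–mild (y = 0); a missing item stays missing and is
excluded from that symptom's fits and denominators.

The cohort splits once into training and test sets before any selection. The
general rule allocates `floor((1 − f)·n)` samples to test; the emulated study's
237/100 split of 337 survivors is not reachable from its stated 70/30 fractions
by any rounding convention, so `split_cohort` takes an explicit `n_test`
override which the study-emulation configuration sets to 100. Splitting is
deterministic under a seed and optionally stratified by outcome.

## Variant QC

A variant is retained iff genotyping rate ≥ 0.95, mean coverage ≥ 10 reads,
Hardy–Weinberg exact p ≥ 10⁻⁴, biallelic, and FILTER = PASS. The thresholds
are removal conditions exactly as printed ("< 0.95" removes), so boundary
values survive. Multi-allelic rows are dropped whole, never decomposed.
Missing genotypes are never imputed at QC; each downstream operation declares
its own missing-data policy (complete-case for the scan and model fits,
variant-mean imputation inside the region-test kernel). The HWE test is the
exact conditional test on genotype counts, summing the probabilities of all
heterozygote counts no more likely than observed (no mid-p); it is computed in
log space and verified against a brute-force enumeration oracle to 10⁻¹²
over >10⁴ genotype tables. The HWE filter uses all samples (whether the
original analysis used founders only is unknowable from the publication; there
is no family structure here).

## Per-SNV scan and permutation FDR

Each variant is tested with a two-parameter logistic model (intercept +
encoded genotype) under additive (0/1/2), dominant (0/1/1) and recessive
(0/0/1) codings; the reference allele is coded 0. The scan is genotype-only —
covariates enter at model building, not at screening. A coding whose encoded
minor category holds fewer than `min_count = 5` samples is skipped (p = 1);
the best coding is the smallest Wald p with ties broken additive > dominant >
recessive, for determinism. The fits run on grouped sufficient statistics
(genotype-category counts), a vectorized Newton solver mathematically
identical to the row-wise fit (verified against the IRLS engine); this makes
1000-permutation FDR runs a handful of matrix products.

The FDR at threshold t is `min(1, mean_perm #{p ≤ t} / max(1, #{p_obs ≤ t}))`,
estimated by permuting the outcome vector only (genotype LD preserved;
covariates are not involved at this stage). The chosen threshold minimizes the
estimated FDR **among thresholds with at least one observed hit** (smallest t
on ties); without the restriction, any threshold below the smallest observed
p-value has a trivial estimated FDR of 0 while selecting nothing. Note the
estimator is a ratio of small counts: at realistic grids (t ≤ 0.005,
m ≈ 2000) the expected hit count is single-digit, so individual FDR(t) values
carry large sampling variance even though the estimator is exactly unbiased in
its numerator and denominator (its permutation-mean hit count equals the
fresh-outcome mean; the test suite measures this). Downstream conclusions
should rest on the chosen threshold's selected set, not on the point FDR value.

## Gene/region score test

For a gene's genotype submatrix G (n × m, m ≥ 2), weights w_j, covariates X
with intercept, and null logistic fit μ̂:

    Q = (y − μ̂)ᵀ G W² Gᵀ (y − μ̂)

with null distribution Σ λ_k χ²₁ where λ are the eigenvalues of Wᵀ Gᵀ P G W,
P = V − V X (XᵀVX)⁻¹ XᵀV, V = diag(μ̂(1−μ̂)). The tail probability is computed
by numerical inversion of the mixture's characteristic function (Imhof's
method, with the linear phase handled by oscillatory-weight quadrature;
validated against Monte Carlo across eigenvalue shapes to < 0.003). A
three-moment Liu-type non-central χ² match serves as numerical fallback, and a
permutation fallback (outcome shuffles, null refit per shuffle) guards cases
where the analytic null itself is unreliable (n < 30, degenerate kernels).

Defaults: weights are the Beta(1,25) density at each variant's MAF (flat
weights available); "rare" region membership is MAF < 0.01; the null model
includes the four clinical covariates when present; genes need ≥ 2 variants.
A variant overlapping several genes enters each of them.

Accuracy caveat: the analytic null is asymptotic. At n = 200 its p-values
differ from the exact finite-sample permutation distribution by up to ~0.01 in
the distribution body (measured against 50,000-permutation references) — the
permutation ensemble is discrete and conditions on the observed outcome
vector, a gap no eigenvalue-based approximation closes. Under the null at
n ≈ 800 with common variants, the analytic p-values are uniform by a pooled
Kolmogorov–Smirnov check at α = 0.01.

## Over-representation filtering

Gene sets come from GMT files; the universe defaults to all genes carrying at
least one tested variant (matching the candidate-generation space, not the
whole genome). Set enrichment is the one-sided hypergeometric tail
P(X ≥ overlap); raw p-values are thresholded by default (Benjamini–Hochberg
across sets is available but off, matching how raw set p-values were used in
the emulated analysis). Candidate genes survive iff they belong to ≥ 1 retained
set; SNVs survive iff mapped to a surviving gene. The threshold is searched
within stage-specific windows (0.005–0.2 for the B2 stage, 0.0025–0.13 for C1)
by maximizing training AUC of the refit model on a small geometric grid.

## Model building

Design matrices are intercept + encoded SNVs + covariates (age, taxane type,
BMI, diabetes treatment). Panel (literature) SNVs use additive coding — their
source effect sizes are reported additively — while cohort-derived SNVs keep
the scan's best coding. Exactly collinear columns are removed greedily
(later-listed first) by a Gram–Schmidt sweep with relative tolerance 1e-10,
so the ML estimate is unique; dropped "singularities" are reported per model.

The fit engine is iteratively reweighted least squares with step-halving,
convergence at max|score| < 1e-8 within 50 iterations, and a divergence guard
(|β| > 15 with still-improving likelihood) that flags quasi-separation. It is
verified against an independently coded Newton–Raphson oracle and against
statsmodels GLM.

An events-per-variable guard refuses fits with more features than minority-
class events (EPV < 1) and warns below EPV 5. The warning threshold is
deliberately permissive: the emulated study fits up to 55 SNVs on ~63 events,
and reproducing that regime (including its instability) is part of the
package's purpose.

Variable importance is the absolute Wald z of each coefficient — the analysis
we emulate says only that VI was "collected" from the fitted model; |z| is the
standard model-based importance for GLM coefficients, and thresholds near
1.0–1.67 are natural on that scale. Separation (undefined SE) maps to VI = +∞
so the feature surfaces in diagnostics instead of vanishing. C2 keeps features
with VI ≥ threshold (boundary inclusive) plus forced covariates; the threshold
is grid-searched (default grid 1.0–1.67) to maximize training AUC, ties going
to the smaller model.

## Evaluation

AUC uses the rank (Mann–Whitney) formulation with ties counting ½, reported in
percent; `AUC(s) + AUC(−s) = 100` exactly. The 95% CI is a stratified
percentile bootstrap (default 2000 resamples; within-class resampling makes
degenerate draws impossible). Classification at cutoff c predicts high
toxicity when probability ≥ c. The cutoff is chosen on training data from the
midpoints of consecutive unique probabilities: cutoffs achieving at least the
target accuracy (default 0.80) are preferred, closest-to-target first, else
the highest achievable accuracy; ties break toward higher sensitivity, then
the lower cutoff. (A pure |accuracy − target| rule would prefer a degraded
cutoff over a perfect separator — e.g. 70% accuracy beats 100% when the target
is 80% — which contradicts the procedure's intent of "around 80%".) A model
is accepted iff training AUC > 80 and test AUC > 60, strictly. Welch's
unequal-variance t-test handles cohort-balance comparisons.

## Synthetic cohort generator

The generator emulates the study conditions; its defaults are the published
cohort's: n = 337 (70/30 split), five symptoms with target prevalences
27.6 / 26.1 / 25.5 / 24.6 / 12.1 %, age ~ Normal(62, 10) truncated to [31, 86],
BMI ~ Normal(26.9, 4.7), paclitaxel ~ Bernoulli(0.445), diabetes ~
Bernoulli(0.047), symptom-item missingness 0.6%. The MAF spectrum mixes
31.6% common variants (uniform on [0.01, 0.5]) with rare variants (Beta(1,25)
truncated below 0.01), matching the study's common-variant share; the default
pool is 20,000 variants ("tens of thousands"), and tests/acceptance runs use
smaller pools (800–3000) as their own problem sizes. Genotypes are two
Bernoulli(MAF) allele draws per sample, so Hardy–Weinberg holds marginally;
optional LD blocks share a per-sample latent Gaussian factor (copula) with
configurable within-block correlation.

Outcomes follow a logistic liability: β₀ + Σ β_j·recode(g_j) + γᵀx, with the
intercept calibrated by root-finding so the expected prevalence hits the
target. Planted effects default to |β| = 0.8 on variants with empirical MAF
≥ 0.05 — an effect planted on a singleton is undetectable at any of these
sample sizes and would test nothing — with codings drawn in the proportions
the scan reports (45.9/35.3/18.8% additive/dominant/recessive) and a quarter
of causal variants shared across symptoms to induce symptom correlation.
Symptom correlation arises only through shared causal variants and covariates
(no residual coupling). By default the generator also produces pre-QC
blemishes — per-variant genotype missingness (Beta(0.3, 60) rates), 2% non-PASS
records, 2% low-coverage records, 1% Hardy–Weinberg-violating (inbred) sites —
so the QC stage filters something real; `qc_artifacts=False` yields pristine
matrices for statistical calibration runs.

What passing tests on this generator do **not** show about real data: no
population structure or relatedness, no haplotype-scale LD or recombination,
no genotyping batch effects, logistic (not probit or liability-scale-h²)
architecture, and independence of covariates from genotypes.

## Numerical and engineering choices

- All randomness flows from one master seed via fixed-order derived streams;
  run reports are byte-identical across reruns of the same configuration.
- Reports are JSON with sorted keys; genotype matrices are float arrays with
  NaN as missing; VCF I/O via pysam (uncompressed VCF 4.2).
- The pipeline runs each symptom independently; one symptom's failure (e.g., a
  degenerate outcome) is recorded and does not abort the others.
- Stage caching was considered and rejected: at the package's default problem
  sizes a full symptom branch completes in seconds, so a config-hash disk
  cache would add state and staleness risk for no benefit.
- Monomorphic sites: HWE p = 1 by convention; scan p = 1 (skipped); zero-
  variance regions p = 1.

## Known limitations

- Wald p-values from the scan are asymptotic; at n of a few hundred with rare
  variants they are conservative near the grid's small thresholds (the
  discrete genotype distribution puts less mass below t than uniform).
- The per-threshold permutation-FDR estimate has high sampling variance at
  realistic hit counts (see above); treat the curve as guidance for threshold
  choice, not as a calibrated error rate per threshold.
- The region test's analytic p is asymptotic (gap to the exact permutation
  null ~0.01 at n = 200); for small cohorts or heavily weighted singleton-rich
  kernels, force `p_method="permutation"`.
- Regularized alternatives (lasso/ridge) and cross-validated selection are out
  of scope by design: the emulated procedure uses a single split and unpenalized
  GLM fits, and its overfitting behavior (A2, C1) is reproduced as a documented
  failure mode rather than engineered away.
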