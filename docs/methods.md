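# Methods

## Scope and data model

The package operates on a per-subject "spine" that every stage joins
against: five NEO-FFI personality scores (each the sum of 12 items scored
0–4, so a 0–48 composite; a 0–36 scale variant is available via
`CohortConfig.trait_max_score`), demographic covariates (age at death,
sex, education, race, ROS/MAP study indicator), technical covariates of
the expression experiment (postmortem interval, RNA batch, RIN), a
genes × subjects expression matrix with a gene → module map, SNP dosages,
amyloid-β and AT8-tau quantified in the eight regions
{MF, EC, SF, CG, CALC, HIP, IT, AG}, longitudinal cognition and a binary
AD status. Module membership is an *input*: clustering, alignment,
quantification, quantile normalization and batch correction are upstream
of this package and out of scope.

## Preprocessing

- **Gene QC filter.** A gene is kept iff at least `min_subjects`
  (default 100) subjects have at least `min_reads` (default 4) reads.
  The underlying prose rule ("genes with less than 4 reads in 100
  individuals are removed") is ambiguous; this prevalence-style reading is
  the standard one and both thresholds are exposed as flags.
- **Module summary.** The per-subject module score is the mean across
  member genes of each gene's z-score (standardized across subjects,
  ddof = 1). The mean-of-z summary was chosen over the first principal
  component (eigengene) as the simplest statistic consistent with "the
  expression level of the module"; the method is recorded in
  `ModuleExpression.attrs["method"]`. Zero-variance genes and modules
  left without retained genes are dropped with a logged warning.
- **Pathology transform.** Regional burdens are square-root transformed;
  the global burden is √(mean of the 8 raw regional values) — transform
  applied last, following the stated convention's sentence order — with a
  `mean_of_sqrt` switch for the other reading. Negative raw values are an
  error.
- **Decline slopes.** Per-subject OLS slope of the cognition score on
  visit year; subjects with < 2 visits get a missing slope and drop out of
  downstream models by complete-case handling. A mixed-model BLUP would
  pool information across subjects but is deliberately out of scope.

## Association engine

All in-scope outcomes are continuous, so "generalized linear regression"
is implemented as OLS with t-tests (the only logistic model in the
package is the mediation outcome model for binary AD). Fits are
complete-case per model with `n_used` recorded, categorical covariates
one-hot encoded against a reference level, sex coded female = 1.
Covariate columns that are constant in the analysis sample are dropped
with a warning (they are indistinguishable from the intercept — this
matters for near-constant indicators like race in small subsamples);
genuine collinearity among the remaining columns raises an error naming
the offending columns. A constant predictor or outcome yields a
degenerate-flagged result with p = NA rather than an exception, so scans
over monomorphic SNPs report rather than silently drop them. Perfect fits
floor the p-value at the smallest positive double instead of 0.

Scans over many outcomes (modules, genes) use a single QR-based
residualization of outcomes and predictor on [1, covariates]
(Frisch–Waugh–Lovell), giving the exact OLS beta/SE/p with residual
df = n − k − 2; the test suite checks agreement with the per-model
statsmodels fit to 1e-10. BH-FDR is applied across exactly the gene
family scanned in one call — never the whole transcriptome implicitly.
Whether a published gene-level FDR was taken jointly across a multi-module
family or per module is generally unstated; joint is the default here and
per-module families can be had by calling the scan per module.

## Permutation omnibus and QQ envelopes

The omnibus statistic is the **count of modules with nominal P < 0.05**,
chosen because an excess of suggestive associations is exactly what the
count captures; Σ −log₁₀ p ("sumlog") is available as a sensitivity
statistic. The null is built by permuting the trait across complete-case
subjects (simple label permutation — covariates and expression stay
attached to subjects) and rerunning the full scan B times; the observed
data are never included in the null matrix (including them as a B+1-th
row would change p by at most 1/(B+1)). The empirical p uses the add-one
estimator with ties counted against the observed data (≥, conservative),
so p ∈ (1/(B+1), 1] and can never be zero. Because the count statistic is
integer-valued, permutation ties make the empirical p conservative: the
measured type-I error of the default test sits at or somewhat below the
nominal level.

Envelopes are **pointwise**: at rank r the level-ℓ band spans the
empirical (1−ℓ)/2 and (1+ℓ)/2 quantiles of the r-th order statistic of
−log₁₀ p across permutations, around the expected −log₁₀(r/(M+1)).
Pointwise bands match the usual visual reading of a QQ plot's "extreme
ranges"; they are not simultaneous coverage bands. Under exchangeability
the r-th order statistic of M uniform p-values is Beta(r, M−r+1), and the
suite checks the empirical rank medians against that closed form.

## Mediation

Quasi-Bayesian Monte Carlo in the style of the standard mediation
methodology: fit the mediator model M ~ T + X, the outcome model
Y ~ T + M + X and the total-effect model Y ~ T + X; draw `n_sims`
(default 1000) coefficient vectors from each fit's asymptotic normal;
form ACME = a·b, ADE = c′ and the total effect per draw; report draw
means, 2.5/97.5 percentile intervals, and two-sided MC tail probabilities
with add-one correction. No treatment–mediator interaction is included by
default (a single ACME/ADE pair is reported). The total effect comes from
its own regression rather than from ACME + ADE, so the linear
no-interaction identity ACME + ADE = total is a checkable property, not a
tautology; the suite verifies it within MC error and verifies 93–97%
empirical coverage of the nominal 95% ACME interval at n = 500.

A chain specification (e.g. trait → module → tau → slope → AD) is fitted
as one mediation per consecutive triple. A binary terminal outcome uses a
logistic outcome model; its ACME/ADE are on the latent log-odds scale,
which preserves sign and significance but is not a risk-difference
quantity. The direction test fits both orderings (T→M→Y vs M→T→Y) and
reports which has the stronger mediated signal; it is labelled a
heuristic consistency check, not a causal identification strategy. Which
covariates enter the mediation models is configurable; the demographic
("base") set is the default. A deterministic treatment–mediator link
makes the outcome design collinear; that case is returned as a
degenerate-flagged result so direction comparisons can report it.

The instrument screen applies a fixed decision rule at level α: a SNP
that predicts the trait and whose module association *vanishes* after
adjusting for the trait is an `instrument_candidate`; if the adjusted
association persists the SNP is `pleiotropic` (it reaches the module
around the trait) and unusable for Mendelian randomization; otherwise
`uninformative`. Full MR estimators are deliberately absent.

## Enrichment

One-sided hypergeometric upper-tail test per gene set with BH across the
sets tested in one call, against a user-supplied GMT. The background
universe defaults to the genes surviving the expression filter (not the
whole genome); query genes and set members outside the universe are
dropped with a warning. Database retrieval is out of scope.

## Synthetic cohort generator

The generator is first-class, tested code, not a fixture. Defaults mirror
the published demographics of the emulated 466-subject sample: 62%
female, age at death 88 (6.8), education 16.7 (3.5), 99% white, NEO-FFI
means/SDs per trait (e.g. neuroticism 17 (6.5)), PMI 7 (3.5) h, 8 RNA
batches, RIN 7 (1), 69 SNPs at configurable MAF (0.3 by default),
13,484 genes in 47 modules when run at full scale. PMI, batch count, RIN
and the mean of 8 annual cognitive visits are not published for this
design and were fixed once at values typical of such cohorts.

- **Expression** is a latent-factor model: one unit-variance-noise factor
  per module; member genes load on it with loadings ~ U(0.4, 0.9) plus
  N(0,1) gene noise. This reproduces the one property used downstream —
  within-module correlation exceeding between-module correlation — and
  nothing else about real RNA-seq. Planted trait effects act per SD of
  the realized trait on the factor; planted SNP effects act per effect
  allele. An optional counts layer (negative-binomial via gamma–Poisson
  on the latent level, baseline depth ~ lognormal around 50 reads) feeds
  the QC filter; all statistics consume the latent (normalized-scale)
  matrix.
- **Traits** are rounded, clipped Gaussians on the configured scale;
  SNP→trait effects are added to the raw score before rounding/clipping.
- **Pathology** builds a latent sqrt-scale burden per mark
  (tau mean 2.0, amyloid mean 1.5, matching the published sqrt-scale
  summary statistics) plus planted module/SNP effects, clipped at zero;
  each region observes (latent + N(0, 0.3))² clipped at zero, so with
  zero regional noise the sqrt of the cross-region mean recovers the
  latent burden exactly — which is what makes the noiseless
  identifiability tests exact.
- **Decline and AD.** The cognitive slope is tau_to_slope per SD of the
  latent tau plus N(0,1); cognition scores are baseline + slope·year +
  N(0, 0.25) over ≥ 2 annual visits; AD is Bernoulli from a logistic
  model on the standardized latent slope around a 40% base rate. The
  slope layer works in standardized units (planted effects are per-SD);
  no attempt is made to mimic the absolute units of published decline
  slopes.
- **Determinism.** One `numpy` Generator is seeded per run and threaded
  through the layers in a fixed order; identical (config, effects, seed)
  reproduce every table byte-identically.

What passing tests on this generator do *not* show: robustness to LD
between SNPs, read-level noise, non-Gaussian expression, informative
missingness, or violations of sequential ignorability in the mediation
models — none of which the generator emulates.

## Problem sizes and numerical choices

Replicate-heavy checks keep the design-defining sizes (n = 466 subjects,
M = 47 modules, B = 199 or 2000 permutations, n = 500 for mediation, the
stated replicate counts) but use a few genes per module and the latent
expression layer only, since module-level statistics depend on per-module
gene count only through a mild attenuation of the summary. The analysis
drivers simulate 50 genes per module (2,350 genes) with B = 999. Planted
effects of 0.25–0.4 SD at n ≥ 400 are the regime the power checks target.
Binomial sampling tolerances (3 SE of a replicate fraction) are applied
when asserting on expected rates such as the ~2.35 modules significant by
chance among 47, because the raw expectation would be violated by an
honest run about half the time. Empirical quantiles use numpy's default
linear interpolation; module ids sort numerically (m2 before m10); BH
ties are handled by the step-up definition; p-values are floored at the
smallest positive double, never zero.

## Known limitations

Cross-sectional mediation cannot establish causal order; the direction
test is a consistency heuristic. The omnibus test's count statistic is
conservative through discreteness. OLS on the 0–48 trait scale treats the
score as interval-valued. The logistic-terminal mediation reports
latent-scale effects only. Monomorphic SNPs are reported as degenerate
rather than tested.
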