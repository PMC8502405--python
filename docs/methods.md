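# Methods

## The model and the six tests

`iehc` tests a SNP set against a right-censored outcome under a Cox
proportional-hazards model whose per-SNP log-hazard effects decompose as
αⱼ = βⱼθ + bⱼ: a component explained by known eQTL effect sizes βⱼ
through the weighted burden score s = Gβ, and residual variant-specific
effects bⱼ ~ N(0, τ).  The joint null is θ = 0 and τ = 0.

Two statistics carry the two components:

* **Burden (U_θ).**  The 1-df Wald chi-square of the s coefficient in the
  Cox model with design [s, X], fitted by Newton–Raphson with
  step-halving (convergence: relative log-partial-likelihood change
  < 1e-9 or gradient max-norm < 1e-6, at most 50 iterations).

* **Kernel machine (U_τ).**  The score statistic Q = rᵀGGᵀr for the
  variance component with the linear kernel GGᵀ, where r are martingale
  residuals of a null fit.  Two variants exist: the *plain* KM test
  (null = covariates only; this is the standalone comparison test) and
  the *decorrelated* variant whose null includes the fitted burden score
  — that operationalises "score for τ without constraining θ" and makes
  U_θ and U_τ asymptotically independent.  The null law of Q is
  Σₗ λₗχ²₁ with λₗ the nonzero eigenvalues of Ṽ^{1/2}GGᵀṼ^{1/2}, where V
  is the n×n observed information of the partial likelihood in the
  linear predictor (with the tie correction of the chosen method) and Ṽ
  projects out the null design: Ṽ = V − VX̃(X̃ᵀVX̃)⁻¹X̃ᵀV.  The spectrum is
  computed on the equivalent S×S cross-product GᵀṼG.

The residuals are computed as the exact gradient of the log partial
likelihood in the linear predictor, so they sum to zero identically and
Gᵀr is the exact block score; with Efron ties this is the Efron-consistent
martingale residual, and without tied event times it coincides with the
Breslow form dᵢ − Λ̂₀(tᵢ)exp(η̂ᵢ).

Combinations of the two (independent) components:

* **Fisher**: T = −2(log p_θ + log p_τ) against a 4-df chi-square.
* **adapt**: binary-subset adaptively weighted Fisher.  Candidates are
  Z_θ, Z_τ and Z_θ + Z_τ; the observed statistic is min(p_θ, p_τ,
  p_Fisher) and its null distribution under independent uniforms is
  computed exactly by 1-D integration (the region reduces to
  {p₁ > m, p₂ > m, p₁p₂ > e^{−q₄(m)/2}}).
* **optim**: T_ρ = ρU_θ + (1−ρ)U_τ over the grid
  {0, 0.1², 0.2², 0.3², 0.5², 0.5, 1} (denser near 0, where the variance
  component dominates).  Each T_ρ has mixture null {ρ} ∪ {(1−ρ)λₗ}; the
  observed statistic is the minimum grid p-value and the final p follows
  by exact conditioning on U_θ ~ χ²₁:
  p = 1 − ∫₀^{q₁} F_τ(min_{ρ<1}(q_ρ − ρu)/(1−ρ)) f(u) du.  The
  substitution u = w² turns the χ²₁ weight into a half-normal, removing
  the endpoint singularity; 64-node Gauss–Legendre integrates the smooth
  result.  Argmin ties resolve to the smallest ρ for reproducibility.
* **ACAT**: equal-weight Cauchy combination of the five p-values (burden,
  plain KM, Fisher, adapt, optim); valid under dependence, with the
  w/(pπ) asymptote below 1e-16.

## Mixture tail probabilities

`davies_pvalue` evaluates P(Σλₗχ²₁ ≥ q) by characteristic-function
inversion.  Three routes, in order:

1. a vectorised midpoint rule on a phase-controlled grid (step chosen so
   the integrand's phase advances < 0.5 rad per step; truncation point
   from the analytic envelope u^{−1−L/2}/√∏λ; grid doubled until two
   refinements agree to 1e-7) — used when the mixture has ≥ 8 components
   and the tail is not extreme;
2. an adaptive rule splitting the integral at the point where the
   arctan phase flattens, with Fourier-weighted (QAWF) tails — exact for
   small mixtures where the envelope decays slowly;
3. the Liu moment-matching approximation, and finally a seeded
   Monte-Carlo estimate, if the integrators misbehave (`tail_method`
   records which route produced the value).

Rank-1 kernels and equal-eigenvalue mixtures use exact scaled chi-square
tails.  Eigenvalues below 1e-10·λ_max are discarded (LD-induced rank
deficiency is the norm).  Mixture quantiles invert these routines by
bracketed root finding started at the Liu quantile; below p = 1e-8 the
Liu quantile itself is used, which is ample for the min-p conditioning
integral at those levels.

## Pipeline and QC

Per gene: SNPs are filtered by MAF (default ≥ 0.01), missingness
(≤ 0.05) and a 1-df Pearson Hardy–Weinberg test (p ≥ 1e-4); survivors are
mean-imputed.  Weights and genotypes are intersected by SNP id;
strand-ambiguous (A/T, C/G) and allele-mismatched SNPs are dropped, and
swapped effect/other labels are harmonised by negating β (equivalent to
recoding dosage as 2 − g up to a subject-constant shift of the burden
score, which the partial likelihood ignores).  Monomorphic genotype
columns are dropped with a log entry rather than failing the gene.
Clinical covariates are standardised by default (off switch available).
A constant burden score (e.g. all-zero weights) flags the burden and
joint tests with p = 1 while the plain KM test still runs.  Study runs
never abort on a bad gene: skipped genes keep NA p-values and a reason.
BH q-values are computed per test column across testable genes.

## Synthetic data generator

The generator emulates a two-cohort eQTL-weighted design: an expression
cohort of n₁ = 165 in which marginal per-SNP eQTL effects are estimated,
and a disjoint survival cohort of n₂ = 300.  Per replicate: S ~
Uniform{20..50} SNPs (mean 35) with MAFs uniform on [0.05, 0.5] and AR(1)
latent-Gaussian LD (default ld_rho = 0.5) — two latent haplotype vectors
thresholded at the allele frequency give hard-call dosages with a single
LD knob.  eQTL effects βⱼ are standard normal with an exact
floor(prop_zero·S) subset zeroed (default prop_zero = 0.3), rescaled so
the realised Var(G₁β) equals pve/(1−pve) times the realised residual
variance — the PVE target (default 0.30) is enforced per replicate, so
small-S replicates still hit it.  Survival effects are α = βθ + b with
b ~ N(0, τ); times follow a Weibull model by inverse transform with shape
1 and scale 0.01 and η = G₂α + 0.5X₁ + 0.5X₂ (X₁ Bernoulli(0.5), X₂
standard normal).  Censoring is random and exact: floor(0.5·n) subjects
are censored at a uniform fraction of their true event time, which fixes
the marginal censored fraction at exactly 50% and keeps censoring
independent of covariates.  By default the weights fed to the tests are
the *estimated* marginal eQTL slopes from the expression cohort (one SNP
at a time), mirroring how external summary statistics are used in
practice; `use_true_beta` switches to the generating β.

What the generator does **not** emulate: real haplotype structure (LD is
stationary AR(1), not block-like), population stratification, allele
frequency spectra, informative censoring, or measurement error in the
weights beyond finite-sample eQTL noise.  Passing calibration and power
checks on these data therefore demonstrates correctness of the
statistical machinery under the stated design, not robustness to
confounding in real cohorts.

All stochastic operations are pure functions of (config, rng): fixed
seeds give bitwise-identical replicates; the random stream is aligned
across (θ, τ) cells so power sweeps share common random numbers.

## Concordance and enrichment

Per SNP, a marginal Cox log-hazard effect is fitted with design [gⱼ, X];
per gene, these are regressed (OLS with intercept, minimum 3 shared SNPs
so the slope t-test has a residual degree of freedom) on the eQTL effect
sizes, with BH FDR across genes.  The enrichment step compares joint-test
detection rates (p < 0.05) between FDR-significant and non-significant
genes with a 1-df Pearson chi-square *with* continuity correction — the
correction is the reproduction-critical choice for the published 2×2
arithmetic — and reports the detection-rate ratio.

## Numerical and design choices

* Tie handling defaults to Efron (the de-facto standard), Breslow
  selectable; without tied event times the two coincide exactly and a
  fully vectorised code path is used.
* The information operator V uses a closed-form O(n²) construction when
  no event times are tied (diag(e·H) − eeᵀ ∘ min(Aᵢ, Aⱼ) with A the
  cumulative 1/S² process) and an explicit per-tie-group accumulation
  otherwise.
* Q is reported unnormalised (rᵀKr); only the (Q, λ) pair matters for
  the p-value, so no ½ factor is applied anywhere.
* p-values of exactly 0 are clamped at 1e-300 with a warning before
  logarithms.
* Genes are processed in input order; all outputs are deterministic.

## Problem sizes used in the shipped checks

The test suite validates type-I error on 2,000 null replicates (3-SE
binomial band at α = 0.05), statistic independence on 5,000 null
replicates (|corr| ≤ 3/√reps), and power orderings on 500 replicates per
(θ, τ) corner; the acceptance script measures the PVE and censoring
targets on 200 replicates each.  These sizes give Monte-Carlo standard
errors comfortably below the tolerances they are checked against.

## Known limitations

Only the linear kernel is implemented (no IBS/polynomial/interaction
kernels) and no small-sample moment adjustment is applied to the score
test.  The Cox engine does not support stratification, time-varying
covariates, left truncation or frailty terms.  Population structure must
be supplied as covariates (e.g. principal components).  The adaptive and
optimal combination constructions preserve the stated statistics
T = ρ_θZ_θ + ρ_τZ_τ and T_ρ = ρU_θ + (1−ρ)U_τ and are calibrated exactly
against their own nulls (verified by Monte-Carlo oracles and uniformity
checks), but other software may implement different weighting schemes
for the same statistics.
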