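# Methods

`medchain` implements a four-stage inference chain linking an ordinal
early-life socioeconomic exposure to an adult inflammatory outcome
(C-reactive protein, CRP) through leukocyte gene regulation, together with
a synthetic-data generator that provides ground truth for every stage.
This note documents the models, the defaults and why they were chosen, the
numerical conventions, and the limits of what the synthetic experiments
demonstrate.

## The exposure and outcome model

The exposure is parental occupational position coded as an ordinal dose,
0 (high) / 1 (intermediate) / 2 (low), modelled linearly throughout
(a dose–response hypothesis). All "low vs high" quantities are therefore
2-unit contrasts. CRP is treated as lognormal; effects on log-CRP
coefficients β are reported as percent changes in the geometric mean,
100·(exp(2β) − 1). Age, sex and centre of blood collection enter every
stage as confounders.

## Two-sample Mendelian randomization (`medchain.mr`)

Per gene, SNP–transcript (exposure) and SNP–CRP (outcome) summary
statistics are combined to estimate the causal effect θ of transcription
on CRP.

**Instrument selection.** SNPs require an exposure association at
p < 1.9 × 10⁻⁵ and are discarded if strongly associated with the outcome
(p < 1.9 × 10⁻⁵, a reverse-causation guard). Linkage pruning is greedy:
SNPs are scanned by ascending exposure p-value and retained only if
r² ≤ 0.25 with every already-retained SNP. Genes with fewer than 10
surviving instruments are skipped, not errored. Instrument strength is
summarized by the mean F-statistic, F = (β̂/σ̂)² per SNP.

**Estimators.**

* *Random-effects IVW*: the Wald ratios r_j = β̂_Yj/β̂_Xj with first-order
  variances v_j = σ²_Yj/β̂²_Xj are inverse-variance averaged. Cochran's Q
  gives a multiplicative overdispersion φ = max(1, Q/(J−1)) that inflates
  the fixed-effect SE (the floor at 1 follows the multiplicative
  random-effects convention).
* *Egger regression*: weighted regression of β̂_Y on β̂_X with intercept,
  weights 1/σ²_Y, after orienting all instruments to positive β̂_X (the
  standard Egger convention; the intercept is meaningless without a fixed
  orientation). Slope = causal effect, intercept = average pleiotropy;
  φ = max(1, RSS/(J−2)) scales both SEs.
* *Penalized weighted median*: the weighted median of the Wald ratios
  under inverse-variance weights down-weighted by a one-df chi-square
  penalty, w_j′ = w_j · min(1, 20 · P(χ²₁ > Q_j)), where Q_j is SNP j's
  heterogeneity contribution about an initial unpenalized weighted median.
  The penalty constant 20 is exposed in the API; the weighted median uses
  cumulative-weight interpolation at 50%, with exactly tied ratios
  collapsed so that splitting an instrument into half-weight duplicates is
  a no-op. The SE comes from a seeded parametric bootstrap of the summary
  statistics (1000 draws by default) because no closed form exists.

**Multiplicity and calling.** Storey q-values are computed per method
across genes, with π₀ estimated by a cubic-polynomial smoother on the
λ-grid 0.05–0.95; for fewer than 100 genes the smoother is unstable and
π₀ = 1 is used, which reduces the q-values to Benjamini–Hochberg. A gene
is called causal only when q ≤ 0.05 in *all three* estimators, whose
pleiotropy assumptions are mutually orthogonal; the called set is unioned
with the fixed 53-gene CTRA indicator list.

## Censored-lognormal multiple imputation (`medchain.censored`)

CRP assays have centre-specific detection limits (1, 2 or 3 mg/L in the
emulated design), leaving ~60% of values known only as "below L". The
observed-data log likelihood combines Gaussian log-densities of log y for
observed records with Φ((log L − xβ)/σ) terms for censored ones; the MLE
is found by BFGS (Nelder–Mead polish if needed) over (β, log σ), with the
asymptotic covariance from the inverse numerical Hessian. The imputation
model contains exposure, BMI, age, sex and centre.

Imputation is *proper*: each of m = 30 completed datasets draws
(β*, log σ*) from the asymptotic normal of the MLE before drawing each
censored record from the conditional lognormal truncated above at its
limit, via inverse-CDF sampling (deterministic given the uniform stream).
σ is drawn on the log scale to preserve positivity. Downstream estimates
are pooled by Rubin's rules: θ̄ = mean, T = W̄ + (1 + 1/m)B. Records
observed below their nominal limit are kept as observed with a warning.

## Mediation by transcription blocks (`medchain.mediation`)

Gene blocks are summarized by PCA on centred, unit-scaled transcripts;
the number of retained components k minimizes |cumvar(k) − 0.50|, ties to
smaller k (a closest-to-target rule: achieved fractions may land just
above or below 50%).

Natural direct and indirect effects use an imputation-based natural effect
model, chosen over weighting because it is deterministic given the data
and stable with many mediators:

1. fit the outcome working model E[log Y | X, PCs, C] (no
   exposure–mediator interactions; the effects are then single
   coefficients per path, and an interaction flag is deliberately not a
   default);
2. expand each record over hypothetical exposure levels x′ ∈ {0, 1, 2},
   imputing the counterfactual outcome with x′ in the direct slot and the
   record's own mediator values (indexed by its observed exposure x) in
   the mediated slot;
3. regress the imputed outcome on (x′, x, C): the x′ coefficient is the
   natural direct effect β_DE, the x coefficient the joint natural
   indirect effect β_IE.

With a linear working model this reproduces the product-of-coefficients
decomposition exactly, and the fitted total effect equals the direct
regression of log Y on (X, C) to numerical precision. The proportion
mediated is PM = ln(1 + IE%/100)/ln(1 + TE%/100) = β_IE/(β_DE + β_IE).

Point estimates under censoring are Rubin-pooled over the m imputations;
confidence intervals are 2.5/97.5 percentiles of a bootstrap over
individuals (5,000 draws in principle; the orchestrated pipeline defaults
to a smaller B for turnaround and exposes it in the config) in which each
replicate re-projects the PCA scores and draws one fresh stochastic
imputation — full nesting of the 30 imputations inside every replicate is
possible but 30× costlier and changes little here.

A binary-outcome mode (indicator CRP ≥ 3 mg/L, logistic working model,
effects on the odds-ratio scale) exists because that indicator is immune
to left censoring at limits ≤ 3 mg/L. Sequential mediation fits the
natural effect model with cumulative, disjoint mediator blocks and reports
incremental indirect effects; the joint (all-block) effect is invariant to
block order. Per-gene screening is an ordinary linear model of each
transcript on exposure and confounders at unadjusted p ≤ 0.05.

## Bayesian-network causal ordering (`medchain.bn`)

For each CpG within 1,500 bp of a selected gene (5,000 bp in a
sensitivity mode; cross-reactive probes and probes with SNPs of
MAF > 0.01 removed; the distance cut is strict, < window), the triplet
(X, M, T) = (exposure dose, methylation residual, transcription residual)
is scored under eleven DAGs — the options {X→M} × {X→T} × {none, M→T,
T→M} minus the collider {X→T, M→T without X→M}, the unique exclusion
consistent with eleven models in five groups of sizes (3, 2, 2, 2, 2).
Residuals are OLS residuals on age, sex, centre (optionally cell-type
proportions); M and T are then standardized to unit variance so that the
prior scale convention below is data-independent. X enters as its numeric
dose, a pragmatic Gaussian treatment of an ordinal variable.

Scores use the BGe metric: the log marginal likelihood under a
normal-Wishart prior, computed per node family as a difference of subset
marginal likelihoods (cached per triplet). Hyperparameters: prior mean =
sample mean (the mean-correction term vanishes), α_μ = 1, α_w = d + 2,
prior scale T = t·I with t = α_μ(α_w − d − 1)/(α_μ + 1), giving unit
prior marginal variances on standardized data. The score is identical
across Markov-equivalent DAGs, which is what makes *group*-level
aggregation meaningful.

Model posteriors (uniform prior over models, log-sum-exp normalized) are
summed into group posteriors. A group wins a CpG only when
ln BF = ln(p₁/p₂) over the runner-up group *strictly* exceeds 1 — the top
group must be roughly three times more probable than any rival; otherwise
the CpG is "none". CpGs whose gene lacks transcription data are reported
as "unscored". A sensitivity mode adds three negative-control DAGs with
edges into X ({M→X}, {T→X}, {M→X, T→X}).

An inherent identifiability limit: the fully connected group-B and
group-D structures are Markov equivalent, so data generated from the
complete B structure split their posterior with D and land on "none" —
consistent with group B being (almost) never selected in practice. A 2×2
chi-square without continuity correction compares island-context and
TSS/UTR annotation of group C∪D CpGs against group A.

## The synthetic-data generator (`medchain.synth`)

The generator's defaults are the emulated study conditions; they are not
tuning knobs.

* **Exposure**: 3-level ordinal with prevalences 17.8/55.9/26.3%
  (high/intermediate/low).
* **Total effect**: +22.6% geometric-mean CRP for low vs high; proportion
  mediated 0.69 through a 10-gene transcription block whose per-gene
  effects are sized analytically so the truth record satisfies the PM
  identity to machine precision.
* **Mediator block**: genes share a latent factor (pairwise correlation
  0.5) on top of the exposure effect, making the block a co-regulated
  program whose top principal component carries the block-level path —
  the regime in which PCA summarization of mediators is sensible. With
  uncorrelated mediator genes, variance-ranked PCs are blind to a small
  exposure signal and the indirect effect through a 50%-variance summary
  is attenuated by construction.
* **CRP**: lognormal with mean log-CRP 0.28 and total log-scale SD ≈ 1.18,
  calibrated (by the normal quantile function, before any test was run)
  so that equal-thirds centres with detection limits 1/2/3 mg/L censor
  60% of individuals; BMI, age, sex and centre effects are wired into the
  mean so the imputation model is correctly specified.
* **CpG triplets**: each CpG links to its own gene and is generated from
  its causal group (A: M→T only; B: X→M, X→T, M→T; C: X→T; D: X→T→M;
  E: X→M) with standardized path coefficients 0.3 and unit noise.
* **GWAS summary statistics**: J = 39 instruments per gene with
  SE-consistent sampling noise (SEs 1/√n at eQTL-consortium and
  CRP-consortium sample sizes), true SNP effects sized for a mean
  F-statistic of 97, exchangeable LD blocks (block size 5, r = 0.3), and
  four pleiotropy regimes — none, balanced (zero-mean), directional
  (shifted mean), and InSIDE-violating (pleiotropy correlated 0.7 with
  instrument strength, which is what breaks IVW/Egger but not the
  median). Wald p-values are exact functions of β̂/SE.

All randomness flows from one master seed through named CRC-32-keyed
substreams, so any artifact regenerates bit-identically regardless of
generation order.

**What the synthetic experiments do not show.** The generator is
linear-Gaussian on the log scale: it contains no exposure–mediator
interactions, no unmeasured mediator–outcome confounding, no measurement
error in transcription beyond additive noise, no realistic LD or allele
frequencies, and independent CpGs. Passing recovery tests therefore
demonstrates correctness of the estimators under their stated assumptions,
not robustness of the scientific conclusions to violations of those
assumptions in real cohorts.

## Numerical and testing conventions

* IVW and Egger are verified against a generic WLS solver to 1e-10; the
  BGe scorer against an independently coded textbook formula to 1e-6 and
  against Markov-equivalence to 1e-8.
* Bootstrap coverage of the total-effect CI is checked at B = 500 over
  300 cohort replicates of n = 500 (a scaled-down budget; the method
  default is B = 5000).
* PM recovery is asserted on effects pooled across 100 replicates of
  n = 5000 before taking the ratio: with the emulated effect size the
  total effect is only ~4 SEs from zero at that n, so per-replicate PM
  ratios are heavy-tailed and their mean is not a faithful measure of
  estimator accuracy.
* BN group recovery uses 200 CpGs per group at n = 1500 and requires
  ≥ 80% agreement among decided CpGs; decision rates near the threshold
  are checked to be monotone in the ln BF cutoff.
* Degenerate inputs fail loudly: zero-variance variables, all-censored
  outcomes, rank-deficient designs, non-positive limits and overlapping
  mediator blocks raise ValueError; under-instrumented genes raise a
  dedicated NotEnoughInstruments and are skipped by the pipeline.

## Known limitations

* The natural effect model omits exposure–mediator interactions by
  design; with strong interactions the reported single-coefficient paths
  would be misspecified.
* The penalized-weighted-median penalty constant (20) and the parametric
  bootstrap SE are conventions, not derived quantities.
* The BGe treatment of a 3-level ordinal exposure as Gaussian is an
  approximation; with heavily skewed exposure distributions the scores of
  X-families are distorted.
* Group B of the DAG partition is structurally confounded with group D
  whenever the generating structure is fully connected (Markov
  equivalence), an identifiability limit of the grouping itself.
* The pipeline operates on synthetic data end to end; readers applying it
  to real cohort data must supply their own files in the documented TSV
  dialects and should revisit the imputation model's covariate set.
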