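# Methods

This note documents the statistical models the package implements, the
conventions and numerical choices behind them, and what the synthetic
generators do and do not emulate.

## Setting and notation

A randomized vaccine trial records, per subject *j*: a binary treatment
indicator `Z_j` (vaccinated vs control), a continuous immunological
surrogate `S_j` (e.g. a log antibody titre), and a binary clinical
endpoint `T_j` (disease).  Vaccine efficacy is
`VE = 1 − P(T=1|Z=1)/P(T=1|Z=0)`.  The package targets the high-VE
regime, where vaccinated-arm events are rare and both classical CoP
frameworks — the Prentice criteria and the meta-analytic approach on
randomized subgroups — misbehave.

## Regression engines (`copkit.glm`)

### Ordinary logistic MLE and separation

Newton/IRLS on the Bernoulli log-likelihood, covariance the inverse
observed (= expected) information at the final iterate.  Under
separation — e.g. an arm with zero events — no finite MLE exists; the
iteration is stopped and the fit flagged `diverged` when any of:

* a coefficient magnitude passes 15 (≈30 on the log-odds-ratio scale
  under ±1 treatment coding),
* the iteration cap (25) is reached with step norms no longer shrinking,
* the score converges but some estimated coefficient variance exceeds
  10³ — a numerically flat likelihood direction.  A quasi-separated fit
  can satisfy a score tolerance at a finite iterate (a treatment-only
  fit to a zero-event 10-per-arm table stops near −9.5 on the ±1 scale
  with variance ≈ 4·10⁷), which the first two rules would miss; extreme
  fitted logits alone, on the other hand, are *not* evidence of
  separation in rare-events models, so they are deliberately not used.

The last iterate is returned with its (huge) covariance rather than
erased, because downstream meta-analysis must be able to reproduce the
behaviour of standard software on separated subgroups.

### Firth (Jeffreys-prior) penalty

Maximizes `l(β) + ½ log det I(β)`; the penalized score shifts each
observation's residual by `h_j(½ − p_j)` with `h_j` the weighted-hat
diagonal.  Newton steps are halved until the penalized objective does
not decrease, so the objective trace is monotone.  For a single binary
covariate the optimum is exactly the add-½-to-each-cell log odds ratio,
which the test suite uses as a closed-form oracle over every 10-per-arm
event pattern.  The reported covariance is the inverse *unpenalized*
Fisher information `(XᵀWX)⁻¹` evaluated at the Firth estimate — for the
zero-event table this gives `1/(20·p(1−p))` with `p = 0.5/11`, i.e.
variance 1.15 on the treatment coefficient.

### Weakly informative Cauchy prior (WIP)

Independent Cauchy priors: scale 10 on the intercept, scale 2.5 on each
slope after rescaling by the predictor's observed spread — divided by
the range for a binary input (so a ±1-coded treatment has effective
slope scale 1.25), by twice the standard deviation otherwise.  The fit
is the classical approximate-EM for t priors: augmented ridge-IRLS at
fixed per-coefficient prior variances `σ_k²`, alternated with the EM
update

    σ_k² ← (β_k² + Var(β_k) + s_k²) / 2 ,

where `Var(β_k)` is the current diagonal of the inverse augmented
information.  Including the posterior-variance term means the fixed
point is *not* the exact Cauchy posterior mode — it is the estimate that
the standard weakly-informative-prior GLM software computes, which is
the relevant convention here (the exact MAP with raw scale 2.5 on a ±1
slope gives −0.91 for the one-control-event zero-vaccinated-event table,
versus −0.59 under this convention).  The covariance is the inverse
augmented information at the fixed point.  Estimates are always finite;
shrinkage toward zero relative to the MLE holds on every non-separated
2×2 and is asserted as a property test.  Exact coding equivariance is
broken (by ~2%) by the fixed intercept prior; the likelihood fits
(MLE, Firth) halve exactly under 0/1 → ±1 recoding.

### Treatment coding

2×2 tables and stage-one subgroup fits default to ±1 coding (the
convention under which the penalized 2×2 estimates take their familiar
half-log-odds-ratio form); criterion models default to 0/1, where
coefficients read as arm contrasts.  Both are available everywhere, and
trial-level R² is coding-invariant (tested to 1e−10).

## Scaled-logit protection curve (`copkit.scaled_logit`)

`P(T=1|S) = π · expit(μ + γS [+ β_S Z])`, with `π` the probability of
pathogen exposure.  The likelihood is maximized by L-BFGS-B with an
analytic gradient on the unconstrained parameterization
`η = logit(π)`.  Because the likelihood can be multimodal as `π → 1`,
fitting uses five starting values `π₀ ∈ {0.05, 0.2, 0.5, 0.8, 0.99}`
with `(μ, γ)` warm-started from a Firth logistic fit, keeping the best
objective.  Standard errors come from a nonparametric case-resampling
bootstrap, stratified by arm when a treatment column exists; replicate
fits warm-start at the full-data estimate, failures are dropped and
counted, and more than 20% failures is an error.  Defaults: B = 500 for
end-user fits, 200 inside simulation studies (Monte-Carlo error on the
resulting Wald p-values is then small relative to the 0.05 decision
threshold at the study's sample sizes).  Note that `π` is weakly
identified when events are rare: its bootstrap distribution is wide and
root-n scaling of standard errors only binds in event-rich regimes.

## Prentice criteria (`copkit.prentice`)

The four criterion models: (1) logistic `T ~ Z`; (2) Gaussian `S ~ Z`;
(3) logistic `T ~ S`; (4) logistic `T ~ Z + f(S)`.  All tests are
two-sided Wald at α = 0.05 by default.  Criterion 4 is met when the
surrogate test rejects *and* the residual treatment test does not.

Model-4 variants:

* `linear` — `f(S) = γ_Z S`;
* `quadratic` — `f(S) = γ_Z S + γ_{Z,2} S²`; the surrogate p-value is
  the joint 2-df Wald test of `(γ_Z, γ_{Z,2})`, the coherent notion of
  "surrogate significance" when S enters twice (the 1-df linear-term
  p-value is also reported for sensitivity);
* `scaled_logit` — the protection curve with a residual treatment term,
  tested with bootstrap standard errors.

A diverged model-4 fit makes the residual treatment test meaningless, so
criterion 4 is reported *not assessable* (with a diagnostic) rather than
met or not met.  In the power study, rejection rates are computed among
assessable replicates, with the failure count reported per cell.

## Two-stage meta-analytic surrogacy (`copkit.meta`)

Stage one fits, per randomized subgroup *i*, `α̂_i` (Gaussian `S ~ Z`)
and `β̂_i` (selectable endpoint fitter for `T ~ Z`).  Stage two runs the
weighted regression `β̂_i = λ₀ + λ α̂_i + ε_i` with `w_i = 1/Var(β̂_i)`
and reports

    R²_w = 1 − Σ w_i (β̂_i − fitted_i)² / Σ w_i (β̂_i − β̄_w)² ,

with `β̄_w` the weighted mean (the total-sum-of-squares convention when
a weighted regression's R² is wanted).  Subgroups with a single arm or
non-finite estimates are excluded with reasons; diverged ordinary-ML
fits are *kept* by default (`weight_policy="naive"`), because their huge
variances self-downweight them — this is what standard software does and
what the broken-logistic benchmark must reproduce.  An
`exclude_diverged` policy exists but is not the default.

**Two R² values are reported.**  Inverse-variance weighting makes the
weighted R² nearly blind to diverged estimates (weight ≈ 10⁻⁷): the
broken logistic benchmark then reduces to the few non-separated
subgroups and its weighted R² becomes wildly variable rather than
systematically small.  The qualitative pathology practitioners actually
observe — a handful of β̂_i near −10 visibly wrecking the fit — lives in
the *unweighted* R² of β̂_i on α̂_i, which is therefore exposed as
`r_squared_unweighted` and used for the penalized-vs-ordinary ordering
properties in the test suite.  The weighted R² remains the primary
trial-level surrogacy measure.

## Synthetic generators (`copkit.simulate`)

### Full-mediation trial (`gen_prentice_trial`)

`Z` assigned 1:1; `S|Z=z ~ Normal(μ_z, 0.2)`;
`T ~ Bernoulli(0.1 · expit(8.3 + log(0.05)·S))`.  Defaults: n = 5000,
`μ₀ = 3`, `μ₁ ∈ {4.5, 4, 3.75, 3.33}` sweeping VE over ≈
{0.97, 0.87, 0.76, 0.41} (verified against Gauss-Hermite integration of
the marginal rates; the control-arm attack rate is ≈ 0.0375).  Treatment
affects the endpoint only through the surrogate, so any rejection of the
residual treatment effect in model 4 is a type-I error.

### Multi-subgroup binary-endpoint trial (`gen_meta_trial`)

25 subgroups of 40 subjects, 1:1.  Per subgroup, random treatment slopes
`(a_i, b_i)` are bivariate normal with variances (10, 4) and correlation
`ρ = √0.9` (no random intercepts), so the true trial-level R² is
`ρ² = 0.9`.  Then `S = 4.609 + (5.458 + a_i)Z + N(0, 1)` and
`T ~ Bernoulli(expit(−2.2401 + (β + b_i)Z))`, `β ∈ {−1, −2, −4}`.

The generator's treatment coding defaults to ±1.  This choice is
load-bearing: the vaccinated-arm event rate `expit(μ_T + β + b_i)` is
identical under either coding, but under 0/1 coding the control arm
carries no trace of `b_i`, so once a subgroup's vaccinated arm has zero
events its penalized `β̂_i` retains *no* information about the true
effect and the penalized trial-level R² collapses to ≈ 0.1–0.2.  Under
±1 coding `b_i` moves both arms and the control event count remains
informative; the simulation then reproduces the published regime
(penalized mean R̂² ≈ 0.72–0.78 with ~20/25 separated subgroups at
β = −4, and penalized MSE several-fold below ordinary logistic at every
β).  The surrogate residual SD (1.0) is small against Var(a_i) = 10, so
R̂² attenuation is driven by endpoint-side noise; a sensitivity switch
is provided.  At β = −4 the mean number of zero-vaccinated-event
subgroups is ≈ 21.8 (published analyses of this nominal
parameterization report ~20; the VE labels attached to these settings
in the literature are not exactly derivable from the stated parameters,
and the generator follows the parameters).

### Continuous-endpoint emulation (`gen_continuous_surrogacy_trial`)

A synthetic stand-in for the classical public multi-center surrogacy
dataset, matching its stated structure only: 50 subgroups of 20, 1:1,
both endpoints Gaussian, correlated random treatment slopes with
`ρ² = 0.9`, ±1 coding.  The endpoint location and effect
(μ_T = −1.085, β = 0.959, Var(b) = 0.5, unit residual SDs) are set by a
closed-form normal-quantile calculation so that dichotomizing at
`T < −2.87` (strict inequality) gives a control event rate ≈ 0.25, a
vaccinated rate ≈ 0.0125, hence VE ≈ 0.95 on the binary scale.  It
emulates the *structure and regime*, not the joint distribution, of the
external data: tests on it demonstrate the information loss of
dichotomization and the penalization orderings, not that external
dataset's specific R² values.

### What passing tests do and do not show

The generators draw i.i.d. Gaussian surrogates within arm, use exact
1:1 allocation, and contain no covariates, missingness, assay floors or
censoring.  Operating characteristics verified on them quantify the
*statistical* phenomena (lack-of-fit type-I inflation, separation, the
penalized rescue) under clean conditions; they do not certify behaviour
under model misspecification beyond the forms simulated.

## Study runners and reproducibility (`copkit.studies`)

Every replicate draws from an explicit counter-based substream
`default_rng([seed, cell, replicate])`, so any cell is reproducible
independently of execution order.  Default replication counts are 1000
per cell for the criterion-4 power study and 300 per cell for the
surrogacy sampling study — enough that three binomial standard errors
(≈ 0.045 at 1000 reps) cleanly separate the contrasts of interest
(e.g. linear 0.34 vs quadratic 0.04 type-I error) — with flags to run
larger.  Probability cells carry their binomial standard errors.  The
CLI exits nonzero when any cell has more than 5% fit failures.

## Known limitations

* Wald tests throughout; profile-penalized-likelihood intervals and
  likelihood-ratio tests are not implemented.
* The WIP fit follows the approximate-EM convention, not the exact
  Cauchy posterior mode, and its covariance is the Gaussian curvature of
  the augmented fit.
* Stage two is a fixed-effect weighted regression; one-stage bivariate
  random-effects models are out of scope.
* `π` in the scaled-logit model is weakly identified when events are
  rare; its bootstrap intervals can be very wide, and the multi-start
  policy (not a proof of global optimality) is the guard against
  likelihood multimodality.
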