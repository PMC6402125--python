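# copkit

Statistics for assessing **correlates of protection (CoPs)** in vaccine
trials with **very high vaccine efficacy** — the regime (VE ≥ 95%) where
events in the vaccinated arm are so rare that the standard statistical
machinery for surrogate-endpoint validation breaks in two distinct ways:

1. **Prentice-criteria assessment suffers lack of fit.**  Criterion 4
   (full mediation) fits `logit P(T=1) = μ̃_T + β_S·Z + γ_Z·S`.  When the
   true risk curve is strongly non-linear in the surrogate `S` — as it is
   under a realistic protection curve — the misfit of the linear surrogate
   term is absorbed by the treatment term `β_S·Z`, inflating its type-I
   error and destroying the power to demonstrate mediation.
2. **Meta-analytic trial-level surrogacy suffers infinite estimates.**
   Splitting one trial into randomized subgroups (centers, regions) and
   regressing per-subgroup endpoint effects `β̂_i` on surrogate effects
   `α̂_i` (weights `w_i = 1/Var(β̂_i)`) requires a logistic fit of `T` on
   `Z` per subgroup; with high VE many subgroups have **zero vaccinated-arm
   events**, the maximum-likelihood `β̂_i` is infinite (separation), and the
   trial-level R² collapses.

`copkit` implements the two matching fixes as statsmodels-style model
objects, plus the machinery to quantify their operating characteristics:

* **Penalized logistic engines** (`PenalizedLogit`): ordinary Newton/IRLS
  MLE with explicit separation diagnostics, the **Firth / Jeffreys-prior**
  penalty `l(β) + ½ log det I(β)` (for a single binary covariate this is
  exactly the add-½-to-each-cell log odds ratio), and the **weakly
  informative Cauchy prior** (scale 2.5 on rescaled slopes, 10 on the
  intercept) fitted by the bayesglm-style EM.  Both penalized fits are
  always finite.
* **Flexible criterion-4 models** (`PrenticeCriteria`): linear, quadratic
  (`… + γ_Z·S + γ_{Z,2}·S²`, with a joint 2-df surrogate test), and the
  **scaled-logit (Dunning) protection curve**
  `P(T=1|S) = π · expit(μ + γ·S)` with bootstrap standard errors
  (`ScaledLogit`).
* **Two-stage meta-analytic surrogacy** (`TwoStageSurrogacy`): per-subgroup
  effect estimation with a selectable endpoint fitter, then weighted
  regression `β̂_i = λ₀ + λ·α̂_i + ε_i` and its R².
* **Synthetic generators and study runners** (`copkit.simulate`,
  `copkit.studies`) reproducing the full-mediation power study and the
  penalized-meta-analysis sampling study, with counter-based seeding.

## Worked example

Simulate one high-efficacy trial (n = 5000, 1:1, empirical VE ≈ 0.98 in
this draw) under *full mediation* — disease risk depends on treatment only
through the antibody titre `S` via the scaled-logit curve — and assess the
Prentice criteria with the classical linear model 4 and the quadratic fix:

```python
from copkit import PrenticeSimConfig, gen_prentice_trial, assess_prentice

trial = gen_prentice_trial(PrenticeSimConfig(mu1=4.5), seed=4)
print(assess_prentice(trial, "linear").summary())
print(assess_prentice(trial, "quadratic").summary())
```

```
Prentice criteria assessment (alpha=0.05, model-4 variant: linear)
  criterion 1: vaccine protects (T ~ Z): p = 3.211e-08  MET
  criterion 2: vaccine moves surrogate (S ~ Z): p = 0  MET
  criterion 3: surrogate predicts disease (T ~ S): p = 2.596e-25  MET
  criterion 4: full mediation [linear] (surrogate): p = 8.88e-12
  criterion 4: full mediation (residual treatment): p = 0.04173  NOT MET
  all criteria met: False

Prentice criteria assessment (alpha=0.05, model-4 variant: quadratic)
  criterion 1: vaccine protects (T ~ Z): p = 3.211e-08  MET
  criterion 2: vaccine moves surrogate (S ~ Z): p = 0  MET
  criterion 3: surrogate predicts disease (T ~ S): p = 2.596e-25  MET
  criterion 4: full mediation [quadratic] (surrogate): p = 2.048e-09
  criterion 4: full mediation (residual treatment): p = 0.5801  MET
  all criteria met: True
```

The surrogate here captures the *entire* treatment effect by
construction, yet the linear model falsely finds a residual treatment
effect (p = 0.042 < 0.05) — the lack-of-fit artifact — and criterion 4
fails.  The quadratic surrogate term absorbs the curvature and the
residual treatment test is correctly non-significant (p = 0.58), so all
four criteria are met.  Across 1000 replicates the linear model rejects
the residual treatment effect ~34% of the time at this efficacy while the
quadratic model stays at the nominal ~4-5%.

The meta-analytic pathology and its Firth rescue, on a simulated trial of
25 randomized subgroups where 22 of 25 vaccinated arms have zero events:

```python
from copkit import MetaSimConfig, gen_meta_trial, TwoStageSurrogacy

data = gen_meta_trial(MetaSimConfig(beta=-4.0), seed=1)
print(TwoStageSurrogacy(data, outcome_method="firth").fit().summary())
```

```
Two-stage trial-level surrogacy
  endpoint fitter: firth (coding pm1)
  subgroups used: 25 (excluded: 0, diverged stage-one fits: 0)
  beta_i = -4.2127 + 0.3227 * alpha_i
  weighted R2 (trial-level surrogacy): 0.7984
  unweighted R2 (diagnostic): 0.8003
```

With `outcome_method="logistic"` the same data give 23 diverged
stage-one fits (estimates near −10 with variances above 10⁶); the
unweighted R² diagnostic drops to 0.62, and across replicates the
ordinary-logistic R̂² has several-fold larger mean-square error than the
penalized versions.

## Command line

```bash
cop assess --input trial.csv --model4 quadratic --out assessment.json
cop meta --input subgroups.csv --method firth --out surrogacy.json
cop fit2x2 --input tables.csv --method wip --out fits.csv
cop simulate prentice --seed 4 --out sim/
cop study prentice-power --reps 1000 --seed 1 --out study/
```

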