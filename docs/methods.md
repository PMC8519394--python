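# Methods

## Model

The core estimand is the joint trajectory of three standardized, correlated
teacher-rated outcomes (concentration problems, disruptive behavior,
prosocial behavior) in a two-arm cluster-randomized school trial with five
annual waves. The model is a multivariate three-level random-slopes growth
curve: occasions (level 1) nested in children (level 2) nested in schools
(level 3),

    y_tij = B' x_tij + u_j + v_ij + w_ij t + e_tij ,

with time t = occasion − 1 so the intercept is the baseline (pre-allocation)
mean. The random part is

- school level: three outcome intercepts, u_j ~ N3(0, Ω_school);
- child level: three outcome intercepts plus three outcome-specific
  linear-time slopes, (v, w)_ij ~ N6(0, Ω_child) — the growth *rate* varies
  across children, the higher time powers do not;
- occasion level: residual triples e_tij ~ N3(0, Ω_resid), independent
  across occasions with a single time-invariant covariance. This is the
  standard multilevel growth-curve assumption and is reasonable for annual
  spacing; it is what distinguishes this formulation from a latent
  growth-curve SEM with occasion-specific residual variances.

The fixed-part design (identical across outcomes) has 20 terms in the full
model: cubic time polynomial; arm indicator and arm × each time power; child
covariates (male, FSM eligibility, baseline conduct-problems at-risk flag)
with arm interactions including the arm × male × at-risk triple; and
standardized school size and %FSM with arm interactions. The *unconditional
means model* (intercept only, intercept-only child part) is used purely to
decompose total variance across the three levels.

Assumptions worth stating: outcome loss is missing at random given arm,
covariates and observed outcomes; covariate effects are time-invariant;
residual covariance is homoscedastic over waves and arms; school effects are
exchangeable given the school covariates.

## Estimation

Estimation is a purpose-built Gibbs sampler; every full conditional is
conjugate, so there is no Metropolis step and no tuning. One scan updates, in
fixed order:

1. **missing outcome components** — for each partially observed triple, a
   draw from the multivariate-normal conditional given the observed
   components and current effects (data augmentation). Child-occasions with
   all three outcomes missing carry no information and are dropped up front.
2. **fixed effects** — one joint draw of all 3p coefficients. With a flat
   prior and shared design X, the precision is Ω_resid⁻¹ ⊗ X'X, which makes
   the draw a single Cholesky solve of a 3p × 3p system.
3. **school effects**, 4. **child effects** — independent normal draws,
   batched over groups (the per-child 6×6 precisions depend only on the
   child's occasion count and Σt, Σt², so all children are factorized in one
   vectorized call).
5. **covariances** — inverse-Wishart draws for Ω_school, Ω_child, Ω_resid
   from their conjugate conditionals.

Random numbers are consumed strictly in this order from one generator per
chain, so a seed reproduces a chain exactly; covariance draws are positive
definite by construction at every iteration.

**Priors.** Flat (improper) on fixed effects. Each covariance gets an
inverse-Wishart with degrees of freedom equal to its dimension — the weakest
proper choice — and scale matrix df × (initializer estimate), so the prior
mode sits near the data-driven start while weighing only df
pseudo-observations. A `prior_scale_factor` (×0.5, ×2) is exposed for
sensitivity checks. With few clusters (≲20 schools) this prior visibly
shrinks the school-level covariance upward; at the trial's scale (≥60
schools) its influence is negligible, which the marginal-variance
conservation test quantifies.

**Starting values.** Per-outcome OLS for the coefficients plus a
method-of-moments split of the OLS residuals: the within-child variance is
the mean per-child sample variance (unbiased), the child-level variance is
the variance of child means minus the within-noise term σ̂²_w/T̄, the school
level analogously from school means; cross-outcome covariances start at 0.
Starting values affect only convergence speed; burn-in adequacy is judged by
ESS and multi-chain agreement rather than by matching any particular
frequentist initializer.

**MCMC settings.** Default 3 chains × 2,500 iterations with 500 burn-in
(per-chain streams spawned from one seed); production-scale settings
(e.g. 3 × 100,000) are plain arguments. **DIC** uses the conditional
deviance: −2 log MVN likelihood of the observed cells given the random
effects, with missing components marginalized by dropping their dimensions;
pD = mean deviance − deviance at the posterior means of all parameters
including random effects. **ESS** is Geyer's initial-positive-sequence
estimator per chain, summed over chains; a constant chain reports ESS 0 with
a warning.

**Numerical choices.** All Cholesky factorizations add 10⁻⁸ to the diagonal;
failure after that raises a `NumericalError` with the offending block named.
Initializer variances are floored at 10⁻⁶ (prior scales at 10⁻³) so
degenerate noise-free inputs stay proper. The BF1/BF2 ratio clamps the
posterior proportion to [1/(2N), 1 − 1/(2N)] to keep BF12 finite, and the
output flags when clamping occurred.

## Posterior analysis

**Variance partition.** Per outcome, the within / between-children /
between-schools shares are the level variances divided by their sum, ×100.
For the full model's 6×6 child covariance only the intercept block enters, so
the partition stays time-invariant and comparable to the unconditional
model; slope variance would otherwise make the shares a function of t.

**Trajectories.** Predicted means per arm and occasion at reference
covariates — female, non-FSM, not at-risk, school covariates at their
standardized mean of 0 — so the occasion-1 control prediction equals the
intercept draw exactly.

**Informative hypotheses.** H1: the intervention arm does better —
Control − GBG > 0 for concentration problems and disruptive behavior,
< 0 for prosocial behavior — against its complement H2, with an encompassing
prior placing mass ½ on each direction: BF1 = 2p, BF2 = 2(1 − p),
PMP1 = p, where p is the posterior proportion of draws satisfying H1. Hence
BF1 + BF2 = 2 and PMP1 + PMP2 = 1 identically, which the reporting layer
asserts on every row. Verbal bands (1–3 weak, 3–10 moderate, >10 strong) are
emitted as annotations only, not decisions.

## Synthetic trial generator

The generator emulates the study design the model assumes: log-normal school
sizes and logit-normal %FSM (standardized before use); Pocock–Simon
minimization of schools over the two factors dichotomized at the running
median, plus the overall arm totals, with deterministic assignment to the
minimizing arm and a seeded fair coin on ties (the concrete minimization
variant is a design choice — published trial reports rarely specify the
internals); independent Bernoulli child covariates (male 0.51, FSM 0.26,
at-risk 0.157); outcomes from the growth model above; and wave-dependent MAR
missingness on whole outcome triples (one rating instrument per occasion),
with optional covariate log-odds shifts, whole-school dropout, and a
cell-level mode that produces partially observed triples to exercise the
imputation path.

The default generating truth is the published trial-scale posterior-mean
estimates bundled in `mvgrowth.params`: 77 schools, 20–60 children per
school (≈3,100 children), five waves, the 20×3 fixed-effect matrix, and the
three level covariances. Two values the source analysis does not report are
fixed as package defaults: the child slope variance (0.01 per outcome, i.e.
slope SD 0.1 SD-units/year, with zero intercept–slope covariance) and the
wave-wise missingness ladder (0, .10, .15, .20, .25 — baseline complete by
design, attrition growing roughly linearly to a quarter by the final wave,
matching the scale of attrition in school cohort trials).

What the generator does *not* emulate: item-level ratings and measurement
non-invariance, rater effects and teacher turnover, school-size-dependent
cohort sizes, MNAR attrition, and time-varying covariates. Passing
recovery tests therefore show the estimator is correct *under the model's
own assumptions* at realistic scale and signal-to-noise — not that those
assumptions hold in any particular real dataset.

## Problem sizes used by the checks

Recovery checks run at 60 schools × 30 children × 5 waves with 3 chains ×
2,000 stored draws (the full trial size, 77 schools × ~3,100 children, runs
the same code and is used by the `analysis/` drivers); the closed-form
coefficient-draw check uses 50,000 draws on a one-level reduction; the
missingness-audit calibration uses 100 replicates of 30-school trials. These
sizes give Monte-Carlo error comfortably inside the asserted tolerances.

## Design choices and limitations

- The missingness audit is a single-level logistic regression with
  school-clustered standard errors, not a multilevel probit/logit — a
  deliberate simplification; it answers the same screening question (do
  covariates predict outcome loss?) with honest cluster-robust uncertainty.
- Standardization pools all occasions into one mean/SD per outcome; per-wave
  z-scoring would erase the growth the model is built to describe.
- The child random part pairs each outcome's intercept with its own linear
  slope (6×6). Slopes on higher time powers, cross-classified teacher
  effects, heterogeneous level-1 variance and >3 levels are out of scope.
- DIC is reported on the conditional (random-effects-given) deviance;
  DIC comparisons are only meaningful between models reported on the same
  convention.
- Frequentist estimation (IGLS/REML), complier-average causal effects and
  equality-constrained Bayes factors are not implemented.
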