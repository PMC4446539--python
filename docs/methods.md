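# Methods

## The generating model

All synthetic data come from a two-level Gaussian hierarchical model for
gradient responses. Subject *i* responds to stimulus *j* at position
`d_j` on the generalization dimension:

```
y_ij = b0_i + b1_i d_j + eps_ij          eps_ij ~ N(0, sigma2_eps), iid
b0_i = gamma00 + gamma01 u_i + U0_i
b1_i = gamma10 + gamma11 u_i + U1_i      (U0_i, U1_i) ~ N(0, T)
```

Level-1 errors and level-2 effects are mutually independent. The
marginal per-subject covariance is `Z T Z' + sigma2_eps I` with
`Z = [1, d]`; a nonzero random-slope variance makes this matrix
non-spherical, which is exactly the regime the rANOVA/HLM comparison is
about.

### Default parameters (the reference study conditions)

`default_config()` fixes the generator at gamma00 = 7.91871,
gamma10 = −0.58322, gamma01 = −0.37375, gamma11 ∈ {0, 0.05, 0.10},
T = [[2.5324, −0.46], [−0.46, 0.1345]], sigma2_eps = 2.4348, with 10
stimuli coded d = 0..9 (CS+ at d = 0, so the intercept is the CS+ mean)
and a subject trait u_i ~ Uniform(0, 10). All quantities are on the
0–10 US-expectancy rating scale (variances on its square). The uniform
trait distribution mirrors the worked example's 0–10 score and is the
one genuinely open choice in the study design; it is exposed as
`u_spec` because power against gamma11 > 0 scales with Var(u) (here
100/12), while the type-I-error and sphericity results do not depend on
it at all: the contrast transform annihilates intercept-variance
contributions, and at gamma11 = 0 the trait moves only intercepts.

### The worked-example emulator

`simulate_worked_example` produces a synthetic stand-in for a
52-subject, 10-stimulus social-exclusion expectancy study: a decreasing
quadratic mean gradient (9.3 − 0.45 d − 0.045 d²), a 0–10 moderator that
lowers the CS+ response (−0.30/unit) and flattens the slope
(+0.08/unit), correlated random intercepts and linear slopes
(2.3, −0.25, 0.12), residual variance 2.3, and responses clipped to the
rating scale. It emulates the *structure* of such data — it is not, and
cannot be checked against, any real dataset. Clipping is a deliberate
realism feature of the emulator only (the reference simulator never
clips, its model being unbounded Gaussian); tests that check parameter
recovery disable it, since recovery is a statement about the unbounded
generating model. What passing tests show is therefore internal
consistency (the fitter recovers what the generator put in), not that
real expectancy data follow a quadratic-plus-Gaussian law — real
gradients are bounded, often skewed near the scale ends, and may have
non-Gaussian subject effects.

## Split-plot rANOVA

`split_plot_anova` implements the classical balanced mixed
between/within decomposition: Group tested against subjects-within-
groups, Stimulus and Stimulus×Group against the within error. Because
every subject contributes a complete stimulus profile, cell frequencies
are proportional even when the median split yields unequal groups
(n odd), so the five sums of squares are orthogonal and add to the total
— the implementation was verified line-by-line against R's `aov` on
seeded fixtures, and every random fixture in the test suite is checked
against an independent sequential-projection oracle.

Degenerate inputs are flagged, not guessed at: a single group omits the
between test; a zero error mean square reports F as undefined rather
than infinite; incomplete or unbalanced data raise an error naming the
offending subjects (complete cases are a hard requirement of this
design).

### Sphericity machinery

Mauchly's W, the Greenhouse-Geisser and Huynh-Feldt epsilons are all
computed from `S = C Sigma_pooled C'`, where C is any orthonormal
contrast basis (Helmert by default; all results are provably and
testably basis-invariant) and Sigma_pooled is the within-group pooled
covariance with error df n − g. Pooling respects the group structure of
the design; the one-group variant is available by passing ungrouped
data. The Mauchly p-value follows the convention of R and other
standard software: the Bartlett-type chi-square statistic
−(n_e − (2p²+p+2)/(6p)) ln W plus Box's second-order series correction
(including the reference implementations' 3k+2 term), validated against
frozen `mauchly.test` output. Epsilon formulas: GG = (tr S)²/(p tr S²);
HF = ((n_e+1) p GG − 2)/(p (n_e − p GG)) capped at 1 (the split-plot
form, validated against pingouin for the one-group case); lower bound
1/p. Corrected tests keep the F statistic and multiply both degrees of
freedom by epsilon.

`median_split` implements both tie conventions (ties-high per
`u < median`, ties-low per `u ≤ median`) because their disagreement on
median-tied subjects is precisely the instability that
`split_sensitivity` demonstrates; the median is the ordinary
midpoint-of-order-statistics sample median.

## The mixed-model fitter

`fit_lmm` maximizes the profiled Gaussian likelihood. With
`V_i = sigma2 (Z_i Lam Lam' Z_i' + I)`, the GLS fixed effects and the
residual variance have closed forms given the relative Cholesky factor
`Lam`, so only the q(q+1)/2 free entries of `Lam` are optimized. Choices
that matter:

- **Parameterization.** Raw (unconstrained) Cholesky entries: `Psi =
  sigma2 Lam Lam'` is positive semi-definite by construction and
  variance components can reach the zero boundary exactly. Boundary
  fits are flagged (`boundary=True`), as is non-convergence.
- **Optimizer.** Nelder-Mead from moment-based starting values
  (per-subject OLS coefficient spread minus the OLS sampling part),
  tolerance 1e-8 on the deviance, with one deterministic restart from
  the incumbent if the first pass does not converge. No stochastic
  search; fits are exactly reproducible.
- **Sufficient statistics.** Subjects sharing a stimulus set share V_i,
  so the deviance is evaluated from pattern-level accumulators
  (O(k³ + k²p²) per evaluation, independent of n). This is what makes
  1500-replicate Monte-Carlo conditions run in under a minute each.
- **REML.** Adds ln det(Σ X_i' V*_i⁻¹ X_i) and rescales by N − p; the
  criterion matches the standard restricted log-likelihood (checked
  against statsmodels MixedLM). Deviance comparisons across different
  fixed parts are refused for REML fits.
- **Inference.** Wald statistics use SEs from the inverse GLS
  information and a standard-normal reference — deliberately no
  Satterthwaite/Kenward-Roger df correction, so with few subjects the
  test runs liberal (the Monte-Carlo study quantifies by how much).
  Likelihood-ratio tests use the naive chi-square reference with df =
  number of added free parameters (covariances count); for variance
  components this is conservative at the boundary, which is documented
  and tested rather than corrected, since the naive reference is what
  the comparison study is about.
- **Bookkeeping.** n_params = fixed coefficients + free covariance
  entries + the residual variance; AIC = deviance + 2p, BIC = deviance +
  p ln(N) with N the level-1 observation count.

`predict_subjects` returns empirical-Bayes (BLUP) conditional curves,
`b_i = Psi Z_i' V_i⁻¹ (y_i − X_i beta)`; the shrinkage factor reduces to
tau²/(tau² + sigma²/n_i) in the random-intercept case, which the tests
verify in closed form. `model_ladder` runs the canonical seven-model
sequence (random intercept → random slope → moderator → quadratic fixed
→ random quadratic → moderator×quadratic → drop d²:u) with the
corresponding deviance tests.

## The Monte-Carlo study

`run_grid` crosses n ∈ {20, 38, 55} with gamma11 ∈ {0, 0.05, 0.10},
1500 replicates per condition, alpha 0.05. Each replicate is analyzed
with (i) Mauchly's test, (ii) the uncorrected split-plot interaction
F test after a strict median split of u, (iii) its GG-corrected version,
and (iv) the ML HLM Wald z test of d:u with u continuous. Per-condition
random substreams derive from (master_seed, n, gamma11), so any cell is
reproducible in isolation and grid order is irrelevant. Failed fits are
excluded from their proportion's denominator and counted.

Problem sizes in the shipped checks: the acceptance script runs the four
graded conditions at the full 1500 replicates (about 3.5 minutes total);
the test suite uses the 300-replicate smoke mode for table cells (with
Monte-Carlo bands widened to match) and 1000 replicates for the null-
calibration checks.

## Known limitations

- The HLM Wald z test over-rejects with ~20 subjects (measured ≈ 0.08
  at nominal 0.05); a small-sample df correction is deliberately out of
  scope. Use REML and larger samples when calibration matters.
- Power against gamma11 > 0 depends on Var(u), which in applications is
  a property of the measured trait, not of the method.
- The rANOVA module requires complete balanced data by design; the HLM
  tolerates missing rows but both assume Gaussian errors and
  homoscedastic level-1 noise.
- No generalized (binomial/count) outcomes, no crossed or >2-level
  random structures, no Bayesian estimation.
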