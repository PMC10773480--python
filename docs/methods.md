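# Methods

## The model

`melsbb` fits a mixed-effects location-scale (MELS) beta-binomial model to a
bounded discrete longitudinal outcome: a word-recall score y_ij ∈ {0..20}
for person i at wave j, treated as the sum of n = 20 Bernoulli trials whose
latent success probability π_ij is drawn from a beta distribution. That beta
is parametrized by its mean p_ij (the *average probability*) and a
dispersion parameter θ_ij, with shape parameters

    α = p·θ,   β = (1 − p)·θ.

Small θ means the latent probabilities are widely spread around p — high
intraindividual variability (IIV) across occasions; large θ approaches the
plain binomial. At p = 0.5, θ = 2 the beta is uniform on (0,1) and every
score 0..20 is equally likely. The count moments are mean np and variance
n·p(1−p)(θ+n)/(θ+1), strictly decreasing in θ.

Both parameters carry regressions:

    logit(p_ij) = x_ij'β_p + u0_i + u1_i·z_ij
    log(θ_ij)   = w_ij'β_θ + v0_i

where z_ij is age centred on 74.2 years and scaled to decades. The
probability predictor contains an intercept, a restricted cubic spline in
centred age (4 knots by default, at Harrell's recommended quantiles
0.05/0.35/0.65/0.95), birth cohort (year turned 65, centred on 1999, in
decades), sex (reference male), education contrasts (reference: no
qualifications), and the between/within decomposition (person mean and
person-mean-centred deviation) of the ADL-difficulty count and the
interviewer-recorded test-issue indicator. The dispersion predictor uses
the same covariates with a single linear age-decade term. Person effects
(u0, u1, v0) — probability intercept, probability age slope, dispersion
intercept — are trivariate normal with free correlations.

Why a beta-binomial rather than a Gaussian MELS: the outcome is a bounded
count, and floor/ceiling effects bias residual-based IIV estimates
downward for people near the extremes; modelling the dispersion of the
latent probability distribution avoids that. The trials making up a single
score are treated as exchangeable; dependence among them (immediate vs
delayed recall of the same words) is absorbed into θ rather than modelled
explicitly.

## Priors

The supplementary prior choices of the original analysis are not
reproduced here; defaults are this package's own, weakly-informative and
configurable via `PriorSpec`:

- fixed effects: normal(0, 5) on intercepts, normal(0, 2.5) on slopes;
- random-effect SDs: half-Student-t(3, 0, 2.5);
- correlation matrix: LKJ(1), i.e. uniform over correlation matrices,
  implemented exactly through the vine decomposition — symmetric-beta
  priors on canonical partial correlations (exponents 1.5, 1, 1.5 for the
  3×3 case), which makes the prior-plus-Jacobian gradient closed form
  under the tanh parametrization.

## Estimation

Two routes share one joint posterior object with analytic gradients
(including second derivatives of the beta-binomial log pmf in both linear
predictors, needed for curvature).

**Nested Laplace (`fit(method="laplace")`, deterministic).** The joint
posterior of a hierarchical model has no usable interior mode in the
variance components — in the non-centred parametrization the density
increases as the SDs grow (shrinkage is removed at only logarithmic prior
cost), in the centred parametrization it spikes as they vanish. The person
effects are therefore *integrated out*: an inner Newton solve finds their
conditional mode (3×3 blocks per person; each observation's 2×2 curvature
block is shifted to positive semidefinite where the beta-binomial log pmf
is locally non-concave, with a true-Hessian polish near the optimum for
quadratic convergence), and a log-determinant correction completes the
Gaussian integral. The fixed effects are profiled inside this objective by
a block Newton step joined through a Schur complement, so the outer
L-BFGS-B runs over only six parameters (three log SDs, three correlation
parameters) with finite-difference gradients. Posterior draws come from
the central-difference curvature of the marginal log posterior at its
optimum, pushed through the constraining transforms; person effects are
drawn from their conditional Gaussians at the mode. Cheaper draw modes
(`hessian="beta"` — analytic Schur-complement covariance of the fixed
effects with variance components pinned; `hessian="none"`) exist for
elpd-based model screening, where full interval accuracy is not needed but
parameter-count penalization is (mode-pinned draws would not penalize
extra fixed effects at all).

**Adaptive HMC (`fit(method="hmc")`).** Full-Bayes Hamiltonian Monte Carlo
on the non-centred parametrization: dual-averaging step-size adaptation to
a 0.8 target acceptance rate, a diagonal mass matrix estimated in doubling
warmup windows with dual-averaging restarts, jittered leapfrog path
lengths, divergence counting, split-R̂/ESS diagnostics via arviz, and a
hard failure (unless `permissive=True`) when any fixed-effect or
variance-component R̂ exceeds 1.05. The sampler is written in-package
against the analytic gradient; it is deterministic given
(seed, chains, warmup, draws).

The two routes agree within Monte-Carlo error on identifiable fixtures
(tested). Laplace credible intervals are slightly conservative-to-nominal
in a 20-seed calibration study at 500 persons (z-score SDs 0.7–1.1 across
the 19 headline parameters).

**Numerical guards.** log θ is clamped to ±27 inside likelihood
evaluation; the latent probability to [1e−12, 1−1e−12]; log SDs and
correlation parameters to ±12 against line-search overshoot. All density
work uses log-gamma; no factorials.

## PSIS-LOO model comparison

Observation-level leave-one-out is computed from the *conditional*
pointwise log likelihood (given each draw's person effects) — the common
convention for this model family; marginalized LOO is out of scope.
Pareto-smoothing of the importance ratios is delegated to
`arviz.psislw`; observations with Pareto k > 0.7 are flagged. The decision
rule for selecting a richer model is explicit because reference analyses
typically leave it implicit: a candidate is selected only when its elpd
improvement exceeds the standard error of the pointwise elpd differences.
Note that duplicating draws leaves elpd unchanged only up to the Pareto
tail-fit window, which grows with the draw count.

## The synthetic cohort generator

`generate_cohort` emulates the structure of a biennial English ageing
panel (2002–2015, waves 1–7): staggered entry (70% at wave 1, refreshment
entries at waves 3, 4, 6, 7), baseline age as 65 + gamma moment-matched to
observed mean 70.5 and SD 6.4 (a left-truncated normal cannot have an SD
larger than its mean excess over the cutoff), 54.5% female, education
47.9/28.9/23.2%, baseline ADL-difficulty counts 78.2/11.7/5.3/3.0/1.5/0.4%,
test issues at 12.5% with a persistent two-state Markov chain
(p01 = 0.08, p11 = 0.44, stationary at 12.5%), and an ADL random walk
(+1 w.p. 0.10, −1 w.p. 0.06 per wave). The cohort variable is derived from
entry year and entry age, so age, cohort and calendar period satisfy the
usual accounting identity and age–cohort effects are identified only
through the multi-wave structure, as in the real design. Monotone dropout
is MCAR (rate 0.21) or covariate-dependent (older, unqualified, frailer
and test-issue-affected people leave sooner; intercept −1.45); both are
calibrated to the study's mean 3.4 observed waves per person.

Outcome scores are simulated from the model above. The default
("paper-default") truth sets every printed estimate to its reported
posterior mean: odds ratios 1.17 (cohort/decade), 1.24 (female), 1.30
(secondary), 1.52 (higher), 0.94/0.98 (ADL between/within), 0.58/0.82
(issues between/within); log-θ effects −2.25 (age/decade), −1.51
(cohort/decade), −0.43 (female), +0.45 (secondary), −0.26/−0.25 (ADL),
−3.93/−2.51 (issues); random-effect correlations 0.37, 0.45, 0.31.
Quantities the source does not print are this package's design choices,
fixed once: probability intercept −0.2 (reference person scores ≈ 9/20),
log-θ intercept 4.5 (near-binomial within-person variation for a typical
74-year-old, consistent with a large negative age effect remaining
meaningful), higher-education log-θ effect +0.65, random-effect SDs
(0.5, 0.15, 1.0), and an age profile declining gently to about 77 and
steeply thereafter, projected onto the spline basis so the truth is
exactly representable by the fitted model. Every cohort returns a
`TruthRecord` with the full generating parameter set.

What the generator does not emulate: mortality as a distinct process,
proxy respondents, survey weights, refreshment-sample age targeting,
item-level recall dependence, or outcome-dependent (informative) dropout.
Passing recovery tests therefore demonstrates internal consistency of
model + estimator under the stated generating process, not robustness to
those real-data features.

## Validation experiments

`melsbb.validation` packages the recovery and model-selection harnesses:

- *recovery_run*: simulate at the paper-default truth (MCAR dropout),
  refit, and check each of the 19 headline parameters against its 95%
  equal-tailed credible interval. At 1,000 persons roughly one miss in 19
  is expected under nominal coverage.
- *spline_selection_replicate*: under a strongly nonlinear age truth
  (near-flat to ~77, then −1.6 per decade), PSIS-LOO should prefer the
  4-knot spline over linear age.
- *interaction_selection_replicate*: under truth with no interaction, the
  age-by-sex interaction model should not pass the selection rule.

Problem sizes used by the shipped tests and the acceptance script — 1,000
persons for the single recovery test, 200 persons × 20 replicates per
selection experiment, 2,000 persons for the acceptance recovery run — are
the package's chosen validation scales; the larger acceptance cohort is
used because the random-effect correlation intervals are wide at 1,000
persons.

## Known limitations

- The Laplace route's person-effect draws are conditional on the outer
  mode, so their uncertainty ignores variance-parameter uncertainty.
- The pointwise log likelihood is conditional on sampled person effects;
  elpd values are not comparable to marginal-likelihood-based ones.
- Random-effect correlations are weakly identified with ~3.4 observations
  per person: their posteriors are wide and their recovered means move by
  roughly one posterior SD across simulated cohorts of 2,000 persons.
- The HMC sampler uses jittered fixed-length trajectories, not NUTS; for
  very stiff posteriors more warmup may be needed, and the R̂ > 1.05 guard
  exists precisely to surface that.
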