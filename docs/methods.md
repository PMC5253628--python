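# Methods

## The task and the behavioral model

The monetary probabilistic selection task presents three fixed pairs of
symbols (AB, CD, EF) whose members deliver a 0.01-unit reward with
complementary probabilities (A 80% vs B 20%, C 70% vs D 30%, E 60% vs
F 40%). A learning phase of 6 blocks x 20 repetitions per pair (360
trials) gives trial-wise feedback; a test phase probes all 15 pairwise
combinations of the six symbols 12 times each (180 trials) without
feedback. Left/right placement is exactly counterbalanced per pair within
each block, and schedules are reproducible from a seed.

Behavior is modeled by temporal-difference Q-learning with separate
learning rates for gains and losses. Each symbol s carries an expected
value Q_s, initialized at 0.5 (the midpoint of the 0/1 reward scale;
configurable). After a choice of s with reward r, the prediction error
PE = r - Q_s updates only the chosen symbol:

    Q_s <- Q_s + alpha_G [PE]_+ + alpha_L [PE]_-

where [x]_+ = max(x, 0) and [x]_- = min(x, 0). Choices follow the softmax
rule P(left) = exp(beta Q_left) / (exp(beta Q_left) + exp(beta Q_right)),
implemented with log-sum-exp stabilization. The single-rate variant ties
alpha_L = alpha_G. The likelihood is the product of the choice
probabilities over non-missed learning trials; missed trials contribute no
likelihood term and trigger no update; test trials (no feedback) are
excluded from fitting but can be predicted with frozen Q-values.

## Hierarchical estimation

Every subject-by-condition dataset i has its own parameters. On
transformed scales (logit for the learning rates, log for beta) they are
exchangeable normal draws whose mean is shifted additively by the placebo
condition:

    theta_ip ~ Normal(mu_p + delta_p_LU LU_i + delta_p_HU HU_i, sigma_p)

Priors are mildly informative and configurable: Normal(0, 5) on group
means and condition effects, half-Normal(0, 2.5) on group SDs. These
scales are weak relative to the parameter ranges the likelihood supports
(logit-scale learning rates of order +-5, log-scale inverse temperatures
of order +-3), so the posterior is dominated by the data.

Sampling uses a blocked scheme chosen to exploit the posterior's
structure rather than generic gradient-based sampling:

* dataset-level parameter vectors are conditionally independent given the
  group level and are updated jointly per dataset with an adaptive
  random-walk Metropolis step on the transformed scale (step size adapted
  toward 30% acceptance during warm-up only, then frozen);
* the group means and both condition effects of each parameter are
  jointly conjugate given the transformed dataset parameters and the
  group SD, and are drawn exactly from their trivariate normal
  conditional (Gibbs);
* each group SD is updated by univariate slice sampling on the log scale
  (stepping-out and shrinkage), which is tuning-free.

The full profile matches the emulated analysis (8 chains, 1000 warm-up
and 1000 kept draws per chain, no thinning); the reduced profile
(2 chains, 500/500) keeps simulate-fit recovery studies to a few seconds
per fit. Chains are seeded deterministically via `SeedSequence` spawning;
identical configuration and seed reproduce draws bit-identically.
Convergence is summarized by split R-hat over all group-level scalars
(classic unsplit formula also available); fits whose worst R-hat exceeds
the threshold (default 1.01) are returned flagged, never discarded, so
recovery studies can count failures. At the reduced profile the worst
R-hat — usually a group SD — commonly sits near 1.1-1.5 while the
condition-effect posteriors are already stable; the full profile is the
one intended for reporting.

Model comparison uses WAIC on the deviance scale, waic = -2 (lppd -
p_waic), with the variance-based penalty (pointwise posterior sample
variance of the log-likelihood, ddof 1, evaluated on thinned draws).
Differences above 10 are labeled strong. Intervals are 95% highest-density
intervals computed by an exhaustive shortest-window scan over sorted
draws (exact for unimodal posteriors). Condition effects are also
back-transformed to the natural scale at the group mean, per draw:
inv_link(mu + delta) - inv_link(mu).

## The synthetic cohort

The generator emulates a 29-subject, three-session within-subject study
(any subject count >= 2 can be requested): per subject-by-condition
dataset, RL parameters are drawn independently from the group model
above (conditions share no parameters or stimuli, mirroring the
new-stimuli-per-session design), choices and rewards are simulated
through the Q-learning model on fresh seeded schedules, log-normal
reaction times carry trial, pair, condition and subject-intercept
effects, categorical subjective reports are drawn from fixed
per-condition probability profiles, and 0-10 arousal ratings come from a
linear model rounded and clipped to the scale.

Defaults are anchored to the emulated study where possible: the gain-rate
centre is the fitted group mean 0.07; the condition effects are the
fitted fixed effects (alpha_G: LU +0.83, HU +1.17; alpha_L: LU -0.74, HU
-0.86; beta: LU -0.02, HU +0.05 on the logit/log scales); RT, accuracy,
arousal and subjective-report generators default to the corresponding
fitted regression coefficients and response profiles.

Two centres are deliberate package choices rather than fitted values,
because the fitted values are mutually inconsistent under the plain
softmax reading. With Q in [0, 1], an inverse temperature of 0.21
produces near-chance choices, contradicting the 70-85% accuracies the
model is meant to emulate; we therefore centre beta at 1/0.21 ~ 4.76,
i.e. we read the reported noise parameter as a temperature. Likewise, a
loss-rate centre of 0.015 combined with the fitted condition effects
inverts the empirical condition ordering in forward simulation: when
alpha_G >> alpha_L, the Q-values of all symbols inflate toward 1 and
pair discrimination compresses, so accuracy falls as the gain rate
rises. A loss-rate centre of 0.20 removes this pathology; with it, the
fitted condition effects reproduce both the empirical accuracy range
(~0.74-0.80) and the HU > LU > baseline direction. Group SDs (0.4, 0.4,
0.25 on the transformed scales) are chosen to give plausible individual
spread (e.g. gain rates roughly 0.03-0.15 at baseline). The
parameterization remains configurable, and the estimation machinery is
agnostic to these choices.

What the generator does not emulate: between-session practice or
carry-over effects, mechanistic expectancy formation, within-subject
parameter correlations across conditions, RT-choice coupling (RTs are
conditionally independent of choices given the predictors), and missed
responses by default (the miss rate is configurable but defaults to 0).
Passing recovery tests therefore demonstrate that the estimation
machinery inverts this generative family at realistic sizes — not that
the model family is correct for any particular empirical dataset.

## Behavioral regressions

Accuracy is modeled by hierarchical logistic regression on learning-phase
correctness with trial number (rescaled to steps of 20 trials so
coefficients are comparable across phases of the session), numeric pair
(1-3, increasing difficulty), condition dummies (baseline reference) and
subject-varying intercepts; reaction times by the same predictor set on
log RT with a normal likelihood; arousal by condition x time (before/
after) with subject intercepts; and the subjective reports by a softmax
regression of decline/neutral/improve on the HU indicator, the
experienced-question indicator and their interaction, with "neutral"
fixed as reference category (a 4 x 3 coefficient matrix whose neutral
column is zero).

Priors are wide (effectively flat: Normal with SD 15 on logistic fixed
effects, SD 5 on softmax coefficients, flat for the linear models) and
the posteriors are approximated by the mode with Gaussian curvature
(Laplace): the hierarchical logistic model through the statsmodels
Bayesian mixed GLM (MAP), the linear mixed models through REML point
estimates with their asymptotic covariance, and the softmax regression by
a penalized MAP fit with analytic gradient and finite-difference Hessian
authored here. At these sample sizes (hundreds to thousands of Bernoulli
or normal observations per coefficient) the posteriors are close to
Gaussian and the approximation agrees with unpenalized maximum likelihood
to well within reporting precision; tests verify this against independent
GLM/MNLogit oracles. Degenerate inputs are flagged rather than fatal:
all-identical outcomes flag separation, non-positive RTs are dropped and
counted, an unobserved response category stays identified through the
prior and is flagged.

## Numerical and design choices

* Q-values initialized at 0.5; rewards drawn independently per trial for
  the chosen symbol only (only the chosen outcome enters the prediction
  error).
* "Correct" means choosing the pair member with the higher reward
  probability.
* Exact-count left/right counterbalancing per block, lexicographic
  canonical pair order.
* Softmax log-probabilities computed as -log1p(exp(-x)) with a linear
  tail below x = -30.
* WAIC penalty uses the sample variance (ddof 1); the arviz cross-check
  in the tests allows the O(1/n_draws) discrepancy from its population
  variance.
* HDI is the shortest window containing ceil(mass x n) sorted draws.
* A single top-level seed fans out to stage seeds through
  `SeedSequence([seed, stage])`; every artifact records its seed and a
  content checksum in the run manifest.
* Recovery and acceptance runs use scaled-down problem sizes (8-12
  subjects, reduced MCMC profile, 5-20 replicates), chosen so the whole
  verification cycle runs in minutes on one CPU while keeping every
  qualitative conclusion (sign recovery, coverage, model selection,
  condition ordering) stable across seeds.

## Known limitations

* The reduced-profile sampler under-mixes group SDs (flagged via R-hat);
  conclusions about condition effects are robust to this in recovery
  tests, but reported SD posteriors at the reduced profile should be
  treated as approximate.
* Laplace summaries for the regressions omit posterior skew; for the
  softmax model at n ~ 29 subjects the true posterior is mildly skewed
  and HDIs are approximate (they remain wide enough that calibration
  tests pass).
* The subjective-report fit is non-hierarchical (one observation per
  subject x condition x question), matching the analysis it mirrors.
* Condition effects enter each dataset's transformed parameters
  additively through the group mean; models where effects enter only
  part of the hierarchy are not implemented.
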