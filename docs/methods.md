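# Methods

This note documents the models, generative assumptions, numerical choices,
and limitations behind `priorlik`.

## The task and its incentive scheme

The package models a two-state probability-estimation task.  On each trial a
responder sees the prior probability of a hidden state (one of two museum
galleries), a sample that carries evidence of strength θ ∈ (0.5, 1) about the
state, and a monetary penalty W, and reports the posterior probability
π(Q|x) of a questioned state Q on a 33-point slider (0.02 to 0.98 in steps
of 0.03; the grid excludes 0 and 1 so every report has a finite log-odds).
The objective posterior follows Bayes' theorem for two complementary
hypotheses,

    Pr(Q|x) = Pr(Q)·Pr(x|Q) / [Pr(Q)·Pr(x|Q) + (1−Pr(Q))·(1−Pr(x|Q))],

equivalently logit Pr(Q|x) = logit Pr(Q) + logit Pr(x|Q), where the
likelihood Pr(x|Q) equals θ when the sample signals Q and 1−θ otherwise.

Payment uses a binarized quadratic scoring rule: one trial is drawn at the
end of the session; the responder keeps an endowment N = $30 unless they
lose the trial's penalty W ∈ {$10, $20}, and the probability of losing is
the squared report error (I − π)², with I indicating whether Q was the true
state.  The trial's expected value is then

    EV = N − W·(Pr − 2·Pr·π + π²),

maximized at π = Pr regardless of W or risk attitude, and equal to
N − W·Pr(1−Pr) for a truthful reporter.  Because EV is a U-shaped (not
linear) function of the posterior, posterior probability and expected value
are decorrelated by design.

## Session generation

A session has 130 trials in four runs of 32/33/32/33, with the questioned
gallery alternating by run.  The 120 non-catch trials come from 60 unique
prior–evidence cores duplicated over the two penalty levels.  Core
construction: each of the 15 combinations of prior bin
{0.1, 0.4, 0.5, 0.6, 0.9} and θ bin {0.6, 0.8, 0.9} is used exactly four
times, and each core's prior and θ receive an independent uniform jitter
from {−0.03, …, +0.03}.  The balanced tiling (rather than sampling bins
independently at random) is what guarantees the design property that prior
and likelihood are uncorrelated across the session; with random bin
sampling, |r| exceeds 0.15 in roughly a quarter of sessions.

The sample category is balanced within each prior×θ cell (half signal each
gallery), and the hidden gallery is then drawn from its Bayes posterior
given the displayed prior, θ, and sample.  This factorization keeps the
hidden state consistent with the displayed information (so payout and
ideal-observer analyses are exact) while pinning the sample–prior
concordance margin, which is what decorrelates likelihood from prior.  Ten
catch trials (prior only, likelihood treated as 0.5, one per prior bin per
penalty) are randomly interleaved.  Inter-trial intervals are exponential
(mean 3.5 s) truncated into [1, 10] s by rejection sampling; the initial
slider position is uniform over the 33 grid values (maximum-entropy reading
of "randomized").  All randomness flows from one integer seed through
NumPy's splittable generator; identical seeds give byte-identical sessions.

An averaging variant generates the same structure but reinterprets the two
displayed probabilities as independent gallery mixtures whose mean (the
first probability alone on catch trials) is the correct response.

## Synthetic responders

The generative response model mirrors the fitted one.  Participant i draws
coefficients from independent normal hyper-distributions and reports

    z = b0 + b_prior·logit Pr(Q) + b_lik·logit Pr(x|Q) + bW·(W−15) + bS·S + ε,
    report = snap(inv_logit(z)),     ε ~ N(0, σ_resp²),

with S the initial slider position and snap() the nearest-grid-value map
(ties upward).  Adding the noise on the logit scale before discretization
keeps the generative model conjugate to the fitted linear model of the logit
report.  Defaults place the population at the conservative-integration
regime (b_prior mean 0.66, b_lik mean 0.50, hyper-SD 0.2 each; elevation
0.07 ± 0.1; penalty 0.01/$ ± 0.005; slider 0 ± 0.05; σ_resp = 0.6).  The
penalty enters centered at $15 so intercepts refer to the mid-penalty
condition.  All hyper-SDs are small but nonzero so the full random-effects
covariance of the fitted mixed models is estimable rather than sitting on
the boundary.  Omissions are Bernoulli at rate 10/2990 per trial (the rate
observed in a 23×130 session).

Reaction time follows an inverted-U in the report,

    RT = a0 + a_quad·π² + a_lin·π + a_D·|D| + a_diff·|Pr(Q)−Pr(x|Q)| + ε,

slowest at maximal uncertainty (π = 0.5).  Defaults: a_quad = −5.88 and
a_lin = +5.88 (peak exactly at 0.5), a0 = 3 s, a_D = 1 s per unit slider
travel, a_diff = 0.5 s, σ_RT = 1 s, truncated into (0.2, 15] s by
resampling; hyper-SDs (0.5, 1.0, 1.0, 0.3, 0.2).  Values not pinned by the
design were chosen once as physiologically plausible and are exposed in
`CohortConfig`.

Two reference cohorts: the ideal observer deterministically reports the grid
value nearest the objective posterior; the mean responder reports the
average of the two displayed probabilities (the prior on catch trials) plus
probability-scale noise (SD 0.05).

The normal form of the hyper-distributions is an assumption: the population
distribution of individual weights is not identified by anything in the
design, and the generator makes no claim beyond unimodality and the stated
spread.

## Behavioral model fitting

Three linear mixed-effects models are fit by maximum likelihood with
by-participant random effects on every term:

* posterior-weight model — logit π on the objective logit posterior plus
  penalty and initial slider.  The slope is the probability-weighting
  parameter (1 = perfect Bayesian; < 1 = conservatism), the intercept the
  elevation.
* prior-likelihood model — logit π on logit prior and logit likelihood
  separately (plus penalty and slider), estimating the weight afforded to
  each source.
* reaction-time model — RT on π², π, |D|, and |prior − likelihood|.

Estimation uses statsmodels' MixedLM with a full random-effects covariance,
optimized by L-BFGS with a Powell retry; on failure the structure degrades
to diagonal (independent variance components) and then to random intercepts
only, with the degradation recorded in the result.  Confidence intervals use
the normal approximation to the ML sampling distribution
(`FitResult.df_method == "normal"`); no small-sample degrees-of-freedom
correction is applied, which at 23 participants is mildly anticonservative
for p-values but immaterial for the CI-based checks the package relies on.
A zero-residual input (noise-free simulation) short-circuits to an exact OLS
solution, since the ML variance estimate is degenerate there.  Fits exclude
catch trials and omissions.  An independent cross-check against lme4 (ML)
on a small cohort is part of the test suite.

Per-participant strategy models are fit in probability space so their
information criteria are comparable across functional forms: a mean model
(unit-coefficient average of the two probabilities plus intercept, penalty,
slider), a weighted-Bayes model (free exponents on the prior and likelihood
odds — algebraically the inverse-logit of a weighted sum of logits — fit by
Levenberg–Marquardt from all-zero starts with five jittered restarts on
failure), and weighted linear models with and without a prior×likelihood
interaction.  Gaussian log-likelihoods count the residual variance as one
parameter in AIC/BIC.

Screening applies the performance criteria evaluable from responses: miss
rate ≤ 6%, catch-trial correlation with the prior ≥ 0.89 (significant at
0.05), and a one-sided Welch test of reports on high- (≥ 0.9) versus low-
(≤ 0.1) posterior trials.  A paired sign test compares report accuracy
between penalty levels (the scoring rule predicts a null), and paired
t-tests with Cohen's d compare per-participant weights (ordinary
per-participant regressions, not BLUPs) against matched ideal observers.

## Random-effects Bayesian model selection

Per-participant log-evidences are approximated as −AIC/2 or −BIC/2 (BIC
default).  The population is a mixture over models with Dirichlet-
distributed frequencies: variational updates (tolerance 1e−6 on α, 10,000
iteration cap) give the Dirichlet posterior; exceedance probabilities are
Monte-Carlo argmax frequencies of 10⁶ Dirichlet draws (chunked, seeded).
The Bayesian omnibus risk compares the mixture's variational free energy
against the null in which all models are equally frequent, and protects the
exceedance probabilities: pxp = xp·(1−bor) + bor/K.

Family comparison partitions model space (default: weighted-Bayes and
linear-with-interaction versus weighted averaging without interaction) under
a prior with equal mass per family split equally within family, correcting
for family size.  Because the mean-field update is unreliable for sub-unit
Dirichlet counts (with flat evidence it drifts toward the smallest family),
family frequencies are sampled from the exact posterior by a seeded Gibbs
sampler (10,000 retained sweeps after 1,000 burn-in) alternating model
assignments and frequencies, then summed within families before the argmax.

## ROI-scale GLM analysis

The fMRI component is deliberately desk-scale: one synthetic timeseries per
participant stands in for a cluster mean; whole-brain mapping and
cluster-level correction are out of scope.  Designs model each completed
non-catch trial's decision period (slider onset to response; 3 s of
information components precede the slider, the window lasts 15 s plus a
0.5 s hold) as a boxcar convolved with a canonical double-gamma HRF
(response/undershoot delays 6/16 s, unit dispersions, 1:6 undershoot, 32-s
support, unit peak).  Convolution is computed in closed form — a boxcar
convolved with the HRF is the difference of two shifted copies of its
running integral — at 10× oversampling, which is exact and removes the FFT
cost.  Parametric modulators multiply the boxcar by z-scored covariates
(group-level scoping by default; participant-level gives identical values
for the shared trial set) with no orthogonalization.  Catch trials and
omissions get separate epoch regressors.  Variants cover the objective-
posterior, prior+likelihood, and subjective-posterior modulator sets, a
quadratic control, a truncated-range control (modulation only below π =
0.8), and a whole-brain-style set (certainty, favored-side and sample-side
dummies, penalty, subjective posterior, subjective EV, initial slider).

Estimation is per-participant least squares (rank-checked, collinear
columns named on failure); group inference is a one-sample t-test on the
contrast unless a Lilliefors normality check rejects at 0.05, in which case
a Wilcoxon signed-rank test with a bootstrap CI is reported.

The label-permutation null asks whether apparent prior and likelihood
responses could be epiphenomena of a pure posterior code: each permutation
independently swaps each trial's logit-prior and logit-likelihood values
with probability ½ — leaving their sum, the logit posterior, untouched —
using the same swap for every participant (the trial set is shared),
re-z-scores both modulators, rebuilds the design, and refits; the statistic
is the group-mean coefficient, and p-values are two-sided percentile
positions with the +1 correction.  A per-trial swap is used rather than a
whole-regressor swap, which would admit only two permutations.  The
permutation solve uses the Frisch–Waugh–Lovell projection with precomputed
cross-products; it agrees with a full-design refit to machine precision and
makes a 1,000-permutation group null a ~1 s computation.  Under a
posterior-only code the observed coefficients sit deep inside the null
(the test is conservative, i.e., valid); with distinct generative prior and
likelihood weights (defaults 0.159 and 0.310 in z-scored units, white noise
SD 1.0) both observed coefficients fall outside it.

## What the synthetic data do and do not show

The generator emulates the study design (trial structure, penalties,
jittered bins, omission rates) and a population of noisy logit-weighted
integrators with inverted-U RTs.  It does not emulate learning or
sequential effects (trials are independent by design), lapses or strategy
mixtures within a participant, non-normal weight distributions, RT-report
coupling beyond the modeled terms, or physiological fMRI noise
(autocorrelation is available but defaults to white).  Passing tests
therefore show that the estimators recover the truth under the design's
assumptions at the design's sample sizes — not that those assumptions hold
for human data.  Group-level coefficients reported from human participants
(weights 0.66/0.50, weighting slope 0.56, RT quadratic −5.88, ROI betas
0.159/0.310, the 0.83/0.17 family split, brain–behavior ρ = 0.439) are used
only as generative defaults and context; reproducing them requires the
original dataset, which this package does not consume.

## Problem sizes

Validation studies run at the design's study conditions: 130-trial
sessions, 23 participants, 20 replicate cohorts for recovery and model-
selection checks, 200 replicates × 1,000 permutations for the permutation-
null calibration, 100 generator seeds for design diagnostics, and 10⁶
Monte-Carlo draws per exceedance computation.
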