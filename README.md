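# priorlik

Tools for studying how people integrate described prior probabilities with
evidence likelihoods when estimating the posterior probability of a hidden
state — and for asking, at ROI scale, whether a neural signal separately
encodes both sources or merely their sum.

The package implements, as a tested and fully synthetic-data-driven
pipeline:

* the **task mathematics** of an incentive-compatible probability-estimation
  task: a two-state Bayes identity that is additive in log odds,
  `logit Pr(Q|x) = logit Pr(Q) + logit Pr(x|Q)`, a 33-point response grid,
  and a binarized quadratic scoring rule in which the probability of losing
  a penalty W from an endowment N equals the squared report error, making
  the trial's expected value `N − W(Pr − 2·Pr·π + π²)` maximal at the
  truthful report π = Pr;
* a **session generator** (130 trials: 60 jittered prior×evidence cores
  duplicated over two penalties, plus 10 prior-only catch trials) whose
  design decorrelates prior from likelihood and expected value from
  posterior;
* a **synthetic cohort generator**: noisy logit-weighted integrators
  (`logit π = b0 + b_prior·logit prior + b_lik·logit likelihood + …`),
  ideal observers, and mean responders, with inverted-U reaction times and
  realistic omission rates;
* **mixed-effects model fitting** (probability-weighting slope and
  elevation; separate prior/likelihood weights; the RT model), participant
  screening, and ideal-observer comparisons;
* **random-effects Bayesian model selection** over per-participant AIC/BIC
  evidences: exceedance probabilities, Bayesian-omnibus-risk-protected
  exceedance probabilities, and size-corrected family-wise exceedance
  probabilities;
* an **ROI-scale GLM analysis**: decision-period boxcars convolved with a
  canonical double-gamma HRF, z-scored parametric modulators without
  orthogonalization, per-participant least squares with group t /
  signed-rank inference, and a prior/likelihood **label-permutation null**
  that holds the logit posterior fixed while swapping its components.

See `docs/methods.md` for the models, assumptions, and numerical choices.

## Worked example

```python
import numpy as np
from priorlik import (generate_session, draw_participants, simulate_cohort,
                      fit_prior_likelihood_model, fit_posterior_weight_model)

plan = generate_session(seed=42)          # 130 trials, reproducible
rng = np.random.default_rng(7)
cohort = simulate_cohort(plan, draw_participants(23, rng=rng), rng)

f = fit_prior_likelihood_model(cohort)
print(f.fixed_effects["logit_prior_q"], f.ci95["logit_prior_q"])
print(f.fixed_effects["logit_lik_q"], f.ci95["logit_lik_q"])
```

Running `python examples/02_simulate_and_fit.py` (which wraps the above)
prints, for this seed:

```
prior weight: 0.610  [95% CI 0.547, 0.674]
likelihood weight: 0.436  [95% CI 0.358, 0.513]
probability-weighting slope: 0.518 (1 = perfect calibration)
RT quadratic coefficient: -6.14 s (negative = slowest near 0.5, where uncertainty peaks)
vs. ideal observers: prior weight -0.37, likelihood weight -0.54 (negative differences = conservatism)
```

Both weights are credibly positive — each probability source contributes to
the reports — but below 1: the simulated population underweights both
sources relative to exact Bayesian integration (conservatism), and the
weighting slope summarizes that compression.  The other example scripts
cover the session design diagnostics (`01`), strategy discrimination by
Bayesian model selection (`03`; an integrating cohort drives the
interaction family's exceedance probability to ~1, a mean-responding cohort
drives the mean model's protected exceedance probability to ~1), and the
ROI permutation null (`04`; with distinct generative prior/likelihood betas
the observed group coefficients fall outside the posterior-only null,
p ≈ 0.002 at 1,000 permutations).

A full run — session → cohort → fits → model selection → ROI simulation and
permutation null, with every artifact persisted — is one call
(`priorlik.run_pipeline(RunConfig(seed=1))`) or one command
(`priorlik pipeline --seed 1`).

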