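"""Can Bayesian model selection tell integration from averaging?

Fits four per-participant strategy models (mean, weighted Bayes, weighted
linear with/without interaction) to an integrating cohort and to an
averaging cohort, then compares them with random-effects Bayesian model
selection: protected exceedance probabilities and a family-level analysis
that groups models capturing a prior-likelihood interaction.
"""

import warnings

import numpy as np

from priorlik import (DEFAULT_FAMILIES, bms, draw_participants,
                      evidence_from_ic, family_xp, fit_all_participants,
                      generate_session, mean_responder_cohort, simulate_cohort)

warnings.filterwarnings("ignore")

plan = generate_session(seed=42)
rng = np.random.default_rng(3)

for label, cohort in [
    ("weighted-Bayes responders", simulate_cohort(plan, draw_participants(23, rng=rng), rng)),
    ("mean responders", mean_responder_cohort(plan, rng)),
]:
    fits = fit_all_participants(cohort)
    ev = evidence_from_ic(fits, source="bic")
    res = bms(ev, seed=0)
    fam = family_xp(ev[[m for m in DEFAULT_FAMILIES]], DEFAULT_FAMILIES, seed=0)
    print(f"{label}:")
    print("  pxp: " + ", ".join(f"{m}={p:.3f}" for m, p in zip(res.models, res.pxp)))
    print("  family xp: " + ", ".join(f"{f}={x:.3f}"
                                      for f, x in zip(fam.families, fam.family_xp)))
print("A high 'interaction' family xp indicates multiplicative (Bayes-like)")
print("combination; mean responders instead drive the mean model's pxp to 1.")
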