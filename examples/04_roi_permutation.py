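"""ROI GLM with the prior/likelihood label-permutation null.

Simulates per-participant ROI timeseries in which the decision-period signal
carries distinct prior and likelihood weights, fits the two-term GLM, and
asks whether those weights could be an artifact of a pure posterior code by
swapping prior/likelihood labels per trial (the logit posterior is invariant
under the swap).
"""

import warnings

import numpy as np

from priorlik import (build_design, draw_participants, fit_glm, generate_session,
                      group_test, permutation_null_prior_lik, simulate_bold,
                      simulate_cohort)

warnings.filterwarnings("ignore")

plan = generate_session(seed=42)
rng = np.random.default_rng(11)
cohort = simulate_cohort(plan, draw_participants(23, rng=rng), rng)

truth = {"epoch": 1.0, "logit_prior": 0.159, "logit_lik": 0.310}
pids = sorted(cohort.participant.unique())
designs, ys = [], []
for pid in pids:
    d = build_design(plan, cohort[cohort.participant == pid], variant="froi2")
    designs.append(d)
    ys.append(simulate_bold(d, truth, noise_sd=1.0, rng=rng))

import pandas as pd
betas = pd.DataFrame([fit_glm(d, y) for d, y in zip(designs, ys)])
for term in ("logit_prior", "logit_lik"):
    g = group_test(betas, term)
    print(f"group {term}: {g.estimate:.3f}  [95% CI {g.ci95[0]:.3f}, "
          f"{g.ci95[1]:.3f}]  p={g.p_value:.2g} ({g.test})")

perm = permutation_null_prior_lik(plan, cohort, np.column_stack(ys),
                                  n_perms=1000, seed=0, designs=designs)
print(f"\npermutation null (1000 label swaps holding the posterior fixed):")
print(f"  observed prior beta {perm.observed_prior:.3f}, p = {perm.p_prior:.3g}")
print(f"  observed likelihood beta {perm.observed_lik:.3f}, p = {perm.p_lik:.3g}")
print("Small p-values mean the two sources are separately encoded - the")
print("pattern cannot be explained by a signal tracking only their sum.")
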