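"""Performance-based participant screening and secondary behavioral tests.

Screening mirrors the study's pre-inclusion criteria that can be evaluated
from responses alone (the instruction-comprehension quiz cannot):

* miss rate: no more than 6% of trials without a response;
* prior sensitivity: on catch trials (prior only), Pearson r between report
  and the prior of at least 0.89, significant at alpha = 0.05;
* posterior sensitivity: reports significantly higher on high-posterior
  (>= 0.9) than low-posterior (<= 0.1) trials by a one-sided Welch test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mixed import per_participant_weights
from .cohort import ideal_observer_cohort
from .session import SessionPlan

__all__ = [
    "ScreeningReport",
    "screen_participants",
    "penalty_accuracy_test",
    "compare_to_ideal",
]

MISS_RATE_MAX = 0.06
CATCH_R_MIN = 0.89
ALPHA = 0.05


@dataclass
class ScreeningReport:
    per_participant: pd.DataFrame

    @property
    def passed(self) -> list:
        return list(self.per_participant.loc[self.per_participant["pass_all"], "participant"])


def screen_participants(cohort: pd.DataFrame) -> ScreeningReport:
    rows = []
    for pid, sub in cohort.groupby("participant"):
        miss_rate = float(sub["omitted"].mean())
        catch = sub[sub["is_catch"] & ~sub["omitted"]]
        if len(catch) >= 3 and catch["prior_q"].std() > 0 and catch["report"].std() > 0:
            r, p = stats.pearsonr(catch["report"], catch["prior_q"])
            catch_ok = bool(r >= CATCH_R_MIN and p < ALPHA)
        elif len(catch) == 0:
            r, p, catch_ok = np.nan, np.nan, None  # not evaluable
        else:
            r, p, catch_ok = np.nan, np.nan, False
        nc = sub[~sub["is_catch"] & ~sub["omitted"]]
        hi = nc.loc[nc["target"] >= 0.9, "report"]
        lo = nc.loc[nc["target"] <= 0.1, "report"]
        if len(hi) >= 2 and len(lo) >= 2:
            t, p_hl = stats.ttest_ind(hi, lo, equal_var=False, alternative="greater")
            hl_ok = bool(p_hl < ALPHA)
        else:
            t, p_hl, hl_ok = np.nan, np.nan, False
        rows.append(dict(
            participant=pid, miss_rate=miss_rate,
            pass_miss=miss_rate <= MISS_RATE_MAX,
            catch_corr=r, catch_p=p, pass_catch=catch_ok,
            high_low_t=t, high_low_t_p=p_hl, pass_high_low=hl_ok,
            pass_all=bool((miss_rate <= MISS_RATE_MAX)
                          and (catch_ok is None or catch_ok) and hl_ok),
        ))
    return ScreeningReport(per_participant=pd.DataFrame(rows))


def penalty_accuracy_test(cohort: pd.DataFrame) -> dict:
    """Does the penalty level change report accuracy?

    Per participant, mean absolute deviation |report - objective posterior| in
    each penalty condition; a paired sign test across participants on the
    high-minus-low-penalty differences.  The incentive scheme predicts a null
    result: truthful reporting is optimal at either penalty.
    """
    nc = cohort[~cohort["is_catch"] & ~cohort["omitted"]].copy()
    penalties = sorted(nc["penalty"].unique())
    if len(penalties) != 2:
        raise ValueError("both penalty levels must be present")
    nc["abs_dev"] = (nc["report"] - nc["target"]).abs()
    per = nc.pivot_table(index="participant", columns="penalty", values="abs_dev",
                         aggfunc="mean")
    diffs = (per[penalties[1]] - per[penalties[0]]).dropna()
    n = len(diffs)
    if n < 6:
        import warnings
        warnings.warn("fewer than 6 participants: sign test is underpowered")
    diffs = diffs.where(diffs.abs() > 1e-12, 0.0)  # float-noise-exact ties
    nonzero = diffs[diffs != 0]
    n_pos = int((nonzero > 0).sum())
    if len(nonzero) == 0:
        p = 1.0  # all ties: the test is degenerate
    else:
        p = stats.binomtest(n_pos, len(nonzero), 0.5).pvalue
    return dict(
        n_participants=n, median_diff=float(diffs.median()),
        sign_statistic=n_pos, n_ties=int((diffs == 0).sum()), p_value=float(p),
        per_participant=per,
    )


def compare_to_ideal(cohort: pd.DataFrame, plan: SessionPlan) -> dict:
    """Per-participant prior/likelihood weights versus matched ideal observers.

    Weights come from ordinary per-participant regressions on the shared trial
    set; the ideal observer answers the same trials with the grid value
    nearest the objective posterior.  Paired t-tests with Cohen's d quantify
    underweighting (negative differences = conservatism).
    """
    weights = per_participant_weights(cohort)
    if len(weights) < 2:
        raise ValueError("need at least 2 participants for the paired comparison")
    ideal = ideal_observer_cohort(plan, n_participants=1)
    ideal_w = per_participant_weights(ideal).iloc[0]

    out = {"ideal_weights": dict(b_prior=float(ideal_w["b_prior"]),
                                 b_lik=float(ideal_w["b_lik"]))}
    for term in ("b_prior", "b_lik"):
        diff = weights[term] - ideal_w[term]
        sd = float(diff.std(ddof=1))
        if sd == 0:
            t, p = np.nan, 1.0
            d = 0.0
        else:
            t, p = stats.ttest_rel(weights[term], np.full(len(weights), ideal_w[term]))
            d = float(diff.mean() / sd)
        out[term] = dict(mean_diff=float(diff.mean()), sd_diff=sd,
                         t=float(t) if np.isfinite(np.asarray(t, dtype=float)) else np.nan,
                         p=float(p), cohens_d=d)
    out["per_participant"] = weights
    return out
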