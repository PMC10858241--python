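"""Per-participant strategy models fit in probability space.

Four candidate accounts of how a responder maps the two displayed
probabilities onto a report:

* ``mean`` — unweighted average of the two probabilities (offset with a
  fixed unit coefficient) plus intercept, penalty and slider terms;
* ``weighted_bayes`` — Bayes' theorem with free exponents on the prior and
  likelihood odds (equivalently, an inverse-logit of a weighted sum of
  logits); reduces to exact Bayesian integration at unit weights;
* ``linear`` — weighted average: free linear weights on the two
  probabilities, no interaction;
* ``linear_interaction`` — weighted linear model plus a product term, whose
  predictions closely mimic Bayesian integration.

All models are fit per participant so their AIC/BIC can feed random-effects
Bayesian model selection.  The same functional forms serve the averaging task
variant, where the two probabilities are independent gallery mixtures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.optimize import least_squares

from .mixed import FitResult

__all__ = [
    "MODEL_NAMES",
    "DEFAULT_FAMILIES",
    "weighted_bayes_predict",
    "fit_participant_models",
    "fit_all_participants",
    "evidence_from_ic",
]

MODEL_NAMES = ("mean", "weighted_bayes", "linear", "linear_interaction")

#: model-space partition used for the family-level comparison: models that
#: capture a prior-likelihood interaction vs. weighted averaging without one
DEFAULT_FAMILIES = {
    "weighted_bayes": "interaction",
    "linear_interaction": "interaction",
    "linear": "averaging",
}


def weighted_bayes_predict(p1: np.ndarray, p2: np.ndarray, w_c: np.ndarray,
                           s: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Predicted report of the weighted-Bayes model.

    ``beta = (b1, b2, b0, bW, bS)``: free exponents on the odds of the two
    probabilities and a linear offset, i.e.
    ``1 - 1 / (odds(p1)**b1 * odds(p2)**b2 * exp(b0 + bW*W + bS*S) + 1)``,
    which is exactly ``inv_logit(b1*logit(p1) + b2*logit(p2) + b0 + bW*W + bS*S)``.
    """
    b1, b2, b0, bw, bs = beta
    odds1 = p1 / (1.0 - p1)
    odds2 = p2 / (1.0 - p2)
    return 1.0 - 1.0 / (odds1**b1 * odds2**b2 * np.exp(b0 + bw * w_c + bs * s) + 1.0)


def _ic_from_resid(resid: np.ndarray, k_coef: int) -> tuple[float, float, float]:
    """Gaussian ML log-likelihood and AIC/BIC; k counts coefficients + sigma."""
    n = resid.size
    s2 = max(float(resid @ resid) / n, 1e-300)
    ll = -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)
    k = k_coef + 1
    return ll, 2 * k - 2 * ll, k * np.log(n) - 2 * ll


def _ols_fit(name: str, df: pd.DataFrame, formula: str) -> FitResult:
    res = smf.ols(formula, df).fit()
    ll, aic, bic = _ic_from_resid(res.resid.to_numpy(), len(res.params))
    ci = res.conf_int()
    return FitResult(
        model_name=name,
        fixed_effects=dict(res.params),
        se=dict(res.bse),
        ci95={n: (float(ci.loc[n, 0]), float(ci.loc[n, 1])) for n in res.params.index},
        loglik=ll, aic=aic, bic=bic, n_obs=len(df), converged=True,
        re_structure="none",
    )


def _fit_weighted_bayes(df: pd.DataFrame, seed: int = 0) -> FitResult:
    y = df["report"].to_numpy()
    p1 = df["prior_q"].to_numpy()
    p2 = df["likelihood_q"].to_numpy()
    wc = df["W_c"].to_numpy()
    s = df["initial_slider"].to_numpy()

    def resid(beta):
        return weighted_bayes_predict(p1, p2, wc, s, beta) - y

    # all free parameters start at 0; jittered restarts only on failure
    starts = [np.zeros(5)]
    rng = np.random.default_rng(seed)
    starts += [0.5 * rng.standard_normal(5) for _ in range(5)]
    best, converged = None, False
    for x0 in starts:
        sol = least_squares(resid, x0, method="lm", max_nfev=10000)
        if best is None or sol.cost < best.cost - 1e-12:
            best = sol
        if sol.success:
            converged = True
            if x0 is starts[0]:
                best = sol
                break
    beta = best.x
    r = resid(beta)
    ll, aic, bic = _ic_from_resid(r, 5)
    names = ["b_prior", "b_lik", "b0", "bW", "bS"]
    # asymptotic SEs from the Gauss-Newton approximation
    J = best.jac
    try:
        cov = np.linalg.inv(J.T @ J) * (r @ r) / max(len(y) - 5, 1)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(5, np.nan)
    z = 1.959963984540054
    return FitResult(
        model_name="weighted_bayes",
        fixed_effects=dict(zip(names, map(float, beta))),
        se=dict(zip(names, map(float, se))),
        ci95={n: (float(b - z * e), float(b + z * e))
              for n, b, e in zip(names, beta, se)},
        loglik=ll, aic=aic, bic=bic, n_obs=len(y),
        converged=converged, re_structure="none",
    )


def fit_participant_models(cohort: pd.DataFrame, participant_id,
                           task: str = "inference",
                           models: tuple[str, ...] = MODEL_NAMES,
                           seed: int = 0) -> dict[str, FitResult]:
    """Fit the candidate strategy models to one participant's completed
    non-catch trials; returns {model name: FitResult} with comparable AIC/BIC."""
    if task not in ("inference", "averaging"):
        raise ValueError(f"unknown task kind {task!r}")
    sub = cohort[(cohort["participant"] == participant_id)
                 & (~cohort["is_catch"]) & (~cohort["omitted"])].copy()
    if sub.empty:
        raise ValueError(f"no completed non-catch trials for participant {participant_id}")
    sub["mu"] = 0.5 * (sub["prior_q"] + sub["likelihood_q"])
    sub["report_minus_mu"] = sub["report"] - sub["mu"]

    out: dict[str, FitResult] = {}
    for m in models:
        if m == "mean":
            out[m] = _ols_fit(m, sub, "report_minus_mu ~ W_c + initial_slider")
            # the mean term has a fixed unit coefficient: same residuals as
            # report ~ offset(mu) + ...
        elif m == "weighted_bayes":
            out[m] = _fit_weighted_bayes(sub, seed=seed)
        elif m == "linear":
            out[m] = _ols_fit(m, sub, "report ~ prior_q + likelihood_q + W_c + initial_slider")
        elif m == "linear_interaction":
            out[m] = _ols_fit(
                m, sub,
                "report ~ prior_q + likelihood_q + prior_q:likelihood_q + W_c + initial_slider")
        else:
            raise ValueError(f"unknown model {m!r}")
    return out


def fit_all_participants(cohort: pd.DataFrame, task: str = "inference",
                         models: tuple[str, ...] = MODEL_NAMES,
                         seed: int = 0) -> dict[int, dict[str, FitResult]]:
    return {
        pid: fit_participant_models(cohort, pid, task=task, models=models, seed=seed)
        for pid in sorted(cohort["participant"].unique())
    }


def evidence_from_ic(fits: dict[int, dict[str, FitResult]],
                     source: str = "bic") -> pd.DataFrame:
    """Participants x models table of approximate log-evidences (-IC/2).

    ``source`` selects the information criterion ("aic" or "bic"). The result
    carries ``.attrs['evidence_source']``.
    """
    if source not in ("aic", "bic"):
        raise ValueError("evidence source must be 'aic' or 'bic'")
    pids = sorted(fits)
    models = list(next(iter(fits.values())))
    data = np.empty((len(pids), len(models)))
    for i, pid in enumerate(pids):
        for j, m in enumerate(models):
            if m not in fits[pid]:
                raise ValueError(f"participant {pid} is missing model {m!r}")
            data[i, j] = -0.5 * getattr(fits[pid][m], source)
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite log-evidences")
    ev = pd.DataFrame(data, index=pids, columns=models)
    ev.attrs["evidence_source"] = f"-{source.upper()}/2"
    return ev
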