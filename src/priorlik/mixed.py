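"""Linear mixed-effects fits for the behavioral models.

Three models are exposed, all fit by maximum likelihood with by-participant
random effects on every term (full random-effects covariance, degrading to
diagonal and then intercept-only structures if the optimizer fails):

* posterior-weight model: logit report ~ logit objective posterior + penalty
  + initial slider.  The slope on the objective logit posterior is the
  probability-weighting parameter (1 for a perfect Bayesian; < 1 indicates
  conservatism) and the intercept is the elevation parameter.
* prior-likelihood model: logit report ~ logit prior + logit likelihood +
  penalty + initial slider, separating the weight afforded to each source.
* reaction-time model: RT ~ report^2 + report + |slider displacement| +
  |prior - likelihood|, the inverted-U difficulty signature.

Confidence intervals use the normal approximation to the ML sampling
distribution (FitResult.df_method == "normal").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "FitResult",
    "fit_posterior_weight_model",
    "fit_prior_likelihood_model",
    "fit_rt_model",
    "per_participant_weights",
]


@dataclass
class FitResult:
    """Container for any fitted model in the package."""

    model_name: str
    fixed_effects: dict[str, float]
    se: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    loglik: float
    aic: float
    bic: float
    n_obs: int
    converged: bool
    df_method: str = "normal"
    re_structure: str | None = None
    re_cov: pd.DataFrame | None = field(default=None, repr=False)
    extra: dict = field(default_factory=dict, repr=False)

    @property
    def params(self) -> dict[str, float]:
        return self.fixed_effects

    def to_dict(self) -> dict:
        return dict(
            model_name=self.model_name,
            fixed_effects=self.fixed_effects,
            se=self.se,
            ci95={k: list(v) for k, v in self.ci95.items()},
            loglik=self.loglik, aic=self.aic, bic=self.bic,
            n_obs=self.n_obs, converged=self.converged,
            df_method=self.df_method, re_structure=self.re_structure,
        )


def _gauss_loglik(resid: np.ndarray) -> float:
    n = resid.size
    s2 = float(resid @ resid) / n
    return -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)


def _ols_degenerate(model_name: str, df: pd.DataFrame, formula: str) -> FitResult:
    """Exact-fit path for noise-free data, where ML variance estimation breaks down."""
    res = smf.ols(formula, df).fit()
    fe = dict(res.params)
    k = len(fe) + 1
    ll = _gauss_loglik(res.resid.to_numpy()) if res.resid.std() > 0 else np.inf
    return FitResult(
        model_name=model_name, fixed_effects=fe,
        se={k_: 0.0 for k_ in fe}, ci95={k_: (v, v) for k_, v in fe.items()},
        loglik=ll, aic=2 * k - 2 * ll if np.isfinite(ll) else -np.inf,
        bic=k * np.log(len(df)) - 2 * ll if np.isfinite(ll) else -np.inf,
        n_obs=len(df), converged=True, re_structure="degenerate-exact",
    )


def _fit_mixed(model_name: str, df: pd.DataFrame, formula: str,
               re_terms: list[str], group_col: str = "participant") -> FitResult:
    """ML mixed fit with the fallback chain full -> diagonal -> intercept-only."""
    if df[group_col].nunique() < 2:
        raise ValueError("mixed-effects fits require at least 2 participants")

    ols_check = smf.ols(formula, df).fit()
    if float(np.std(ols_check.resid)) < 1e-10:
        return _ols_degenerate(model_name, df, formula)

    attempts: list[tuple[str, dict]] = [
        ("full", dict(re_formula="~" + " + ".join(re_terms))),
        ("diagonal", dict(re_formula="~1",
                          vc_formula={t: f"0 + {t}" for t in re_terms})),
        ("intercept", dict(re_formula="~1")),
    ]
    last = None
    for structure, kw in attempts:
        model = smf.mixedlm(formula, df, groups=df[group_col], **kw)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(reml=False, method="lbfgs", maxiter=2000)
            except (np.linalg.LinAlgError, ValueError):
                res = None
            if res is None or not res.converged:
                try:
                    res2 = model.fit(reml=False, method="powell", maxiter=5000)
                    if res2.converged or res is None:
                        res = res2
                except (np.linalg.LinAlgError, ValueError):
                    pass
        if res is None:
            continue
        last = (structure, res)
        if res.converged and np.all(np.isfinite(res.bse_fe)):
            break
    if last is None:
        raise RuntimeError(f"all random-effects structures failed for {model_name}")
    structure, res = last

    fe_names = list(res.fe_params.index)
    fe = {n: float(res.fe_params[n]) for n in fe_names}
    se = {n: float(res.bse_fe[n]) for n in fe_names}
    ci = res.conf_int()
    ci95 = {n: (float(ci.loc[n, 0]), float(ci.loc[n, 1])) for n in fe_names}
    k = res.params.size + 1  # fixed effects + covariance params + residual var
    ll = float(res.llf)
    return FitResult(
        model_name=model_name, fixed_effects=fe, se=se, ci95=ci95,
        loglik=ll, aic=2 * k - 2 * ll, bic=k * np.log(len(df)) - 2 * ll,
        n_obs=len(df), converged=bool(res.converged),
        re_structure=structure,
        re_cov=res.cov_re if structure == "full" else None,
        extra=dict(resid_var=float(res.scale)),
    )


def _completed_non_catch(cohort: pd.DataFrame, need_rt: bool = False) -> pd.DataFrame:
    m = (~cohort["is_catch"]) & (~cohort["omitted"])
    if need_rt:
        m &= cohort["rt"].notna()
    out = cohort[m].copy()
    if out.empty:
        raise ValueError("no completed non-catch trials to fit")
    return out


def fit_posterior_weight_model(cohort: pd.DataFrame) -> FitResult:
    """Probability-weighting (slope) and elevation (intercept) of the logit
    report against the objective logit posterior, controlling penalty and
    initial slider position."""
    df = _completed_non_catch(cohort)
    df = df.rename(columns={"logit_target": "logit_obj_post"})
    return _fit_mixed(
        "posterior_weight",
        df,
        "logit_report ~ logit_obj_post + W_c + initial_slider",
        ["logit_obj_post", "W_c", "initial_slider"],
    )


def fit_prior_likelihood_model(cohort: pd.DataFrame) -> FitResult:
    """Separate weights on the logit prior and logit likelihood (both 1 for a
    perfect Bayesian), controlling penalty and initial slider position."""
    df = _completed_non_catch(cohort)
    return _fit_mixed(
        "prior_likelihood",
        df,
        "logit_report ~ logit_prior_q + logit_lik_q + W_c + initial_slider",
        ["logit_prior_q", "logit_lik_q", "W_c", "initial_slider"],
    )


def fit_rt_model(cohort: pd.DataFrame) -> FitResult:
    """Inverted-U reaction-time model (negative coefficient on the squared
    report), controlling slider travel and the prior-likelihood discrepancy."""
    df = _completed_non_catch(cohort, need_rt=True)
    return _fit_mixed(
        "reaction_time",
        df,
        "rt ~ report_sq + report + abs_displacement + abs_prior_lik_diff",
        ["report_sq", "report", "abs_displacement", "abs_prior_lik_diff"],
    )


def per_participant_weights(cohort: pd.DataFrame) -> pd.DataFrame:
    """Ordinary per-participant regressions of the prior-likelihood model;
    returns one row per participant with the four coefficient estimates."""
    df = _completed_non_catch(cohort)
    rows = []
    for pid, sub in df.groupby("participant"):
        res = smf.ols("logit_report ~ logit_prior_q + logit_lik_q + W_c + initial_slider",
                      sub).fit()
        rows.append(dict(participant=pid,
                         intercept=res.params["Intercept"],
                         b_prior=res.params["logit_prior_q"],
                         b_lik=res.params["logit_lik_q"],
                         bW=res.params["W_c"],
                         bS=res.params["initial_slider"]))
    return pd.DataFrame(rows)
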