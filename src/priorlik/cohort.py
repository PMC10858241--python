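"""Synthetic responders: approximate-Bayesian participants, ideal observers,
and mean-responders, with reaction times and omissions.

The generative response model mirrors the fitted one: a participant's latent
logit report is a weighted sum of the logit prior and logit likelihood of the
questioned category, plus small penalty and initial-slider effects and
additive Gaussian noise on the logit scale, then discretized onto the slider
grid.  Reaction time follows an inverted-U in the reported probability
(slowest near 0.5, i.e., maximal uncertainty) with additive contributions of
slider travel and the prior-likelihood discrepancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .session import SessionPlan
from .task import inv_logit, logit, make_slider_grid, snap_to_grid

__all__ = [
    "ParticipantParams",
    "CohortConfig",
    "draw_participants",
    "simulate_response",
    "simulate_rt",
    "simulate_cohort",
    "ideal_observer_cohort",
    "mean_responder_cohort",
    "participants_to_frame",
    "W_CENTER",
]

#: penalty is centered at this many dollars in generative and fitted models,
#: so intercepts refer to the mid-penalty condition
W_CENTER = 15.0


@dataclass(frozen=True)
class ParticipantParams:
    """Generative coefficients for one simulated responder."""

    b0: float = 0.07            # logit-scale elevation (overestimation bias)
    b_prior: float = 0.66       # weight on logit prior
    b_lik: float = 0.50         # weight on logit likelihood
    bW: float = 0.01            # per centered dollar of penalty
    bS: float = 0.0             # per unit of initial slider position
    sigma_resp: float = 0.6     # logit-scale response noise SD
    rt_a0: float = 3.0          # RT intercept, seconds
    rt_quad: float = -5.88      # coefficient of report^2 (inverted U: <= 0)
    rt_lin: float = 5.88        # coefficient of report
    rt_aD: float = 1.0          # seconds per unit |slider displacement|
    rt_adiff: float = 0.5       # seconds per unit |prior - likelihood|
    sigma_rt: float = 1.0       # RT noise SD, seconds
    omission_rate: float = 10.0 / 2990.0

    def __post_init__(self) -> None:
        if self.sigma_resp < 0 or self.sigma_rt < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.rt_quad > 0:
            raise ValueError("rt_quad must be <= 0 (inverted-U reaction times)")
        if not 0 <= self.omission_rate < 1:
            raise ValueError("omission_rate must lie in [0, 1)")


@dataclass(frozen=True)
class CohortConfig:
    """Population hyper-distribution: each coefficient is drawn
    independently normal with the given (mean, SD) per participant."""

    n_participants: int = 23
    b0: tuple[float, float] = (0.07, 0.1)
    b_prior: tuple[float, float] = (0.66, 0.2)
    b_lik: tuple[float, float] = (0.50, 0.2)
    bW: tuple[float, float] = (0.01, 0.005)
    bS: tuple[float, float] = (0.0, 0.05)
    sigma_resp: float = 0.6
    rt_a0: tuple[float, float] = (3.0, 0.5)
    rt_quad: tuple[float, float] = (-5.88, 1.0)
    rt_lin: tuple[float, float] = (5.88, 1.0)
    rt_aD: tuple[float, float] = (1.0, 0.3)
    rt_adiff: tuple[float, float] = (0.5, 0.2)
    sigma_rt: float = 1.0
    omission_rate: float = 10.0 / 2990.0

    def validate(self) -> None:
        for name in ("b0", "b_prior", "b_lik", "bW", "bS",
                     "rt_a0", "rt_quad", "rt_lin", "rt_aD", "rt_adiff"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"hyper-SD for {name} must be non-negative")
        if self.sigma_resp < 0 or self.sigma_rt < 0:
            raise ValueError("noise SDs must be non-negative")


def draw_participants(n: int, hyper: CohortConfig | None = None,
                      rng: np.random.Generator | None = None) -> list[ParticipantParams]:
    """Independent draws from the population hyper-distribution."""
    hyper = hyper or CohortConfig()
    hyper.validate()
    if n < 1:
        raise ValueError("need at least one participant")
    rng = rng if rng is not None else np.random.default_rng()

    def draw(ms: tuple[float, float]) -> float:
        return float(rng.normal(*ms))

    out = []
    for _ in range(n):
        quad = draw(hyper.rt_quad)
        while quad > 0:  # inverted-U constraint
            quad = draw(hyper.rt_quad)
        out.append(ParticipantParams(
            b0=draw(hyper.b0), b_prior=draw(hyper.b_prior), b_lik=draw(hyper.b_lik),
            bW=draw(hyper.bW), bS=draw(hyper.bS), sigma_resp=hyper.sigma_resp,
            rt_a0=draw(hyper.rt_a0), rt_quad=quad, rt_lin=draw(hyper.rt_lin),
            rt_aD=draw(hyper.rt_aD), rt_adiff=draw(hyper.rt_adiff),
            sigma_rt=hyper.sigma_rt, omission_rate=hyper.omission_rate,
        ))
    return out


def participants_to_frame(participants: list[ParticipantParams]) -> pd.DataFrame:
    df = pd.DataFrame([vars(p) for p in participants])
    df.insert(0, "participant", np.arange(1, len(df) + 1))
    return df


def simulate_response(trial: pd.Series, params: ParticipantParams,
                      rng: np.random.Generator, snap: bool = True) -> float:
    """One report: latent logit draw, inverse-logit, grid snap; NaN if omitted."""
    if rng.random() < params.omission_rate:
        return np.nan
    z = (params.b0
         + params.b_prior * trial["logit_prior_q"]
         + params.b_lik * trial["logit_lik_q"]
         + params.bW * (trial["penalty"] - W_CENTER)
         + params.bS * trial["initial_slider"]
         + params.sigma_resp * rng.standard_normal())
    p = inv_logit(z)
    return snap_to_grid(p, make_slider_grid()) if snap else float(p)


def simulate_rt(pi: float, displacement: float, abs_prior_lik_diff: float,
                params: ParticipantParams, rng: np.random.Generator,
                floor: float = 0.2, ceiling: float = 15.0) -> float:
    """Reaction time from the inverted-U model, truncated into (floor, ceiling]
    by resampling the noise term."""
    mean = (params.rt_a0 + params.rt_quad * pi**2 + params.rt_lin * pi
            + params.rt_aD * abs(displacement)
            + params.rt_adiff * abs_prior_lik_diff)
    if params.sigma_rt == 0:
        return float(np.clip(mean, floor + 1e-9, ceiling))
    for _ in range(1000):
        rt = mean + params.sigma_rt * rng.standard_normal()
        if floor < rt <= ceiling:
            return float(rt)
    return float(np.clip(mean, floor + 1e-9, ceiling))


def _vector_responses(plan: SessionPlan, params: ParticipantParams,
                      rng: np.random.Generator, snap: bool) -> np.ndarray:
    """Vectorized equivalent of calling :func:`simulate_response` per trial."""
    t = plan.trials
    n = len(t)
    z = (params.b0
         + params.b_prior * t["logit_prior_q"].to_numpy()
         + params.b_lik * t["logit_lik_q"].to_numpy()
         + params.bW * (t["penalty"].to_numpy() - W_CENTER)
         + params.bS * t["initial_slider"].to_numpy()
         + params.sigma_resp * rng.standard_normal(n))
    p = inv_logit(z)
    if snap:
        p = snap_to_grid(p, make_slider_grid())
    omitted = rng.random(n) < params.omission_rate
    return np.where(omitted, np.nan, p)


def _assemble(plan: SessionPlan, reports_by_participant: list[np.ndarray],
              rts_by_participant: list[np.ndarray]) -> pd.DataFrame:
    frames = []
    for i, (rep, rts) in enumerate(zip(reports_by_participant, rts_by_participant), start=1):
        df = plan.trials.copy()
        df.insert(0, "participant", i)
        df["report"] = rep
        df["rt"] = rts
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["omitted"] = out["report"].isna()
    ok = ~out["omitted"]
    out["displacement"] = np.where(ok, out["report"] - out["initial_slider"], np.nan)
    out["W_c"] = out["penalty"] - W_CENTER
    out["logit_report"] = np.nan
    out.loc[ok, "logit_report"] = logit(out.loc[ok, "report"].to_numpy())
    out["abs_logit_report"] = out["logit_report"].abs()
    out["abs_prior_lik_diff"] = (out["prior_q"] - out["likelihood_q"]).abs()
    out["report_sq"] = out["report"] ** 2
    out["abs_displacement"] = out["displacement"].abs()
    return out


def simulate_cohort(plan: SessionPlan, participants: list[ParticipantParams],
                    rng: np.random.Generator, snap: bool = True) -> pd.DataFrame:
    """Simulate every participant on the shared trial set.

    Returns the long-format cohort table: one row per participant x trial with
    the trial design columns, the report, reaction time, and derived analysis
    columns (logit report, slider displacement, |prior - likelihood|, ...).
    """
    reports, rts = [], []
    for params in participants:
        rep = _vector_responses(plan, params, rng, snap)
        ok = ~np.isnan(rep)
        rt = np.full(len(rep), np.nan)
        t = plan.trials
        for j in np.flatnonzero(ok):
            rt[j] = simulate_rt(
                rep[j], rep[j] - t["initial_slider"].iat[j],
                abs(t["prior_q"].iat[j] - t["likelihood_q"].iat[j]),
                params, rng)
        reports.append(rep)
        rts.append(rt)
    return _assemble(plan, reports, rts)


def ideal_observer_cohort(plan: SessionPlan, n_participants: int = 23) -> pd.DataFrame:
    """Deterministic responders that report the grid value nearest the
    objective target (the Bayesian posterior, or the prior on catch trials)."""
    grid = make_slider_grid()
    rep = snap_to_grid(plan.trials["target"].to_numpy(), grid)
    t = plan.trials
    params = ParticipantParams(sigma_rt=0.0)
    rt = np.array([
        simulate_rt(rep[j], rep[j] - t["initial_slider"].iat[j],
                    abs(t["prior_q"].iat[j] - t["likelihood_q"].iat[j]),
                    params, np.random.default_rng(0))
        for j in range(len(rep))
    ])
    return _assemble(plan, [rep] * n_participants, [rt] * n_participants)


def mean_responder_cohort(plan: SessionPlan, rng: np.random.Generator,
                          n_participants: int = 23, noise_sd: float = 0.05) -> pd.DataFrame:
    """Responders that average the two displayed probabilities (plus
    probability-scale noise) instead of integrating them; on catch trials they
    report the prior."""
    grid = make_slider_grid()
    t = plan.trials
    base = np.where(t["is_catch"], t["prior_q"], 0.5 * (t["prior_q"] + t["likelihood_q"]))
    params = ParticipantParams(sigma_rt=0.0)
    reports, rts = [], []
    for _ in range(n_participants):
        rep = snap_to_grid(np.clip(base + noise_sd * rng.standard_normal(len(t)), 0.0, 1.0), grid)
        rt = np.array([
            simulate_rt(rep[j], rep[j] - t["initial_slider"].iat[j],
                        abs(t["prior_q"].iat[j] - t["likelihood_q"].iat[j]),
                        params, rng)
            for j in range(len(rep))
        ])
        reports.append(rep)
        rts.append(rt)
    return _assemble(plan, reports, rts)
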