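"""Session (trial-set) generation, design diagnostics, payout simulation, and I/O.

A session is 130 trials: 120 non-catch trials built from 60 unique
prior-evidence "cores" duplicated over the two penalty levels, plus 10 catch
trials (prior only, two per prior bin, one per penalty).  Prior and evidence
strength are drawn from discrete bins, jittered by up to +/-0.03, and the
prior-evidence design is balanced so that prior probabilities and likelihoods
are uncorrelated across the session.  Trials run in four runs of
32/33/32/33 with the questioned gallery alternating by run.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .task import (
    SliderGrid,
    ideal_ev,
    likelihood_from_theta,
    logit,
    make_slider_grid,
    objective_posterior,
    p_loss,
)

__all__ = [
    "SessionConfig",
    "SessionPlan",
    "DesignDiagnostics",
    "generate_session",
    "generate_averaging_session",
    "session_diagnostics",
    "simulate_payout",
    "read_session_tsv",
    "load_supplementary_trials",
]

PORTRAIT, LANDSCAPE = "portrait", "landscape"
FACE, PLACE = "face", "place"

#: columns that define a trial, in on-disk order
TRIAL_COLUMNS = [
    "trial_id", "run", "is_catch", "questioned_gallery", "prior_portrait",
    "theta", "sample_category", "hidden_gallery", "penalty", "initial_slider",
    "iti_s", "temporal_order", "spatial_order", "sample_side",
]
_PROB_COLUMNS = ("prior_portrait", "theta", "initial_slider")


@dataclass(frozen=True)
class SessionConfig:
    """Design parameters for one session; defaults reproduce the study design."""

    prior_bins: Sequence[float] = (0.1, 0.4, 0.5, 0.6, 0.9)
    theta_bins: Sequence[float] = (0.6, 0.8, 0.9)
    jitters: Sequence[float] = (-0.03, -0.02, -0.01, 0.0, 0.01, 0.02, 0.03)
    penalties: Sequence[float] = (10.0, 20.0)
    endowment: float = 30.0
    n_cores: int = 60
    catch_per_bin_per_penalty: int = 1
    run_sizes: Sequence[int] = (32, 33, 32, 33)
    iti_mean: float = 3.5
    iti_bounds: tuple[float, float] = (1.0, 10.0)
    response_window: float = 15.0
    task: str = "inference"  # or "averaging"

    def validate(self) -> None:
        if max(self.penalties) > self.endowment:
            raise ValueError("penalty exceeds endowment")
        for b in self.prior_bins:
            if not 0.0 < b < 1.0:
                raise ValueError("prior bins must lie in (0, 1)")
        for b in self.theta_bins:
            if not 0.5 < b + min(self.jitters) or not b + max(self.jitters) < 1.0:
                raise ValueError("theta bins +/- jitter must stay in (0.5, 1)")
        n_combos = len(self.prior_bins) * len(self.theta_bins)
        if self.n_cores % n_combos:
            raise ValueError("n_cores must be a multiple of the number of prior x theta bins")
        if self.task not in ("inference", "averaging"):
            raise ValueError(f"unknown task kind {self.task!r}")


@dataclass
class SessionPlan:
    """One session's full trial table plus session-level metadata.

    ``trials`` carries the raw design columns (:data:`TRIAL_COLUMNS`) and
    derived analysis columns (prior/likelihood of the questioned category in
    probability and logit space, the objective target, and per-trial ideal
    expected value).
    """

    trials: pd.DataFrame
    endowment: float
    run_sizes: tuple[int, ...]
    seed: int | None
    task: str = "inference"
    source: str = "generated"

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def non_catch(self) -> pd.DataFrame:
        return self.trials[~self.trials["is_catch"]]

    def to_tsv(self, path: str | Path | None = None) -> str | None:
        """Serialize losslessly (probabilities at 6 decimals; metadata in # header)."""
        buf = io.StringIO()
        buf.write(f"# endowment={self.endowment:.2f}\n")
        buf.write(f"# seed={'' if self.seed is None else self.seed}\n")
        buf.write(f"# task={self.task}\n")
        buf.write(f"# run_sizes={','.join(str(r) for r in self.run_sizes)}\n")
        out = self.trials[TRIAL_COLUMNS].copy()
        for c in _PROB_COLUMNS:
            out[c] = out[c].map(lambda v: "" if pd.isna(v) else f"{v:.6f}")
        out["iti_s"] = out["iti_s"].map(lambda v: f"{v:.6f}")
        out.to_csv(buf, sep="\t", index=False)
        text = buf.getvalue()
        if path is None:
            return text
        Path(path).write_text(text)
        return None


@dataclass(frozen=True)
class DesignDiagnostics:
    """Pearson correlations among design quantities over non-catch trials."""

    r_prior_lik_prob: float
    r_prior_lik_logit: float
    r_ev_posterior: float
    n_trials_used: int
    degenerate: bool = False


def _truncated_exponential(rng: np.random.Generator, mean: float,
                           bounds: tuple[float, float], size: int) -> np.ndarray:
    """Exponential ITIs truncated into [lo, hi] by rejection sampling."""
    lo, hi = bounds
    out = np.empty(size)
    need = np.arange(size)
    while need.size:
        draw = rng.exponential(mean, size=need.size)
        ok = (draw >= lo) & (draw <= hi)
        out[need[ok]] = draw[ok]
        need = need[~ok]
    return out


def _derive_columns(df: pd.DataFrame, task: str, endowment: float) -> pd.DataFrame:
    """Attach analysis columns w.r.t. the questioned category."""
    df = df.copy()
    q_is_portrait = df["questioned_gallery"].eq(PORTRAIT).to_numpy()
    prior_q = np.where(q_is_portrait, df["prior_portrait"], 1.0 - df["prior_portrait"])
    catch = df["is_catch"].to_numpy()

    lik_q = np.full(len(df), 0.5)
    nc = ~catch
    if nc.any():
        sample_signals_q = np.where(
            q_is_portrait[nc],
            df.loc[nc, "sample_category"].eq(FACE),
            df.loc[nc, "sample_category"].eq(PLACE),
        )
        lik_q[nc] = likelihood_from_theta(df.loc[nc, "theta"].to_numpy(), sample_signals_q)

    df["prior_q"] = prior_q
    df["likelihood_q"] = lik_q
    df["logit_prior_q"] = logit(prior_q)
    # catch trials carry no likelihood information, equivalent to lik = 0.5
    df["logit_lik_q"] = logit(lik_q)
    if task == "averaging":
        target = np.where(catch, prior_q, 0.5 * (prior_q + lik_q))
    else:
        target = objective_posterior(prior_q, lik_q)
    df["target"] = target
    df["logit_target"] = logit(target)
    df["ideal_ev"] = ideal_ev(target, endowment, df["penalty"].to_numpy())
    return df


def generate_session(seed: int, config: SessionConfig | None = None) -> SessionPlan:
    """Construct a randomized session, reproducible from ``seed``.

    Non-catch construction: each prior-bin x theta-bin combination is used
    equally often among the ``n_cores`` unique cores (balanced tiling keeps
    prior and likelihood uncorrelated by design); each core's prior and theta
    receive independent uniform jitters; a hidden gallery is drawn from the
    (portrait) prior; the sample signals the hidden gallery with probability
    theta; the cores are then duplicated over the two penalty levels.  Catch
    trials carry a jittered prior only.  Trial order is globally permuted and
    split into runs, with the questioned gallery fixed per run (portrait on
    runs 1 and 3).
    """
    config = config or SessionConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    grid = make_slider_grid()

    combos = list(product(config.prior_bins, config.theta_bins))
    reps = config.n_cores // len(combos)
    cores = []
    core_id = 0
    for pb, tb in combos:
        # sample category is balanced within each prior x theta design cell so
        # that likelihood and prior are uncorrelated across the session (the
        # design requirement); the hidden gallery is then drawn from its Bayes
        # posterior given the sample, so hidden-state frequencies stay
        # consistent with the displayed prior and evidence strength
        samples = np.array([FACE, PLACE] * ((reps + 1) // 2))[:reps]
        rng.shuffle(samples)
        for sample in samples:
            prior = pb + rng.choice(config.jitters)
            theta = tb + rng.choice(config.jitters)
            assert 0.5 < theta < 1.0, "jittered theta left (0.5, 1)"
            lik_portrait = theta if sample == FACE else 1.0 - theta
            post_portrait = objective_posterior(prior, lik_portrait)
            hidden = PORTRAIT if rng.random() < post_portrait else LANDSCAPE
            cores.append((core_id, prior, theta, hidden, sample))
            core_id += 1

    rows = []
    for W in config.penalties:
        for core_id, prior, theta, hidden, sample in cores:
            rows.append(dict(is_catch=False, core_id=core_id, prior_portrait=prior,
                             theta=theta, sample_category=sample, hidden_gallery=hidden,
                             penalty=float(W)))
    for _ in range(config.catch_per_bin_per_penalty):
        for W in config.penalties:
            for pb in config.prior_bins:
                prior = pb + rng.choice(config.jitters)
                hidden = PORTRAIT if rng.random() < prior else LANDSCAPE
                rows.append(dict(is_catch=True, core_id=-1, prior_portrait=prior,
                                 theta=np.nan, sample_category="", hidden_gallery=hidden,
                                 penalty=float(W)))

    df = pd.DataFrame(rows)
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)

    run_sizes = tuple(config.run_sizes)
    if sum(run_sizes) != len(df):
        raise ValueError("run sizes do not sum to the trial count")
    run = np.repeat(np.arange(1, len(run_sizes) + 1), run_sizes)
    df["run"] = run
    # questioned category alternates by run (first framing on runs 1 and 3)
    df["questioned_gallery"] = np.where(run % 2 == 1, PORTRAIT, LANDSCAPE)
    df["trial_id"] = np.arange(1, len(df) + 1)
    df["initial_slider"] = rng.choice(grid.values, size=len(df))
    df["iti_s"] = _truncated_exponential(rng, config.iti_mean, config.iti_bounds, len(df))
    # presentation metadata: temporal order of (prior, likelihood, penalty) is
    # randomized per trial; spatial layout is fixed within a session
    df["temporal_order"] = rng.integers(0, 6, size=len(df))
    df["spatial_order"] = int(rng.integers(0, 4))
    # side of the screen the sample picture appears on (+1 right, -1 left)
    df["sample_side"] = rng.choice([-1, 1], size=len(df))

    df = _derive_columns(df, config.task, config.endowment)
    df = df[TRIAL_COLUMNS + ["core_id", "prior_q", "likelihood_q", "logit_prior_q",
                             "logit_lik_q", "target", "logit_target", "ideal_ev"]]
    return SessionPlan(trials=df, endowment=config.endowment, run_sizes=run_sizes,
                       seed=seed, task=config.task)


def generate_averaging_session(seed: int, config: SessionConfig | None = None) -> SessionPlan:
    """Averaging-variant session: same structure, but the two displayed
    probabilities are independent gallery mixtures and the correct response is
    their mean (the first gallery's value alone on catch trials)."""
    config = replace(config or SessionConfig(), task="averaging")
    return generate_session(seed, config)


def session_diagnostics(plan: SessionPlan) -> DesignDiagnostics:
    """Design correlations over non-catch trials.

    Checks that prior and likelihood are uncorrelated (probability and logit
    space) and that per-trial ideal expected value is uncorrelated with the
    objective posterior (the scoring rule makes EV a U-shaped, not linear,
    function of the posterior).
    """
    nc = plan.non_catch
    if len(nc) < 3:
        raise ValueError("need at least 3 non-catch trials")
    cols = [
        (nc["prior_q"], nc["likelihood_q"]),
        (nc["logit_prior_q"], nc["logit_lik_q"]),
        (nc["ideal_ev"], nc["target"]),
    ]
    rs, degenerate = [], False
    for a, b in cols:
        if np.std(a) < 1e-12 or np.std(b) < 1e-12:
            rs.append(np.nan)
            degenerate = True
        else:
            rs.append(float(np.corrcoef(a, b)[0, 1]))
    return DesignDiagnostics(*rs, n_trials_used=len(nc), degenerate=degenerate)


def simulate_payout(plan: SessionPlan, reports: pd.Series | np.ndarray,
                    rng: np.random.Generator) -> float:
    """Payout stage: one trial is selected uniformly; an omitted response
    forfeits the penalty outright, otherwise the penalty is lost with
    probability equal to the squared report error.  Returns dollars.

    ``reports`` aligns with ``plan.trials`` rows; NaN marks an omission.
    """
    reports = np.asarray(reports, dtype=float)
    if reports.size == 0:
        raise ValueError("no responses to pay out")
    if reports.size != plan.n_trials:
        raise ValueError("one response per trial required (NaN for omissions)")
    idx = int(rng.integers(0, plan.n_trials))
    trial = plan.trials.iloc[idx]
    # money in integer cents to keep payouts exact
    endow_c = round(plan.endowment * 100)
    penalty_c = round(trial["penalty"] * 100)
    pi = reports[idx]
    if np.isnan(pi):
        return (endow_c - penalty_c) / 100.0
    I = int(trial["hidden_gallery"] == trial["questioned_gallery"])
    lost = rng.random() < p_loss(I, pi)
    return (endow_c - penalty_c) / 100.0 if lost else endow_c / 100.0


def read_session_tsv(path: str | Path) -> SessionPlan:
    """Inverse of :meth:`SessionPlan.to_tsv` (lossless round trip)."""
    text = Path(path).read_text()
    meta: dict[str, str] = {}
    lines = text.splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("# "):
            k, _, v = line[2:].partition("=")
            meta[k] = v
        else:
            body_start = i
            break
    df = pd.read_csv(io.StringIO("\n".join(lines[body_start:])), sep="\t")
    df["sample_category"] = df["sample_category"].fillna("")
    df["is_catch"] = df["is_catch"].astype(bool)
    task = meta.get("task", "inference")
    endowment = float(meta.get("endowment", 30.0))
    df = _derive_columns(df, task, endowment)
    seed_s = meta.get("seed", "")
    return SessionPlan(
        trials=df,
        endowment=endowment,
        run_sizes=tuple(int(x) for x in meta.get("run_sizes", "").split(",") if x),
        seed=int(seed_s) if seed_s else None,
        task=task,
        source=str(path),
    )


#: our column name -> likely external names for a published trial-parameter table
_DEFAULT_COLUMN_MAP = {c: c for c in TRIAL_COLUMNS}


def load_supplementary_trials(path: str | Path, column_map: dict[str, str] | None = None,
                              endowment: float = 30.0, task: str = "inference",
                              sep: str | None = None) -> SessionPlan:
    """Load an externally published trial-parameter table as a SessionPlan.

    ``column_map`` maps our canonical column names (:data:`TRIAL_COLUMNS`) to
    the file's column names; unmapped optional columns are filled with
    defaults.  Catch rows may leave ``theta`` empty; their likelihood is
    treated as 0.5.
    """
    colmap = dict(_DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)
    raw = pd.read_csv(path, sep=sep, engine="python")
    required = ["prior_portrait", "penalty", "questioned_gallery"]
    missing = [ours for ours in required if colmap[ours] not in raw.columns]
    if missing:
        raise ValueError(f"external trial table is missing required columns: {missing}")

    df = pd.DataFrame()
    for ours, theirs in colmap.items():
        if theirs in raw.columns:
            df[ours] = raw[theirs]
    n = len(df)
    if "theta" not in df:
        df["theta"] = np.nan
    if "is_catch" in df:
        df["is_catch"] = df["is_catch"].astype(bool)
    else:
        df["is_catch"] = df["theta"].isna()
    df.loc[df["is_catch"], "theta"] = np.nan
    defaults = dict(trial_id=np.arange(1, n + 1), run=1, sample_category="",
                    hidden_gallery="", initial_slider=np.nan, iti_s=np.nan,
                    temporal_order=0, spatial_order=0, sample_side=1)
    for c, v in defaults.items():
        if c not in df:
            df[c] = v
    df["sample_category"] = df["sample_category"].fillna("")
    bad = (df["prior_portrait"] <= 0) | (df["prior_portrait"] >= 1)
    if bad.any():
        raise ValueError("malformed prior probabilities outside (0, 1)")
    nc = ~df["is_catch"]
    if ((df.loc[nc, "theta"] <= 0.5) | (df.loc[nc, "theta"] >= 1)).any():
        raise ValueError("malformed evidence strengths outside (0.5, 1)")
    df = _derive_columns(df, task, endowment)
    return SessionPlan(trials=df, endowment=endowment, run_sizes=(),
                       seed=None, task=task, source=f"external:{path}")
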