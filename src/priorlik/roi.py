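"""ROI-scale GLM analysis: HRF, decision-period designs with parametric
modulators, synthetic BOLD, group tests, and the prior/likelihood
label-permutation null.

The designs model the decision period (slider onset to response) of each
completed non-catch trial as a boxcar convolved with a canonical double-gamma
HRF.  Trial-varying covariates enter as parametric modulators: the boxcar
multiplied by the (z-scored) covariate before convolution, with no
orthogonalization, so correlated modulators stay correlated in the design.
Catch trials get their own unmodulated epoch regressor, omitted trials a
separate full-window regressor.

The permutation null asks whether apparent prior and likelihood responses
could be epiphenomena of a pure posterior code: each trial's logit prior and
logit likelihood labels are swapped with probability 1/2 (their sum, the
logit posterior, is unchanged), the design is rebuilt, and the group-level
coefficients refit.  True separate encodings land outside this null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import kstest_normal

from .session import SessionPlan
from .task import subjective_ev

__all__ = [
    "hrf_kernel",
    "GLM_VARIANTS",
    "DesignMatrix",
    "build_design",
    "group_z_stats",
    "simulate_bold",
    "fit_glm",
    "group_test",
    "GLMResult",
    "PermutationNull",
    "permutation_null_prior_lik",
    "brain_behavior_correlation",
]

# canonical double-gamma parameters: response/undershoot delays 6 s and 16 s,
# unit dispersions, peak:undershoot ratio 6, 32-s support
_HRF_PEAK_DELAY = 6.0
_HRF_UNDER_DELAY = 16.0
_HRF_RATIO = 6.0
_HRF_LEN = 32.0

GLM_VARIANTS = ("froi1", "froi2", "froi3", "quadratic", "truncated", "wb1")

#: decision onset lags trial start by the three 1-s-spaced information
#: components plus 1 s to slider onset
_PRE_SLIDER = 3.0
_POST_WINDOW = 0.5


def hrf_kernel(tr: float) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``tr`` seconds over 32 s,
    normalized to unit peak."""
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(0.0, _HRF_LEN + tr / 2, tr)
    h = stats.gamma.pdf(t, _HRF_PEAK_DELAY) - stats.gamma.pdf(t, _HRF_UNDER_DELAY) / _HRF_RATIO
    return h / h.max()


def _decision_epochs(trials: pd.DataFrame, responses: pd.DataFrame,
                     response_window: float = 15.0):
    """Per-trial decision-period (onset, duration) plus total session length.

    Omitted trials get the full response window as their epoch.
    """
    merged = trials.merge(responses, on="trial_id", how="left", suffixes=("", "_r"))
    responded = merged["report"].notna() & merged["rt"].notna()
    durations = np.where(responded, merged["rt"], response_window)
    # trial length = pre-slider components + full response window + hold + ITI
    trial_len = _PRE_SLIDER + response_window + _POST_WINDOW + merged["iti_s"].to_numpy()
    starts = np.concatenate([[0.0], np.cumsum(trial_len)[:-1]])
    merged["onset"] = starts + _PRE_SLIDER
    merged["duration"] = durations
    return merged, float(starts[-1] + trial_len[-1])


def _convolve_epochs(onsets: np.ndarray, durations: np.ndarray, total_s: float,
                     tr: float, oversampling: int = 10) -> np.ndarray:
    """(volumes x epochs) matrix: each column is one epoch's boxcar convolved
    with the HRF, sampled at volume times.

    A boxcar convolved with h is the difference of two shifted copies of h's
    running integral, so each column is two table lookups instead of an FFT.
    The dt factor approximates the continuous convolution integral, keeping
    regressor amplitudes independent of the oversampling rate.
    """
    dt = tr / oversampling
    h = hrf_kernel(dt)
    F = np.concatenate([np.cumsum(h) * dt, [np.sum(h) * dt]])  # running integral
    LH = len(h)
    i0 = np.round(np.asarray(onsets) / dt).astype(np.int64)
    i1 = np.maximum(np.round((np.asarray(onsets) + np.asarray(durations)) / dt).astype(np.int64),
                    i0 + 1)
    n_vols = int(np.ceil(total_s / tr))
    v = (np.arange(n_vols) * oversampling)[:, None]

    def G(u: np.ndarray) -> np.ndarray:
        vals = F[np.clip(u, 0, LH)]
        return np.where(u < 0, 0.0, vals)

    return G(v - i0[None, :]) - G(v - i1[None, :])


def _modulator_table(merged: pd.DataFrame, variant: str, endowment: float) -> pd.DataFrame:
    """Raw (pre-z-scoring) parametric modulators for one GLM variant, indexed
    like ``merged`` (completed non-catch trials only are meaningful)."""
    m = pd.DataFrame(index=merged.index)
    if variant == "froi1":
        m["logit_obj_post"] = merged["logit_target"]
        m["penalty"] = merged["penalty"]
        m["displacement"] = merged["displacement"]
    elif variant == "froi2":
        m["logit_prior"] = merged["logit_prior_q"]
        m["logit_lik"] = merged["logit_lik_q"]
        m["penalty"] = merged["penalty"]
        m["displacement"] = merged["displacement"]
    elif variant == "froi3":
        m["logit_subj_post"] = merged["logit_report"]
        m["penalty"] = merged["penalty"]
        m["displacement"] = merged["displacement"]
    elif variant == "quadratic":
        m["logit_subj_post"] = merged["logit_report"]
        m["logit_subj_post_sq"] = merged["logit_report"] ** 2
        m["penalty"] = merged["penalty"]
        m["displacement"] = merged["displacement"]
    elif variant == "truncated":
        m["logit_subj_post"] = merged["logit_report"]
        m["penalty"] = merged["penalty"]
        m["displacement"] = merged["displacement"]
    elif variant == "wb1":
        lr = merged["logit_report"]
        m["abs_logit_subj_post"] = lr.abs()
        m["favored_dummy"] = np.where(merged["report"] >= 0.5, 1.0, -1.0)
        m["sample_side"] = merged["sample_side"]
        m["penalty"] = merged["penalty"]
        m["logit_subj_post"] = lr
        rep = merged["report"].to_numpy()
        ev = np.full(len(merged), np.nan)
        ok = ~np.isnan(rep)
        ev[ok] = subjective_ev(rep[ok], endowment, merged["penalty"].to_numpy()[ok])
        m["subjective_ev"] = ev
        m["initial_slider"] = merged["initial_slider"]
    else:
        raise ValueError(f"unknown GLM variant {variant!r}; choose from {GLM_VARIANTS}")
    return m


def _included_mask(merged: pd.DataFrame, variant: str) -> np.ndarray:
    ok = (~merged["is_catch"]) & merged["report"].notna()
    if variant == "truncated":
        ok &= merged["report"] < 0.8
    return ok.to_numpy()


@dataclass
class DesignMatrix:
    """A built design: the matrix plus the pieces needed to rebuild modulator
    columns cheaply (per-trial convolved boxcar basis and z-scoring stats)."""

    X: pd.DataFrame
    C: np.ndarray = field(repr=False)          # volumes x modulated trials
    trial_ids: np.ndarray                      # trial ids behind C's columns
    modulators_raw: pd.DataFrame = field(repr=False)
    z_stats: dict[str, tuple[float, float]]
    variant: str
    tr: float

    @property
    def n_volumes(self) -> int:
        return len(self.X)

    def modulator_columns(self) -> list[str]:
        return list(self.modulators_raw.columns)


def group_z_stats(plan: SessionPlan, cohort: pd.DataFrame, variant: str) -> dict:
    """Pooled (group-level) mean/SD for each modulator across all
    participants' included trials; feeding these into :func:`build_design`
    implements group-scope z-scoring."""
    stats_: dict[str, tuple[float, float]] = {}
    tabs = []
    for pid, sub in cohort.groupby("participant"):
        resp = sub[["trial_id", "report", "rt", "displacement", "logit_report"]]
        merged, _ = _decision_epochs(plan.trials, resp)
        tab = _modulator_table(merged, variant, plan.endowment)
        tabs.append(tab[_included_mask(merged, variant)])
    pooled = pd.concat(tabs, ignore_index=True)
    for c in pooled.columns:
        stats_[c] = (float(pooled[c].mean()), float(pooled[c].std(ddof=0)))
    return stats_


def build_design(plan: SessionPlan, responses: pd.DataFrame, variant: str = "froi2",
                 tr: float = 1.0, z_stats: dict | None = None,
                 oversampling: int = 10) -> DesignMatrix:
    """Build a decision-period design for one participant.

    ``responses`` needs columns trial_id, report, rt, displacement (a cohort
    table slice works).  ``z_stats`` (from :func:`group_z_stats`) selects
    group-scope z-scoring; by default modulators are z-scored within this
    participant's included trials.
    """
    need = {"trial_id", "report", "rt", "displacement"}
    if not need.issubset(responses.columns):
        raise ValueError(f"responses must carry columns {sorted(need)}")
    if "logit_report" not in responses.columns:
        responses = responses.copy()
        ok = responses["report"].notna()
        responses["logit_report"] = np.nan
        responses.loc[ok, "logit_report"] = np.log(
            responses.loc[ok, "report"] / (1 - responses.loc[ok, "report"]))

    merged, total_s = _decision_epochs(
        plan.trials, responses[["trial_id", "report", "rt", "displacement", "logit_report"]])
    included = _included_mask(merged, variant)
    catch = merged["is_catch"].to_numpy()
    omitted = merged["report"].isna().to_numpy() & ~catch
    extra_epoch = ~included & ~catch & ~omitted  # e.g. high-report trials in "truncated"

    conv_all = _convolve_epochs(merged["onset"].to_numpy(), merged["duration"].to_numpy(),
                                total_s, tr, oversampling)
    C = conv_all[:, included]

    raw = _modulator_table(merged, variant, plan.endowment)[included]
    zs: dict[str, tuple[float, float]] = {}
    cols: dict[str, np.ndarray] = {}
    cols["epoch"] = conv_all[:, included].sum(axis=1)
    dropped = []
    for c in raw.columns:
        mu, sd = z_stats[c] if z_stats is not None else \
            (float(raw[c].mean()), float(raw[c].std(ddof=0)))
        if sd == 0:
            warnings.warn(f"modulator {c!r} is constant after z-scoring; dropped")
            dropped.append(c)
            continue
        zs[c] = (mu, sd)
        cols[c] = C @ ((raw[c].to_numpy() - mu) / sd)
    if catch.any():
        cols["epoch_catch"] = conv_all[:, catch].sum(axis=1)
    if omitted.any():
        cols["epoch_omitted"] = conv_all[:, omitted].sum(axis=1)
    if extra_epoch.any():
        cols["epoch_unmodulated"] = conv_all[:, extra_epoch].sum(axis=1)
    cols["intercept"] = np.ones(len(conv_all))

    X = pd.DataFrame(cols)
    return DesignMatrix(X=X, C=C, trial_ids=merged.loc[included, "trial_id"].to_numpy(),
                        modulators_raw=raw.drop(columns=dropped), z_stats=zs,
                        variant=variant, tr=tr)


def simulate_bold(design: DesignMatrix, true_betas: dict[str, float],
                  noise_sd: float = 1.0, ar1_rho: float = 0.0,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Synthetic ROI timeseries ``y = X beta + AR(1) Gaussian noise`` (white
    by default); regressors absent from ``true_betas`` contribute 0."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not -1 < ar1_rho < 1:
        raise ValueError("|ar1_rho| must be < 1")
    rng = rng if rng is not None else np.random.default_rng()
    beta = np.array([true_betas.get(c, 0.0) for c in design.X.columns])
    y = design.X.to_numpy() @ beta
    if noise_sd > 0:
        e = rng.standard_normal(len(y)) * noise_sd
        if ar1_rho != 0.0:
            from scipy.signal import lfilter
            e = lfilter([np.sqrt(1 - ar1_rho**2)], [1, -ar1_rho], e)
        y = y + e
    return y


def fit_glm(design: DesignMatrix, y: np.ndarray) -> pd.Series:
    """Least-squares betas; raises on rank deficiency, naming the collinear
    columns."""
    X = design.X.to_numpy()
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [design.X.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, np.asarray(y, dtype=float), rcond=None)
    return pd.Series(beta, index=design.X.columns)


@dataclass
class GLMResult:
    contrast: str
    estimate: float
    ci95: tuple[float, float]
    p_value: float
    test: str  # "t" or "signed-rank"
    n: int


def group_test(betas: pd.DataFrame, contrast) -> GLMResult:
    """Group-level inference on a contrast of per-participant betas.

    ``contrast`` is a column name or {column: weight} dict.  A one-sample
    t-test is used unless a Lilliefors-type normality check rejects at 0.05,
    in which case a Wilcoxon signed-rank test is reported (with a bootstrap
    CI).
    """
    if isinstance(contrast, str):
        vals = betas[contrast].to_numpy(dtype=float)
        name = contrast
    else:
        vals = sum(w * betas[c].to_numpy(dtype=float) for c, w in contrast.items())
        name = "+".join(f"{w:g}*{c}" for c, w in contrast.items())
    n = vals.size
    if n < 4 or np.std(vals) == 0:
        normal = True
    else:
        try:
            _, p_norm = kstest_normal(vals)
            normal = p_norm >= 0.05
        except Exception:
            normal = True
    mean = float(vals.mean())
    if normal:
        if np.std(vals, ddof=1) == 0:
            return GLMResult(name, mean, (mean, mean), 0.0 if mean != 0 else 1.0, "t", n)
        t, p = stats.ttest_1samp(vals, 0.0)
        half = stats.t.ppf(0.975, n - 1) * vals.std(ddof=1) / np.sqrt(n)
        return GLMResult(name, mean, (mean - half, mean + half), float(p), "t", n)
    try:
        _, p = stats.wilcoxon(vals)
    except ValueError:
        p = 1.0
    rng = np.random.default_rng(0)
    boots = np.array([vals[rng.integers(0, n, n)].mean() for _ in range(2000)])
    return GLMResult(name, mean, (float(np.percentile(boots, 2.5)),
                                  float(np.percentile(boots, 97.5))),
                     float(p), "signed-rank", n)


@dataclass
class PermutationNull:
    n_perms: int
    null_prior: np.ndarray
    null_lik: np.ndarray
    observed_prior: float
    observed_lik: float
    p_prior: float
    p_lik: float
    seed: int


def _two_sided_p(null: np.ndarray, obs: float) -> float:
    n = null.size
    lo = int(np.sum(null <= obs))
    hi = int(np.sum(null >= obs))
    return min(1.0, 2.0 * (1 + min(lo, hi)) / (n + 1))


def permutation_null_prior_lik(plan: SessionPlan, cohort: pd.DataFrame,
                               timeseries: np.ndarray, n_perms: int = 1000,
                               seed: int = 0, tr: float = 1.0,
                               engine: str = "fwl",
                               designs: list[DesignMatrix] | None = None) -> PermutationNull:
    """Prior/likelihood label-permutation null for the two-term GLM.

    ``timeseries`` is (volumes x participants), column order matching sorted
    participant ids in ``cohort``.  Each permutation independently swaps each
    trial's logit prior and logit likelihood with probability 1/2 (the same
    swap for every participant, since the trial set is shared), leaving the
    logit posterior untouched; both modulators are re-z-scored at the group
    level and the group-mean betas refit.  Reported p-values are two-sided
    percentile positions of the observed group means in their nulls.

    ``engine='fwl'`` solves each permutation through the Frisch-Waugh-Lovell
    projection with precomputed cross-products; ``engine='refit'`` rebuilds
    the full design every time (slow, for validation).
    """
    if n_perms < 1:
        raise ValueError("n_perms must be positive")
    pids = np.asarray(sorted(cohort["participant"].unique()))
    Y = np.asarray(timeseries, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[1] != pids.size:
        raise ValueError("timeseries must have one column per participant")

    # shared raw labels per trial (identical across participants)
    if designs is None:
        designs = [build_design(plan, cohort[cohort["participant"] == pid],
                                variant="froi2", tr=tr) for pid in pids]
    elif len(designs) != pids.size:
        raise ValueError("need one prebuilt design per participant")

    rng = np.random.default_rng(seed)
    n_trials_all = plan.non_catch.shape[0]
    swaps = rng.random((n_perms, n_trials_all)) < 0.5
    nc_ids = plan.non_catch["trial_id"].to_numpy()

    lp_raw = plan.non_catch["logit_prior_q"].to_numpy()
    ll_raw = plan.non_catch["logit_lik_q"].to_numpy()

    # per-participant FWL precomputations
    pre = []
    for d, y in zip(designs, Y.T):
        keep = [c for c in d.X.columns if c not in ("logit_prior", "logit_lik")]
        F = d.X[keep].to_numpy()
        Q, _ = np.linalg.qr(F)
        y_t = y - Q @ (Q.T @ y)
        idx = np.searchsorted(nc_ids, d.trial_ids)
        pre.append(dict(Q=Q, y_t=y_t, idx=idx,
                        A=Q.T @ d.C, c=d.C.T @ y_t, K=d.C.T @ d.C, design=d, y=y))

    def stat_for_labels(lp_t: np.ndarray, ll_t: np.ndarray) -> np.ndarray:
        # group z-scoring over the pooled included trials
        out = np.zeros(2)
        zl = [(lp_t - lp_t.mean()) / lp_t.std(), (ll_t - ll_t.mean()) / ll_t.std()]
        for p in pre:
            M = np.column_stack([z[p["idx"]] for z in zl])
            if engine == "refit":
                d = p["design"]
                mu_sd = {"logit_prior": (lp_t.mean(), lp_t.std()),
                         "logit_lik": (ll_t.mean(), ll_t.std())}
                X = d.X.copy()
                X["logit_prior"] = d.C @ M[:, 0]
                X["logit_lik"] = d.C @ M[:, 1]
                beta, *_ = np.linalg.lstsq(X.to_numpy(), p["y"], rcond=None)
                bser = pd.Series(beta, index=X.columns)
                out += np.array([bser["logit_prior"], bser["logit_lik"]])
            else:
                AM = p["A"] @ M
                GtG = M.T @ (p["K"] @ M) - AM.T @ AM
                Gty = M.T @ p["c"]
                out += np.linalg.solve(GtG, Gty)
        return out / len(pre)

    observed = stat_for_labels(lp_raw, ll_raw)
    null = np.empty((n_perms, 2))
    for i in range(n_perms):
        s = swaps[i]
        lp_t = np.where(s, ll_raw, lp_raw)
        ll_t = np.where(s, lp_raw, ll_raw)
        null[i] = stat_for_labels(lp_t, ll_t)

    return PermutationNull(
        n_perms=n_perms, null_prior=null[:, 0], null_lik=null[:, 1],
        observed_prior=float(observed[0]), observed_lik=float(observed[1]),
        p_prior=_two_sided_p(null[:, 0], observed[0]),
        p_lik=_two_sided_p(null[:, 1], observed[1]),
        seed=seed)


def brain_behavior_correlation(neural_betas, behavioral_weights,
                               n_boot: int = 10_000, seed: int = 0) -> dict:
    """Spearman correlation between per-participant neural parameter
    estimates and behavioral probability weights, with a seeded bootstrap
    percentile CI."""
    x = np.asarray(neural_betas, dtype=float)
    y = np.asarray(behavioral_weights, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need matched vectors with at least 5 participants")
    rho, p = stats.spearmanr(x, y)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n = x.size
    for b in range(n_boot):
        i = rng.integers(0, n, n)
        if np.unique(x[i]).size < 2 or np.unique(y[i]).size < 2:
            boots[b] = np.nan
            continue
        boots[b] = stats.spearmanr(x[i], y[i]).statistic
    boots = boots[~np.isnan(boots)]
    return dict(rho=float(rho), p_value=float(p),
                ci95=(float(np.percentile(boots, 2.5)),
                      float(np.percentile(boots, 97.5))),
                n=int(n), n_boot=n_boot, seed=seed)
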