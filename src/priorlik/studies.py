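"""Replicate simulation studies that validate the pipeline end to end.

Each function runs a self-contained study at the design's study conditions
(130-trial sessions, 23 participants, generative weights 0.66/0.50 with
response noise 0.6, RT quadratic -5.88, ROI betas 0.159/0.310) and returns
summary rates.  They are used by the test suite and the acceptance script.
"""

from __future__ import annotations

import warnings

import numpy as np

from .bms import bms, family_xp
from .cohort import CohortConfig, draw_participants, mean_responder_cohort, simulate_cohort
from .mixed import fit_posterior_weight_model, fit_prior_likelihood_model, fit_rt_model
from .roi import build_design, permutation_null_prior_lik, simulate_bold
from .session import generate_session, session_diagnostics
from .strategies import DEFAULT_FAMILIES, evidence_from_ic, fit_all_participants
from .task import make_slider_grid, p_loss, snap_to_grid, trial_ev

__all__ = [
    "design_structure_study",
    "design_correlation_study",
    "scoring_oracle_study",
    "recovery_study",
    "ideal_observer_study",
    "strategy_discrimination_study",
    "rt_recovery_study",
    "permutation_validity_study",
    "permutation_detection_study",
]


def _seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) % (2**31)]


def design_structure_study(seed: int = 0, n_seeds: int = 100) -> dict:
    """Structural invariants of generated sessions over many seeds."""
    ok_counts = ok_cores = ok_runs = 0
    for s in _seeds(seed, n_seeds):
        t = generate_session(s).trials
        nc = t[~t["is_catch"]]
        ok_counts += (len(t) == 130 and t["is_catch"].sum() == 10)
        per_core = nc.groupby("core_id")["penalty"].nunique()
        ok_cores += (nc["core_id"].nunique() == 60 and (per_core == 2).all())
        ok_runs += (t.groupby("run").size().tolist() == [32, 33, 32, 33])
    grid = make_slider_grid()
    return dict(
        n_seeds=n_seeds,
        n_trials=130 if ok_counts == n_seeds else -1,
        n_catch=10 if ok_counts == n_seeds else -1,
        n_non_catch=120 if ok_counts == n_seeds else -1,
        n_unique_cores=60 if ok_cores == n_seeds else -1,
        runs_ok=ok_runs == n_seeds,
        grid_bins=grid.n, grid_lo=float(grid.values.min()),
        grid_hi=float(grid.values.max()), grid_step=grid.step,
    )


def design_correlation_study(seed: int = 0, n_seeds: int = 100,
                             threshold: float = 0.15) -> dict:
    """Fraction of generator seeds with |r(prior, likelihood)| below threshold."""
    rs = []
    for s in _seeds(seed, n_seeds):
        d = session_diagnostics(generate_session(s))
        rs.append((d.r_prior_lik_prob, d.r_prior_lik_logit, d.r_ev_posterior))
    rs = np.asarray(rs)
    return dict(
        n_seeds=n_seeds,
        frac_below_threshold=float((np.abs(rs[:, 0]) < threshold).mean()),
        mean_abs_r_prob=float(np.abs(rs[:, 0]).mean()),
        mean_abs_r_logit=float(np.abs(rs[:, 1]).mean()),
        mean_abs_r_ev_post=float(np.abs(rs[:, 2]).mean()),
    )


def scoring_oracle_study(seed: int = 0, n_random: int = 1000) -> dict:
    """Closed-form EV vs. the two-outcome enumeration oracle, and whether the
    EV-maximizing grid report is the grid point nearest the posterior."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    for _ in range(n_random):
        pi, pr = rng.uniform(0, 1, 2)
        N = rng.uniform(20, 50)
        W = rng.uniform(1, N)
        oracle = pr * (N - W * p_loss(1, pi)) + (1 - pr) * (N - W * p_loss(0, pi))
        max_err = max(max_err, abs(trial_ev(pi, pr, N, W) - oracle))
    grid = make_slider_grid()
    matches = total = 0
    for pr in np.linspace(0.01, 0.99, 197):
        for W in (10.0, 20.0):
            evs = trial_ev(grid.values, pr, 30.0, W)
            best = trial_ev(snap_to_grid(pr, grid), pr, 30.0, W)
            matches += abs(best - evs.max()) < 1e-12
            total += 1
    return dict(max_abs_ev_error=float(max_err),
                argmax_match_rate=float(matches / total), n_random=n_random)


def _replicate_cohort(seed: int, n_participants: int = 23,
                      config: CohortConfig | None = None):
    ss = np.random.SeedSequence(seed)
    plan = generate_session(int(ss.generate_state(1)[0] % (2**31)))
    rng = np.random.default_rng(ss.spawn(1)[0])
    cfg = config or CohortConfig(n_participants=n_participants)
    parts = draw_participants(n_participants, cfg, rng)
    return plan, simulate_cohort(plan, parts, rng), rng


def recovery_study(seed: int = 0, n_reps: int = 20) -> dict:
    """Do the prior-likelihood model's 95% CIs cover the generative group
    weights (0.66 / 0.50) across replicate cohorts?"""
    cov_prior = cov_lik = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in _seeds(seed, n_reps):
            _, cohort, _ = _replicate_cohort(s)
            f = fit_prior_likelihood_model(cohort)
            lo, hi = f.ci95["logit_prior_q"]
            cov_prior += lo <= 0.66 <= hi
            lo, hi = f.ci95["logit_lik_q"]
            cov_lik += lo <= 0.50 <= hi
    return dict(n_reps=n_reps,
                coverage_prior=cov_prior / n_reps,
                coverage_lik=cov_lik / n_reps)


def ideal_observer_study(seed: int = 0) -> dict:
    """Weights and slope recovered from deterministic ideal observers; grid
    discretization attenuates them slightly below 1."""
    from .cohort import ideal_observer_cohort
    plan = generate_session(seed)
    cohort = ideal_observer_cohort(plan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f10 = fit_prior_likelihood_model(cohort)
        f9 = fit_posterior_weight_model(cohort)
    return dict(b_prior=f10.fixed_effects["logit_prior_q"],
                b_lik=f10.fixed_effects["logit_lik_q"],
                slope=f9.fixed_effects["logit_obj_post"],
                intercept=f9.fixed_effects["Intercept"])


def strategy_discrimination_study(seed: int = 0, n_reps: int = 20,
                                  mc_samples: int = 500_000) -> dict:
    """Can model selection tell integration from averaging?

    Weighted-Bayes cohorts should give the interaction family (weighted Bayes
    + linear-with-interaction) family-xp > 0.8; mean-responder cohorts should
    give the mean model pxp > 0.8.
    """
    fam_wins = mean_wins = 0
    fam_models = [m for m in DEFAULT_FAMILIES]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in _seeds(seed, n_reps):
            plan, wb_cohort, rng = _replicate_cohort(s)
            fits = fit_all_participants(wb_cohort)
            ev = evidence_from_ic(fits)
            fam = family_xp(ev[fam_models], DEFAULT_FAMILIES,
                            mc_samples=mc_samples, seed=s)
            fam_wins += fam.family_xp[fam.families.index("interaction")] > 0.8

            mean_cohort = mean_responder_cohort(plan, rng)
            fits_m = fit_all_participants(mean_cohort)
            res = bms(evidence_from_ic(fits_m), mc_samples=mc_samples, seed=s)
            mean_wins += res.pxp[res.models.index("mean")] > 0.8
    return dict(n_reps=n_reps,
                family_xp_win_rate=fam_wins / n_reps,
                mean_pxp_win_rate=mean_wins / n_reps)


def rt_recovery_study(seed: int = 0, n_reps: int = 20) -> dict:
    """Recovery of the negative RT quadratic (generative -5.88): the fixed
    effect must be negative with a CI excluding zero."""
    detected = 0
    est = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in _seeds(seed, n_reps):
            _, cohort, _ = _replicate_cohort(s)
            f = fit_rt_model(cohort)
            lo, hi = f.ci95["report_sq"]
            detected += hi < 0
            est.append(f.fixed_effects["report_sq"])
    return dict(n_reps=n_reps, detection_rate=detected / n_reps,
                mean_quadratic=float(np.mean(est)))


def _roi_replicate_base(seed: int, n_participants: int = 23):
    plan, cohort, rng = _replicate_cohort(seed, n_participants)
    pids = sorted(cohort["participant"].unique())
    designs = [build_design(plan, cohort[cohort["participant"] == p],
                            variant="froi2") for p in pids]
    return plan, cohort, designs, rng


def permutation_validity_study(seed: int = 0, n_reps: int = 200,
                               n_perms: int = 1000, n_cohorts: int = 4,
                               alpha: float = 0.05,
                               equal_beta: float = 0.2345) -> dict:
    """Type-I behavior: swap-symmetric generative data (equal prior and
    likelihood betas, i.e., a pure posterior code) must give permutation
    p-values rejecting at most alpha of the time (super-uniformity)."""
    truth = {"epoch": 1.0, "logit_prior": equal_beta, "logit_lik": equal_beta}
    rejections = 0
    done = 0
    reps_per = int(np.ceil(n_reps / n_cohorts))
    for i, s in enumerate(_seeds(seed, n_cohorts)):
        plan, cohort, designs, rng = _roi_replicate_base(s)
        for rep in range(reps_per):
            if done >= n_reps:
                break
            Y = np.column_stack([simulate_bold(d, truth, noise_sd=1.0, rng=rng)
                                 for d in designs])
            r = permutation_null_prior_lik(plan, cohort, Y, n_perms=n_perms,
                                           seed=s + rep, designs=designs)
            rejections += (r.p_prior <= alpha) or (r.p_lik <= alpha)
            done += 1
    return dict(n_reps=done, alpha=alpha, rejection_rate=rejections / done)


def permutation_detection_study(seed: int = 0, n_reps: int = 20,
                                n_perms: int = 1000,
                                betas: tuple[float, float] = (0.159, 0.310)) -> dict:
    """Power: distinct generative prior/likelihood betas must land outside the
    posterior-only null (both p < 0.05) in most replicates."""
    truth = {"epoch": 1.0, "logit_prior": betas[0], "logit_lik": betas[1]}
    plan, cohort, designs, rng = _roi_replicate_base(_seeds(seed, 1)[0])
    detected = 0
    for rep in range(n_reps):
        Y = np.column_stack([simulate_bold(d, truth, noise_sd=1.0, rng=rng)
                             for d in designs])
        r = permutation_null_prior_lik(plan, cohort, Y, n_perms=n_perms,
                                       seed=seed + rep, designs=designs)
        detected += (r.p_prior < 0.05) and (r.p_lik < 0.05)
    return dict(n_reps=n_reps, detection_rate=detected / n_reps)
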