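"""End-to-end orchestration: generate a session, simulate a cohort, fit the
behavioral models, run model selection, simulate and analyze ROI data, and
write every intermediate artifact plus a machine-readable report.

All randomness flows from one seed through a splittable generator; sub-seeds
per stage are recorded in the report, so a run is reproducible from its
archived config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import roi as roi_mod
from .bms import bms, family_xp
from .cohort import (CohortConfig, draw_participants, participants_to_frame,
                     simulate_cohort)
from .mixed import fit_posterior_weight_model, fit_prior_likelihood_model, fit_rt_model
from .screening import compare_to_ideal, penalty_accuracy_test, screen_participants
from .session import SessionConfig, generate_session, session_diagnostics
from .strategies import DEFAULT_FAMILIES, MODEL_NAMES, evidence_from_ic, fit_all_participants

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    seed: int = 1
    session: SessionConfig = field(default_factory=SessionConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    models: tuple[str, ...] = MODEL_NAMES
    family_partition: dict = field(default_factory=lambda: dict(DEFAULT_FAMILIES))
    evidence_source: str = "bic"
    bms_mc_samples: int = 1_000_000
    roi_noise_sd: float = 1.0
    roi_true_betas: dict = field(default_factory=lambda: {
        "epoch": 1.0, "logit_prior": 0.159, "logit_lik": 0.310})
    n_perms: int = 1000
    out_dir: str = "priorlik_run"

    def validate(self) -> None:
        self.session.validate()
        self.cohort.validate()
        unknown = [m for m in self.models if m not in MODEL_NAMES]
        if unknown:
            raise ValueError(f"unknown model names: {unknown}")
        uncovered = [m for m in self.models if m != "mean" and m not in self.family_partition]
        if uncovered:
            raise ValueError(f"family partition does not cover: {uncovered}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        kw = dict(data)
        if "session" in kw:
            kw["session"] = SessionConfig(**kw["session"])
        if "cohort" in kw:
            c = dict(kw["cohort"])
            for k, v in c.items():
                if isinstance(v, list):
                    c[k] = tuple(v)
            kw["cohort"] = CohortConfig(**c)
        if "models" in kw:
            kw["models"] = tuple(kw["models"])
        return cls(**kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def run_pipeline(config: RunConfig, quiet: bool = True) -> dict:
    """Run every stage in order, persisting artifacts under ``config.out_dir``.

    Returns the run report: a nested dict of machine-readable metrics, also
    written to ``report.json`` with a human-readable ``summary.txt``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(config.seed)
    sub = ss.spawn(4)
    seeds = dict(session=int(ss.generate_state(1)[0] % (2**31)),
                 cohort=sub[0], roi=sub[1], bms=int(np.random.default_rng(sub[2]).integers(2**31)))

    report: dict = {"seed": config.seed,
                    "stage_seeds": {"session": seeds["session"], "bms": seeds["bms"]}}

    # 1. session
    plan = generate_session(seeds["session"], config.session)
    plan.to_tsv(out / "session.tsv")
    diag = session_diagnostics(plan)
    report["session"] = dict(
        n_trials=plan.n_trials, n_catch=int(plan.trials["is_catch"].sum()),
        n_non_catch=int((~plan.trials["is_catch"]).sum()),
        run_sizes=list(plan.run_sizes),
        r_prior_lik_prob=diag.r_prior_lik_prob,
        r_prior_lik_logit=diag.r_prior_lik_logit,
        r_ev_posterior=diag.r_ev_posterior)

    # 2. cohort
    rng_cohort = np.random.default_rng(seeds["cohort"])
    participants = draw_participants(config.cohort.n_participants, config.cohort, rng_cohort)
    participants_to_frame(participants).to_csv(out / "participants.tsv", sep="\t", index=False)
    cohort = simulate_cohort(plan, participants, rng_cohort)
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
    report["cohort"] = dict(n_participants=len(participants), n_rows=len(cohort),
                            n_omitted=int(cohort["omitted"].sum()))

    # 3. behavioral fits and tests
    fits = {}
    for fn in (fit_posterior_weight_model, fit_prior_likelihood_model, fit_rt_model):
        r = fn(cohort)
        fits[r.model_name] = r.to_dict()
    _write_json(out / "fits.json", fits)
    screening = screen_participants(cohort)
    screening.per_participant.to_csv(out / "screening.tsv", sep="\t", index=False)
    pen = penalty_accuracy_test(cohort)
    ideal_cmp = compare_to_ideal(cohort, plan)
    report["fits"] = fits
    report["screening"] = dict(n_pass=int(screening.per_participant["pass_all"].sum()))
    report["penalty_test"] = {k: pen[k] for k in
                              ("n_participants", "median_diff", "sign_statistic", "p_value")}
    report["ideal_comparison"] = {t: ideal_cmp[t] for t in ("b_prior", "b_lik")}

    # 4. strategy model selection
    per_fits = fit_all_participants(cohort, models=config.models)
    ev = evidence_from_ic(per_fits, source=config.evidence_source)
    res = bms(ev, mc_samples=config.bms_mc_samples, seed=seeds["bms"])
    fam_models = [m for m in config.models if m in config.family_partition]
    fam = family_xp(ev[fam_models], config.family_partition,
                    mc_samples=config.bms_mc_samples, seed=seeds["bms"])
    _write_json(out / "bms.json", dict(model_level=res.to_dict(), family_level=fam.to_dict()))
    report["bms"] = dict(models=res.models, xp=res.xp.tolist(), pxp=res.pxp.tolist(),
                         bor=res.bor, families=fam.families,
                         family_xp=fam.family_xp.tolist())

    # 5. ROI simulation and permutation null
    rng_roi = np.random.default_rng(seeds["roi"])
    pids = sorted(cohort["participant"].unique())
    designs, ys = [], []
    for pid in pids:
        d = roi_mod.build_design(plan, cohort[cohort["participant"] == pid], variant="froi2")
        designs.append(d)
        ys.append(roi_mod.simulate_bold(d, config.roi_true_betas,
                                        noise_sd=config.roi_noise_sd, rng=rng_roi))
    Y = np.column_stack(ys)
    betas = pd.DataFrame([roi_mod.fit_glm(d, y) for d, y in zip(designs, ys)])
    betas.insert(0, "participant", pids)
    betas.to_csv(out / "roi_betas.tsv", sep="\t", index=False)
    gt_prior = roi_mod.group_test(betas, "logit_prior")
    gt_lik = roi_mod.group_test(betas, "logit_lik")
    perm = roi_mod.permutation_null_prior_lik(
        plan, cohort, Y, n_perms=config.n_perms,
        seed=int(np.random.default_rng(seeds["roi"]).integers(2**31)))
    _write_json(out / "permnull.json", dict(
        n_perms=perm.n_perms, observed_prior=perm.observed_prior,
        observed_lik=perm.observed_lik, p_prior=perm.p_prior, p_lik=perm.p_lik,
        seed=perm.seed, null_prior=perm.null_prior, null_lik=perm.null_lik))
    report["roi"] = dict(
        group_prior=dict(estimate=gt_prior.estimate, ci95=list(gt_prior.ci95),
                         p=gt_prior.p_value, test=gt_prior.test),
        group_lik=dict(estimate=gt_lik.estimate, ci95=list(gt_lik.ci95),
                       p=gt_lik.p_value, test=gt_lik.test),
        perm_p_prior=perm.p_prior, perm_p_lik=perm.p_lik)

    _write_json(out / "report.json", report)
    lines = [
        f"seed {config.seed}: {plan.n_trials} trials "
        f"({report['session']['n_non_catch']} non-catch), "
        f"{len(participants)} participants",
        f"design r(prior, lik) = {diag.r_prior_lik_prob:+.3f} (prob), "
        f"{diag.r_prior_lik_logit:+.3f} (logit); r(EV, posterior) = {diag.r_ev_posterior:+.3f}",
        f"prior weight = {fits['prior_likelihood']['fixed_effects']['logit_prior_q']:.3f}, "
        f"likelihood weight = {fits['prior_likelihood']['fixed_effects']['logit_lik_q']:.3f}",
        f"posterior weight (slope) = "
        f"{fits['posterior_weight']['fixed_effects']['logit_obj_post']:.3f}",
        f"RT quadratic = {fits['reaction_time']['fixed_effects']['report_sq']:.3f}",
        f"family xp: " + ", ".join(f"{f}={x:.3f}" for f, x in
                                   zip(fam.families, fam.family_xp)),
        f"ROI permutation p: prior {perm.p_prior:.4f}, likelihood {perm.p_lik:.4f}",
    ]
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    if not quiet:
        print("\n".join(lines))
    return report
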