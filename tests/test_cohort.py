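"""Synthetic responders: generative response model, RTs, special cohorts."""

import numpy as np
import pytest

import priorlik as pl
from priorlik.cohort import CohortConfig, ParticipantParams, W_CENTER


class TestDrawParticipants:
    def test_count_and_reproducibility(self):
        a = pl.draw_participants(23, rng=np.random.default_rng(0))
        b = pl.draw_participants(23, rng=np.random.default_rng(0))
        assert len(a) == 23 and a == b

    def test_zero_hyper_sd_gives_identical_participants(self):
        cfg = CohortConfig(b0=(0.07, 0), b_prior=(0.66, 0), b_lik=(0.5, 0),
                           bW=(0.01, 0), bS=(0.0, 0), rt_a0=(3, 0),
                           rt_quad=(-5.88, 0), rt_lin=(5.88, 0),
                           rt_aD=(1, 0), rt_adiff=(0.5, 0))
        ps = pl.draw_participants(5, cfg, np.random.default_rng(1))
        assert len(set(ps)) == 1

    def test_population_means_recovered(self):
        ps = pl.draw_participants(10_000, rng=np.random.default_rng(2))
        b_lik = np.array([p.b_lik for p in ps])
        se = 0.2 / np.sqrt(len(ps))
        assert abs(b_lik.mean() - 0.50) < 3 * se
        b_prior = np.array([p.b_prior for p in ps])
        assert abs(b_prior.mean() - 0.66) < 3 * 0.2 / np.sqrt(len(ps))

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            pl.draw_participants(2, CohortConfig(b_prior=(0.66, -0.1)),
                                 np.random.default_rng(0))

    def test_param_invariants_enforced(self):
        with pytest.raises(ValueError):
            ParticipantParams(sigma_resp=-1)
        with pytest.raises(ValueError):
            ParticipantParams(rt_quad=0.5)
        with pytest.raises(ValueError):
            ParticipantParams(omission_rate=1.0)


class TestSimulateCohort:
    def test_row_count_is_participants_by_trials(self, cohort23):
        assert len(cohort23) == 23 * 130

    def test_zero_omission_rate(self, plan):
        cfg = CohortConfig(n_participants=4, omission_rate=0.0)
        rng = np.random.default_rng(3)
        c = pl.simulate_cohort(plan, pl.draw_participants(4, cfg, rng), rng)
        assert not c["omitted"].any()

    def test_reports_on_grid_and_displacement_consistent(self, cohort23):
        ok = cohort23[~cohort23["omitted"]]
        grid = np.round(pl.make_slider_grid().values, 10)
        assert np.isin(np.round(ok["report"], 10), grid).all()
        assert np.allclose(ok["displacement"], ok["report"] - ok["initial_slider"])

    def test_derived_logits_recomputable(self, cohort23):
        ok = cohort23[~cohort23["omitted"]]
        assert np.allclose(ok["logit_report"],
                           np.log(ok["report"] / (1 - ok["report"])))
        assert np.allclose(ok["logit_target"],
                           ok["logit_prior_q"] + ok["logit_lik_q"])

    def test_unit_weights_noiseless_is_ideal_observer(self, plan):
        p = ParticipantParams(b0=0, b_prior=1, b_lik=1, bW=0, bS=0,
                              sigma_resp=0, omission_rate=0)
        c = pl.simulate_cohort(plan, [p], np.random.default_rng(0))
        ideal = pl.ideal_observer_cohort(plan, n_participants=1)
        assert np.allclose(c["report"], ideal["report"])

    def test_flat_responder_reports_constant(self, plan):
        p = ParticipantParams(b0=0.3, b_prior=0, b_lik=0, bW=0, bS=0,
                              sigma_resp=0, omission_rate=0)
        c = pl.simulate_cohort(plan, [p], np.random.default_rng(0))
        expected = pl.snap_to_grid(pl.inv_logit(0.3), pl.make_slider_grid())
        assert (c["report"] == expected).all()

    def test_seed_reproducibility(self, plan):
        parts = pl.draw_participants(3, rng=np.random.default_rng(5))
        a = pl.simulate_cohort(plan, parts, np.random.default_rng(9))
        b = pl.simulate_cohort(plan, parts, np.random.default_rng(9))
        assert a.equals(b)


class TestReactionTime:
    def test_inverted_u_peaks_at_half(self):
        p = ParticipantParams(sigma_rt=0)
        rng = np.random.default_rng(0)
        rt = {pi: pl.simulate_rt(pi, 0.0, 0.0, p, rng) for pi in (0.02, 0.5, 0.98)}
        assert rt[0.5] > rt[0.02] and rt[0.5] > rt[0.98]
        # analytic peak of a*pi^2 + b*pi with a = -b is at 0.5
        assert rt[0.5] == pytest.approx(p.rt_a0 + p.rt_quad * 0.25 + p.rt_lin * 0.5)

    def test_truncation_bounds(self):
        p = ParticipantParams(sigma_rt=5.0)
        rng = np.random.default_rng(1)
        rts = [pl.simulate_rt(0.5, 0.2, 0.1, p, rng) for _ in range(500)]
        assert min(rts) > 0.2 and max(rts) <= 15.0


class TestSpecialCohorts:
    def test_ideal_observer_reports_snapped_posterior(self, plan):
        c = pl.ideal_observer_cohort(plan, n_participants=2)
        grid = pl.make_slider_grid()
        expected = pl.snap_to_grid(plan.trials["target"].to_numpy(), grid)
        assert np.allclose(c[c["participant"] == 1]["report"], expected)

    def test_ideal_observer_simple_trial(self):
        # prior 0.5, likelihood 0.6 -> posterior 0.6 -> nearest grid value 0.59
        grid = pl.make_slider_grid()
        assert pl.snap_to_grid(pl.objective_posterior(0.5, 0.6), grid) == pytest.approx(0.59)

    def test_mean_responder_noiseless(self, plan):
        c = pl.mean_responder_cohort(plan, np.random.default_rng(0),
                                     n_participants=1, noise_sd=0.0)
        nc = c[~c["is_catch"]]
        grid = pl.make_slider_grid()
        expected = pl.snap_to_grid(
            (0.5 * (nc["prior_q"] + nc["likelihood_q"])).to_numpy(), grid)
        assert np.allclose(nc["report"], expected)
        # e.g. prior 0.9 with likelihood 0.6 averages to 0.75 -> grid 0.74
        assert pl.snap_to_grid(0.75, grid) == pytest.approx(0.74)
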