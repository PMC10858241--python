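"""ROI GLM machinery: HRF, designs, estimation, group tests, permutation."""

import numpy as np
import pandas as pd
import pytest

import priorlik as pl
from priorlik.roi import DesignMatrix, GLM_VARIANTS, _two_sided_p


@pytest.fixture(scope="module")
def roi_setup(plan):
    rng = np.random.default_rng(50)
    parts = pl.draw_participants(8, rng=rng)
    cohort = pl.simulate_cohort(plan, parts, rng)
    pids = sorted(cohort["participant"].unique())
    designs = [pl.build_design(plan, cohort[cohort["participant"] == p],
                               variant="froi2") for p in pids]
    return cohort, designs


class TestHRF:
    def test_peak_near_five_seconds(self):
        h = pl.hrf_kernel(0.1)
        assert abs(np.argmax(h) * 0.1 - 5.0) <= 0.1
        assert h.max() == 1.0

    def test_returns_to_baseline_by_32s(self):
        h = pl.hrf_kernel(0.5)
        assert abs(h[-1]) < 1e-3

    def test_matches_independent_spm_implementation(self):
        """Cross-check against nilearn's canonical SPM HRF."""
        nilearn = pytest.importorskip("nilearn.glm.first_level.hemodynamic_models")
        ours = pl.hrf_kernel(0.1)
        theirs = nilearn.spm_hrf(1.0, oversampling=10, time_length=32.1)
        n = min(len(ours), len(theirs))
        r = np.corrcoef(ours[:n], theirs[:n])[0, 1]
        assert r > 0.999

    def test_invalid_tr(self):
        with pytest.raises(ValueError):
            pl.hrf_kernel(0.0)


class TestDesign:
    def test_expected_columns_per_variant(self, plan, cohort23):
        sub = cohort23[cohort23["participant"] == 1]
        d = pl.build_design(plan, sub, variant="froi2")
        assert list(d.X.columns) == ["epoch", "logit_prior", "logit_lik",
                                     "penalty", "displacement", "epoch_catch",
                                     "intercept"]
        d3 = pl.build_design(plan, sub, variant="froi3")
        assert "logit_subj_post" in d3.X.columns
        dq = pl.build_design(plan, sub, variant="quadratic")
        assert "logit_subj_post_sq" in dq.X.columns
        dt_ = pl.build_design(plan, sub, variant="truncated")
        assert "epoch_unmodulated" in dt_.X.columns
        dw = pl.build_design(plan, sub, variant="wb1")
        for col in ("abs_logit_subj_post", "favored_dummy", "sample_side",
                    "subjective_ev", "initial_slider"):
            assert col in dw.X.columns

    def test_unknown_variant_rejected(self, plan, cohort23):
        with pytest.raises(ValueError):
            pl.build_design(plan, cohort23[cohort23["participant"] == 1],
                            variant="nope")

    def test_modulators_not_orthogonalized(self, plan, cohort23):
        """Raw-covariate correlation must survive into the design columns."""
        sub = cohort23[cohort23["participant"] == 1]
        d = pl.build_design(plan, sub, variant="froi3")
        raw_r = np.corrcoef(d.modulators_raw["logit_subj_post"],
                            d.modulators_raw["displacement"])[0, 1]
        col_r = np.corrcoef(d.X["logit_subj_post"], d.X["displacement"])[0, 1]
        assert abs(raw_r) > 0.2
        assert np.sign(col_r) == np.sign(raw_r)
        assert abs(col_r) > 0.5 * abs(raw_r)

    def test_group_z_scope_matches_participant_scope_for_shared_trials(self, plan):
        """Participants answering identically have identical group- and
        participant-level z-scores."""
        ideal = pl.ideal_observer_cohort(plan, n_participants=2)
        zs = pl.group_z_stats(plan, ideal, "froi2")
        sub = ideal[ideal["participant"] == 1]
        d_group = pl.build_design(plan, sub, variant="froi2", z_stats=zs)
        d_part = pl.build_design(plan, sub, variant="froi2")
        pd.testing.assert_frame_equal(d_group.X, d_part.X, atol=1e-10, rtol=0)

    def test_constant_modulator_dropped_with_warning(self, plan, cohort23):
        sub = cohort23[cohort23["participant"] == 1].copy()
        single = plan.trials.copy()
        single["penalty"] = 10.0
        from priorlik.session import SessionPlan
        plan1 = SessionPlan(trials=single, endowment=30.0,
                            run_sizes=plan.run_sizes, seed=None)
        with pytest.warns(UserWarning, match="constant"):
            d = pl.build_design(plan1, sub, variant="froi2")
        assert "penalty" not in d.X.columns

    def test_posterior_columns_invariant_to_prior_lik_swap(self, plan, cohort23):
        """Swapping every trial's prior and likelihood leaves the posterior
        modulator numerically unchanged (log-odds additivity)."""
        sub = cohort23[cohort23["participant"] == 1]
        swapped_trials = plan.trials.copy()
        swapped_trials[["logit_prior_q", "logit_lik_q"]] = \
            swapped_trials[["logit_lik_q", "logit_prior_q"]].to_numpy()
        from priorlik.session import SessionPlan
        plan_sw = SessionPlan(trials=swapped_trials, endowment=30.0,
                              run_sizes=plan.run_sizes, seed=None)
        d1 = pl.build_design(plan, sub, variant="froi1")
        d2 = pl.build_design(plan_sw, sub, variant="froi1")
        assert np.allclose(d1.X["logit_obj_post"], d2.X["logit_obj_post"],
                           atol=1e-10)


class TestEstimation:
    def test_noiseless_recovery(self, plan, cohort23):
        d = pl.build_design(plan, cohort23[cohort23["participant"] == 2],
                            variant="froi2")
        truth = {"epoch": 1.0, "logit_prior": 0.159, "logit_lik": 0.310,
                 "penalty": -0.06, "intercept": 5.0}
        y = pl.simulate_bold(d, truth, noise_sd=0.0)
        b = pl.fit_glm(d, y)
        for k, v in truth.items():
            assert b[k] == pytest.approx(v, abs=1e-10)

    def test_matches_normal_equations_oracle(self, plan, cohort23):
        d = pl.build_design(plan, cohort23[cohort23["participant"] == 3],
                            variant="froi1")
        rng = np.random.default_rng(0)
        y = pl.simulate_bold(d, {"epoch": 1.0}, noise_sd=1.0, rng=rng)
        b = pl.fit_glm(d, y)
        X = d.X.to_numpy()
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(b.to_numpy(), oracle, atol=1e-8)

    def test_rank_deficiency_names_columns(self, plan, cohort23):
        d = pl.build_design(plan, cohort23[cohort23["participant"] == 1],
                            variant="froi2")
        X = d.X.copy()
        X["dup"] = X["logit_prior"]
        bad = DesignMatrix(X=X, C=d.C, trial_ids=d.trial_ids,
                           modulators_raw=d.modulators_raw, z_stats=d.z_stats,
                           variant=d.variant, tr=d.tr)
        with pytest.raises(ValueError, match="rank deficient"):
            pl.fit_glm(bad, np.zeros(len(X)))

    def test_beta_estimates_unbiased(self, plan, cohort23):
        d = pl.build_design(plan, cohort23[cohort23["participant"] == 4],
                            variant="froi2")
        rng = np.random.default_rng(1)
        ests = []
        for _ in range(100):
            y = pl.simulate_bold(d, {"logit_prior": 0.2}, noise_sd=1.0, rng=rng)
            ests.append(pl.fit_glm(d, y)["logit_prior"])
        ests = np.asarray(ests)
        assert abs(ests.mean() - 0.2) < 3 * ests.std() / 10


class TestGroupInference:
    def test_strong_common_effect_detected(self):
        betas = pd.DataFrame({"b": np.full(23, 0.3) + np.random.default_rng(0).normal(0, 0.01, 23)})
        r = pl.group_test(betas, "b")
        assert r.p_value < 1e-6 and r.test == "t"

    def test_null_effect_not_detected(self):
        betas = pd.DataFrame({"b": np.random.default_rng(1).normal(0, 1, 23)})
        r = pl.group_test(betas, "b")
        assert r.ci95[0] < 0 < r.ci95[1]

    def test_heavy_tails_switch_to_signed_rank(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 0.05, 40)
        vals[::6] += rng.normal(0, 8, len(vals[::6]))  # contamination
        r = pl.group_test(pd.DataFrame({"b": vals}), "b")
        assert r.test == "signed-rank"


class TestPermutationNull:
    def test_fast_path_equals_full_refit(self, plan, roi_setup):
        cohort, designs = roi_setup
        rng = np.random.default_rng(60)
        Y = np.column_stack([
            pl.simulate_bold(d, {"epoch": 1.0, "logit_prior": 0.159,
                                 "logit_lik": 0.310}, noise_sd=1.0, rng=rng)
            for d in designs])
        a = pl.permutation_null_prior_lik(plan, cohort, Y, n_perms=15, seed=3,
                                          designs=designs)
        b = pl.permutation_null_prior_lik(plan, cohort, Y, n_perms=15, seed=3,
                                          engine="refit", designs=designs)
        assert np.allclose(a.null_prior, b.null_prior, atol=1e-10)
        assert np.allclose(a.null_lik, b.null_lik, atol=1e-10)
        assert a.observed_prior == pytest.approx(b.observed_prior, abs=1e-12)

    def test_distinct_generative_weights_fall_outside_null(self, plan, roi_setup):
        cohort, designs = roi_setup
        rng = np.random.default_rng(61)
        Y = np.column_stack([
            pl.simulate_bold(d, {"epoch": 1.0, "logit_prior": 0.159,
                                 "logit_lik": 0.310}, noise_sd=0.5, rng=rng)
            for d in designs])
        r = pl.permutation_null_prior_lik(plan, cohort, Y, n_perms=400, seed=4,
                                          designs=designs)
        assert r.p_prior < 0.05 and r.p_lik < 0.05
        assert r.observed_prior < r.observed_lik

    def test_posterior_only_encoding_stays_inside_null(self, plan, roi_setup):
        """Equal implied prior/likelihood weights: the swap-symmetric case."""
        cohort, designs = roi_setup
        rng = np.random.default_rng(62)
        Y = np.column_stack([
            pl.simulate_bold(d, {"epoch": 1.0, "logit_prior": 0.25,
                                 "logit_lik": 0.25}, noise_sd=1.0, rng=rng)
            for d in designs])
        r = pl.permutation_null_prior_lik(plan, cohort, Y, n_perms=400, seed=5,
                                          designs=designs)
        assert r.p_prior > 0.05 and r.p_lik > 0.05

    def test_reproducible_and_validated_inputs(self, plan, roi_setup):
        cohort, designs = roi_setup
        rng = np.random.default_rng(63)
        Y = np.column_stack([pl.simulate_bold(d, {"epoch": 1.0}, noise_sd=1.0,
                                              rng=rng) for d in designs])
        a = pl.permutation_null_prior_lik(plan, cohort, Y, n_perms=20, seed=8,
                                          designs=designs)
        b = pl.permutation_null_prior_lik(plan, cohort, Y, n_perms=20, seed=8,
                                          designs=designs)
        assert np.array_equal(a.null_prior, b.null_prior)
        with pytest.raises(ValueError):
            pl.permutation_null_prior_lik(plan, cohort, Y, n_perms=0)

    def test_two_sided_p_definition(self):
        null = np.arange(99, dtype=float)
        assert _two_sided_p(null, 200.0) == pytest.approx(2 / 100)
        assert _two_sided_p(null, 49.0) == 1.0


class TestBrainBehavior:
    def test_identical_vectors_give_rho_one(self):
        x = np.arange(10, dtype=float)
        r = pl.brain_behavior_correlation(x, x, n_boot=200, seed=0)
        assert r["rho"] == pytest.approx(1.0)

    def test_independent_vectors_centered_at_zero(self):
        rng = np.random.default_rng(3)
        rhos = [pl.brain_behavior_correlation(rng.normal(size=23),
                                              rng.normal(size=23),
                                              n_boot=50, seed=0)["rho"]
                for _ in range(30)]
        assert abs(np.mean(rhos)) < 0.15

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            pl.brain_behavior_correlation([1, 2, 3], [1, 2, 3])
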