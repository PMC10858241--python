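"""Session generation structure, diagnostics, payout, and I/O."""

import numpy as np
import pandas as pd
import pytest

import priorlik as pl
from priorlik.session import SessionConfig, SessionPlan, _derive_columns


class TestStructure:
    @pytest.mark.parametrize("seed", range(10))
    def test_session_counts_and_runs(self, seed):
        p = pl.generate_session(seed)
        t = p.trials
        assert len(t) == 130
        assert t["is_catch"].sum() == 10
        assert (~t["is_catch"]).sum() == 120
        assert p.run_sizes == (32, 33, 32, 33)
        assert t.groupby("run").size().tolist() == [32, 33, 32, 33]
        by_run = t.groupby("run")["questioned_gallery"].agg(lambda s: s.unique().tolist())
        assert by_run[1] == ["portrait"] and by_run[3] == ["portrait"]
        assert by_run[2] == ["landscape"] and by_run[4] == ["landscape"]

    def test_sixty_unique_cores_duplicated_over_penalties(self):
        t = pl.generate_session(3).trials
        nc = t[~t["is_catch"]]
        assert nc["core_id"].nunique() == 60
        per_core = nc.groupby("core_id")["penalty"].agg(["size", "nunique"])
        assert (per_core["size"] == 2).all()
        assert (per_core["nunique"] == 2).all()
        # duplicates share prior, theta, sample and hidden gallery
        varying = nc.groupby("core_id")[["prior_portrait", "theta",
                                         "sample_category", "hidden_gallery"]].nunique()
        assert (varying == 1).all().all()
        assert (nc.groupby("penalty").size() == 60).all()

    def test_catch_trials_two_per_prior_bin(self):
        cfg = SessionConfig()
        t = pl.generate_session(5, cfg).trials
        catch = t[t["is_catch"]]
        assert len(catch) == 10
        assert catch["theta"].isna().all()
        assert (catch["sample_category"] == "").all()
        assert (catch["likelihood_q"] == 0.5).all()
        bins = np.asarray(cfg.prior_bins)
        nearest = bins[np.argmin(np.abs(catch["prior_portrait"].to_numpy()[:, None]
                                        - bins[None, :]), axis=1)]
        # one trial per prior bin per penalty level
        assert catch.groupby([nearest, "penalty"]).size().tolist() == [1] * 10

    def test_value_ranges(self):
        t = pl.generate_session(8).trials
        nc = t[~t["is_catch"]]
        assert ((nc["theta"] > 0.5) & (nc["theta"] < 1)).all()
        assert ((t["prior_portrait"] > 0) & (t["prior_portrait"] < 1)).all()
        assert ((t["iti_s"] >= 1) & (t["iti_s"] <= 10)).all()
        grid = pl.make_slider_grid().values
        assert np.isin(np.round(t["initial_slider"], 10), np.round(grid, 10)).all()

    def test_determinism_and_seed_sensitivity(self):
        a = pl.generate_session(17).to_tsv()
        b = pl.generate_session(17).to_tsv()
        c = pl.generate_session(18).to_tsv()
        assert a == b
        assert a != c

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            pl.generate_session(0, SessionConfig(penalties=(10, 40)))
        with pytest.raises(ValueError):
            pl.generate_session(0, SessionConfig(prior_bins=(0.1, 1.2)))


class TestDiagnostics:
    def test_generated_sessions_decorrelate_prior_and_likelihood(self):
        rs = [pl.session_diagnostics(pl.generate_session(s)).r_prior_lik_prob
              for s in range(10)]
        assert all(abs(r) < 0.15 for r in rs)

    def test_perfectly_coupled_design_gives_r_one(self):
        n = 20
        vals = np.linspace(0.2, 0.8, n)
        df = pd.DataFrame(dict(
            trial_id=np.arange(1, n + 1), run=1, is_catch=False,
            questioned_gallery="portrait", prior_portrait=vals, theta=0.7,
            sample_category="face", hidden_gallery="portrait", penalty=10.0,
            initial_slider=0.5, iti_s=2.0, temporal_order=0, spatial_order=0,
            sample_side=1))
        df = _derive_columns(df, "inference", 30.0)
        df["likelihood_q"] = df["prior_q"]
        df["logit_lik_q"] = df["logit_prior_q"]
        plan = SessionPlan(trials=df, endowment=30.0, run_sizes=(n,), seed=None)
        d = pl.session_diagnostics(plan)
        assert d.r_prior_lik_prob == pytest.approx(1.0)

    def test_constant_column_flagged_degenerate(self):
        plan = pl.generate_session(2)
        t = plan.trials.copy()
        t["prior_q"] = 0.6
        d = pl.session_diagnostics(SessionPlan(trials=t, endowment=30.0,
                                               run_sizes=plan.run_sizes, seed=None))
        assert d.degenerate and np.isnan(d.r_prior_lik_prob)

    def test_too_few_trials_rejected(self, plan):
        tiny = SessionPlan(trials=plan.trials.head(2), endowment=30.0,
                           run_sizes=(2,), seed=None)
        with pytest.raises(ValueError):
            pl.session_diagnostics(tiny)


class TestPayout:
    def test_perfect_report_on_true_gallery_keeps_endowment(self, plan):
        reports = np.where(plan.trials["hidden_gallery"] == plan.trials["questioned_gallery"],
                           1.0, 0.0)
        for s in range(20):
            assert pl.simulate_payout(plan, reports, np.random.default_rng(s)) == 30.0

    def test_omission_forfeits_penalty(self, plan):
        reports = np.full(plan.n_trials, np.nan)
        rng = np.random.default_rng(0)
        out = pl.simulate_payout(plan, reports, rng)
        idx_rng = np.random.default_rng(0)
        trial = plan.trials.iloc[int(idx_rng.integers(0, plan.n_trials))]
        assert out == 30.0 - trial["penalty"]

    def test_empty_responses_rejected(self, plan):
        with pytest.raises(ValueError):
            pl.simulate_payout(plan, np.array([]), np.random.default_rng(0))


class TestAveragingVariant:
    def test_counts_match_inference_structure(self, avg_plan):
        assert avg_plan.n_trials == 130
        assert avg_plan.trials["is_catch"].sum() == 10
        assert avg_plan.task == "averaging"

    def test_target_is_mean_of_the_two_probabilities(self, avg_plan):
        nc = avg_plan.non_catch
        assert np.allclose(nc["target"], 0.5 * (nc["prior_q"] + nc["likelihood_q"]))

    def test_catch_target_is_first_gallery_probability(self, avg_plan):
        catch = avg_plan.trials[avg_plan.trials["is_catch"]]
        assert np.allclose(catch["target"], catch["prior_q"])


class TestIO:
    def test_tsv_round_trip_lossless(self, tmp_path, plan):
        p = tmp_path / "session.tsv"
        plan.to_tsv(p)
        back = pl.read_session_tsv(p)
        assert back.n_trials == plan.n_trials
        assert back.endowment == plan.endowment
        assert back.run_sizes == plan.run_sizes
        assert back.seed == plan.seed
        pd.testing.assert_frame_equal(
            back.trials[pl.session.TRIAL_COLUMNS].reset_index(drop=True),
            plan.trials[pl.session.TRIAL_COLUMNS].reset_index(drop=True),
            check_dtype=False, atol=1e-6)
        assert back.to_tsv() == plan.to_tsv()

    def test_external_table_loads(self, tmp_path, plan):
        p = tmp_path / "external.tsv"
        plan.trials[pl.session.TRIAL_COLUMNS].to_csv(p, sep="\t", index=False)
        loaded = pl.load_supplementary_trials(p)
        assert loaded.n_trials == 130
        assert loaded.source.startswith("external:")
        catch = loaded.trials[loaded.trials["is_catch"]]
        assert (catch["likelihood_q"] == 0.5).all()
        d = pl.session_diagnostics(loaded)
        assert abs(d.r_prior_lik_prob) < 0.15

    def test_external_table_missing_columns_listed(self, tmp_path):
        p = tmp_path / "bad.tsv"
        pd.DataFrame({"x": [1, 2]}).to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="prior_portrait"):
            pl.load_supplementary_trials(p)

    def test_external_table_malformed_probability(self, tmp_path, plan):
        t = plan.trials[pl.session.TRIAL_COLUMNS].copy()
        t.loc[t.index[0], "prior_portrait"] = 1.5
        p = tmp_path / "bad2.tsv"
        t.to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="prior"):
            pl.load_supplementary_trials(p)
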