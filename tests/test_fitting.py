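"""Inference: exclusion rule, likelihood assembly, MLE backend, transforms."""

import numpy as np
import pandas as pd
import pytest

import driftlearn as dl
from driftlearn import wiener
from driftlearn.fitting import (ParamLayout, WienerLearningModel,
                                negative_log_likelihood)
from driftlearn.models import PriorSpec


class TestExclusion:
    def test_printed_thresholds_on_forced_list(self):
        table = pd.DataFrame({
            "subject": 1, "rt_s": [0.10, 0.16, 0.50, 2.50, 2.60]})
        kept, rep = dl.exclude_trials(table)
        assert len(kept) == 3
        np.testing.assert_allclose(kept["rt_s"], [0.16, 0.50, 2.50])
        assert rep.loc[0, "n_excluded"] == 2

    def test_all_in_range_is_identity(self, small_model_a_table):
        _, _, table = small_model_a_table
        inr = table[(table["rt_s"] >= 0.16) & (table["rt_s"] <= 2.5)].reset_index(drop=True)
        kept, _ = dl.exclude_trials(inr)
        assert kept.equals(inr)

    def test_contaminated_keep_rate_matches_analytic_expectation(self):
        # ~9,800 trials with 2% uniform(0.05, 3.0) contaminants
        p = (0.8, 1.6, 0.5, 0.25)
        from driftlearn.dynamics import TrajectorySpec
        from driftlearn.simulate import GroundTruth
        subj = dl.SubjectParams(TrajectorySpec("constant", p[0]),
                                TrajectorySpec("constant", 0.0),
                                TrajectorySpec("constant", np.log(p[1])),
                                bias_logit=0.0, ndt_offset=p[3] - 0.001)
        truth = GroundTruth({1: subj, 2: subj}, {1: "AVGP", 2: "AVGP"}, 0.02,
                            (0.05, 3.0))
        spec = dl.ModelSpec("A", n_days=1, trials_per_day=4900)
        design = dl.generate_design(2, 1, 4900, per_level=700, seed=21)
        table = dl.simulate_trials(design, truth, spec, seed=22)
        kept, _ = dl.exclude_trials(table)
        # expected keep probability: mixture of model mass in [0.16, 2.5]
        # and the uniform contaminant law's mass in the window
        cov = spec.coherence_covariate(table["coherence_pct"].to_numpy())
        keep_model = np.mean([
            (wiener.fpt_cdf(2.5, "upper", p) - wiener.fpt_cdf(0.16, "upper", p))
            + (wiener.fpt_cdf(2.5, "lower", p) - wiener.fpt_cdf(0.16, "lower", p))])
        keep_contam = (2.5 - 0.16) / (3.0 - 0.05)
        expect = 0.98 * keep_model + 0.02 * keep_contam
        n = len(table)
        phat = len(kept) / n
        assert abs(phat - expect) < 1.96 * np.sqrt(expect * (1 - expect) / n) + 0.003

    def test_empty_subject_flagged(self):
        table = pd.DataFrame({"subject": [1, 1, 2], "rt_s": [0.5, 0.7, 0.05]})
        with pytest.warns(UserWarning, match="no retained trials"):
            dl.exclude_trials(table)


class TestLikelihood:
    def test_single_trial_pointwise(self, small_model_a_table):
        spec, truth, table = small_model_a_table
        row = table.iloc[[10]].reset_index(drop=True)
        total, pw = negative_log_likelihood(spec, truth.subjects, row)
        assert pw.shape == (1,)
        subj = truth.subjects[row.loc[0, "subject"]]
        v, a, z, t0 = dl.per_trial_params(spec, subj, row)
        bound = "upper" if row.loc[0, "correct"] else "lower"
        direct = wiener.fpt_logdensity(row.loc[0, "rt_s"], bound,
                                       (v[0], a[0], z[0], t0[0]))
        assert pw[0] == pytest.approx(direct, abs=1e-12)
        assert total == pytest.approx(-direct)

    def test_additivity_over_concatenation(self, small_model_a_table):
        spec, truth, table = small_model_a_table
        filtered, _ = dl.exclude_trials(table)
        a = filtered.iloc[:200].reset_index(drop=True)
        b = filtered.iloc[200:].reset_index(drop=True)
        t_all, _ = negative_log_likelihood(spec, truth.subjects, filtered)
        t_a, _ = negative_log_likelihood(spec, truth.subjects, a)
        t_b, _ = negative_log_likelihood(spec, truth.subjects, b)
        assert t_all == pytest.approx(t_a + t_b, rel=1e-12)

    def test_row_order_invariance(self, small_model_a_table):
        spec, truth, table = small_model_a_table
        filtered, _ = dl.exclude_trials(table)
        shuffled = filtered.sample(frac=1.0, random_state=0).reset_index(drop=True)
        t1, _ = negative_log_likelihood(spec, truth.subjects, filtered)
        t2, _ = negative_log_likelihood(spec, truth.subjects, shuffled)
        assert t1 == pytest.approx(t2, rel=1e-12)

    def test_oracle_recomputation_loop(self, small_model_a_table):
        # independent re-implementation: plain python loop over wiener calls
        spec, truth, table = small_model_a_table
        sub = table[table["subject"] == 1].iloc[:100].reset_index(drop=True)
        total, _ = negative_log_likelihood(spec, truth.subjects, sub)
        subj = truth.subjects[1]
        acc = 0.0
        for _, row in sub.iterrows():
            v = subj.dr_intercept.starts + subj.dr_slope.starts * (row.coherence_pct - 6.4)
            a = np.exp(subj.log_rb.starts)
            acc += wiener.fpt_logdensity(
                row.rt_s, "upper" if row.correct else "lower",
                (v, a, subj.z, subj.t0))
        assert total == pytest.approx(-acc, rel=1e-10)

    def test_impossible_trial_makes_total_infinite(self, small_model_a_table):
        spec, truth, table = small_model_a_table
        bad = table.iloc[:5].copy().reset_index(drop=True)
        bad.loc[0, "rt_s"] = truth.subjects[bad.loc[0, "subject"]].t0 / 2
        total, pw = negative_log_likelihood(spec, truth.subjects, bad)
        assert total == np.inf
        assert pw[0] == -np.inf


class TestParamLayout:
    @pytest.mark.parametrize("mid", list("ABCDEF"))
    def test_pack_unpack_round_trip(self, mid):
        spec = dl.ModelSpec(mid, trials_per_day=98)
        layout = ParamLayout(spec)
        rng = np.random.default_rng(3)
        prior = PriorSpec()
        for _ in range(5):
            vec = layout.draw_init(rng, prior, min_rt=0.4)
            subj = layout.unpack(vec, min_rt=0.4)
            back = layout.pack(subj, min_rt=0.4)
            np.testing.assert_allclose(back, vec, atol=1e-9)

    def test_ndt_respects_min_rt_bound(self):
        layout = ParamLayout(dl.ModelSpec("A"))
        for u in (-50.0, 0.0, 50.0):
            vec = np.zeros(layout.size)
            vec[layout.names.index("ndt_u")] = u
            subj = layout.unpack(vec, min_rt=0.3)
            assert 0.001 <= subj.t0 < 0.3
            assert subj.ndt_offset > 0

    def test_parameter_vector_length_matches_count(self):
        for mid in "ABCDEF":
            spec = dl.ModelSpec(mid)
            assert ParamLayout(spec).size == dl.parameter_count(spec, 1)


class TestMle:
    @pytest.fixture(scope="class")
    def one_subject_fit(self):
        spec = dl.ModelSpec("A", n_days=2, trials_per_day=980)
        truth = dl.sample_ground_truth(spec, 1, seed=31,
                                       config=dl.PopulationConfig(contaminant_rate=0.0))
        design = dl.generate_design(1, 2, 980, per_level=140, seed=31)
        table = dl.simulate_trials(design, truth, spec, seed=32)
        filtered, _ = dl.exclude_trials(table)
        res = dl.fit_mle(spec, filtered, n_restarts=3, seed=0)
        return spec, truth, filtered, res

    def test_recovers_constant_parameters_within_ten_percent(self, one_subject_fit):
        spec, truth, _, res = one_subject_fit
        t, e = truth.subjects[1], res.subject_params[1]
        assert e.dr_intercept.starts == pytest.approx(t.dr_intercept.starts, rel=0.10)
        assert np.exp(e.log_rb.starts) == pytest.approx(np.exp(t.log_rb.starts), rel=0.10)
        assert e.t0 == pytest.approx(t.t0, rel=0.10)

    def test_mle_loglik_at_least_truth_loglik(self, one_subject_fit):
        spec, truth, filtered, res = one_subject_fit
        nll_truth, _ = negative_log_likelihood(spec, truth.subjects, filtered)
        assert res.llf >= -nll_truth - 1e-6

    def test_bitwise_determinism_under_seed(self, one_subject_fit):
        spec, _, filtered, res = one_subject_fit
        res2 = dl.fit_mle(spec, filtered, n_restarts=3, seed=0)
        np.testing.assert_array_equal(res2.diagnostics[1]["vec"],
                                      res.diagnostics[1]["vec"])

    def test_pointwise_sums_to_total(self, one_subject_fit):
        _, _, _, res = one_subject_fit
        assert res.pointwise.shape[0] == 1
        assert res.pointwise.sum() == pytest.approx(res.llf, abs=1e-6)

    def test_few_trials_warns(self, small_model_a_table):
        spec, _, table = small_model_a_table
        tiny = table.groupby("subject").head(20).reset_index(drop=True)
        with pytest.warns(UserWarning, match="trials"):
            dl.fit_mle(spec, tiny, n_restarts=1, seed=0, maxiter=30)

    def test_nested_model_attains_lower_nll(self, small_model_a_table):
        # fitted flexible/flexible model must fit at least as well as constant
        spec_a, _, table = small_model_a_table
        filtered, _ = dl.exclude_trials(table)
        res_a = dl.fit_mle(spec_a, filtered, n_restarts=2, seed=1)
        spec_f = dl.ModelSpec("F", n_days=4, trials_per_day=98)
        init = {sid: dl.embed_subject_params(p, spec_f)
                for sid, p in res_a.subject_params.items()}
        res_f = dl.fit_mle(spec_f, filtered, n_restarts=1, seed=1, init=init)
        assert res_f.llf >= res_a.llf - 1e-6


    def test_shrinkage_pulls_subjects_toward_group_mean(self, small_model_a_table):
        spec, _, table = small_model_a_table
        filtered, _ = dl.exclude_trials(table)
        free = dl.fit_mle(spec, filtered, n_restarts=1, seed=3, maxiter=200)
        shrunk = dl.fit_mle(spec, filtered, n_restarts=1, seed=3, maxiter=200,
                            shrinkage=0.05)
        for col in ("dr_int", "log_rb"):
            spread_free = free.natural_estimates()[col].std()
            spread_shrunk = shrunk.natural_estimates()[col].std()
            assert spread_shrunk <= spread_free + 1e-9


class TestModelFrontEnd:
    def test_front_end_applies_exclusion_and_fits(self, small_model_a_table):
        _, _, table = small_model_a_table
        model = WienerLearningModel(table, "A")
        assert model.exclusion_report is not None
        res = model.fit(n_restarts=1, seed=0, maxiter=150)
        assert res.model_id == "A"
        assert res.converged
        s = res.summary()
        assert "log-likelihood" in s and "AIC" in s

    def test_predictions_have_sane_ranges(self, small_model_a_table):
        _, _, table = small_model_a_table
        res = WienerLearningModel(table, "A").fit(n_restarts=1, seed=0, maxiter=150)
        pred = res.predict()
        assert ((pred["pred_accuracy"] > 0) & (pred["pred_accuracy"] < 1)).all()
        assert (pred["pred_rt_s"] > 0).all()

    def test_results_simulate_round_trip(self, small_model_a_table):
        _, _, table = small_model_a_table
        res = WienerLearningModel(table, "A").fit(n_restarts=1, seed=0, maxiter=150)
        sim = res.simulate(seed=3)
        assert len(sim) == len(res.table)
        assert (sim["rt_s"] > 0).all()
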