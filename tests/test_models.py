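"""Candidate-model assembly: forms, parameter counts, per-trial mapping,
priors and nesting embeddings."""

import numpy as np
import pandas as pd
import pytest

import driftlearn as dl
from driftlearn.dynamics import TrajectorySpec
from driftlearn.fitting import negative_log_likelihood
from driftlearn.models import MODEL_FORMS, PriorSpec


def _subject_for(spec, seed=0):
    truth = dl.sample_ground_truth(spec, 1, seed=seed,
                                   config=dl.PopulationConfig(contaminant_rate=0.0))
    return truth.subjects[1]


def _trials(n_days=4, tpd=98):
    design = dl.generate_design(1, n_days, tpd, per_level=tpd // 7, seed=3)
    return design


class TestModelSpec:
    def test_form_mapping(self):
        assert MODEL_FORMS["A"] == ("constant", "constant")
        assert MODEL_FORMS["B"] == ("continuous", "continuous")
        assert MODEL_FORMS["C"] == ("continuous", "day_resetting")
        assert MODEL_FORMS["D"] == ("continuous", "flexible")
        assert MODEL_FORMS["E"] == ("flexible", "continuous")
        assert MODEL_FORMS["F"] == ("flexible", "flexible")

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError):
            dl.ModelSpec("G")

    def test_log_link_changes_only_covariate(self):
        lin = dl.ModelSpec("A")
        logl = dl.ModelSpec("A", coherence_link="log")
        coh = np.array([0.8, 6.4, 51.2])
        np.testing.assert_allclose(lin.coherence_covariate(coh), coh - 6.4)
        np.testing.assert_allclose(logl.coherence_covariate(coh),
                                   np.log(coh) - np.log(6.4))
        assert logl.coherence_covariate(6.4) == pytest.approx(0.0)


class TestParameterCount:
    def test_constant_model_has_five_per_subject(self):
        assert dl.parameter_count(dl.ModelSpec("A"), n_subjects=1) == 5

    def test_counts_scale_with_subjects(self):
        assert dl.parameter_count(dl.ModelSpec("A"), n_subjects=21) == 105

    def test_nesting_order(self):
        for nd in (2, 4, 6):
            k = {m: dl.parameter_count(dl.ModelSpec(m, n_days=nd), 1, n_days=nd)
                 for m in "ACDF"}
            assert k["F"] >= k["D"] >= k["C"] >= k["A"]

    def test_continuous_model_independent_of_n_days(self):
        k2 = dl.parameter_count(dl.ModelSpec("B", n_days=2), 1, n_days=2)
        k6 = dl.parameter_count(dl.ModelSpec("B", n_days=6), 1, n_days=6)
        assert k2 == k6

    def test_group_covariate_adds_fixed_shifts(self):
        spec = dl.ModelSpec("A", group_covariate=True)
        assert dl.parameter_count(spec, 2) == 2 * 5 + 4


class TestPerTrialParams:
    def test_median_coherence_recovers_intercept(self):
        spec = dl.ModelSpec("A", trials_per_day=98)
        subj = _subject_for(spec)
        trials = {"day": np.array([1]), "trial_in_day": np.array([5]),
                  "trial_overall": np.array([5]), "coherence_pct": np.array([6.4])}
        v, a, z, t0 = dl.per_trial_params(spec, subj, trials)
        assert v[0] == pytest.approx(subj.dr_intercept.starts)

    def test_constant_model_identical_across_trials(self):
        spec = dl.ModelSpec("A", trials_per_day=98)
        subj = _subject_for(spec)
        design = _trials()
        same_coh = design[design["coherence_pct"] == 6.4]
        v, a, z, t0 = dl.per_trial_params(spec, subj, same_coh)
        for arr in (v, a, z, t0):
            assert np.ptp(arr) == 0.0

    def test_flexible_boundary_day_start(self):
        spec = dl.ModelSpec("D", trials_per_day=98)
        subj = _subject_for(spec)
        for d in range(1, 5):
            trials = {"day": np.array([d]), "trial_in_day": np.array([1]),
                      "trial_overall": np.array([(d - 1) * 98 + 1]),
                      "coherence_pct": np.array([6.4])}
            _, a, _, _ = dl.per_trial_params(spec, subj, trials)
            assert a[0] == pytest.approx(np.exp(subj.log_rb.starts[d - 1]))

    def test_out_of_design_coherence_warns_but_evaluates(self):
        spec = dl.ModelSpec("A", trials_per_day=98)
        subj = _subject_for(spec)
        trials = {"day": np.array([1]), "trial_in_day": np.array([1]),
                  "trial_overall": np.array([1]), "coherence_pct": np.array([10.0])}
        with pytest.warns(UserWarning):
            v, _, _, _ = dl.per_trial_params(spec, subj, trials)
        expected = subj.dr_intercept.starts + subj.dr_slope.starts * (10.0 - 6.4)
        assert v[0] == pytest.approx(expected)

    def test_group_shift_is_additive_on_drift(self):
        spec = dl.ModelSpec("A", trials_per_day=98)
        subj = _subject_for(spec)
        shifted = dl.SubjectParams(subj.dr_intercept, subj.dr_slope, subj.log_rb,
                                   subj.bias_logit, subj.ndt_offset,
                                   group_effects={"dr": -0.2})
        trials = {"day": np.array([1]), "trial_in_day": np.array([1]),
                  "trial_overall": np.array([1]), "coherence_pct": np.array([6.4])}
        v0 = dl.per_trial_params(spec, subj, trials)[0][0]
        v1 = dl.per_trial_params(spec, shifted, trials)[0][0]
        assert v1 == pytest.approx(v0 - 0.2)


class TestNestingEmbedding:
    def test_constant_embeds_into_dynamic_models_with_equal_likelihood(
            self, small_model_a_table):
        spec_a, truth, table = small_model_a_table
        filtered, _ = dl.exclude_trials(table)
        nll_a, _ = negative_log_likelihood(spec_a, truth.subjects, filtered)
        for mid in ("B", "C", "D", "F"):
            spec_m = dl.ModelSpec(mid, n_days=4, trials_per_day=98)
            embedded = {sid: dl.embed_subject_params(p, spec_m)
                        for sid, p in truth.subjects.items()}
            nll_m, _ = negative_log_likelihood(spec_m, embedded, filtered)
            assert nll_m == pytest.approx(nll_a, abs=1e-8)

    def test_day_resetting_embeds_into_flexible(self):
        spec_c = dl.ModelSpec("C", n_days=4, trials_per_day=98)
        spec_f = dl.ModelSpec("F", n_days=4, trials_per_day=98)
        subj = _subject_for(spec_c, seed=5)
        emb = dl.embed_subject_params(subj, spec_f)
        design = _trials()
        v0, a0, _, _ = dl.per_trial_params(spec_c, subj, design)
        # boundary trajectory must be preserved exactly (day_resetting -> flexible)
        _, a1, _, _ = dl.per_trial_params(spec_f, emb, design)
        np.testing.assert_allclose(a1, a0, rtol=1e-12)


class TestPriors:
    def test_rate_prior_centers(self):
        prior = PriorSpec()
        full = dl.ModelSpec("B", n_days=4, trials_per_day=700)
        within = dl.ModelSpec("C", n_days=4, trials_per_day=700)
        # continuous: 25% of 2800 = 700; within-day: 25% of 700 = 175
        assert prior.dist_for("dr_rate", full).mean() == pytest.approx(np.log2(700))
        assert prior.dist_for("rb_rate", within).mean() == pytest.approx(np.log2(175))

    def test_stated_prior_families(self):
        prior = PriorSpec()
        spec = dl.ModelSpec("A")
        drift = prior.dist_for("dr_int", spec)
        assert drift.mean() == pytest.approx(1.0)
        lb = prior.dist_for("log_rb", spec)
        assert (lb.mean(), lb.std()) == (pytest.approx(-0.6), pytest.approx(1.3))
        bias = prior.dist_for("bias_logit", spec)
        assert (bias.mean(), bias.std()) == (0.0, 1.0)
        ndt = prior.dist_for("ndt_offset", spec)
        assert ndt.mean() == pytest.approx(0.15)

    def test_subject_params_invariants(self):
        with pytest.raises(ValueError):
            dl.SubjectParams(TrajectorySpec("constant", 0.5),
                             TrajectorySpec("constant", 0.05),
                             TrajectorySpec("constant", 0.3),
                             bias_logit=0.0, ndt_offset=-0.1)
        subj = _subject_for(dl.ModelSpec("A"))
        assert 0.0 < subj.z < 1.0
        assert subj.t0 > 0.001
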