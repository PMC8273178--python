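"""Generators: schedule invariants, BOLD simulation, Bernoulli observer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromasupp.hrf import CONDITIONS, model_response
from chromasupp.psychometrics import aggregate_rates, fit_psychometric
from chromasupp.synthetic import (
    BoldSimConfig,
    ObserverConfig,
    STUDY_TEMPORAL,
    ScheduleConfig,
    condition_params_for_peak,
    study_2afc_cohort,
    study_bold_cohort,
    schedule_fmri,
    simulate_2afc,
    simulate_bold,
)


class TestSchedule:
    def test_block_counts_match_design(self):
        sched = schedule_fmri(seed=0)
        counts = sched.blocks_per_condition(include_excluded=True)
        assert counts == {c: 54 for c in CONDITIONS}
        assert sched.total_blocks(include_excluded=True) == 216

    def test_excluding_one_run_removes_three_blocks_per_condition(self):
        sched = schedule_fmri(seed=1)
        before = sched.blocks_per_condition()
        run = sched.retained_runs()[0]
        sched.mark_excluded(run)
        after = sched.blocks_per_condition()
        assert all(before[c] - after[c] == 3 for c in CONDITIONS)

    @settings(max_examples=100, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_multiplicity_invariant_for_every_seed(self, seed):
        sched = schedule_fmri(seed=seed)
        for order in sched.run_orders:
            assert len(order) == 12
            for c in CONDITIONS:
                assert order.count(c) == 3

    def test_awareness_errors_drive_exclusion(self):
        sched = schedule_fmri(ScheduleConfig(awareness_accuracy=0.5), seed=3)
        limit = sched.config.awareness_error_limit
        assert sched.excluded_runs == {
            i for i, e in enumerate(sched.awareness_errors) if e > limit}

    def test_impossible_multiplicity_rejected(self):
        with pytest.raises(ValueError):
            ScheduleConfig(blocks_per_run=10)


@pytest.fixture(scope="module")
def sim_setup():
    per_cond = {
        c: condition_params_for_peak(STUDY_TEMPORAL, peak, condition=c)
        for c, peak in zip(CONDITIONS, (3.23, 3.06, 3.11, 3.16))
    }
    return STUDY_TEMPORAL, per_cond


class TestSimulateBold:
    def test_zero_noise_reproduces_model(self, sim_setup):
        temporal, per_cond = sim_setup
        sched = schedule_fmri(seed=0)
        cfg = BoldSimConfig(temporal=temporal, per_condition=per_cond,
                            noise_sd=0.0)
        data = simulate_bold(sched, cfg, seed=0)
        for c in CONDITIONS:
            clean = model_response(temporal, per_cond[c])
            assert np.allclose(data[c].responses, clean)
            assert data[c].n_blocks_averaged == 54

    def test_same_seed_is_identical(self, sim_setup):
        temporal, per_cond = sim_setup
        sched = schedule_fmri(seed=0)
        cfg = BoldSimConfig(temporal=temporal, per_condition=per_cond,
                            noise_sd=0.15, mode="per_block")
        a = simulate_bold(sched, cfg, seed=9)
        b = simulate_bold(sched, cfg, seed=9)
        for c in CONDITIONS:
            assert np.array_equal(a[c].responses, b[c].responses)

    def test_block_averaging_shrinks_noise_by_sqrt_n(self, sim_setup):
        # sampling-theory oracle: the SD of a 54-block mean is sd/sqrt(54)
        temporal, per_cond = sim_setup
        sched = schedule_fmri(seed=0)
        sd = 0.2
        cfg = BoldSimConfig(temporal=temporal, per_condition=per_cond,
                            noise_sd=sd, mode="per_block")
        clean = model_response(temporal, per_cond["/0"])
        reps = np.array([
            simulate_bold(sched, cfg, seed=100 + r)["/0"].responses - clean
            for r in range(50)
        ])
        empirical = reps.std(ddof=1, axis=0).mean()
        assert empirical == pytest.approx(sd / np.sqrt(54), rel=0.20)

    def test_config_validation(self, sim_setup):
        temporal, per_cond = sim_setup
        with pytest.raises(ValueError):
            BoldSimConfig(temporal=temporal, per_condition=per_cond,
                          noise_sd=-0.1)
        with pytest.raises(ValueError):
            BoldSimConfig(temporal=temporal, per_condition=per_cond, ar1=1.0)


class TestConditionParamsForPeak:
    @pytest.mark.parametrize("target", [0.7, 1.69, 3.14])
    def test_peak_hits_target(self, target):
        cp = condition_params_for_peak(STUDY_TEMPORAL, target)
        t = np.arange(0, 30.001, 0.01)
        from chromasupp.hrf import STIM_DURATION, pulse_window_integral
        g1 = pulse_window_integral(STUDY_TEMPORAL.T1,
                                   STUDY_TEMPORAL.alpha1,
                                   t - STIM_DURATION, t)
        g2 = pulse_window_integral(STUDY_TEMPORAL.T2,
                                   STUDY_TEMPORAL.alpha2,
                                   t - STIM_DURATION, t)
        curve = cp.a1 * g1 + cp.a2 * g2 + cp.b * t + cp.d
        assert curve.max() == pytest.approx(target, abs=1e-6)


class TestSimulate2AFC:
    def test_response_saturates_far_above_mu(self):
        cfg = ObserverConfig(mu={"/0": 0.50}, sigma={"/0": 0.01},
                             contrasts=(0.60, 0.62, 0.64), n_sessions=3400)
        trials = simulate_2afc(cfg, seed=0)
        # every contrast sits >= 10 sigma above mu
        assert trials["response"].mean() >= 0.999

    def test_each_session_has_36_trials(self):
        trials = simulate_2afc(ObserverConfig(), seed=1)
        per_session = trials.groupby("session").size()
        assert set(per_session) == {36}
        assert per_session.size == 12

    def test_generator_is_pure(self):
        a = simulate_2afc(ObserverConfig(), seed=5)
        b = simulate_2afc(ObserverConfig(), seed=5)
        assert a.equals(b)

    def test_end_to_end_sigma_recovery(self):
        sigmas = []
        for seed in range(5):
            cfg = ObserverConfig(mu={"/0": 0.50}, sigma={"/0": 0.06},
                                 n_sessions=202)
            trials = simulate_2afc(cfg, seed=seed)
            fit = fit_psychometric(
                aggregate_rates(trials)[["test_contrast", "n_trials",
                                         "n_chose_test"]])
            sigmas.append(fit.sigma)
        assert np.mean(sigmas) == pytest.approx(0.06, rel=0.10)

    def test_lapse_validation(self):
        with pytest.raises(ValueError):
            ObserverConfig(lapse=0.7)


class TestPaperLikePresets:
    def test_bold_cohort_schema_and_determinism(self):
        df, truth = study_bold_cohort(seed=4, n_subjects=3)
        assert set(df.columns) == {"subject", "area", "condition", "t_s",
                                   "psc", "n_blocks"}
        assert df["subject"].nunique() == 3
        assert len(df) == 3 * 4 * 13
        df2, _ = study_bold_cohort(seed=4, n_subjects=3)
        assert df.equals(df2)

    def test_2afc_cohort_contains_inflated_outlier(self):
        trials = study_2afc_cohort(seed=2, n_subjects=5)
        assert trials["subject"].nunique() == 5
        # last observer is generated with ~4x sigma: their responses are
        # far less consistent; check via fitted sigma
        sigmas = {}
        for subject, sub in trials.groupby("subject"):
            rates = aggregate_rates(sub)
            fits = [fit_psychometric(g[["test_contrast", "n_trials",
                                        "n_chose_test"]])
                    for _, g in rates.groupby("chroma")]
            sigmas[subject] = np.mean([f.sigma for f in fits])
        assert max(sigmas, key=sigmas.get) == "P05"
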