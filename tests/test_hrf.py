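"""HRF model: window integrals, error value, joint fit, peaks."""

import numpy as np
import pytest

from chromasupp.hrf import (
    CONDITIONS,
    BlockTimeCourse,
    ConditionParams,
    FitConfig,
    HRFTemporalParams,
    JointHRFFit,
    TimeGrid,
    error_value,
    error_value_detailed,
    fit_joint_hrf,
    model_response,
    normalize_peaks,
    peak_response,
    pulse_window_integral,
)


def _quadrature_integral(T, alpha, lower, upper, dt=1e-3):
    lo = max(lower, 0.0)
    if upper <= lo:
        return 0.0
    tau = np.arange(lo, upper + dt, dt)
    tau[-1] = upper
    return np.trapezoid(np.exp(-((tau - T) ** 2) / (2 * alpha**2)), tau)


class TestPulseWindowIntegral:
    def test_empty_interval_is_zero(self):
        assert pulse_window_integral(6.0, 2.0, 5.0, 5.0) == 0.0

    def test_heaviside_gates_negative_windows(self):
        assert pulse_window_integral(6.0, 2.0, -15.0, 0.0) == 0.0

    def test_closed_form_matches_millisecond_trapezoid(self):
        exact = pulse_window_integral(6.0, 2.0, 0.0, 15.0)
        approx = _quadrature_integral(6.0, 2.0, 0.0, 15.0, dt=1e-3)
        assert exact == pytest.approx(approx, rel=1e-8)

    def test_random_parameter_box_against_quadrature(self):
        # finer step: the O(dt^2) trapezoid error of narrow pulses at 1 ms
        # sits above the 1e-8 target this check enforces
        rng = np.random.default_rng(0)
        for _ in range(25):
            T = rng.uniform(2, 25)
            alpha = rng.uniform(0.5, 8)
            lower = rng.uniform(-15, 25)
            upper = lower + rng.uniform(0, 20)
            exact = pulse_window_integral(T, alpha, lower, upper)
            assert exact == pytest.approx(
                _quadrature_integral(T, alpha, lower, upper, dt=1e-4),
                rel=1e-8, abs=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pulse_window_integral(6.0, -1.0, 0.0, 10.0)
        with pytest.raises(ValueError):
            pulse_window_integral(6.0, 2.0, 5.0, 4.0)


class TestModelResponse:
    def test_degenerate_constant_and_linear_terms(self, true_temporal):
        grid = TimeGrid()
        t = grid.as_array()
        flat = ConditionParams(a1=1e-9, a2=-1e-9, b=0.0, d=1.7)
        assert np.allclose(model_response(true_temporal, flat, grid), 1.7,
                           atol=1e-7)
        ramp = ConditionParams(a1=1e-9, a2=-1e-9, b=1.0, d=0.0)
        assert np.allclose(model_response(true_temporal, ramp, grid), t,
                           atol=1e-7)

    def test_response_at_onset_is_offset_only(self, true_temporal):
        # the [-15, 0] window is annihilated by the Heaviside gate
        cp = ConditionParams(a1=5.0, a2=-2.0, b=0.0, d=0.42)
        assert model_response(true_temporal, cp, TimeGrid())[0] == \
            pytest.approx(0.42)


class TestErrorValue:
    def test_perfect_fit_is_zero(self, noise_free_data):
        curves = [tc.responses for tc in noise_free_data]
        assert error_value(noise_free_data, curves) == 0.0

    def test_ten_percent_offset_closed_form(self):
        data = [np.full(13, 1.1)] * 4
        curves = [np.ones(13)] * 4
        assert error_value(data, curves) == pytest.approx(0.52, rel=1e-12)

    def test_matches_double_loop_resummation(self):
        rng = np.random.default_rng(3)
        data = [rng.normal(1.0, 0.3, 13) for _ in range(4)]
        curves = [rng.normal(1.0, 0.3, 13) for _ in range(4)]
        eps = 1e-3
        expected = 0.0
        for r, m in zip(data, curves):
            for rv, mv in zip(r, m):
                denom = mv if abs(mv) >= eps else np.sign(mv) * eps or eps
                expected += ((rv - mv) / denom) ** 2
        assert error_value(data, curves, eps) == pytest.approx(expected,
                                                               rel=1e-12)

    def test_invariant_under_condition_permutation(self):
        rng = np.random.default_rng(4)
        data = [rng.normal(1, 0.2, 13) for _ in range(4)]
        curves = [rng.normal(1, 0.2, 13) for _ in range(4)]
        ev = error_value(data, curves)
        order = [2, 0, 3, 1]
        assert error_value([data[i] for i in order],
                           [curves[i] for i in order]) == pytest.approx(ev)

    def test_clamped_denominators_are_counted(self):
        data = [np.ones(13)] * 4
        curves = [np.full(13, 1e-6)] * 4
        _, n_clamped = error_value_detailed(data, curves, eps=1e-3)
        assert n_clamped == 52


class TestJointFit:
    def test_noise_free_recovery(self, noise_free_data, true_temporal,
                                 true_condition_params):
        fit = fit_joint_hrf(noise_free_data, FitConfig(seed=0))
        assert fit.ev <= 1e-6
        rel = np.abs(fit.temporal.as_array() - true_temporal.as_array()) \
            / true_temporal.as_array()
        assert rel.max() < 0.01
        for c in CONDITIONS:
            est, true = fit.per_condition[c], true_condition_params[c]
            assert est.a1 == pytest.approx(true.a1, rel=0.01)
            assert est.a2 == pytest.approx(true.a2, rel=0.01)

    def test_shared_temporal_with_distinct_amplitudes(self, noise_free_data):
        fit = fit_joint_hrf(noise_free_data, FitConfig(seed=0))
        # one temporal parameter set serves all four conditions, whose
        # amplitudes nevertheless differ
        a1s = [fit.per_condition[c].a1 for c in CONDITIONS]
        assert len(set(np.round(a1s, 6))) == 4
        for c in CONDITIONS:
            curve = model_response(fit.temporal, fit.per_condition[c],
                                   noise_free_data[0].grid)
            assert np.allclose(curve, fit.curves[c])

    def test_fit_is_deterministic(self, noise_free_data):
        rng = np.random.default_rng(8)
        noisy = [BlockTimeCourse(tc.condition,
                                 tc.responses + rng.normal(0, 0.02, 13))
                 for tc in noise_free_data]
        f1 = fit_joint_hrf(noisy, FitConfig(seed=5))
        f2 = fit_joint_hrf(noisy, FitConfig(seed=5))
        assert f1.ev == f2.ev
        assert np.array_equal(f1.temporal.as_array(), f2.temporal.as_array())

    def test_stored_ev_consistent_with_recomputation(self, noise_free_data):
        fit = fit_joint_hrf(noise_free_data, FitConfig(seed=0))
        recomputed = error_value(
            noise_free_data, [fit.curves[c] for c in CONDITIONS])
        assert recomputed == pytest.approx(fit.ev, rel=1e-10, abs=1e-15)

    def test_wrong_condition_count_rejected(self, noise_free_data):
        with pytest.raises(ValueError, match="four"):
            fit_joint_hrf(noise_free_data[:3])


class TestPeakResponse:
    def _fit_for(self, temporal, cp):
        return JointHRFFit(temporal=temporal, per_condition={cp.condition: cp},
                           ev=0.0, peaks={}, curves={}, diagnostics={})

    def test_constant_curve_peak(self, true_temporal):
        cp = ConditionParams(a1=1e-9, a2=-1e-9, b=0.0, d=2.5, condition="/0")
        fit = self._fit_for(true_temporal, cp)
        assert peak_response(fit, "/0") == pytest.approx(2.5, abs=1e-7)

    def test_peak_is_linear_in_a1(self, true_temporal):
        base = ConditionParams(a1=1.0, a2=-1e-9, b=0.0, d=0.0, condition="/0")
        double = ConditionParams(a1=2.0, a2=-1e-9, b=0.0, d=0.0, condition="/0")
        p1 = peak_response(self._fit_for(true_temporal, base), "/0")
        p2 = peak_response(self._fit_for(true_temporal, double), "/0")
        assert p2 == pytest.approx(2 * p1, rel=1e-9)

    def test_dense_grid_matches_brute_force(self, true_temporal,
                                            true_condition_params):
        cp = true_condition_params["/0"]
        fit = self._fit_for(true_temporal, cp)
        peak = peak_response(fit, "/0", dt=0.01)
        tt = np.arange(0.0, 30.0 + 1e-9, 0.001)
        from chromasupp.hrf import STIM_DURATION
        g1 = pulse_window_integral(true_temporal.T1, true_temporal.alpha1,
                                   tt - STIM_DURATION, tt)
        g2 = pulse_window_integral(true_temporal.T2, true_temporal.alpha2,
                                   tt - STIM_DURATION, tt)
        brute = (cp.a1 * g1 + cp.a2 * g2 + cp.b * tt + cp.d).max()
        assert peak == pytest.approx(brute, abs=1e-4)

    def test_drift_exclusion_mode(self, true_temporal):
        cp = ConditionParams(a1=1.0, a2=-0.3, b=0.05, d=1.0, condition="/0")
        fit = self._fit_for(true_temporal, cp)
        with_drift = peak_response(fit, "/0", include_drift=True)
        pulses_only = peak_response(fit, "/0", include_drift=False)
        assert with_drift > pulses_only


class TestNormalizePeaks:
    def test_subtract_examples(self):
        assert np.allclose(normalize_peaks([1, 2, 3, 4]),
                           [-1.5, -0.5, 0.5, 1.5])
        assert np.allclose(normalize_peaks([2.2] * 4), 0.0)

    def test_subtract_mode_sums_to_zero(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            vals = rng.normal(3, 1, 4)
            assert normalize_peaks(vals).sum() == pytest.approx(0.0, abs=1e-12)

    def test_ratio_mode(self):
        out = normalize_peaks({"/0": 2.0, "/2": 4.0, "/4": 2.0, "/6": 0.0},
                              mode="ratio")
        assert out["/2"] == pytest.approx(2.0)

    def test_requires_four_finite_values(self):
        with pytest.raises(ValueError):
            normalize_peaks([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            normalize_peaks([1.0, 2.0, np.nan, 3.0])


def test_temporal_param_validation():
    with pytest.raises(ValueError):
        HRFTemporalParams(T1=16.0, T2=6.0, alpha1=2.0, alpha2=4.0)
    with pytest.raises(ValueError):
        HRFTemporalParams(T1=6.0, T2=16.0, alpha1=-1.0, alpha2=4.0)


def test_condition_param_sign_constraints():
    with pytest.raises(ValueError):
        ConditionParams(a1=-1.0, a2=-0.5, b=0.0, d=0.0)
    with pytest.raises(ValueError):
        ConditionParams(a1=1.0, a2=0.5, b=0.0, d=0.0)


def test_time_grid_requires_13_uniform_samples():
    with pytest.raises(ValueError):
        TimeGrid(tuple(np.arange(12) * 2.5))
    with pytest.raises(ValueError):
        TimeGrid(tuple(np.r_[np.arange(12) * 2.5, 31.0]))
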