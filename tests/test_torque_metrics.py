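"""Torque-metric extraction against analytic and construction oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import neurofatigue as nf
from neurofatigue.errors import (
    InsufficientSamplesError,
    InvalidInputError,
    InvalidResponseError,
    OnsetNotFoundError,
    TargetNotReachedError,
)
from neurofatigue.trace import SampledTrace


def ramp_trace(start=0.5, rate=100.0, slope=1000.0, total=2.0):
    t = np.arange(int(total * rate)) / rate
    return SampledTrace(np.maximum(t - start, 0) * slope, rate)


class TestOnsetDetection:
    def test_clean_ramp_onset(self):
        tr = ramp_trace(start=0.5)
        assert nf.detect_torque_onset(tr) == pytest.approx(0.5, abs=0.01)

    def test_flat_trace_raises(self):
        tr = SampledTrace(np.zeros(200), 100.0)
        with pytest.raises(OnsetNotFoundError):
            nf.detect_torque_onset(tr)

    def test_noisy_ramp_within_20ms(self, rng):
        """Monte-Carlo: detected onset within 20 ms of the true ramp start."""
        errors = []
        for _ in range(300):
            tr = ramp_trace(slope=1069.0)
            noisy = tr.with_values(tr.values + rng.normal(0, 8.6, len(tr)))
            errors.append(nf.detect_torque_onset(noisy) - 0.5)
        assert np.mean(np.abs(errors)) < 0.02

    def test_short_baseline_rejected(self):
        tr = SampledTrace(np.ones(10), 100.0)
        with pytest.raises(InsufficientSamplesError):
            nf.detect_torque_onset(tr, baseline_window=0.005)


class TestRTD:
    def test_linear_ramp_exact(self):
        tr = ramp_trace(start=0.5, slope=1000.0)
        assert nf.compute_rtd(tr, 0.5) == pytest.approx(1000.0, rel=1e-12)

    def test_constant_zero_slope(self):
        tr = SampledTrace(np.full(100, 50.0), 100.0)
        assert nf.compute_rtd(tr, 0.1) == pytest.approx(0.0, abs=1e-12)

    def test_quadratic_matches_hand_ols(self):
        """OLS oracle computed directly from the normal equations."""
        rate, a = 100.0, 5000.0
        t = np.arange(200) / rate
        tr = SampledTrace(a * t**2, rate)
        got = nf.compute_rtd(tr, 0.0)
        tw = t[t <= 0.075 + 1e-9]
        yw = a * tw**2
        tc = tw - tw.mean()
        expected = np.dot(tc, yw - yw.mean()) / np.dot(tc, tc)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_too_few_samples_raises(self):
        tr = SampledTrace(np.arange(10.0), 10.0)
        with pytest.raises(InsufficientSamplesError):
            nf.compute_rtd(tr, 0.0, window=0.075)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(offset=st.floats(-500, 500), scale=st.floats(0.1, 10))
    def test_offset_invariance_and_scaling(self, offset, scale):
        tr = ramp_trace(slope=800.0)
        base = nf.compute_rtd(tr, 0.5)
        shifted = nf.compute_rtd(tr.with_values(tr.values + offset), 0.5)
        scaled = nf.compute_rtd(tr.with_values(tr.values * scale), 0.5)
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-9)
        assert scaled == pytest.approx(base * scale, rel=1e-9)


class TestPeakMean:
    def test_half_sine(self):
        rate = 1000.0
        t = np.arange(400) / rate
        tr = SampledTrace(172.8 * np.sin(np.pi * t / 0.4), rate)
        t_peak, t_mean, t2p = nf.compute_tpeak_tmean(tr, 0.0, 0.4)
        assert t_peak == pytest.approx(172.8, rel=1e-4)
        assert t2p == pytest.approx(0.2, abs=2e-3)

    def test_constant_window(self):
        tr = SampledTrace(np.full(100, 50.0), 100.0)
        assert nf.compute_tpeak_tmean(tr, 0.2, 0.8) == (50.0, 50.0, 0.0)

    def test_triangle_direct_summation_oracle(self):
        rate = 100.0
        t = np.arange(101) / rate
        y = 100.0 * (1 - np.abs(t - 0.5) / 0.5)
        tr = SampledTrace(y, rate)
        t_peak, t_mean, _ = nf.compute_tpeak_tmean(tr, 0.0, 1.0)
        sel = t < 1.0 - 1e-12
        assert t_mean == pytest.approx(y[sel].sum() / sel.sum(), rel=1e-12)
        assert t_peak == 100.0

    def test_empty_interval_raises(self):
        tr = SampledTrace(np.ones(50), 100.0)
        with pytest.raises(InsufficientSamplesError):
            nf.compute_tpeak_tmean(tr, 0.3, 0.3)


class TestTimeToVelocity:
    def test_linear_ramp_interpolated(self):
        rate = 1000.0
        t = np.arange(200) / rate
        tr = SampledTrace(240.0 * t / 0.057, rate)
        assert nf.time_to_target_velocity(tr, 240.0, 0.0) == pytest.approx(0.057, abs=1e-9)

    def test_starts_at_target(self):
        tr = SampledTrace(np.full(50, 240.0), 100.0)
        assert nf.time_to_target_velocity(tr, 240.0, 0.0) == 0.0

    def test_never_reached_raises(self):
        tr = SampledTrace(np.full(50, 200.0), 100.0)
        with pytest.raises(TargetNotReachedError):
            nf.time_to_target_velocity(tr, 240.0, 0.0)


class TestIMVC:
    def test_plateau_value(self):
        tr = SampledTrace(np.full(400, 320.0), 100.0)
        assert nf.compute_imvc(tr, stim_time=2.5) == 320.0

    def test_spike_after_stim_excluded(self):
        v = np.full(400, 300.0)
        v[260] = 500.0  # spike at 2.6 s, after the stimulation
        tr = SampledTrace(v, 100.0)
        assert nf.compute_imvc(tr, stim_time=2.5) == 300.0

    def test_window_before_trace_start_raises(self):
        tr = SampledTrace(np.ones(30), 100.0)
        with pytest.raises(InsufficientSamplesError):
            nf.compute_imvc(tr, stim_time=0.2)


class TestVoluntaryActivation:
    @pytest.mark.parametrize("sup,rest,expected", [
        (5.0, 100.0, 95.0), (0.0, 100.0, 100.0), (100.0, 100.0, 0.0)])
    def test_closed_form(self, sup, rest, expected):
        assert nf.voluntary_activation(sup, rest) == pytest.approx(expected)

    def test_invalid_resting(self):
        with pytest.raises(InvalidInputError):
            nf.voluntary_activation(5.0, 0.0)

    def test_clipping_warns(self):
        with pytest.warns(UserWarning):
            assert nf.voluntary_activation(150.0, 100.0) == 0.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(sup=st.floats(0, 50), rest=st.floats(60, 200), d=st.floats(0.1, 10))
    def test_monotone_in_both_arguments(self, sup, rest, d):
        base = nf.voluntary_activation(sup, rest)
        assert nf.voluntary_activation(sup + d, rest) <= base
        assert nf.voluntary_activation(sup, rest + d) >= base


class TestEvokedMetrics:
    def test_peak_of_generated_doublet(self):
        tr = nf.generate_evoked_response(120.6, 0.02, 0.1, 1000.0)
        e_tpeak, _ = nf.evoked_metrics(tr)
        assert e_tpeak == pytest.approx(120.6, rel=1e-4)

    def test_ertd_matches_analytic_derivative_max(self):
        """At a high sampling rate the central-difference maximum converges to
        the analytic derivative maximum K(1/τr − 1/τd) at t = 0."""
        from neurofatigue.synthetic_data import true_evoked_rtd
        tr = nf.generate_evoked_response(120.6, 0.09, 0.12, 20000.0)
        _, e_rtd = nf.evoked_metrics(tr)
        assert e_rtd == pytest.approx(true_evoked_rtd(120.6, 0.09, 0.12), rel=0.01)

    def test_zero_response_rejected(self):
        tr = SampledTrace(np.zeros(100), 100.0)
        with pytest.raises(InvalidResponseError):
            nf.evoked_metrics(tr)


class TestDbRatio:
    def test_reference_values(self):
        assert nf.db_ratio(107.7, 121.0) == pytest.approx(0.89, abs=0.005)
        assert nf.db_ratio(5.0, 5.0) == 1.0
        assert nf.db_ratio(0.64 * 88.0, 88.0) == pytest.approx(0.64, rel=1e-12)

    def test_non_positive_rejected(self):
        with pytest.raises(InvalidInputError):
            nf.db_ratio(0.0, 100.0)
        with pytest.raises(InvalidInputError):
            nf.db_ratio(10.0, -1.0)


class TestFullChainOnGeneratedData:
    def test_noise_free_extraction_matches_truth(self, noise_free_experiment):
        """The torque chain on noise-free contractions recovers the programmed
        RTD, T_peak and T_mean to <= 0.1 % relative error."""
        exp = noise_free_experiment
        res = {}
        for rec in exp.contractions[:6]:
            m = nf.contraction_torque_metrics(rec.torque, rec.velocity)
            row = exp.truth.contractions.query(
                "subject == @rec.subject and set == @rec.set and rep == @rec.rep"
            ).iloc[0]
            assert m.rtd == pytest.approx(row.rtd, rel=1e-3)
            assert m.t_peak == pytest.approx(row.t_peak, rel=1e-3)
            assert m.t_mean == pytest.approx(row.t_mean, rel=1e-3)
            res[rec.subject] = m
        assert res

    def test_onset_plus_rtd_on_pure_ramp_equals_endpoint_slope(self):
        tr = ramp_trace(slope=900.0)
        onset = nf.detect_torque_onset(tr)
        rtd = nf.compute_rtd(tr, onset)
        t, y = tr.window(onset, onset + 0.0751)
        assert rtd == pytest.approx((y[-1] - y[0]) / (t[-1] - t[0]), rel=1e-9)
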