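"""Transient metrics: closed-form agreement on noiseless traces, invariance
properties, and Monte-Carlo parameter recovery on noisy ones."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocal import kinetics, simulate
from mitocal.kinetics import (
    FluorescenceTrace,
    KineticsConfig,
    NoResponse,
    analyze_batch,
    analyze_transient,
    clearance_times,
    detect_onset,
    estimate_baseline,
    max_rate,
    peak_metrics,
)


def make_trace(values, dt=0.5, t_app=30.0):
    v = np.asarray(values, dtype=float)
    return FluorescenceTrace(time=np.arange(v.size) * dt, fluorescence=v, t_app=t_app)


class TestBaseline:
    def test_constant_trace(self, constant_trace, default_config):
        assert estimate_baseline(constant_trace, default_config) == (100.0, 0.0)

    def test_hand_computed_mean_and_sd(self):
        # exactly three samples {98, 100, 102} inside the window
        f = np.concatenate([[98, 100, 102, 98, 100, 102], np.full(30, 200.0)])
        tr = make_trace(f, dt=1.0, t_app=6.0)
        f0, sd = estimate_baseline(tr, KineticsConfig(baseline_window=6.0))
        assert f0 == pytest.approx(100.0)
        assert sd == pytest.approx(np.std([98, 100, 102] * 2, ddof=1))

    def test_noiseless_generator_baseline(self):
        p = simulate.TraceParams(baseline_f0=500.0)
        f0, sd = estimate_baseline(simulate.simulate_trace(p))
        assert (f0, sd) == (500.0, 0.0)

    def test_too_few_prestimulus_samples(self):
        tr = make_trace(np.full(30, 1.0), dt=1.0, t_app=2.0)
        with pytest.raises(ValueError, match="pre-stimulus"):
            estimate_baseline(tr, KineticsConfig(baseline_window=3.0))


class TestOnset:
    def test_constant_trace_has_no_response(self, constant_trace, default_config):
        base = estimate_baseline(constant_trace, default_config)
        with pytest.raises(NoResponse):
            detect_onset(constant_trace, base, default_config)

    def test_noiseless_latency_within_one_sample(self, canonical_trace,
                                                 canonical_params, default_config):
        base = estimate_baseline(canonical_trace, default_config)
        onset = detect_onset(canonical_trace, base, default_config)
        assert onset == pytest.approx(canonical_params.latency,
                                      abs=canonical_params.dt)

    def test_noisy_latency_recovery(self, canonical_params, default_config):
        # 2 % amplitude noise, 200 seeds: within ±2·dt in at least 95 %
        ok = 0
        for seed in range(200):
            p = dataclasses.replace(canonical_params,
                                    noise_sd=0.02 * canonical_params.amplitude,
                                    seed=seed)
            m = analyze_transient(simulate.simulate_trace(p), default_config)
            ok += abs(m.response_time - p.latency) <= 2 * p.dt
        assert ok >= 0.95 * 200


class TestPeak:
    def test_noiseless_amplitude_and_time_to_peak(self, canonical_trace,
                                                  default_config):
        base = estimate_baseline(canonical_trace, default_config)
        onset = detect_onset(canonical_trace, base, default_config)
        amp, ttp, _ = peak_metrics(canonical_trace, base, onset)
        assert amp == pytest.approx(2450.0)
        assert ttp == pytest.approx(10.0, abs=0.5)

    def test_step_trace_tie_break_earliest(self):
        f = np.concatenate([np.zeros(40), np.ones(40)])
        tr = make_trace(f, dt=1.0, t_app=30.0)
        amp, ttp, i_peak = peak_metrics(tr, (0.0, 0.0), 10.0)
        assert ttp == 0.0
        assert i_peak == 40

    def test_noisy_amplitude_bias_bounded(self, canonical_params, default_config):
        noise_sd = 0.02 * canonical_params.amplitude
        errs = []
        for seed in range(200):
            p = dataclasses.replace(canonical_params, noise_sd=noise_sd, seed=seed)
            m = analyze_transient(simulate.simulate_trace(p), default_config)
            errs.append(abs(m.amplitude - p.amplitude))
        assert np.mean(errs) <= 3 * noise_sd


class TestMaxRate:
    def test_noiseless_linear_rise_exact(self, canonical_trace, default_config):
        base = estimate_baseline(canonical_trace, default_config)
        onset = detect_onset(canonical_trace, base, default_config)
        _, _, i_peak = peak_metrics(canonical_trace, base, onset)
        rate, low_conf = max_rate(canonical_trace, onset, i_peak, default_config)
        assert rate == pytest.approx(245.0, rel=1e-9)
        assert not low_conf

    def test_constant_trace_forced_evaluation(self, constant_trace, default_config):
        rate, _ = max_rate(constant_trace, 0.0, constant_trace.n - 1, default_config)
        assert rate == pytest.approx(0.0)

    def test_two_sample_rise_flagged_low_confidence(self, default_config):
        f = np.concatenate([np.zeros(40), [5.0], np.full(40, 10.0)])
        tr = make_trace(f, dt=1.0, t_app=39.0)
        rate, low_conf = max_rate(tr, 1.0, 41, default_config)
        assert low_conf

    def test_noisy_rate_recovery(self, canonical_params, default_config):
        # 1 % noise, window 5: the max-of-derivative estimator carries a
        # small upward bias; mean relative error stays within 10 %
        errs = []
        for seed in range(200):
            p = dataclasses.replace(canonical_params,
                                    noise_sd=0.01 * canonical_params.amplitude,
                                    seed=seed)
            m = analyze_transient(simulate.simulate_trace(p), default_config)
            errs.append(abs(m.max_rate - p.rise_slope) / p.rise_slope)
        assert np.mean(errs) <= 0.10


class TestClearance:
    def test_closed_form_exponential(self, default_config):
        p = dataclasses.replace(simulate.TraceParams(), decay_tau=30.0,
                                rise_slope=245.0, rise_duration=10.0,
                                t_app=30.0, latency=14.0)
        m = analyze_transient(simulate.simulate_trace(p), default_config)
        assert m.t25 == pytest.approx(30 * math.log(4 / 3), abs=p.dt / 2)
        assert m.t50 == pytest.approx(30 * math.log(2), abs=p.dt / 2)
        assert m.t90 == pytest.approx(30 * math.log(10), abs=p.dt / 2)
        assert not (m.t25_censored or m.t50_censored or m.t90_censored)

    def test_truncated_record_censors_t90(self, default_config):
        p = simulate.TraceParams(t_app=10.0, latency=5.0, rise_slope=100.0,
                                 rise_duration=5.0, decay_tau=30.0,
                                 duration=30.0, dt=0.5)  # ends 10 s after peak
        m = analyze_transient(simulate.simulate_trace(p), default_config)
        assert m.t90_censored
        assert m.t90 == pytest.approx(10.0, abs=p.dt)
        assert not m.t25_censored  # 30·ln(4/3) ≈ 8.6 s < 10 s

    def test_nonpositive_amplitude_rejected(self, constant_trace):
        with pytest.raises(ValueError, match="amplitude"):
            clearance_times(constant_trace, (100.0, 0.0), 0.0, 10)

    def test_noisy_t50_recovery(self, canonical_params, default_config):
        errs = []
        for seed in range(200):
            p = dataclasses.replace(canonical_params,
                                    noise_sd=0.01 * canonical_params.amplitude,
                                    seed=seed)
            m = analyze_transient(simulate.simulate_trace(p), default_config)
            errs.append(abs(m.t50 - 60 * math.log(2)))
        # first-crossing detection is biased slightly early under noise
        assert np.median(errs) <= 4 * canonical_params.dt
        assert np.mean(errs) / (60 * math.log(2)) <= 0.10


class TestAnalyzeTransient:
    def test_canonical_metrics_within_one_sample(self, canonical_params,
                                                 default_config):
        tau, dt = 60.0, canonical_params.dt
        m = analyze_transient(simulate.simulate_trace(canonical_params),
                              default_config)
        assert m.response_time == pytest.approx(14.0, abs=dt)
        assert m.time_to_peak == pytest.approx(10.0, abs=dt)
        assert m.amplitude == pytest.approx(2450.0, abs=1e-9)
        assert m.max_rate == pytest.approx(245.0, rel=1e-9)
        assert m.t25 == pytest.approx(tau * math.log(4 / 3), abs=dt)
        assert m.t50 == pytest.approx(tau * math.log(2), abs=dt)
        assert m.t90 == pytest.approx(tau * math.log(10), abs=dt)

    def test_constant_trace_fully_flagged(self, constant_trace, default_config):
        m = analyze_transient(constant_trace, default_config)
        assert m.no_response
        assert math.isnan(m.amplitude) and math.isnan(m.response_time)

    def test_batch_preserves_order(self, default_config):
        params = [dataclasses.replace(simulate.TraceParams(), noise_sd=5.0,
                                      seed=s) for s in range(40)]
        traces = [simulate.simulate_trace(p) for p in params]
        df = analyze_batch(traces, default_config,
                           trace_ids=[f"tr{s}" for s in range(40)],
                           groups=["g"] * 40)
        assert list(df.trace_id) == [f"tr{s}" for s in range(40)]
        assert len(df) == 40 and df.amplitude.notna().all()


class TestInvariances:
    @given(c=st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=20, deadline=None)
    def test_intensity_scaling(self, c):
        p = simulate.TraceParams()
        tr = simulate.simulate_trace(p)
        scaled = FluorescenceTrace(time=tr.time, fluorescence=c * tr.fluorescence,
                                   t_app=tr.t_app)
        cfg = KineticsConfig(onset_abs_floor=1e-9)
        m0 = analyze_transient(tr, cfg)
        m1 = analyze_transient(scaled, cfg)
        assert m1.amplitude == pytest.approx(c * m0.amplitude, rel=1e-9)
        assert m1.max_rate == pytest.approx(c * m0.max_rate, rel=1e-9)
        for name in ("response_time", "time_to_peak", "t25", "t50", "t90"):
            assert getattr(m1, name) == pytest.approx(getattr(m0, name), rel=1e-9)

    # dyadic shifts keep t + Δ exactly representable, so sample/window
    # membership is bit-identical; arbitrary floats would perturb the
    # boundary comparisons by rounding
    @given(shift=st.integers(min_value=-80, max_value=400).map(lambda k: k / 4.0))
    @settings(max_examples=20, deadline=None)
    def test_time_shift(self, shift):
        p = simulate.TraceParams(noise_sd=8.0, seed=5)
        tr = simulate.simulate_trace(p)
        shifted = FluorescenceTrace(time=tr.time + shift,
                                    fluorescence=tr.fluorescence,
                                    t_app=tr.t_app + shift)
        m0 = analyze_transient(tr)
        m1 = analyze_transient(shifted)
        for name in ("response_time", "time_to_peak", "amplitude", "max_rate",
                     "t25", "t50", "t90"):
            assert getattr(m1, name) == pytest.approx(getattr(m0, name), rel=1e-6)

    @pytest.mark.parametrize("tau", [20.0, 40.0, 80.0, 160.0])
    def test_clearance_ordering_and_monotonicity_in_tau(self, tau, default_config):
        p = simulate.TraceParams(decay_tau=tau, duration=900.0)
        m = analyze_transient(simulate.simulate_trace(p), default_config)
        assert m.t25 <= m.t50 <= m.t90
        assert m.t50 == pytest.approx(tau * math.log(2), abs=p.dt)


class TestTraceValidation:
    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="20 samples"):
            FluorescenceTrace(np.arange(5.0), np.zeros(5), 1.0)

    def test_nonuniform_grid_rejected(self):
        t = np.arange(30.0)
        t[10] += 0.01
        with pytest.raises(ValueError, match="uniform"):
            FluorescenceTrace(t, np.zeros(30), 1.0)

    def test_t_app_outside_record_rejected(self):
        with pytest.raises(ValueError, match="t_app"):
            FluorescenceTrace(np.arange(30.0), np.zeros(30), 99.0)
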