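"""Spike features: LJP handling, threshold, half-width, amplitude stats."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_triangle_trace
from dendricap.core import Trace, ValidationError
from dendricap.spike_features import (
    SpikeConfig,
    detect_spikes,
    extract_features,
    first_n_spike_halfwidths,
    half_width,
    ljp_correct,
    spike_threshold,
    trace_amplitude_stats,
)
from dendricap.synthetic_data import SpikeShape, simulate_spike_trace


class TestLjpCorrection:
    def test_constant_trace_shifted_down(self):
        tr = Trace(samples=np.full(100, -40.0), dt=0.01, kind="voltage")
        out = ljp_correct(tr)
        assert np.allclose(out.samples, -50.0)

    def test_zero_ljp_is_identity(self):
        tr = Trace(samples=np.full(100, -40.0), dt=0.01, kind="voltage")
        out = ljp_correct(tr, SpikeConfig(ljp_mv=0.0))
        assert np.allclose(out.samples, tr.samples)

    def test_double_application_rejected(self):
        tr = Trace(samples=np.full(100, -40.0), dt=0.01, kind="voltage")
        once = ljp_correct(tr)
        with pytest.raises(ValidationError):
            ljp_correct(once)


class TestDetection:
    def test_planted_spike_count_and_times(self, nofilter_cfg):
        tr, truth = simulate_spike_trace(
            SpikeShape(), n_spikes=10, duration_ms=1000.0, rate_hz=20.0
        )
        windows = detect_spikes(tr, nofilter_cfg)
        assert len(windows) == 10
        for w, t_peak in zip(windows, truth["peak_times_ms"]):
            i = w.meta["i_peak"]
            assert w.t0 + i * w.dt == pytest.approx(t_peak, abs=w.dt)

    def test_flat_trace_yields_no_spikes(self, nofilter_cfg):
        tr = Trace(samples=np.full(10_000, -65.0), dt=0.01, kind="voltage")
        assert detect_spikes(tr, nofilter_cfg) == []

    def test_close_peaks_merged_by_refractory(self, nofilter_cfg):
        """Two planted spikes 1 ms apart with a 2 ms refractory: one window."""
        dt = 0.01
        n = int(round(20.0 / dt))
        v = np.full(n, -60.0)
        for t_on in (8.0, 9.0):
            i0 = int(t_on / dt)
            up = np.linspace(-60, 40, 21)
            v[i0 : i0 + 21] = np.maximum(v[i0 : i0 + 21], up)
            v[i0 + 21 : i0 + 41] = np.maximum(
                v[i0 + 21 : i0 + 41], np.linspace(40, -60, 20)
            )
        tr = Trace(samples=v, dt=dt, kind="voltage")
        assert len(detect_spikes(tr, nofilter_cfg)) == 1


class TestThreshold:
    def test_triangle_threshold_at_rise_onset(self, nofilter_cfg):
        tr = make_triangle_trace()
        w = detect_spikes(tr, nofilter_cfg)[0]
        t_thr, v_thr = spike_threshold(w, nofilter_cfg)
        assert v_thr == pytest.approx(-60.0, abs=1.1)  # within one sample step
        assert t_thr == pytest.approx(5.0, abs=2 * tr.dt)

    def test_sigmoid_upstroke_five_percent_point(self, nofilter_cfg):
        """For a logistic upstroke the 5% dV/dt point is analytic:
        s(1-s) = 0.05/4 on the rise gives the expected crossing time."""
        dt, k, t0, amp, base = 0.01, 5.0, 10.0, 100.0, -60.0
        t = np.arange(0, 20.0, dt)
        v = base + amp / (1.0 + np.exp(-k * (t - t0)))
        s = (1.0 - np.sqrt(1.0 - 0.05)) / 2.0  # small root of s(1-s)=0.0125
        t_expected = t0 + np.log(s / (1.0 - s)) / k
        tr = Trace(samples=v, dt=dt, kind="voltage")
        tr.meta["i_peak"] = int(np.argmax(v))
        t_thr, _ = spike_threshold(tr, nofilter_cfg)
        assert t_thr == pytest.approx(t_expected, abs=1.5 * dt)

    def test_monotone_decreasing_window_rejected(self, nofilter_cfg):
        v = np.linspace(0.0, -50.0, 200)
        tr = Trace(samples=v, dt=0.01, kind="voltage")
        tr.meta["i_peak"] = 1
        with pytest.raises(ValidationError):
            spike_threshold(tr, nofilter_cfg)


class TestHalfWidth:
    @pytest.mark.parametrize(
        "rise,fall,expected",
        [(1.0, 1.0, 1.0), (1.0, 3.0, 2.0), (0.5, 0.5, 0.5)],
    )
    def test_triangle_geometry(self, nofilter_cfg, rise, fall, expected):
        tr = make_triangle_trace(rise_ms=rise, fall_ms=fall, pad_ms=5.0)
        w = detect_spikes(tr, nofilter_cfg)[0]
        assert half_width(w, nofilter_cfg) == pytest.approx(expected, abs=1e-9)

    def test_translation_invariance(self, nofilter_cfg):
        base = make_triangle_trace()
        shifted = base.with_samples(base.samples - 10.0)
        hw0 = half_width(detect_spikes(base, nofilter_cfg)[0], nofilter_cfg)
        hw1 = half_width(detect_spikes(shifted, nofilter_cfg)[0], nofilter_cfg)
        assert hw1 == pytest.approx(hw0, abs=1e-9)

    def test_resampling_changes_half_width_less_than_one_sample(self, nofilter_cfg):
        coarse = make_triangle_trace(dt=0.02)
        fine = make_triangle_trace(dt=0.01)
        hw_c = half_width(detect_spikes(coarse, nofilter_cfg)[0], nofilter_cfg)
        hw_f = half_width(detect_spikes(fine, nofilter_cfg)[0], nofilter_cfg)
        assert abs(hw_c - hw_f) < 0.02

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(offset=st.floats(-30.0, 30.0))
    def test_offset_never_changes_amplitude_or_width(self, offset):
        cfg = SpikeConfig(filter_cutoff_khz=None)
        tr, truth = simulate_spike_trace(
            SpikeShape(), n_spikes=3, duration_ms=300.0, rate_hz=15.0
        )
        shifted = tr.with_samples(tr.samples + offset)
        f0 = extract_features(tr, cfg)
        f1 = extract_features(shifted, cfg)
        for a, b in zip(f0, f1):
            assert b.amplitude == pytest.approx(a.amplitude, abs=1e-9)
            assert b.half_width == pytest.approx(a.half_width, abs=1e-9)
            assert b.v_threshold == pytest.approx(a.v_threshold + offset, abs=1e-9)


class TestAmplitudeStats:
    def test_planted_amplitude_recovered_exactly(self, nofilter_cfg):
        shape = SpikeShape(v_baseline=-60.0, v_peak=10.0, v_antipeak=-60.0)
        tr, truth = simulate_spike_trace(
            shape, n_spikes=10, duration_ms=1000.0, rate_hz=20.0
        )
        mean_amp, amps = trace_amplitude_stats(tr, nofilter_cfg, duration_ms=1000.0)
        assert len(amps) == 10
        assert mean_amp == pytest.approx(70.0, abs=1e-9)

    def test_single_spike_mean_is_that_spike(self, nofilter_cfg):
        tr, truth = simulate_spike_trace(
            SpikeShape(), n_spikes=1, duration_ms=200.0, rate_hz=10.0
        )
        mean_amp, amps = trace_amplitude_stats(tr, nofilter_cfg, duration_ms=200.0)
        assert len(amps) == 1
        assert mean_amp == amps[0]

    def test_no_spikes_flagged_missing(self, nofilter_cfg):
        tr = Trace(samples=np.full(20_000, -65.0), dt=0.01, kind="voltage")
        mean_amp, amps = trace_amplitude_stats(tr, nofilter_cfg, duration_ms=200.0)
        assert np.isnan(mean_amp) and amps == []

    def test_short_trace_rejected(self, nofilter_cfg):
        tr = Trace(samples=np.full(100, -65.0), dt=0.01, kind="voltage")
        with pytest.raises(ValidationError):
            trace_amplitude_stats(tr, nofilter_cfg, duration_ms=10_000.0)


class TestFirstNHalfwidths:
    def test_mean_of_first_five(self, nofilter_cfg):
        tr, truth = simulate_spike_trace(
            SpikeShape(), n_spikes=7, duration_ms=700.0, rate_hz=15.0
        )
        got = first_n_spike_halfwidths(tr, nofilter_cfg, n=5)
        assert got == pytest.approx(truth["half_width_ms"], abs=1e-6)

    def test_too_few_spikes_flagged_missing(self, nofilter_cfg):
        tr, _ = simulate_spike_trace(
            SpikeShape(), n_spikes=3, duration_ms=300.0, rate_hz=15.0
        )
        assert np.isnan(first_n_spike_halfwidths(tr, nofilter_cfg, n=5))
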