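"""Spike-feature extraction from current-clamp voltage traces.

Feature definitions:

* threshold — the earliest point on the upstroke where dV/dt reaches 5%
  of its maximum within the spike window;
* amplitude — peak minus anti-peak membrane potential, where the
  anti-peak is the minimum between a spike's peak and the following
  spike's threshold (or the end of the analysis window);
* half-width — the time the voltage spends above the level halfway
  between threshold and peak, with linear interpolation between samples.

Recorded voltages are corrected for a +10 mV liquid junction potential
by subtracting 10 mV (the true membrane potential is more negative than
the pipette reading for a K-gluconate internal); the correction is
guarded by a metadata flag so it cannot be applied twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core import VOLTAGE, Trace, ValidationError, lowpass


@dataclass
class SpikeConfig:
    """Tunable constants of the feature extractors.

    dvdt_threshold_fraction : fraction of max dV/dt defining threshold
    ljp_mv : liquid junction potential magnitude subtracted from voltages
    min_peak_prominence : mV, peak prominence for spike detection
    refractory_ms : minimum peak separation; closer peaks are merged
    filter_cutoff_khz : low-pass cutoff applied before detection (None = off)
    """

    dvdt_threshold_fraction: float = 0.05
    ljp_mv: float = 10.0
    min_peak_prominence: float = 20.0
    refractory_ms: float = 2.0
    filter_cutoff_khz: float | None = 5.0

    def __post_init__(self):
        if not 0 < self.dvdt_threshold_fraction < 1:
            raise ValidationError("dvdt_threshold_fraction must be in (0, 1)")


@dataclass
class SpikeFeature:
    """Per-spike measurements (all voltages in mV, times in ms)."""

    t_peak: float
    v_peak: float
    v_antipeak: float
    v_threshold: float
    t_threshold: float
    amplitude: float
    half_width: float


def ljp_correct(trace: Trace, cfg: SpikeConfig | None = None) -> Trace:
    """Subtract the liquid junction potential from a voltage trace.

    Raises if the trace is already corrected (idempotence guard).
    """
    cfg = cfg or SpikeConfig()
    if trace.kind != VOLTAGE:
        raise ValidationError("LJP correction applies to voltage traces")
    if trace.meta.get("ljp_corrected"):
        raise ValidationError("trace is already LJP-corrected")
    return trace.with_samples(trace.samples - cfg.ljp_mv, ljp_corrected=True)


def _prepared(trace: Trace, cfg: SpikeConfig) -> Trace:
    if trace.kind != VOLTAGE:
        raise ValidationError("spike analysis requires a voltage trace")
    if "filtered_khz" in trace.meta:
        return trace
    return lowpass(trace, cfg.filter_cutoff_khz)


def detect_spikes(trace: Trace, cfg: SpikeConfig | None = None) -> list[Trace]:
    """Split a voltage trace into non-overlapping single-spike windows.

    Each window contains exactly one peak of prominence >=
    ``min_peak_prominence``; peaks closer than ``refractory_ms`` are
    merged by the underlying peak picker (the larger peak wins).  Window
    boundaries are the midpoints between adjacent peaks.  Returns an
    empty list for a spike-free trace.
    """
    cfg = cfg or SpikeConfig()
    prepared = _prepared(trace, cfg)
    distance = max(1, int(round(cfg.refractory_ms / prepared.dt)))
    peaks, _ = find_peaks(
        prepared.samples, prominence=cfg.min_peak_prominence, distance=distance
    )
    if peaks.size == 0:
        return []
    bounds = [0]
    for a, b in zip(peaks[:-1], peaks[1:]):
        bounds.append(int((a + b) // 2))
    bounds.append(prepared.n - 1)
    windows = []
    for k, pk in enumerate(peaks):
        i0, i1 = bounds[k], bounds[k + 1]
        w = prepared.slice(
            prepared.t0 + i0 * prepared.dt, prepared.t0 + i1 * prepared.dt
        )
        w.meta["i_peak"] = int(pk - i0)
        windows.append(w)
    return windows


def spike_threshold(
    window: Trace, cfg: SpikeConfig | None = None
) -> tuple[float, float]:
    """Locate the spike threshold within a single-spike window.

    Returns ``(t_threshold, v_threshold)`` — the earliest sample before
    the peak at which dV/dt (central differences) reaches
    ``dvdt_threshold_fraction`` of its maximum.  Raises if the window has
    no upstroke (max dV/dt <= 0).
    """
    cfg = cfg or SpikeConfig()
    v = window.samples
    i_peak = window.meta.get("i_peak", int(np.argmax(v)))
    dvdt = np.gradient(v, window.dt)
    if i_peak < 1:
        raise ValidationError("window peak is at its first sample; no upstroke")
    max_dvdt = float(dvdt[: i_peak + 1].max())
    if max_dvdt <= 0:
        raise ValidationError("no upstroke in window (max dV/dt <= 0)")
    level = cfg.dvdt_threshold_fraction * max_dvdt
    above = np.nonzero(dvdt[: i_peak + 1] >= level)[0]
    i_thr = int(above[0])
    return window.t0 + i_thr * window.dt, float(v[i_thr])


def _interp_crossing(t0: float, t1: float, v0: float, v1: float, level: float) -> float:
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def half_width(window: Trace, cfg: SpikeConfig | None = None) -> float:
    """Spike width at half the threshold-to-peak distance, in ms.

    Crossing times are linearly interpolated between samples.  Returns
    NaN if the voltage never falls back through the half level before
    the window ends (flagged missing).
    """
    cfg = cfg or SpikeConfig()
    t_thr, v_thr = spike_threshold(window, cfg)
    v = window.samples
    i_peak = window.meta.get("i_peak", int(np.argmax(v)))
    v_peak = float(v[i_peak])
    v_half = 0.5 * (v_thr + v_peak)
    times = window.times
    i_up = None
    for i in range(i_peak, 0, -1):  # walk back from the peak to the rise crossing
        if v[i - 1] < v_half <= v[i]:
            i_up = i
            break
    if i_up is None:
        return float("nan")
    t_up = _interp_crossing(times[i_up - 1], times[i_up], v[i_up - 1], v[i_up], v_half)
    for j in range(i_peak, window.n - 1):
        if v[j] >= v_half > v[j + 1]:
            t_down = _interp_crossing(
                times[j], times[j + 1], v[j], v[j + 1], v_half
            )
            return t_down - t_up
    return float("nan")


def _spike_features(
    windows: list[Trace], trace_end_ms: float, cfg: SpikeConfig
) -> list[SpikeFeature]:
    feats = []
    thresholds = []
    for w in windows:
        t_thr, v_thr = spike_threshold(w, cfg)
        thresholds.append((t_thr, v_thr))
    for k, w in enumerate(windows):
        i_peak = w.meta.get("i_peak", int(np.argmax(w.samples)))
        t_peak = w.t0 + i_peak * w.dt
        v_peak = float(w.samples[i_peak])
        t_thr, v_thr = thresholds[k]
        # anti-peak: minimum between this peak and the next spike's threshold
        t_stop = thresholds[k + 1][0] if k + 1 < len(windows) else trace_end_ms
        seg = w.samples[i_peak:]
        seg_times = w.times[i_peak:]
        mask = seg_times <= t_stop
        v_anti = float(seg[mask].min()) if mask.any() else float(seg.min())
        feats.append(
            SpikeFeature(
                t_peak=t_peak,
                v_peak=v_peak,
                v_antipeak=v_anti,
                v_threshold=v_thr,
                t_threshold=t_thr,
                amplitude=v_peak - v_anti,
                half_width=half_width(w, cfg),
            )
        )
    return feats


def extract_features(trace: Trace, cfg: SpikeConfig | None = None) -> list[SpikeFeature]:
    """Full per-spike feature table for a voltage trace."""
    cfg = cfg or SpikeConfig()
    windows = detect_spikes(trace, cfg)
    return _spike_features(windows, trace.t0 + trace.duration, cfg)


def trace_amplitude_stats(
    trace: Trace, cfg: SpikeConfig | None = None, duration_ms: float = 10_000.0
) -> tuple[float, list[float]]:
    """Mean peak-to-anti-peak amplitude over the first ``duration_ms``.

    The trace must span at least ``duration_ms``.  Returns
    ``(mean_amplitude, per_spike_amplitudes)``; the mean is NaN when the
    trace contains no spikes (flagged missing).
    """
    cfg = cfg or SpikeConfig()
    if trace.duration + 1e-9 < duration_ms:
        raise ValidationError(
            f"trace spans {trace.duration:.1f} ms, shorter than {duration_ms} ms"
        )
    region = trace.slice(trace.t0, trace.t0 + duration_ms)
    feats = extract_features(region, cfg)
    amps = [f.amplitude for f in feats]
    if not amps:
        return float("nan"), []
    return float(np.mean(amps)), amps


def first_n_spike_halfwidths(
    trace: Trace, cfg: SpikeConfig | None = None, n: int = 5
) -> float:
    """Mean half-width of the first ``n`` consecutive spikes, NaN if fewer."""
    cfg = cfg or SpikeConfig()
    windows = detect_spikes(trace, cfg)
    if len(windows) < n:
        return float("nan")
    widths = [half_width(w, cfg) for w in windows[:n]]
    return float(np.mean(widths))
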