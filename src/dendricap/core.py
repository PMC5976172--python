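"""Core containers for sampled electrophysiology traces.

Internal unit convention: time in ms, voltage in mV, current in pA.
Products of these come out in pF (capacitance, ms*pA/mV) and GOhm
(resistance, mV/pA); the reporting layer rescales resistances to MOhm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

VOLTAGE = "voltage"
CURRENT = "current"

#: canonical unit for each signal kind
UNIT_FOR_KIND = {VOLTAGE: "mV", CURRENT: "pA"}

MOHM_PER_GOHM = 1000.0


class ValidationError(ValueError):
    """An input object violates one of its declared invariants."""


@dataclass
class Trace:
    """A uniformly sampled time series (one sweep of one signal).

    Parameters
    ----------
    samples : array-like
        Sample values in ``units``.
    dt : float
        Sampling interval in ms (100 kHz acquisition -> dt = 0.01 ms).
    kind : str
        ``"voltage"`` or ``"current"``.
    units : str, optional
        Defaults to the canonical unit for ``kind`` (mV or pA).
    t0 : float
        Time of the first sample relative to protocol start, ms.
    meta : dict
        Free-form provenance flags (e.g. ``ljp_corrected``, ``filtered_khz``).
    """

    samples: np.ndarray
    dt: float
    kind: str = VOLTAGE
    units: str | None = None
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValidationError("samples must be a non-empty 1-D array")
        if not self.dt > 0:
            raise ValidationError(f"dt must be > 0, got {self.dt}")
        if self.kind not in UNIT_FOR_KIND:
            raise ValidationError(f"kind must be one of {sorted(UNIT_FOR_KIND)}")
        if self.units is None:
            self.units = UNIT_FOR_KIND[self.kind]
        elif self.units != UNIT_FOR_KIND[self.kind]:
            raise ValidationError(
                f"units {self.units!r} inconsistent with kind {self.kind!r}"
            )

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace duration in ms."""
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms, relative to protocol start."""
        return self.t0 + np.arange(self.n) * self.dt

    def index_at(self, t: float) -> int:
        """Index of the sample closest to time ``t`` (ms), clipped in range."""
        i = int(round((t - self.t0) / self.dt))
        return min(max(i, 0), self.n - 1)

    def slice(self, t_start: float, t_stop: float) -> "Trace":
        """Sub-trace covering [t_start, t_stop) ms; t0 is adjusted."""
        i0 = self.index_at(t_start)
        i1 = max(self.index_at(t_stop), i0 + 1)
        return replace(
            self,
            samples=self.samples[i0 : i1 + 1].copy(),
            t0=self.t0 + i0 * self.dt,
            meta=dict(self.meta),
        )

    def with_samples(self, samples: np.ndarray, **meta) -> "Trace":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return replace(self, samples=np.asarray(samples, dtype=float), meta=new_meta)


@dataclass
class VoltageStepProtocol:
    """A single voltage-clamp step.

    Defaults follow a standard capacitance protocol: a 1 s step from a
    holding potential of -80 mV to -90 mV.
    """

    v_hold: float = -80.0
    v_step: float = -90.0
    step_onset: float = 10.0
    step_duration: float = 1000.0

    def __post_init__(self):
        if self.delta_v == 0:
            raise ValidationError("delta_v must be non-zero (v_step != v_hold)")
        if not self.step_duration > 0:
            raise ValidationError("step_duration must be > 0")

    @property
    def delta_v(self) -> float:
        """Step amplitude v_step - v_hold, in mV."""
        return self.v_step - self.v_hold

    @property
    def step_end(self) -> float:
        return self.step_onset + self.step_duration


@dataclass
class SweepSet:
    """Repeated sweeps of a single protocol (congruent traces)."""

    sweeps: list
    protocol: VoltageStepProtocol

    def __post_init__(self):
        if not self.sweeps:
            raise ValidationError("SweepSet requires at least one sweep")
        first = self.sweeps[0]
        for s in self.sweeps[1:]:
            if s.n != first.n or s.dt != first.dt or s.kind != first.kind:
                raise ValidationError("sweeps are incongruent (dt, length or kind)")

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)

    @property
    def dt(self) -> float:
        return self.sweeps[0].dt


def lowpass(trace: Trace, cutoff_khz: float | None) -> Trace:
    """Zero-phase 4th-order Butterworth low-pass filter.

    ``cutoff_khz=None`` disables filtering.  If the cutoff is at or above
    the Nyquist frequency the trace is returned unchanged (nothing to
    remove), with the effective cutoff recorded in ``meta``.
    """
    if cutoff_khz is None:
        return trace
    nyquist_khz = 0.5 / trace.dt  # dt in ms -> fs in kHz
    if cutoff_khz >= 0.99 * nyquist_khz:
        return trace.with_samples(trace.samples, filtered_khz=nyquist_khz)
    b, a = _signal.butter(4, cutoff_khz / nyquist_khz)
    filtered = _signal.filtfilt(b, a, trace.samples)
    return trace.with_samples(filtered, filtered_khz=cutoff_khz)
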