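"""Two-compartment capacitance decomposition of voltage-clamp transients.

A Purkinje neuron under somatic voltage clamp behaves, to first order,
as a two-compartment equivalent circuit: a somatic/proximal compartment
(capacitance C1, charged through the access + somatic resistance R1) and
a distal dendritic compartment (capacitance C2, coupled through the
intermediate dendritic resistance R2).  The capacitative current after a
voltage step dV then decays as the sum of two exponentials,

    I(t) = A1 * exp(-t / tau1) + A2 * exp(-t / tau2),

and the circuit quantities follow algebraically from the fitted
coefficients:

    C1 = tau1 * (A1 + A2)**2 / (A1 * dV)
    C2 = A2 * tau2 / dV
    R1 = dV / (A1 + A2)
    R2 = dV / A2 - dV / (A1 + A2)

With currents in pA, times in ms and voltages in mV these come out in
pF and GOhm; resistances are reported in MOhm.

The preprocessing chain mirrors standard practice: average ten sweeps,
zero-phase low-pass filter at 5 kHz, subtract the steady-state leak so
the corrected transient decays to zero, and exclude cells whose input
resistance is below 100 MOhm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core import (
    CURRENT,
    MOHM_PER_GOHM,
    SweepSet,
    Trace,
    ValidationError,
    VoltageStepProtocol,
    lowpass,
)

#: cells with input resistance below this are excluded from capacitance QC
RIN_QC_MOHM = 100.0

#: steady-state leak is estimated over this much of the end of the step (ms)
LEAK_WINDOW_MS = 100.0

#: fitted baseline offset is constrained to this fraction of the peak current
BASELINE_FRACTION = 0.05


@dataclass
class BiexpFit:
    """Coefficients of the two-exponential transient decay.

    Components are ordered fast-first (``tau1 < tau2``); amplitudes carry
    the sign of the capacitative transient (negative for a hyperpolarizing
    step).  ``baseline`` absorbs residual leak-correction error and is
    constrained near zero.
    """

    a1: float
    tau1: float
    a2: float
    tau2: float
    baseline: float = 0.0
    rss: float = 0.0
    converged: bool = True

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Model current at times ``t`` (ms since step onset), in pA."""
        t = np.asarray(t, dtype=float)
        return (
            self.a1 * np.exp(-t / self.tau1)
            + self.a2 * np.exp(-t / self.tau2)
            + self.baseline
        )


@dataclass
class CompartmentParams:
    """Two-compartment circuit quantities derived from a BiexpFit.

    ``c1``/``c2`` in pF, ``r1``/``r2`` in MOhm, ``delta_v`` in mV.
    ``r2`` is None for a single-compartment cell (a2 == 0).
    """

    c1: float
    c2: float
    r1: float
    r2: float | None
    delta_v: float
    single_compartment: bool = False


def average_sweeps(sweeps: SweepSet) -> Trace:
    """Pointwise mean of all sweeps in the set."""
    stack = np.stack([s.samples for s in sweeps.sweeps])
    first = sweeps.sweeps[0]
    return first.with_samples(stack.mean(axis=0), n_averaged=sweeps.n_sweeps)


def leak_correct(trace: Trace, protocol: VoltageStepProtocol) -> Trace:
    """Subtract the steady-state leak current so the transient decays to 0.

    The steady state is estimated as the mean current over the final
    ``LEAK_WINDOW_MS`` of the step (or the final 20% for short steps),
    which for a settled cell equals delta_v / R_input.
    """
    win = min(LEAK_WINDOW_MS, 0.2 * protocol.step_duration)
    tail = trace.slice(protocol.step_end - win, protocol.step_end)
    leak = float(tail.samples.mean())
    return trace.with_samples(trace.samples - leak, leak_pa=leak)


def preprocess_transient(
    sweeps: SweepSet,
    r_input: float,
    filter_cutoff_khz: float | None = 5.0,
) -> Trace:
    """Average, low-pass filter and leak-correct a capacitance sweep set.

    Parameters
    ----------
    sweeps : SweepSet
        Repeated voltage-step sweeps (current traces).
    r_input : float
        Measured input resistance in MOhm; must be positive.  Recorded in
        the output metadata and used by :func:`qc_cell`.
    filter_cutoff_khz : float or None
        Low-pass cutoff (zero-phase Butterworth); None disables.

    Returns
    -------
    Trace
        The corrected mean current, decaying toward zero during the step.
    """
    if not r_input > 0:
        raise ValidationError(f"r_input must be > 0 MOhm, got {r_input}")
    if sweeps.sweeps[0].kind != CURRENT:
        raise ValidationError("capacitance sweeps must be current traces")
    mean = average_sweeps(sweeps)
    filtered = lowpass(mean, filter_cutoff_khz)
    corrected = leak_correct(filtered, sweeps.protocol)
    corrected.meta["r_input_mohm"] = r_input
    return corrected


def _model(t, a1, tau1, a2, tau2, c):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + c


def _peel_off_init(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Seed (a1, tau1, a2, tau2) by fitting the slow tail first.

    ``y`` is sign-flipped to be positive.  Falls back to crude heuristics
    if either log-linear fit is degenerate.
    """
    span = t[-1] - t[0]
    tail = t >= t[0] + 0.4 * span
    eps = max(1e-12, 1e-6 * float(y.max()))
    yt = np.clip(y[tail], eps, None)
    slope, intercept = np.polyfit(t[tail], np.log(yt), 1)
    tau2 = -1.0 / slope if slope < 0 else span
    tau2 = float(np.clip(tau2, 1e-3, 100 * span))
    a2 = float(np.exp(intercept))
    resid = y - a2 * np.exp(-t / tau2)
    head = t <= t[0] + 0.1 * span
    pos = head & (resid > eps)
    if pos.sum() >= 3:
        slope1, intercept1 = np.polyfit(t[pos], np.log(resid[pos]), 1)
        tau1 = -1.0 / slope1 if slope1 < 0 else tau2 / 20.0
        a1 = float(np.exp(intercept1))
    else:
        tau1 = tau2 / 20.0
        a1 = max(float(y[0] - a2), eps)
    tau1 = float(np.clip(tau1, 1e-4, tau2))
    return a1, tau1, a2, tau2


def fit_biexponential(
    transient: Trace,
    protocol: VoltageStepProtocol,
    fit_window: tuple[float, float] | None = None,
    max_points: int | None = 20000,
) -> BiexpFit:
    """Least-squares fit of the two-exponential decay to a corrected transient.

    Time in the model is measured from the step onset, so the fitted
    amplitudes refer to t = 0 at the onset regardless of where the fit
    window starts.  The window defaults to (sample after the post-step
    peak of \\|I\\|, end of step), excluding the rise that is shaped by the
    amplifier and the anti-alias filter.

    Long windows are uniformly strided down to at most ``max_points``
    samples before fitting; a 1 s step at 100 kHz is heavily oversampled
    relative to the slow time constant, so this changes the estimates
    negligibly while keeping the fit fast.

    Non-convergence is reported through ``converged=False``, never
    silently.  A window shorter than 10 samples is an error.
    """
    if fit_window is None:
        search = transient.slice(protocol.step_onset, min(protocol.step_end, protocol.step_onset + 10.0))
        i_peak = int(np.argmax(np.abs(search.samples)))
        # guard interval: the zero-phase filter's edge response rings for
        # several filter time constants past the onset; fitting starts
        # after it has settled (5/f_c = 1 ms at a 5 kHz cutoff)
        fc = transient.meta.get("filtered_khz")
        guard = 5.0 / fc if fc else 0.0
        t_start = search.t0 + (i_peak + 1) * transient.dt + guard
        fit_window = (t_start, protocol.step_end)
    t_lo, t_hi = fit_window
    if not (protocol.step_onset <= t_lo < t_hi <= protocol.step_end + transient.dt):
        raise ValidationError("fit_window must lie within the voltage step")
    window = transient.slice(t_lo, t_hi)
    if window.n < 10:
        raise ValidationError(f"fit window has {window.n} samples; need >= 10")

    t = window.times - protocol.step_onset
    y_raw = window.samples
    if max_points and window.n > max_points:
        stride = int(np.ceil(window.n / max_points))
        t, y_raw = t[::stride], y_raw[::stride]
    sign = -1.0 if y_raw[: max(1, window.n // 20)].mean() < 0 else 1.0
    y = sign * y_raw

    a1_0, tau1_0, a2_0, tau2_0 = _peel_off_init(t, y)
    peak = float(np.abs(y).max())
    c_bound = max(BASELINE_FRACTION * peak, 1e-9)
    lower = [0.0, 1e-5, 0.0, 1e-5, -c_bound]
    upper = [np.inf, np.inf, np.inf, np.inf, c_bound]
    p0 = [
        min(max(a1_0, 1e-9), 1e9),
        tau1_0,
        min(max(a2_0, 1e-9), 1e9),
        tau2_0,
        0.0,
    ]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _model, t, y, p0=p0, bounds=(lower, upper), maxfev=20000
            )
        converged = bool(np.all(np.isfinite(popt)))
    except (RuntimeError, ValueError):
        popt = p0
        converged = False
    a1, tau1, a2, tau2, c = popt
    if tau1 > tau2:  # enforce fast-component-first ordering
        a1, tau1, a2, tau2 = a2, tau2, a1, tau1
    rss = float(np.sum((_model(t, a1, tau1, a2, tau2, c) - y) ** 2))
    if converged and tau2 > 0 and abs(tau2 - tau1) < 1e-6 * tau2:
        converged = False  # ill-conditioned: the two time constants collapsed
    return BiexpFit(
        a1=sign * a1,
        tau1=float(tau1),
        a2=sign * a2,
        tau2=float(tau2),
        baseline=sign * c,
        rss=rss,
        converged=converged,
    )


def derive_compartments(
    fit: BiexpFit, protocol: VoltageStepProtocol
) -> CompartmentParams:
    """Map biexponential coefficients to the circuit quantities.

    Requires a converged fit with a1 + a2 != 0.  A vanishing slow
    amplitude (a2 == 0) denotes a single-compartment cell: C2 = 0 and R2
    is undefined (None).
    """
    if not fit.converged:
        raise ValidationError("cannot derive compartments from a non-converged fit")
    dv = protocol.delta_v
    a1, a2 = fit.a1, fit.a2
    if a1 + a2 == 0:
        raise ValidationError("a1 + a2 must be non-zero")
    if a1 == 0:
        raise ValidationError("a1 must be non-zero (no fast component)")
    c1 = fit.tau1 * (a1 + a2) ** 2 / (a1 * dv)  # pF
    r1_gohm = dv / (a1 + a2)
    if a2 == 0:
        return CompartmentParams(
            c1=float(c1),
            c2=0.0,
            r1=float(r1_gohm * MOHM_PER_GOHM),
            r2=None,
            delta_v=dv,
            single_compartment=True,
        )
    c2 = a2 * fit.tau2 / dv  # pF
    r2_gohm = dv / a2 - dv / (a1 + a2)
    return CompartmentParams(
        c1=float(c1),
        c2=float(c2),
        r1=float(r1_gohm * MOHM_PER_GOHM),
        r2=float(r2_gohm * MOHM_PER_GOHM),
        delta_v=dv,
    )


def compartments_to_biexponential(params: CompartmentParams) -> BiexpFit:
    """Algebraic inverse of :func:`derive_compartments`.

    Used by the simulator to obtain the transient coefficients of a known
    circuit; ``derive_compartments`` of the result reproduces the input
    exactly (up to round-off).
    """
    for name in ("c1", "c2", "r1", "r2"):
        v = getattr(params, name)
        if v is None or not v > 0:
            raise ValidationError(f"{name} must be strictly positive, got {v}")
    dv = params.delta_v
    r1 = params.r1 / MOHM_PER_GOHM  # GOhm
    r2 = params.r2 / MOHM_PER_GOHM
    a_tot = dv / r1
    a2 = dv / (r1 + r2)
    a1 = a_tot - a2
    tau2 = params.c2 * (r1 + r2)  # pF * GOhm = ms
    tau1 = params.c1 * a1 * dv / a_tot**2
    return BiexpFit(a1=float(a1), tau1=float(tau1), a2=float(a2), tau2=float(tau2))


def qc_cell(r_input: float) -> str:
    """Cell inclusion rule: exclude iff input resistance < 100 MOhm (strict)."""
    return "exclude" if r_input < RIN_QC_MOHM else "include"
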