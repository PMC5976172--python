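"""Synthetic-data generators with planted ground truth.

Every input the analysis pipeline consumes can be generated here from
explicit parameters and a seed, with the statistical structure the
analysis assumes:

* capacitative transients from a known two-compartment circuit plus
  additive i.i.d. Gaussian current noise;
* per-cell bAP datasets whose amplitude decays and half-width grows
  exponentially with distance;
* stereotyped spike trains with known peak/anti-peak/half-width;
* current-step families in which an all-or-none calcium spike (an
  alpha-function bump) appears above a planted threshold current;
* expression tables with a planted set of significant channel genes.

Generators are pure functions of (spec, seed): the same spec and seed
reproduce bit-identical output.  Traces default to a 100 kHz sampling
rate, matching typical high-bandwidth patch-clamp acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attenuation import AttenuationDataset
from .calcium_spike import CurrentStepFamily
from .capacitance import CompartmentParams, compartments_to_biexponential
from .channel_expression import GeneTable
from .core import CURRENT, VOLTAGE, SweepSet, Trace, ValidationError, VoltageStepProtocol

DEFAULT_RATE_KHZ = 100.0


def _check(cond: bool, name: str, msg: str):
    if not cond:
        raise ValidationError(f"{name}: {msg}")


# --------------------------------------------------------------------------
# capacitance sweeps
# --------------------------------------------------------------------------

@dataclass
class SimCircuitSpec:
    """Ground-truth two-compartment circuit for the capacitance simulator.

    Capacitances in pF, resistances in MOhm, noise in pA.  The default
    input resistance sits above the 100 MOhm QC bar so generated cells
    pass inclusion.
    """

    c1: float = 112.5
    c2: float = 500.0
    r1: float = 6.67
    r2: float = 13.33
    r_input: float = 150.0
    noise_sd: float = 5.0
    n_sweeps: int = 10
    seed: int = 0
    sample_rate_khz: float = DEFAULT_RATE_KHZ

    def __post_init__(self):
        _check(self.c1 > 0, "c1", "must be > 0 pF")
        _check(self.c2 > 0, "c2", "must be > 0 pF")
        _check(self.r1 > 0, "r1", "must be > 0 MOhm")
        _check(self.r2 > 0, "r2", "must be > 0 MOhm")
        _check(self.r_input > 0, "r_input", "must be > 0 MOhm")
        _check(self.noise_sd >= 0, "noise_sd", "must be >= 0 pA")
        _check(self.n_sweeps >= 1, "n_sweeps", "must be >= 1")
        _check(self.sample_rate_khz > 0, "sample_rate_khz", "must be > 0")

    def compartments(self, delta_v: float) -> CompartmentParams:
        return CompartmentParams(
            c1=self.c1, c2=self.c2, r1=self.r1, r2=self.r2, delta_v=delta_v
        )


def simulate_capacitance_sweeps(
    spec: SimCircuitSpec, protocol: VoltageStepProtocol | None = None
) -> SweepSet:
    """Noisy biexponential-plus-leak current sweeps for a known circuit.

    Each sweep is I(t) = A1 exp(-t/tau1) + A2 exp(-t/tau2) + dV/R_input
    during the step (t from step onset; coefficients from the algebraic
    inverse of the compartment equations) plus independent Gaussian noise
    of sd ``noise_sd``; zero before the step.
    """
    protocol = protocol or VoltageStepProtocol()
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.sample_rate_khz
    n = int(round((protocol.step_onset + protocol.step_duration) / dt))
    t = np.arange(n) * dt
    in_step = t >= protocol.step_onset
    fit = compartments_to_biexponential(spec.compartments(protocol.delta_v))
    leak_pa = protocol.delta_v / (spec.r_input / 1000.0)  # mV / GOhm = pA
    clean = np.zeros(n)
    ts = t[in_step] - protocol.step_onset
    clean[in_step] = fit.evaluate(ts) + leak_pa
    sweeps = []
    for _ in range(spec.n_sweeps):
        noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else 0.0
        sweeps.append(
            Trace(samples=clean + noise, dt=dt, kind=CURRENT, meta={"synthetic": True})
        )
    return SweepSet(sweeps=sweeps, protocol=protocol)


# --------------------------------------------------------------------------
# bAP attenuation datasets
# --------------------------------------------------------------------------

@dataclass
class SimBapSpec:
    """Planted exponential attenuation of bAP amplitude and half-width.

    ``a0`` mV and ``hw0`` ms are the somatic values; ``b_amp`` and
    ``b_hw`` the per-um decay/growth rates.  One cell per distance.
    """

    a0: float = 75.0
    b_amp: float = 0.0376
    hw0: float = 0.35
    b_hw: float = 0.004
    distances: tuple = tuple(float(x) for x in range(10, 130, 10))
    noise_sd_amp: float = 2.0
    noise_sd_hw: float = 0.02
    seed: int = 0

    def __post_init__(self):
        _check(self.a0 > 0, "a0", "must be > 0 mV")
        _check(self.b_amp >= 0, "b_amp", "must be >= 0 per um")
        _check(self.hw0 > 0, "hw0", "must be > 0 ms")
        _check(self.b_hw >= 0, "b_hw", "must be >= 0 per um")
        _check(all(d >= 0 for d in self.distances), "distances", "must be >= 0 um")
        _check(len(set(self.distances)) >= 2, "distances",
               "need >= 2 distinct distances (fit would be undetermined)")


def simulate_bap_dataset(spec: SimBapSpec, group: str = "group") -> AttenuationDataset:
    """One (distance, amplitude, half-width) record per simulated cell.

    amplitude = a0 exp(-b_amp x) + noise, clipped below at 0;
    half_width = hw0 exp(b_hw x) + noise, clipped below at a tiny
    positive floor so downstream log-initialized fits stay defined.
    """
    rng = np.random.default_rng(spec.seed)
    x = np.asarray(spec.distances, dtype=float)
    amp = spec.a0 * np.exp(-spec.b_amp * x)
    hw = spec.hw0 * np.exp(spec.b_hw * x)
    if spec.noise_sd_amp > 0:
        amp = amp + rng.normal(0.0, spec.noise_sd_amp, size=x.size)
    if spec.noise_sd_hw > 0:
        hw = hw + rng.normal(0.0, spec.noise_sd_hw, size=x.size)
    amp = np.clip(amp, 0.0, None)
    hw = np.clip(hw, 1e-6, None)
    df = pd.DataFrame(
        {
            "cell_id": [f"{group}_{k:02d}" for k in range(x.size)],
            "group": group,
            "distance_um": x,
            "amplitude_mV": amp,
            "halfwidth_ms": hw,
        }
    )
    return AttenuationDataset(records=df)


# --------------------------------------------------------------------------
# spike trains
# --------------------------------------------------------------------------

@dataclass
class SpikeShape:
    """Piecewise-linear stereotyped spike.

    Rise baseline->peak over ``rise_ms``; fall at the slope that returns
    to baseline in ``fall_ms``, continuing to ``v_antipeak``; linear
    recovery back to baseline over ``ahp_ms``.  Ground truth: amplitude =
    v_peak - v_antipeak; half-width (threshold at rise onset, constant
    rise slope) = (rise_ms + fall_ms) / 2.
    """

    v_baseline: float = -60.0
    v_peak: float = 10.0
    v_antipeak: float = -60.0
    rise_ms: float = 0.4
    fall_ms: float = 0.6
    ahp_ms: float = 5.0

    def __post_init__(self):
        _check(self.v_peak > self.v_baseline, "v_peak", "must exceed baseline")
        _check(self.v_antipeak <= self.v_baseline, "v_antipeak",
               "must not exceed baseline")
        _check(self.rise_ms > 0 and self.fall_ms > 0, "rise_ms/fall_ms",
               "must be > 0")

    @property
    def fall_to_antipeak_ms(self) -> float:
        span = self.v_peak - self.v_baseline
        return self.fall_ms * (self.v_peak - self.v_antipeak) / span

    @property
    def footprint_ms(self) -> float:
        return self.rise_ms + self.fall_to_antipeak_ms + self.ahp_ms

    @property
    def true_amplitude(self) -> float:
        return self.v_peak - self.v_antipeak

    @property
    def true_half_width(self) -> float:
        return 0.5 * (self.rise_ms + self.fall_ms)


def simulate_spike_trace(
    shape: SpikeShape,
    n_spikes: int = 10,
    duration_ms: float = 1000.0,
    rate_hz: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_rate_khz: float = DEFAULT_RATE_KHZ,
) -> tuple[Trace, dict]:
    """A voltage trace of stereotyped spikes at known times.

    Returns ``(trace, ground_truth)`` where the ground truth dict holds
    the planted peak times, amplitude and half-width.  Raises if the
    requested spikes would overlap or overrun the trace.
    """
    _check(n_spikes >= 0, "n_spikes", "must be >= 0")
    isi = 1000.0 / rate_hz
    _check(isi > shape.footprint_ms, "rate_hz",
           f"spikes would overlap (ISI {isi:.2f} ms < footprint "
           f"{shape.footprint_ms:.2f} ms)")
    _check(duration_ms >= (n_spikes - 0.5) * isi + shape.footprint_ms,
           "duration_ms", "duration does not cover n_spikes at this rate")
    dt = 1.0 / sample_rate_khz
    n = int(round(duration_ms / dt))
    t = np.arange(n) * dt
    v = np.full(n, shape.v_baseline, dtype=float)
    first = 0.5 * isi
    # snap onsets to the sample grid so planted features are exact
    onsets = [round((first + k * isi) / dt) * dt for k in range(n_spikes)]
    peak_times = [t_on + shape.rise_ms for t_on in onsets]
    span = shape.v_peak - shape.v_baseline
    fall_slope = -span / shape.fall_ms
    for k in range(n_spikes):
        t_on = onsets[k]
        tt = t - t_on
        rise = (tt >= 0) & (tt < shape.rise_ms)
        v[rise] = shape.v_baseline + span * tt[rise] / shape.rise_ms
        t_fall = tt - shape.rise_ms
        falling = (t_fall >= 0) & (t_fall < shape.fall_to_antipeak_ms)
        v[falling] = shape.v_peak + fall_slope * t_fall[falling]
        t_ahp = t_fall - shape.fall_to_antipeak_ms
        ahp = (t_ahp >= 0) & (t_ahp < shape.ahp_ms)
        v[ahp] = shape.v_antipeak + (
            (shape.v_baseline - shape.v_antipeak) * t_ahp[ahp] / shape.ahp_ms
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=n)
    trace = Trace(samples=v, dt=dt, kind=VOLTAGE, meta={"synthetic": True})
    truth = {
        "peak_times_ms": peak_times,
        "amplitude_mv": shape.true_amplitude,
        "half_width_ms": shape.true_half_width,
        "v_threshold_mv": shape.v_baseline,
    }
    return trace, truth


# --------------------------------------------------------------------------
# calcium-spike step families
# --------------------------------------------------------------------------

@dataclass
class SimCaSpikeSpec:
    """Planted calcium-spike threshold within an ascending step protocol.

    ``threshold_current`` may lie above the largest step (then the
    threshold is genuinely not reached).  The passive response follows a
    single membrane time constant; the calcium spike is an alpha-function
    bump (amplitude 35 mV, time-to-peak 4 ms) superimposed identically —
    all-or-none — on every suprathreshold step.
    """

    threshold_current: float = 600.0
    r_input: float = 50.0
    step_levels: tuple = (25.0, 50.0, 75.0, 100.0, 200.0, 300.0, 400.0,
                          500.0, 600.0, 700.0, 800.0, 900.0, 1000.0)
    step_duration: float = 200.0
    baseline_vm: float = -80.0
    seed: int = 0
    step_onset: float = 20.0
    tau_m_ms: float = 15.0
    spike_amp_mv: float = 35.0
    spike_tau_ms: float = 4.0
    noise_sd: float = 0.0
    sample_rate_khz: float = 10.0

    def __post_init__(self):
        levels = self.step_levels
        _check(len(levels) >= 2, "step_levels", "need >= 2 levels")
        _check(all(b > a for a, b in zip(levels, levels[1:])),
               "step_levels", "must be strictly increasing")
        _check(self.threshold_current >= levels[0], "threshold_current",
               "must lie within or above the step range")
        _check(self.r_input > 0, "r_input", "must be > 0 MOhm")
        _check(self.step_duration > 0, "step_duration", "must be > 0 ms")


def simulate_castep_family(spec: SimCaSpikeSpec) -> CurrentStepFamily:
    """Voltage responses to ascending current steps with a planted threshold.

    Subthreshold responses are passive charging curves with slope set by
    ``r_input``; at and above ``threshold_current`` an identical
    regenerative depolarization is superimposed partway into the step.
    """
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.sample_rate_khz
    total = spec.step_onset + spec.step_duration
    n = int(round(total / dt))
    t = np.arange(n) * dt
    r_gohm = spec.r_input / 1000.0
    t_spike = spec.step_onset + 0.3 * spec.step_duration
    steps = []
    for current in spec.step_levels:
        v = np.full(n, spec.baseline_vm, dtype=float)
        tt = t - spec.step_onset
        in_step = tt >= 0
        v[in_step] = spec.baseline_vm + current * r_gohm * (
            1.0 - np.exp(-tt[in_step] / spec.tau_m_ms)
        )
        if current >= spec.threshold_current:
            ts = t - t_spike
            bump = ts > 0
            v[bump] += spec.spike_amp_mv * (ts[bump] / spec.spike_tau_ms) * np.exp(
                1.0 - ts[bump] / spec.spike_tau_ms
            )
        if spec.noise_sd > 0:
            v = v + rng.normal(0.0, spec.noise_sd, size=n)
        steps.append(
            (float(current), Trace(samples=v, dt=dt, kind=VOLTAGE,
                                   meta={"synthetic": True}))
        )
    return CurrentStepFamily(
        steps=steps,
        baseline_vm=spec.baseline_vm,
        step_onset_ms=spec.step_onset,
        step_duration_ms=spec.step_duration,
        conditions={"TTX": True},
    )


# --------------------------------------------------------------------------
# expression tables
# --------------------------------------------------------------------------

def simulate_expression_table(
    n_genes: int,
    channel_list,
    n_signif_channels: int,
    lfc_range: tuple[float, float] = (1.5, 3.0),
    seed: int = 0,
    timepoint: str = "",
    signif_fraction_other: float = 0.05,
) -> GeneTable:
    """A gene table with a planted set of significant channel genes.

    Exactly ``n_signif_channels`` channel genes receive q <= 0.05; their
    fold-change magnitudes are log-uniform in ``lfc_range`` with random
    direction.  All other channel genes get q > 0.05 and fold changes
    near 1.  A ``signif_fraction_other`` share of the non-channel filler
    genes is also significant, so the channel subset is a genuine subset
    of a larger screen.
    """
    if isinstance(channel_list, pd.DataFrame):
        symbols = channel_list["gene"].tolist()
        subfam = dict(zip(channel_list["gene"],
                          channel_list.get("subfamily", [""] * len(symbols))))
    else:
        symbols = list(channel_list)
        subfam = {}
    _check(0 <= n_signif_channels <= len(symbols), "n_signif_channels",
           "must not exceed the channel list size")
    _check(len(symbols) <= n_genes, "n_genes",
           "must be >= the channel list size")
    lo, hi = lfc_range
    _check(1.0 < lo < hi, "lfc_range", "must satisfy 1 < lo < hi")
    rng = np.random.default_rng(seed)
    n_other = n_genes - len(symbols)
    other = [f"GENE{k:05d}" for k in range(n_other)]
    genes = symbols + other
    is_channel = np.array([True] * len(symbols) + [False] * n_other)

    sig = np.zeros(n_genes, dtype=bool)
    sig_ch = rng.choice(len(symbols), size=n_signif_channels, replace=False)
    sig[sig_ch] = True
    if n_other:
        n_sig_other = int(round(signif_fraction_other * n_other))
        sig_other = rng.choice(n_other, size=n_sig_other, replace=False)
        sig[len(symbols) + sig_other] = True

    q = np.where(
        sig,
        rng.uniform(5e-4, 0.05, size=n_genes),
        rng.uniform(0.0501, 1.0, size=n_genes),
    )
    p = q * rng.uniform(0.05, 0.8, size=n_genes)
    mag = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    direction = rng.choice([-1.0, 1.0], size=n_genes)
    fc = np.where(
        sig,
        np.where(direction > 0, mag, 1.0 / mag),
        np.exp(rng.normal(0.0, 0.05, size=n_genes)),
    )
    df = pd.DataFrame(
        {
            "gene": genes,
            "fold_change": fc,
            "p_value": p,
            "q_value": q,
            "is_channel": is_channel,
            "subfamily": [subfam.get(g, "") for g in genes],
        }
    )
    return GeneTable(records=df, timepoint=timepoint)
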