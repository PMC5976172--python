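"""Dendritic calcium-spike threshold analysis from somatic current steps.

An ascending family of somatic current steps is screened for the
all-or-none dendritic calcium spike: a step response is called positive
when it exceeds the passive (ohmic, scaled from the smallest step)
prediction by at least 20 mV for at least 2 ms.  The threshold current
is the smallest step that elicits a spike.

Input resistance is the slope of the steady-state voltage/current
relation restricted to steady-state potentials between -80 and -75 mV,
a window chosen to minimize the influence of active conductances.

Non-firing cells are usable only if they start more depolarized than
-45 mV (depolarization block, not slicing injury) and hyperpolarize
below -55 mV under TTX + CdCl2; otherwise they are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MOHM_PER_GOHM, Trace, ValidationError

VM_WINDOW_MV = (-80.0, -75.0)
STEADY_STATE_FRACTION = 0.2  # steady state = mean over final 20% of the step
USABLE_VM_START_MV = -45.0   # non-firing cells must start above this
USABLE_VM_BLOCKED_MV = -55.0  # and fall below this under TTX + CdCl2


@dataclass
class DetectionConfig:
    """Calcium-spike detection criterion (package defaults, configurable)."""

    min_amplitude_mv: float = 20.0
    min_duration_ms: float = 2.0


@dataclass
class CurrentStepFamily:
    """Ascending somatic current steps and their voltage responses."""

    steps: list  # list of (current_pA, Trace)
    baseline_vm: float
    step_onset_ms: float
    step_duration_ms: float
    conditions: dict = field(default_factory=dict)

    def __post_init__(self):
        currents = [i for i, _ in self.steps]
        if len(currents) < 1:
            raise ValidationError("family must contain at least one step")
        if any(b <= a for a, b in zip(currents, currents[1:])):
            raise ValidationError("step currents must be strictly increasing")
        first = self.steps[0][1]
        for _, tr in self.steps[1:]:
            if tr.n != first.n or tr.dt != first.dt:
                raise ValidationError("step traces are incongruent")

    @property
    def currents(self) -> list:
        return [i for i, _ in self.steps]

    @property
    def step_end_ms(self) -> float:
        return self.step_onset_ms + self.step_duration_ms


@dataclass
class CalciumSpikeCall:
    present: bool
    onset_ms: float | None = None
    peak_amplitude_above_passive: float = 0.0


@dataclass
class ThresholdResult:
    """Smallest current eliciting a calcium spike, or not-reached."""

    current_pa: float | None
    reached: bool
    non_monotonic: bool = False
    calls: dict = field(default_factory=dict)


@dataclass
class CellUsability:
    firing: bool
    vm_baseline: float
    vm_after_blockers: float | None
    verdict: str  # usable | excluded | pending
    reason: str


def detect_calcium_spike(
    response: Trace,
    passive: Trace,
    step_onset_ms: float,
    step_duration_ms: float,
    cfg: DetectionConfig | None = None,
) -> CalciumSpikeCall:
    """Call a calcium spike from the excess of a response over its passive prediction.

    Present iff (response - passive) >= ``min_amplitude_mv`` continuously
    for >= ``min_duration_ms`` during the step; onset is the start of the
    first qualifying run.
    """
    cfg = cfg or DetectionConfig()
    if response.n != passive.n or response.dt != passive.dt:
        raise ValidationError("response and passive prediction are incongruent")
    i0 = response.index_at(step_onset_ms)
    i1 = response.index_at(step_onset_ms + step_duration_ms)
    excess = response.samples[i0 : i1 + 1] - passive.samples[i0 : i1 + 1]
    mask = excess >= cfg.min_amplitude_mv
    need = max(1, int(round(cfg.min_duration_ms / response.dt)))
    run = 0
    onset_idx = None
    for k, m in enumerate(mask):
        run = run + 1 if m else 0
        if run >= need:
            onset_idx = k - run + 1
            break
    peak = float(excess.max()) if excess.size else 0.0
    if onset_idx is None:
        return CalciumSpikeCall(present=False, peak_amplitude_above_passive=max(peak, 0.0))
    onset_ms = response.t0 + (i0 + onset_idx) * response.dt
    return CalciumSpikeCall(
        present=True, onset_ms=onset_ms, peak_amplitude_above_passive=peak
    )


def _passive_prediction(family: CurrentStepFamily, current_pa: float) -> Trace:
    """Ohmic prediction: the smallest step's deviation from baseline scaled
    by the current ratio.  Assumes the smallest step is subthreshold."""
    i_ref, ref = family.steps[0]
    scaled = family.baseline_vm + (ref.samples - family.baseline_vm) * (
        current_pa / i_ref
    )
    return ref.with_samples(scaled)


def threshold_current(
    family: CurrentStepFamily, cfg: DetectionConfig | None = None
) -> ThresholdResult:
    """Smallest injected current whose response contains a calcium spike.

    The smallest step serves as the passive reference and is assumed
    subthreshold.  If a spike appears at some step but not at a larger
    one (noise), the smallest spiking step is still reported and the
    result is flagged non-monotonic.
    """
    cfg = cfg or DetectionConfig()
    if len(family.steps) < 2:
        raise ValidationError("threshold search requires >= 2 steps")
    calls = {}
    for current, tr in family.steps[1:]:
        passive = _passive_prediction(family, current)
        calls[current] = detect_calcium_spike(
            tr, passive, family.step_onset_ms, family.step_duration_ms, cfg
        )
    spiking = [i for i, c in calls.items() if c.present]
    if not spiking:
        return ThresholdResult(current_pa=None, reached=False, calls=calls)
    threshold = min(spiking)
    above = [i for i in calls if i >= threshold]
    non_monotonic = any(not calls[i].present for i in above)
    return ThresholdResult(
        current_pa=float(threshold),
        reached=True,
        non_monotonic=non_monotonic,
        calls=calls,
    )


def input_resistance(
    family: CurrentStepFamily, window: tuple[float, float] = VM_WINDOW_MV
) -> float:
    """Input resistance (MOhm) from the windowed steady-state V-I relation.

    Steady state is the mean voltage over the final 20% of each step;
    only steps whose steady state lies inside ``window`` (default -80 to
    -75 mV) enter the regression.  Returns NaN (flagged missing) with
    fewer than two in-window points.
    """
    lo, hi = window
    t_ss = family.step_end_ms - STEADY_STATE_FRACTION * family.step_duration_ms
    currents, volts = [], []
    for current, tr in family.steps:
        seg = tr.slice(t_ss, family.step_end_ms)
        vss = float(seg.samples.mean())
        if lo <= vss <= hi:
            currents.append(current)
            volts.append(vss)
    if len(currents) < 2:
        return float("nan")
    slope_gohm = float(np.polyfit(currents, volts, 1)[0])  # mV/pA = GOhm
    return slope_gohm * MOHM_PER_GOHM


def classify_cell_usability(
    firing: bool,
    vm_baseline: float,
    vm_after_blockers: float | None = None,
) -> CellUsability:
    """Apply the cell-inclusion decision table.

    Firing cells are always usable.  A non-firing cell is usable only if
    it began the recording more depolarized than -45 mV (consistent with
    depolarization block) AND hyperpolarized below -55 mV under
    TTX + CdCl2; a depolarized non-firing cell without the blocker
    measurement is pending, never silently defaulted.
    """
    if firing:
        return CellUsability(
            firing=True,
            vm_baseline=vm_baseline,
            vm_after_blockers=vm_after_blockers,
            verdict="usable",
            reason="firing cell",
        )
    if not vm_baseline > USABLE_VM_START_MV:
        return CellUsability(
            firing=False,
            vm_baseline=vm_baseline,
            vm_after_blockers=vm_after_blockers,
            verdict="excluded",
            reason=(
                f"non-firing and baseline Vm <= {USABLE_VM_START_MV} mV; "
                "likely a product of slicing injury"
            ),
        )
    if vm_after_blockers is None:
        return CellUsability(
            firing=False,
            vm_baseline=vm_baseline,
            vm_after_blockers=None,
            verdict="pending",
            reason="non-firing, depolarized; awaiting TTX + CdCl2 measurement",
        )
    if vm_after_blockers < USABLE_VM_BLOCKED_MV:
        return CellUsability(
            firing=False,
            vm_baseline=vm_baseline,
            vm_after_blockers=vm_after_blockers,
            verdict="usable",
            reason="depolarization block reversed by TTX + CdCl2",
        )
    return CellUsability(
        firing=False,
        vm_baseline=vm_baseline,
        vm_after_blockers=vm_after_blockers,
        verdict="excluded",
        reason=(
            f"did not hyperpolarize below {USABLE_VM_BLOCKED_MV} mV under "
            "TTX + CdCl2; likely a product of slicing injury"
        ),
    )
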