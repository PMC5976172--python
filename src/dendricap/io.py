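"""Plain-text readers and writers.

Traces travel as two-column delimited text (time_ms, value) with a JSON
sidecar carrying units, sampling rate, protocol and any ground truth;
sweep sets and step families are directories of such files plus a
manifest.  Tables are CSV (or XLSX for expression tables, handled in
:mod:`dendricap.channel_expression`).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .attenuation import AttenuationDataset
from .calcium_spike import CurrentStepFamily
from .core import SweepSet, Trace, ValidationError, VoltageStepProtocol


def write_trace(trace: Trace, path: str | Path, **extra_meta) -> None:
    """Write (time_ms, value) text plus a ``.json`` metadata sidecar."""
    path = Path(path)
    data = np.column_stack([trace.times, trace.samples])
    np.savetxt(path, data, fmt="%.9g", delimiter="\t",
               header="time_ms\tvalue", comments="")
    meta = {
        "kind": trace.kind,
        "units": trace.units,
        "dt_ms": trace.dt,
        "t0_ms": trace.t0,
        **{k: v for k, v in trace.meta.items() if _jsonable(v)},
        **extra_meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise ValidationError(f"missing metadata sidecar for {path}")
    meta = json.loads(sidecar.read_text())
    t, v = data[:, 0], data[:, 1]
    extra = {k: val for k, val in meta.items()
             if k not in ("kind", "units", "dt_ms", "t0_ms")}
    return Trace(samples=v, dt=meta["dt_ms"], kind=meta["kind"],
                 units=meta["units"], t0=float(t[0]), meta=extra)


def write_sweepset(sweeps: SweepSet, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    p = sweeps.protocol
    (directory / "protocol.json").write_text(json.dumps({
        "v_hold": p.v_hold, "v_step": p.v_step,
        "step_onset": p.step_onset, "step_duration": p.step_duration,
    }, indent=2))
    for k, sweep in enumerate(sweeps.sweeps):
        write_trace(sweep, directory / f"sweep_{k:03d}.txt")


def read_sweepset(directory: str | Path) -> SweepSet:
    directory = Path(directory)
    proto = json.loads((directory / "protocol.json").read_text())
    protocol = VoltageStepProtocol(**proto)
    files = sorted(directory.glob("sweep_*.txt"))
    if not files:
        raise ValidationError(f"no sweep files in {directory}")
    return SweepSet(sweeps=[read_trace(f) for f in files], protocol=protocol)


def write_step_family(family: CurrentStepFamily, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "baseline_vm": family.baseline_vm,
        "step_onset_ms": family.step_onset_ms,
        "step_duration_ms": family.step_duration_ms,
        "conditions": family.conditions,
        "currents_pa": family.currents,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for current, tr in family.steps:
        write_trace(tr, directory / f"step_{current:07.1f}pA.txt")


def read_step_family(directory: str | Path) -> CurrentStepFamily:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    steps = []
    for current in manifest["currents_pa"]:
        tr = read_trace(directory / f"step_{current:07.1f}pA.txt")
        steps.append((float(current), tr))
    return CurrentStepFamily(
        steps=steps,
        baseline_vm=manifest["baseline_vm"],
        step_onset_ms=manifest["step_onset_ms"],
        step_duration_ms=manifest["step_duration_ms"],
        conditions=manifest.get("conditions", {}),
    )


def read_attenuation_table(path: str | Path) -> AttenuationDataset:
    """CSV with columns cell_id, group, distance_um, amplitude_mV, halfwidth_ms."""
    return AttenuationDataset(records=pd.read_csv(path))


def write_attenuation_table(data: AttenuationDataset, path: str | Path) -> None:
    data.records.to_csv(path, index=False)


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
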