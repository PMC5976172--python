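"""End-to-end synthetic study: configuration, provenance, and reporting.

``run_synthetic_study`` generates synthetic cohorts for two genotype
groups at two ages, runs every analysis stage (capacitance
decomposition, spike features, attenuation fits with the nested-curve F
test, calcium-spike thresholds, gene screen) and reports recovered
versus planted parameters alongside all test statistics.

One global seed is expanded into independent per-stage substreams
(``numpy.random.SeedSequence.spawn``) so any stage can be rerun alone
with stable results.  Every report carries a config hash; two runs with
the same hash produce identical reports for deterministic stages.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__
from .attenuation import extra_ss_f_test, fit_exponential_model, length_constant
from .calcium_spike import input_resistance, threshold_current
from .capacitance import (
    derive_compartments,
    fit_biexponential,
    preprocess_transient,
    qc_cell,
)
from .channel_expression import (
    flag_significant,
    load_channel_list,
    log2_heatmap_matrix,
    persistent_dysregulated,
    subset_channels,
)
from .core import ValidationError, VoltageStepProtocol
from .spike_features import (
    SpikeConfig,
    first_n_spike_halfwidths,
    trace_amplitude_stats,
)
from .synthetic_data import (
    SimBapSpec,
    SimCaSpikeSpec,
    SimCircuitSpec,
    SpikeShape,
    simulate_bap_dataset,
    simulate_capacitance_sweeps,
    simulate_castep_family,
    simulate_expression_table,
    simulate_spike_trace,
)

#: study-level defaults; group attenuation rates follow the reported
#: wild-type / mutant decay constants at the two recording ages
DEFAULTS = {
    "seed": 0,
    "report_format": "json",
    "ljp_mv": 10.0,
    "q_cut": 0.05,
    "capacitance": {
        "groups": {
            "wild_type": {"c1": 112.5, "c2": 500.0, "r1": 6.67, "r2": 13.33},
            "mutant": {"c1": 112.5, "c2": 300.0, "r1": 6.67, "r2": 20.0},
        },
        "r_input": 150.0,
        "noise_sd": 5.0,
        "n_sweeps": 10,
    },
    "bap": {
        "ages": {
            "5wk": {
                "wild_type": {"a0": 72.86, "b_amp": 0.0376},
                "mutant": {"a0": 75.40, "b_amp": 0.0215},
            },
            "15wk": {
                "wild_type": {"a0": 75.64, "b_amp": 0.0385},
                "mutant": {"a0": 72.99, "b_amp": 0.0230},
            },
        },
        "hw0": 0.35,
        "b_hw": 0.004,
        "distances": [float(x) for x in range(10, 130, 10)],
        "noise_sd_amp": 2.0,
        "noise_sd_hw": 0.02,
    },
    "spikes": {"n_spikes": 10, "duration_ms": 1000.0, "rate_hz": 20.0},
    "caspike": {
        "groups": {"wild_type": 600.0, "mutant": 300.0},
        "r_input": 50.0,
    },
    "genes": {
        "n_genes": 2000,
        "n_signif_channels": {"5wk": 18, "12wk": 22},
        "lfc_range": [1.5, 3.0],
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def validate_and_log(config: dict | None = None) -> tuple[dict, list]:
    """Fill defaults, validate ranges, and collect provenance log lines.

    Returns ``(normalized_config, log_lines)``.  Out-of-range values
    raise naming the field and bound; unusual-but-legal values (ljp = 0)
    are accepted with a warning line.
    """
    cfg = _deep_merge(DEFAULTS, config or {})
    log = []
    if not 0 <= cfg["q_cut"] <= 1:
        raise ValidationError(f"q_cut must be in [0, 1], got {cfg['q_cut']}")
    if cfg["ljp_mv"] == 0:
        log.append("warning: ljp_mv = 0 (no junction-potential correction)")
    if cfg["capacitance"]["noise_sd"] < 0:
        raise ValidationError("capacitance.noise_sd must be >= 0")
    if cfg["capacitance"]["n_sweeps"] < 1:
        raise ValidationError("capacitance.n_sweeps must be >= 1")
    if cfg["bap"]["noise_sd_amp"] < 0:
        raise ValidationError("bap.noise_sd_amp must be >= 0")
    if not isinstance(cfg["seed"], (int, np.integer)) or cfg["seed"] < 0:
        raise ValidationError(f"seed must be a non-negative integer, got {cfg['seed']}")
    log.append(f"config hash {config_hash(cfg)}")
    log.append("package defaults in use for any parameter not set explicitly")
    return cfg, log


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def run_synthetic_study(config: dict | None = None, out_dir: str | Path | None = None) -> dict:
    """Run every analysis stage on freshly generated synthetic cohorts.

    Returns the report dict; if ``out_dir`` is given, also writes
    ``report.json`` and a ``study.log`` there.  Any stage failure aborts
    the run with the failing stage named.
    """
    cfg, log = validate_and_log(config)
    seeds = _stage_seeds(cfg["seed"])
    report = {
        "version": __version__,
        "seed": cfg["seed"],
        "config_hash": config_hash(cfg),
        "stages": {},
    }

    # --- capacitance ------------------------------------------------------
    stage = {}
    try:
        protocol = VoltageStepProtocol()
        cap_cfg = cfg["capacitance"]
        for gi, (group, circ) in enumerate(cap_cfg["groups"].items()):
            spec = SimCircuitSpec(
                **circ,
                r_input=cap_cfg["r_input"],
                noise_sd=cap_cfg["noise_sd"],
                n_sweeps=cap_cfg["n_sweeps"],
                seed=seeds[0] + gi,
            )
            sweeps = simulate_capacitance_sweeps(spec, protocol)
            corrected = preprocess_transient(sweeps, r_input=spec.r_input)
            fit = fit_biexponential(corrected, protocol)
            params = derive_compartments(fit, protocol)
            stage[group] = {
                "planted": {"c1_pF": circ["c1"], "c2_pF": circ["c2"],
                            "r1_MOhm": circ["r1"], "r2_MOhm": circ["r2"]},
                "recovered": {"c1_pF": params.c1, "c2_pF": params.c2,
                              "r1_MOhm": params.r1, "r2_MOhm": params.r2},
                "rss": fit.rss,
                "converged": fit.converged,
                "qc": qc_cell(spec.r_input),
            }
    except Exception as exc:
        raise RuntimeError(f"capacitance stage failed: {exc}") from exc
    report["stages"]["capacitance"] = stage

    # --- bAP attenuation --------------------------------------------------
    stage = {}
    try:
        bap_cfg = cfg["bap"]
        for ai, (age, groups) in enumerate(bap_cfg["ages"].items()):
            datasets = []
            fits = {}
            for gi, (group, pars) in enumerate(groups.items()):
                spec = SimBapSpec(
                    a0=pars["a0"],
                    b_amp=pars["b_amp"],
                    hw0=bap_cfg["hw0"],
                    b_hw=bap_cfg["b_hw"],
                    distances=tuple(bap_cfg["distances"]),
                    noise_sd_amp=bap_cfg["noise_sd_amp"],
                    noise_sd_hw=bap_cfg["noise_sd_hw"],
                    seed=seeds[1] + 10 * ai + gi,
                )
                ds = simulate_bap_dataset(spec, group=group)
                datasets.append(ds)
                x, y = ds.xy("amplitude")
                fit = fit_exponential_model(x, y, "decay")
                fits[group] = {
                    "planted_b": pars["b_amp"],
                    "recovered_b": fit.b,
                    "length_constant_um": round(length_constant(fit), 1),
                    "planted_length_constant_um": round(
                        length_constant(pars["b_amp"]), 1
                    ),
                    "r2": fit.r2,
                }
            import pandas as pd

            merged = type(datasets[0])(
                records=pd.concat([d.records for d in datasets], ignore_index=True)
            )
            ftest = extra_ss_f_test(merged, response="amplitude")
            stage[age] = {
                "groups": fits,
                "f_test": {
                    "f_stat": ftest.f_stat,
                    "df": [ftest.df_num, ftest.df_den],
                    "p_value": ftest.p_value,
                },
            }
    except Exception as exc:
        raise RuntimeError(f"attenuation stage failed: {exc}") from exc
    report["stages"]["attenuation"] = stage

    # --- spike features ---------------------------------------------------
    try:
        sp = cfg["spikes"]
        shape = SpikeShape()
        trace, truth = simulate_spike_trace(
            shape,
            n_spikes=sp["n_spikes"],
            duration_ms=sp["duration_ms"],
            rate_hz=sp["rate_hz"],
            seed=seeds[2],
        )
        scfg = SpikeConfig(ljp_mv=cfg["ljp_mv"], filter_cutoff_khz=None)
        mean_amp, _ = trace_amplitude_stats(trace, scfg, duration_ms=sp["duration_ms"])
        mean_hw = first_n_spike_halfwidths(trace, scfg, n=5)
        report["stages"]["spike_features"] = {
            "planted": {"amplitude_mV": truth["amplitude_mv"],
                        "half_width_ms": truth["half_width_ms"]},
            "recovered": {"amplitude_mV": mean_amp, "half_width_ms": mean_hw},
        }
    except Exception as exc:
        raise RuntimeError(f"spike-feature stage failed: {exc}") from exc

    # --- calcium-spike thresholds -----------------------------------------
    stage = {}
    try:
        ca = cfg["caspike"]
        for gi, (group, planted) in enumerate(ca["groups"].items()):
            spec = SimCaSpikeSpec(
                threshold_current=planted,
                r_input=ca["r_input"],
                seed=seeds[3] + gi,
            )
            family = simulate_castep_family(spec)
            res = threshold_current(family)
            rin = input_resistance(family)
            stage[group] = {
                "planted_threshold_pA": planted,
                "recovered_threshold_pA": res.current_pa,
                "reached": res.reached,
                "planted_rin_MOhm": ca["r_input"],
                "recovered_rin_MOhm": rin,
            }
    except Exception as exc:
        raise RuntimeError(f"calcium-spike stage failed: {exc}") from exc
    report["stages"]["calcium_spike"] = stage

    # --- gene screen ------------------------------------------------------
    try:
        g = cfg["genes"]
        channels = load_channel_list()
        tables = {}
        for ti, (tp, n_sig) in enumerate(g["n_signif_channels"].items()):
            table = simulate_expression_table(
                n_genes=g["n_genes"],
                channel_list=channels,
                n_signif_channels=n_sig,
                lfc_range=tuple(g["lfc_range"]),
                seed=seeds[4] + ti,
                timepoint=tp,
            )
            tables[tp] = flag_significant(
                subset_channels(table, channels), q_cut=cfg["q_cut"]
            )
        (tp_a, tab_a), (tp_b, tab_b) = list(tables.items())
        persistent = persistent_dysregulated(tab_a, tab_b)
        matrix = log2_heatmap_matrix(list(tables.values()), significant_only=True)
        report["stages"]["gene_screen"] = {
            "n_channel_genes": len(tab_a.records),
            "n_significant": {tp: len(t.significant_genes)
                              for tp, t in tables.items()},
            "planted_significant": dict(g["n_signif_channels"]),
            "n_persistent": len(persistent),
            "heatmap_shape": list(matrix.shape),
        }
    except Exception as exc:
        raise RuntimeError(f"gene-screen stage failed: {exc}") from exc

    report["log"] = log
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=_json_default))
        (out_dir / "study.log").write_text("\n".join(log) + "\n")
    return report


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
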