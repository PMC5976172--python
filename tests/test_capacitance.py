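"""Two-compartment capacitance: equations, round trips, preprocessing, QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dendricap.capacitance import (
    BiexpFit,
    CompartmentParams,
    average_sweeps,
    compartments_to_biexponential,
    derive_compartments,
    fit_biexponential,
    leak_correct,
    preprocess_transient,
    qc_cell,
)
from dendricap.core import SweepSet, Trace, ValidationError, VoltageStepProtocol
from dendricap.synthetic_data import SimCircuitSpec, simulate_capacitance_sweeps


def recovered_params(spec, protocol, **fit_kw):
    sweeps = simulate_capacitance_sweeps(spec, protocol)
    corrected = preprocess_transient(sweeps, r_input=spec.r_input)
    fit = fit_biexponential(corrected, protocol, **fit_kw)
    return derive_compartments(fit, protocol)


class TestCompartmentEquations:
    def test_direct_evaluation(self):
        """dV=10 mV, A1=1000 pA, A2=500 pA, tau1=0.5 ms, tau2=10 ms maps to
        C1=112.5 pF, C2=500 pF, R1~6.67 MOhm, R2~13.33 MOhm."""
        proto = VoltageStepProtocol(v_hold=-80.0, v_step=-70.0)  # dv = +10
        fit = BiexpFit(a1=1000.0, tau1=0.5, a2=500.0, tau2=10.0)
        p = derive_compartments(fit, proto)
        assert p.c1 == pytest.approx(112.5)
        assert p.c2 == pytest.approx(500.0)
        assert p.r1 == pytest.approx(10.0 / 1500.0 * 1000.0)  # 6.67 MOhm
        assert p.r2 == pytest.approx((10.0 / 500.0 - 10.0 / 1500.0) * 1000.0)

    def test_hyperpolarizing_step_gives_positive_circuit(self):
        proto = VoltageStepProtocol()  # dv = -10
        fit = BiexpFit(a1=-1000.0, tau1=0.5, a2=-500.0, tau2=10.0)
        p = derive_compartments(fit, proto)
        assert p.c1 > 0 and p.c2 > 0 and p.r1 > 0 and p.r2 > 0

    def test_single_compartment_limit(self):
        proto = VoltageStepProtocol(v_hold=-80.0, v_step=-70.0)
        fit = BiexpFit(a1=1000.0, tau1=0.5, a2=0.0, tau2=10.0)
        p = derive_compartments(fit, proto)
        assert p.c2 == 0.0
        assert p.r2 is None
        assert p.single_compartment

    def test_inverse_matches_hand_algebra(self):
        params = CompartmentParams(c1=112.5, c2=500.0, r1=20.0 / 3.0,
                                   r2=40.0 / 3.0, delta_v=10.0)
        fit = compartments_to_biexponential(params)
        assert fit.a1 == pytest.approx(1000.0)
        assert fit.a2 == pytest.approx(500.0)
        assert fit.tau1 == pytest.approx(0.5)
        assert fit.tau2 == pytest.approx(10.0)

    def test_isolated_distal_compartment_limit(self):
        """r2 -> very large sends the slow amplitude toward zero."""
        params = CompartmentParams(c1=100.0, c2=500.0, r1=10.0, r2=1e9,
                                   delta_v=10.0)
        fit = compartments_to_biexponential(params)
        assert abs(fit.a2) < 1e-5 * abs(fit.a1)

    def test_nonpositive_params_rejected(self):
        params = CompartmentParams(c1=100.0, c2=-1.0, r1=10.0, r2=10.0,
                                   delta_v=10.0)
        with pytest.raises(ValidationError):
            compartments_to_biexponential(params)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        c1=st.floats(10.0, 500.0),
        c2=st.floats(50.0, 2000.0),
        r1=st.floats(1.0, 30.0),
        r2=st.floats(1.0, 50.0),
        dv=st.floats(2.0, 20.0),
        neg=st.booleans(),
    )
    def test_round_trip_identity(self, c1, c2, r1, r2, dv, neg):
        """compartments -> biexponential -> compartments is the identity."""
        dv = -dv if neg else dv
        params = CompartmentParams(c1=c1, c2=c2, r1=r1, r2=r2, delta_v=dv)
        proto = VoltageStepProtocol(v_hold=-80.0, v_step=-80.0 + dv)
        back = derive_compartments(compartments_to_biexponential(params), proto)
        for name in ("c1", "c2", "r1", "r2"):
            assert getattr(back, name) == pytest.approx(
                getattr(params, name), rel=1e-10
            )


class TestPreprocessing:
    def test_identical_sweeps_average_to_one_sweep_minus_leak(self, protocol):
        spec = SimCircuitSpec(noise_sd=0.0, n_sweeps=10)
        sweeps = simulate_capacitance_sweeps(spec, protocol)
        out = preprocess_transient(sweeps, r_input=spec.r_input,
                                   filter_cutoff_khz=None)
        single = sweeps.sweeps[0]
        leak = out.meta["leak_pa"]
        assert np.allclose(out.samples, single.samples - leak, atol=1e-9)

    def test_leak_only_trace_corrects_to_zero(self, protocol):
        leak = -100.0
        tr = Trace(samples=np.full(2000, leak), dt=0.5, kind="current")
        out = leak_correct(tr, protocol)
        assert np.allclose(out.samples, 0.0, atol=1e-12)

    def test_averaging_reduces_noise_by_sqrt_n(self, protocol):
        spec = SimCircuitSpec(noise_sd=5.0, n_sweeps=10, seed=11)
        sweeps = simulate_capacitance_sweeps(spec, protocol)
        mean = average_sweeps(sweeps)
        clean = simulate_capacitance_sweeps(
            SimCircuitSpec(noise_sd=0.0, n_sweeps=1), protocol
        ).sweeps[0]
        tail = slice(-10_000, None)  # final 100 ms: transient fully decayed
        resid_sd = np.std(mean.samples[tail] - clean.samples[tail])
        assert resid_sd == pytest.approx(5.0 / np.sqrt(10), rel=0.1)

    def test_bad_r_input_rejected(self, protocol):
        spec = SimCircuitSpec(noise_sd=0.0, n_sweeps=1)
        sweeps = simulate_capacitance_sweeps(spec, protocol)
        with pytest.raises(ValidationError):
            preprocess_transient(sweeps, r_input=0.0)


class TestBiexponentialFit:
    def test_noiseless_recovery(self, protocol):
        """Planted (A1, tau1, A2, tau2) recovered within 0.1% end to end."""
        spec = SimCircuitSpec(noise_sd=0.0, n_sweeps=1)
        planted = compartments_to_biexponential(
            spec.compartments(protocol.delta_v)
        )
        sweeps = simulate_capacitance_sweeps(spec, protocol)
        corrected = preprocess_transient(sweeps, r_input=spec.r_input)
        fit = fit_biexponential(corrected, protocol)
        assert fit.converged
        for name in ("a1", "tau1", "a2", "tau2"):
            assert getattr(fit, name) == pytest.approx(
                getattr(planted, name), rel=1e-3
            )

    def test_pure_noise_is_flagged_or_fits_nothing(self, protocol):
        rng = np.random.default_rng(0)
        n = int(round((protocol.step_onset + protocol.step_duration) / 0.01))
        tr = Trace(samples=rng.normal(0, 5.0, n), dt=0.01, kind="current")
        fit = fit_biexponential(tr, protocol)
        # either flagged, or the fit found essentially no transient: the
        # fitted amplitudes are far below the noise floor
        assert (not fit.converged) or max(abs(fit.a1), abs(fit.a2)) < 5.0

    def test_short_window_rejected(self, protocol):
        spec = SimCircuitSpec(noise_sd=0.0, n_sweeps=1)
        sweeps = simulate_capacitance_sweeps(spec, protocol)
        corrected = preprocess_transient(sweeps, r_input=spec.r_input)
        with pytest.raises(ValidationError):
            fit_biexponential(
                corrected, protocol,
                fit_window=(protocol.step_onset, protocol.step_onset + 0.05),
            )


class TestEndToEnd:
    def test_scale_equivariance_in_delta_v(self):
        """Doubling dV doubles the amplitudes but leaves the circuit estimates
        unchanged."""
        fits = {}
        for dv in (-10.0, -20.0):
            proto = VoltageStepProtocol(v_hold=-80.0, v_step=-80.0 + dv)
            spec = SimCircuitSpec(noise_sd=0.0, n_sweeps=1)
            sweeps = simulate_capacitance_sweeps(spec, proto)
            corrected = preprocess_transient(sweeps, r_input=spec.r_input)
            fit = fit_biexponential(corrected, proto)
            fits[dv] = (fit, derive_compartments(fit, proto))
        f1, p1 = fits[-10.0]
        f2, p2 = fits[-20.0]
        assert f2.a1 == pytest.approx(2 * f1.a1, rel=1e-3)
        assert f2.a2 == pytest.approx(2 * f1.a2, rel=1e-3)
        for name in ("c1", "c2", "r1", "r2"):
            assert getattr(p2, name) == pytest.approx(
                getattr(p1, name), rel=1e-3
            )

    def test_noiseless_recovery_of_circuit(self, protocol):
        spec = SimCircuitSpec(noise_sd=0.0, n_sweeps=1)
        p = recovered_params(spec, protocol)
        assert p.c1 == pytest.approx(spec.c1, rel=1e-3)
        assert p.c2 == pytest.approx(spec.c2, rel=1e-3)
        assert p.r1 == pytest.approx(spec.r1, rel=1e-3)
        assert p.r2 == pytest.approx(spec.r2, rel=1e-3)


class TestQC:
    @pytest.mark.parametrize(
        "rin,verdict",
        [(99.9, "exclude"), (100.0, "include"), (250.0, "include")],
    )
    def test_input_resistance_rule(self, rin, verdict):
        assert qc_cell(rin) == verdict
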