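"""Population model: activation function, steady states, dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dorsalhorn.circuits import (
    circuit_from_config,
    simple_circuit,
    static_circuit,
    steady_state,
)
from dorsalhorn.dynamics import simulate_trace
from dorsalhorn.populations import (
    EXCITATORY,
    INHIBITORY,
    PopulationParams,
    activation_rate,
)
from dorsalhorn.stimulus import constant_trace, generate_abeta_trace


class TestActivation:
    @pytest.mark.parametrize("pop", [INHIBITORY, EXCITATORY],
                             ids=["inhibitory", "excitatory"])
    def test_half_activation_at_beta(self, pop):
        assert activation_rate(pop.beta, pop) == pytest.approx(pop.m / 2)

    @pytest.mark.parametrize("pop", [INHIBITORY, EXCITATORY],
                             ids=["inhibitory", "excitatory"])
    def test_voltage_floor_is_effectively_silent(self, pop):
        """At V_min = beta - 12 alpha the rate is ~4e-11 of the maximum."""
        frac = activation_rate(pop.V_min, pop) / pop.m
        assert f"{frac:.0e}" == "4e-11"

    def test_rate_at_threshold(self):
        """V_thr = beta - alpha puts the rate at 0.5(1+tanh(-1)) of max."""
        expected = 0.5 * (1 + math.tanh(-1.0))
        for pop in (INHIBITORY, EXCITATORY):
            assert activation_rate(pop.V_thr, pop) / pop.m == pytest.approx(
                expected, rel=1e-12)
        assert expected == pytest.approx(0.1192, abs=5e-5)

    @settings(max_examples=200, deadline=None)
    @given(v1=st.floats(-200, 140), v2=st.floats(-200, 140))
    def test_monotone_and_bounded(self, v1, v2):
        """Strict bounds and monotonicity over the representable sigmoid
        range (beyond ~19 alpha from beta, float tanh saturates exactly)."""
        pop = INHIBITORY
        r1, r2 = activation_rate(v1, pop), activation_rate(v2, pop)
        assert 0 < r1 < pop.m
        if v1 + 1e-6 < v2:
            assert r1 < r2

    def test_nonfinite_voltage_rejected(self):
        with pytest.raises(ValueError):
            activation_rate(float("nan"), INHIBITORY)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PopulationParams("inhibitory", m=-1, alpha=1, beta=0,
                             V_rest=-60, tau=0.02)
        with pytest.raises(ValueError):
            PopulationParams("other", m=1, alpha=1, beta=0,
                             V_rest=-60, tau=0.02)


class TestDefaultParameters:
    def test_derived_voltage_cutoffs(self):
        assert INHIBITORY.V_thr == pytest.approx(-39.3)
        assert INHIBITORY.V_min == pytest.approx(-141.6)
        assert INHIBITORY.V_max == pytest.approx(81.6)
        assert EXCITATORY.V_thr == pytest.approx(-24.9)
        assert EXCITATORY.V_min == pytest.approx(-111.8)
        assert EXCITATORY.V_max == pytest.approx(77.8)
        for pop in (INHIBITORY, EXCITATORY):
            assert pop.V_min < pop.V_rest < pop.V_thr < pop.V_max

    def test_time_constant_ratio(self):
        assert EXCITATORY.tau == pytest.approx(0.024)
        assert INHIBITORY.tau == pytest.approx(0.02)
        assert EXCITATORY.tau / INHIBITORY.tau == pytest.approx(1.2)


class TestSteadyState:
    def test_zero_input_rests(self):
        """Without Abeta drive, Abeta-only populations sit exactly at rest;
        downstream populations deviate only by the sigmoid's residual rest
        rate (0.13 Hz for the inhibitory parameters) times the coupling."""
        spec = simple_circuit()
        g = {"g_AbI": 3.0, "g_IE": 1.0, "g_AbE": 4.0}
        ss = steady_state(spec, g, 0.0)
        assert ss.voltage["I"] == pytest.approx(-60.0)
        leak = spec.params("I").rate(-60.0)
        assert ss.voltage["E"] == pytest.approx(-60.0 - g["g_IE"] * leak)
        assert abs(ss.voltage["E"] + 60.0) < 0.2

    def test_inhibitory_threshold_drive(self):
        """g_AbI = 2.07 at 10 Hz lands I exactly on its firing threshold."""
        spec = simple_circuit()
        ss = steady_state(spec, {"g_AbI": 2.07, "g_IE": 1.0, "g_AbE": 0.0}, 10.0)
        assert ss.voltage["I"] == pytest.approx(-39.3)
        assert ss.rate["I"] == pytest.approx(0.5 * 80 * (1 + math.tanh(-1)),
                                             rel=1e-12)
        assert ss.rate["I"] == pytest.approx(9.54, abs=0.01)

    def test_ablation_removes_only_inhibitory_term(self):
        spec = static_circuit()
        g = {"g_AbI1": 3.0, "g_AbI2": 4.0, "g_AbE": 6.0,
             "g_I1E": 1.0, "g_I2E": 0.8}
        full = steady_state(spec, g, 15.0)
        abl = steady_state(spec, g, 15.0, ablated={"I1"})
        # E loses exactly the g_I1E * f_I1 term
        assert abl.voltage["E"] - full.voltage["E"] == pytest.approx(
            g["g_I1E"] * full.rate["I1"])
        assert abl.voltage["I1"] == pytest.approx(-60.0)
        assert abl.rate["I1"] == 0.0
        # the other inhibitory population is untouched
        assert abl.voltage["I2"] == pytest.approx(full.voltage["I2"])

    def test_rates_consistent_with_voltages(self):
        spec = simple_circuit()
        f = np.linspace(0, 20, 7)
        ss = steady_state(spec, {"g_AbI": 3.0, "g_IE": 1.0, "g_AbE": 4.0}, f)
        for pid in spec.population_ids:
            pop = spec.params(pid)
            np.testing.assert_allclose(ss.rate[pid], pop.rate(ss.voltage[pid]))
            assert np.all((ss.rate[pid] >= 0) & (ss.rate[pid] <= pop.m))

    def test_unknown_ablation_id_rejected(self):
        with pytest.raises(ValueError):
            steady_state(simple_circuit(),
                         {"g_AbI": 3.0, "g_IE": 1.0, "g_AbE": 4.0},
                         10.0, ablated={"Z"})


class TestSimulation:
    def test_zero_stimulus_stays_at_rest(self):
        """With zero drive the trace stays at the f_ab = 0 fixed point (rest
        up to the sigmoid's residual rest-rate leak)."""
        spec = simple_circuit()
        g = {"g_AbI": 3.0, "g_IE": 1.0, "g_AbE": 4.0}
        stim = generate_abeta_trace(0.0, t_on=0.1, t_off=0.2, T=0.3,
                                    background=0.0, seed=0)
        tr = simulate_trace(spec, g, stim)
        ss = steady_state(spec, g, 0.0)
        np.testing.assert_allclose(tr.voltage["I"], -60.0, atol=1e-9)
        assert abs(tr.voltage["E"][-1] - ss.voltage["E"]) < 1e-6
        np.testing.assert_allclose(tr.voltage["E"], ss.voltage["E"], atol=0.2)

    def test_constant_drive_relaxes_to_steady_state(self):
        """After 10 max(tau) the trace matches the closed-form steady state
        to better than 0.5% of each population's dynamic range."""
        spec = static_circuit()
        g = {"g_AbI1": 3.0, "g_AbI2": 4.0, "g_AbE": 6.0,
             "g_I1E": 1.0, "g_I2E": 0.8}
        f_ab = 14.0
        stim = constant_trace(f_ab, T=0.5)
        tr = simulate_trace(spec, g, stim)
        ss = steady_state(spec, g, f_ab)
        for pid in spec.population_ids:
            pop = spec.params(pid)
            span = pop.V_max - pop.V_min
            err = abs(tr.voltage[pid][-1] - ss.voltage[pid]) / span
            assert err < 0.005

    def test_dt_validation(self):
        spec = simple_circuit()
        stim = constant_trace(10.0, T=0.1)
        g = {"g_AbI": 3.0, "g_IE": 1.0, "g_AbE": 4.0}
        with pytest.raises(ValueError):
            simulate_trace(spec, g, stim, dt=-1e-3)
        with pytest.raises(ValueError):
            simulate_trace(spec, g, stim, dt=0.01)  # > tau/10

    def test_trace_export_is_tidy(self):
        spec = simple_circuit()
        stim = constant_trace(10.0, T=0.05)
        tr = simulate_trace(spec, {"g_AbI": 3.0, "g_IE": 1.0, "g_AbE": 4.0}, stim)
        df = tr.to_frame()
        assert list(df.columns) == ["time_s", "population", "V_mV", "rate_Hz"]
        assert set(df["population"]) == set(spec.population_ids)


class TestCircuitSpec:
    def test_builtin_wiring(self):
        spec = simple_circuit()
        assert spec.dim == 3
        assert spec.output == "E"
        assert spec.output_abeta == "g_AbE"
        assert static_circuit().dim == 5

    def test_hierarchy_must_cover_couplings(self):
        spec = simple_circuit()
        with pytest.raises(ValueError):
            type(spec)(
                name="broken", populations=spec.populations,
                connections=spec.connections, output="E",
                hierarchy=("g_AbI", "g_IE"),
            )

    def test_config_roundtrip(self, tmp_path):
        cfg = tmp_path / "circuit.yaml"
        cfg.write_text(
            """
name: custom
output: E
populations:
  - {id: I, role: inhibitory}
  - {id: E, role: excitatory}
connections:
  - {source: Abeta, target: I, sign: 1, name: g_AbI}
  - {source: Abeta, target: E, sign: 1, name: g_AbE}
  - {source: I, target: E, sign: -1, name: g_IE}
hierarchy: [g_AbI, g_IE, g_AbE]
"""
        )
        spec = circuit_from_config(cfg)
        ref = simple_circuit()
        g = {"g_AbI": 3.0, "g_IE": 1.0, "g_AbE": 4.0}
        a = steady_state(spec, g, 12.0)
        b = steady_state(ref, g, 12.0)
        for pid in ("I", "E"):
            assert a.voltage[pid] == pytest.approx(b.voltage[pid])
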