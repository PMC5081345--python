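import numpy as np
import pytest

from fusiform import engine
from fusiform.engine import (ProtocolSpec, Segment, integrate, detect_spikes,
                             run_dynamic_clamp, run_rmp_protocol,
                             SimulationError)
from fusiform.model import find_resting_potential
from fusiform.parameters import ModelParameters, quiet_preset, nS_to_density
from fusiform.trace import Trace, TraceError


def passive_cell(g_leak=0.15):
    return ModelParameters(g_Na=0, g_Kd=0, g_h=0, g_NaP=0, g_Kir=0,
                           g_leak=g_leak)


class TestIntegratorAccuracy:
    def test_passive_rc_matches_analytic_exponential(self):
        """Leak-only relaxation from -65 mV: V(t) = E + (V0-E) exp(-t/tau),
        tau = c_m/g_leak = 6.67 ms; numerical error < 0.1 mV everywhere."""
        p = passive_cell()
        protocol = ProtocolSpec(mode="current-clamp",
                                segments=(Segment(100.0, 0.0),),
                                settle=0.0, v_init=-65.0)
        tr = integrate(p, protocol)
        tau = p.c_m / p.g_leak
        analytic = p.E_leak + (-65.0 - p.E_leak) * np.exp(-(tr.time + protocol.dt) / tau)
        assert np.max(np.abs(tr.signal - analytic)) < 0.1
        assert tr.signal[-1] == pytest.approx(p.E_leak, abs=0.01)

    def test_pure_capacitor_holds_initial_potential(self):
        p = ModelParameters(g_Na=0, g_Kd=0, g_h=0, g_NaP=0, g_Kir=0, g_leak=0)
        protocol = ProtocolSpec(mode="current-clamp",
                                segments=(Segment(50.0, 0.0),), settle=0.0)
        tr = integrate(p, protocol)
        assert np.all(tr.signal == -65.0)

    def test_subthreshold_final_voltage_matches_bisection_oracle(self):
        p = quiet_preset().sodium_zeroed()
        rmp = run_rmp_protocol(quiet_preset())
        assert rmp == pytest.approx(find_resting_potential(p), abs=0.5)

    def test_dt_refinement_changes_steady_state_below_50uV(self):
        coarse = run_rmp_protocol(quiet_preset(), dt=0.1)
        fine = run_rmp_protocol(quiet_preset(), dt=0.05)
        assert abs(coarse - fine) < 0.05

    def test_higher_order_mode_agrees_on_subthreshold_model(self):
        """The RK4 cross-check lands on the same steady state as the
        exponential-Euler integrator for the sodium-zeroed quiet model."""
        exp_euler = run_rmp_protocol(quiet_preset())
        rk4 = engine.integrate_rk4(quiet_preset().sodium_zeroed(),
                                   duration=5000.0)
        assert abs(exp_euler - rk4) < 0.05

    def test_determinism_bit_identical(self):
        protocol = ProtocolSpec(mode="current-clamp",
                                segments=(Segment(200.0, -20.0),),
                                settle=500.0)
        t1 = integrate(quiet_preset(), protocol)
        t2 = integrate(quiet_preset(), protocol)
        assert np.array_equal(t1.signal, t2.signal)


class TestVoltageClamp:
    def test_holding_current_matches_steady_state_balance(self):
        """After gates equilibrate at the command, the holding current is
        the analytic sum g_x * x_inf(V_h) * (V_h - E_x), within 1%."""
        from fusiform.model import steady_state_current
        p = quiet_preset().sodium_zeroed()
        v_hold = -80.0
        protocol = ProtocolSpec(mode="voltage-clamp",
                                segments=(Segment(6000.0, v_hold),),
                                settle=0.0, holding=v_hold)
        tr = integrate(p, protocol)
        analytic_pA = steady_state_current(v_hold, p) * p.area_cm2 * 1e6
        assert tr.signal[-1] == pytest.approx(analytic_pA, rel=0.01)
        assert tr.units == "pA" and tr.kind == "current"


class TestBlowUpDetection:
    def test_runaway_voltage_aborts_with_step_index(self):
        # pure capacitor driven hard: V ramps linearly out of range
        p = ModelParameters(g_Na=0, g_Kd=0, g_h=0, g_NaP=0, g_Kir=0, g_leak=0)
        protocol = ProtocolSpec(mode="current-clamp",
                                segments=(Segment(1000.0, 500.0),),
                                settle=0.0)
        with pytest.raises(SimulationError, match="step"):
            integrate(p, protocol)


class TestDynamicClamp:
    def test_zero_artificial_conductance_is_identity(self):
        segs = (Segment(300.0, 0.0),)
        base = integrate(quiet_preset(),
                         ProtocolSpec(mode="current-clamp", segments=segs,
                                      settle=200.0))
        dyn = run_dynamic_clamp(quiet_preset(), 0.0, segs, settle=200.0)
        np.testing.assert_allclose(dyn.signal, base.signal, atol=1e-12)

    def test_5nS_equals_equivalent_density_increase(self):
        """Injecting g_art with native kinetics is the same as raising the
        HCN density by g_art/area (~0.398 mS/cm^2 for 5 nS)."""
        p = quiet_preset()
        extra = nS_to_density(5.0, p.area_cm2)
        assert extra == pytest.approx(0.3979, rel=1e-3)
        segs = (Segment(500.0, -50.0),)
        dyn = run_dynamic_clamp(p, 5.0, segs, settle=300.0)
        equiv = integrate(p.replace(g_h=p.g_h + extra),
                          ProtocolSpec(mode="current-clamp", segments=segs,
                                       settle=300.0))
        np.testing.assert_allclose(dyn.signal, equiv.signal, atol=1e-9)

    def test_negative_artificial_conductance_rejected(self):
        with pytest.raises(ValueError):
            run_dynamic_clamp(quiet_preset(), -1.0, (Segment(10.0, 0.0),))


class TestSpikeDetection:
    def test_upward_crossings_with_refractory(self):
        t = np.arange(0, 10.0, 0.1)
        v = np.full_like(t, -60.0)
        v[10:12] = 0.0   # spike at 1.0 ms
        v[14:16] = 0.0   # 0.4 ms later: inside refractory
        v[40:42] = 0.0   # 4.0 ms: counted
        tr = Trace(time=t, signal=v, kind="voltage", units="mV")
        times = detect_spikes(tr)
        np.testing.assert_allclose(times, [1.0, 4.0])

    def test_requires_voltage_trace(self):
        tr = Trace(time=np.arange(5.0), signal=np.zeros(5),
                   kind="current", units="pA")
        with pytest.raises(ValueError):
            detect_spikes(tr)


class TestProtocolValidation:
    def test_bad_protocols_rejected(self):
        with pytest.raises(ValueError):
            ProtocolSpec(mode="teleportation", segments=(Segment(10.0),))
        with pytest.raises(ValueError):
            ProtocolSpec(mode="current-clamp", segments=())
        with pytest.raises(ValueError):
            ProtocolSpec(mode="current-clamp", segments=(Segment(10.0),), dt=0)
        with pytest.raises(ValueError):
            Segment(duration=0.0)


class TestTraceIO:
    def _trace(self):
        t = np.arange(0, 5.0, 0.1)
        return Trace(time=t, signal=np.sin(t), kind="voltage", units="mV",
                     channel="V_m", meta={"protocol": {"mode": "x"}, "n": 3})

    def test_csv_round_trip(self, tmp_path):
        tr = self._trace()
        path = tmp_path / "trace.csv"
        tr.to_csv(path)
        back = Trace.from_csv(path)
        np.testing.assert_allclose(back.signal, tr.signal, rtol=1e-9)
        assert back.units == "mV" and back.meta["n"] == 3

    def test_hdf5_round_trip(self, tmp_path):
        tr = self._trace()
        path = tmp_path / "trace.h5"
        tr.to_hdf5(path)
        back = Trace.from_hdf5(path)
        np.testing.assert_array_equal(back.time, tr.time)
        np.testing.assert_array_equal(back.signal, tr.signal)
        assert back.kind == "voltage"

    def test_invalid_traces_rejected(self):
        with pytest.raises(TraceError):
            Trace(time=np.array([0.0, 1.0, 1.0]), signal=np.zeros(3),
                  kind="voltage", units="mV")
        with pytest.raises(TraceError):
            Trace(time=np.arange(3.0), signal=np.array([0.0, np.nan, 1.0]),
                  kind="voltage", units="mV")
        with pytest.raises(TraceError):
            Trace(time=np.arange(3.0), signal=np.zeros(3),
                  kind="impedance", units="MOhm")
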