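import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fusiform import ephys
from fusiform.ephys import (classify_firing, input_resistance_cc,
                            input_resistance_vc, sag_amplitude,
                            isolate_by_subtraction, slope_conductance,
                            boltzmann_fit, biexponential_fit, ljp_correct,
                            steady_state_value, MeasurementResult, FitError)
from fusiform.kinetics import hcn_steady_state
from fusiform.trace import Trace, TraceError


def voltage_trace(signal, dt=0.1, **meta):
    t = np.arange(len(signal)) * dt
    return Trace(time=t, signal=np.asarray(signal, float),
                 kind="voltage", units="mV", meta=meta)


class TestClassifyFiring:
    @pytest.mark.parametrize("n_spikes,duration,expected", [
        (3, 2.0, "active"),    # 1.5 Hz
        (0, 1.0, "quiet"),
        (1, 2.0, "quiet"),     # exactly 0.5 Hz: strict inequality
        (2, 2.0, "active"),
    ])
    def test_threshold_rule(self, n_spikes, duration, expected):
        assert classify_firing(np.arange(n_spikes), duration) == expected

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            classify_firing([1.0], -1.0)


class TestInputResistance:
    def test_exact_line_current_clamp(self):
        I = np.arange(0, -101, -20.0)              # pA
        V = -60.0 + I * 0.1                        # 2 mV per 20 pA -> 100 MOhm
        assert input_resistance_cc(I, V) == pytest.approx(100.0)

    def test_flat_vi_curve_is_zero_resistance(self):
        I = np.arange(0, -101, -20.0)
        assert input_resistance_cc(I, np.full_like(I, -60.0)) == pytest.approx(0.0)

    def test_ohmic_membrane_voltage_clamp(self):
        V = np.linspace(-80, -65, 4)
        I = 10.0 * (V + 60.0)                      # 10 nS -> 100 MOhm
        assert input_resistance_vc(V, I) == pytest.approx(100.0)

    def test_zero_slope_declared_nonmeasurable(self):
        V = np.linspace(-80, -65, 4)
        assert input_resistance_vc(V, np.zeros_like(V)) == np.inf

    def test_singular_designs_rejected(self):
        with pytest.raises(ValueError):
            input_resistance_cc([5.0, 5.0], [-60.0, -61.0])
        with pytest.raises(ValueError):
            input_resistance_vc([-70.0, -70.0], [0.0, 1.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(min_value=1.0, max_value=50.0))
    def test_cc_and_vc_agree_for_linear_membrane(self, g_nS):
        """Both definitions equal 1/g for an ohmic membrane (within 0.1%)."""
        V = np.linspace(-80, -65, 6)
        I = g_nS * (V + 55.0)
        r_vc = input_resistance_vc(V, I)
        r_cc = input_resistance_cc(I, V)
        assert r_cc == pytest.approx(r_vc, rel=1e-3)
        assert r_vc == pytest.approx(1000.0 / g_nS, rel=1e-9)


class TestSag:
    def test_definition_steady_minus_peak(self):
        v = np.full(2000, -75.0)
        v[100:400] = np.linspace(-75, -80, 300)   # dip to -80
        v[400:700] = np.linspace(-80, -75, 300)   # relax back
        tr = voltage_trace(v)
        assert sag_amplitude(tr, (0.0, tr.time[-1])) == pytest.approx(5.0, abs=0.01)

    def test_passive_monotone_relaxation_has_no_sag(self):
        t = np.arange(0, 200.0, 0.1)
        v = -75.0 + 10.0 * np.exp(-t / 6.67)      # RC decay, no rebound
        tr = voltage_trace(v)
        assert sag_amplitude(tr, (0.0, 199.0)) == pytest.approx(0.0, abs=0.02)

    def test_window_outside_trace_rejected(self):
        tr = voltage_trace(np.zeros(100))
        with pytest.raises(TraceError):
            sag_amplitude(tr, (0.0, 1000.0))


class TestSubtraction:
    def test_identical_traces_cancel(self):
        tr = voltage_trace(np.sin(np.arange(100) / 10))
        diff = isolate_by_subtraction(tr, tr)
        assert np.all(diff.signal == 0.0)

    def test_grid_mismatch_rejected(self):
        a = voltage_trace(np.zeros(100))
        b = voltage_trace(np.zeros(99))
        with pytest.raises(TraceError):
            isolate_by_subtraction(a, b)


class TestSlopeConductance:
    def test_ohmic_slope_on_any_window(self):
        V = np.linspace(-110, -60, 11)
        I = 5.0 * (V + 43.0)
        assert slope_conductance(V, I) == pytest.approx(5.0)
        assert slope_conductance(V, I, (-100, -75)) == pytest.approx(5.0)

    def test_doubling_gh_doubles_ih_slope(self):
        from fusiform.model import steady_state_current
        from fusiform.parameters import ModelParameters
        V = np.linspace(-100, -75, 6)
        base = ModelParameters(g_Na=0, g_Kd=0, g_NaP=0, g_Kir=0, g_leak=0)
        i1 = steady_state_current(V, base.replace(g_h=0.5))
        i2 = steady_state_current(V, base.replace(g_h=1.0))
        s1 = slope_conductance(V, i1, (-100, -75))
        s2 = slope_conductance(V, i2, (-100, -75))
        assert s2 == pytest.approx(2 * s1, rel=1e-9)
        assert s1 > 0

    def test_empty_window_rejected(self):
        V = np.linspace(-110, -100, 5)
        with pytest.raises(ValueError):
            slope_conductance(V, V, (-80, -70))


class TestBoltzmannFit:
    def test_recovers_model_activation_exactly(self):
        V = np.arange(-120.0, -54.9, 5.0)
        fit = boltzmann_fit(V, hcn_steady_state(V))
        assert fit.v_half == pytest.approx(-87.0, abs=1e-6)
        assert fit.slope == pytest.approx(8.9, abs=1e-6)

    def test_shift_equivariance(self):
        V = np.arange(-120.0, -54.9, 5.0)
        a = hcn_steady_state(V)
        f0 = boltzmann_fit(V, a)
        f5 = boltzmann_fit(V + 5.0, a)
        assert f5.v_half == pytest.approx(f0.v_half + 5.0, abs=1e-6)
        assert f5.slope == pytest.approx(f0.slope, abs=1e-6)

    def test_noisy_recovery_within_1mV(self):
        rng = np.random.default_rng(7)
        V = np.linspace(-120, -60, 12)
        a = hcn_steady_state(V) + rng.normal(0, 0.02, V.size)
        fit = boltzmann_fit(V, a)
        assert fit.v_half == pytest.approx(-87.0, abs=1.0)

    def test_too_few_points_refused(self):
        with pytest.raises(ValueError):
            boltzmann_fit([-100, -90, -80], [0.9, 0.5, 0.1])


class TestBiexponentialFit:
    def _biexp(self, t, tf, ts, af=-200.0, as_=-300.0, c=-50.0):
        return af * np.exp(-t / tf) + as_ * np.exp(-t / ts) + c

    def test_recovers_both_time_constants(self):
        t = np.arange(0, 8000.0, 2.0)
        y = self._biexp(t, 279.0, 1877.0)
        fit = biexponential_fit(t, y)
        assert fit.tau_fast == pytest.approx(279.0, rel=0.01)
        assert fit.tau_slow == pytest.approx(1877.0, rel=0.01)
        assert not fit.degenerate

    def test_single_exponential_flags_degeneracy(self):
        t = np.arange(0, 3000.0, 2.0)
        y = -500.0 * np.exp(-t / 400.0) - 50.0
        fit = biexponential_fit(t, y)
        assert fit.degenerate

    def test_amplitude_scale_invariance_of_taus(self):
        t = np.arange(0, 8000.0, 2.0)
        f1 = biexponential_fit(t, self._biexp(t, 279.0, 1877.0))
        f2 = biexponential_fit(t, 2.0 * self._biexp(t, 279.0, 1877.0))
        assert f2.tau_fast == pytest.approx(f1.tau_fast, rel=1e-3)
        assert f2.tau_slow == pytest.approx(f1.tau_slow, rel=1e-3)

    def test_short_segments_refused(self):
        with pytest.raises(ValueError):
            biexponential_fit(np.arange(10.0), np.exp(-np.arange(10.0)))


class TestLJP:
    def test_correction_direction_and_magnitude(self):
        tr = voltage_trace(np.full(10, -55.0))
        out = ljp_correct(tr)
        assert np.all(out.signal == -65.0)

    def test_zero_offset_is_identity(self):
        tr = voltage_trace(np.full(10, -55.0))
        assert np.all(ljp_correct(tr, 0.0).signal == tr.signal)

    def test_double_correction_rejected(self):
        tr = ljp_correct(voltage_trace(np.zeros(5)))
        with pytest.raises(TraceError, match="already"):
            ljp_correct(tr)

    def test_current_trace_rejected(self):
        tr = Trace(time=np.arange(5.0), signal=np.zeros(5),
                   kind="current", units="pA")
        with pytest.raises(TraceError):
            ljp_correct(tr)


class TestMeasurementResult:
    def test_units_required(self):
        with pytest.raises(ValueError):
            MeasurementResult(name="rin", value=100.0, units="")
        m = MeasurementResult(name="rin", value=100.0, units="MOhm")
        assert m.units == "MOhm"
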