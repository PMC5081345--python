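"""Measurements on voltage/current traces: the analysis layer.

Implements the standard whole-cell measurements used to characterize
fusiform neurons: firing-phenotype classification (active iff the
spontaneous rate exceeds 0.5 Hz, strictly), input resistance in current
clamp (slope of the V-I curve) and voltage clamp (inverse slope of the
I-V curve), depolarization sag, pharmacological isolation by trace
subtraction, slope conductance over a voltage window, tail-current
activation curves with Boltzmann fits, bi-exponential kinetics fits, and
liquid-junction-potential correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .trace import Trace, TraceError

__all__ = [
    "MeasurementResult",
    "BoltzmannFit",
    "BiexponentialFit",
    "FitError",
    "classify_firing",
    "input_resistance_cc",
    "input_resistance_vc",
    "sag_amplitude",
    "isolate_by_subtraction",
    "slope_conductance",
    "tail_activation_curve",
    "boltzmann_fit",
    "biexponential_fit",
    "ljp_correct",
    "steady_state_value",
    "ih_conductance_from_subtraction",
    "ih_from_onset_difference",
]


class FitError(RuntimeError):
    """Non-convergence or degenerate fit input, with diagnostics."""


@dataclass
class MeasurementResult:
    name: str
    value: float
    units: str
    extras: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.units:
            raise ValueError("units must always be declared")


@dataclass
class BoltzmannFit:
    """a(V) = amplitude / (1 + exp((V - v_half)/slope)) [+ offset].

    ``slope`` is reported positive; the curve rises with
    hyperpolarization (HCN convention).
    """

    v_half: float
    slope: float
    amplitude: float
    offset: float
    residual_norm: float


@dataclass
class BiexponentialFit:
    tau_fast: float
    tau_slow: float
    amp_fast: float
    amp_slow: float
    offset: float
    residual_norm: float
    degenerate: bool  # tau_slow / tau_fast < 1.5


# ---------------------------------------------------------------------------

def classify_firing(spike_times, duration_s: float) -> str:
    """'active' iff rate > 0.5 Hz (strict); exactly 0.5 Hz is quiet."""
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    rate = len(spike_times) / duration_s
    return "active" if rate > 0.5 else "quiet"


def input_resistance_cc(currents_pA, voltages_mV) -> float:
    """Input resistance (MOhm) as the slope of V against I."""
    I = np.asarray(currents_pA, dtype=float)
    V = np.asarray(voltages_mV, dtype=float)
    if I.size < 2 or I.size != V.size:
        raise ValueError("need >= 2 matching (I, V) points")
    if np.ptp(I) == 0:
        raise ValueError("singular design: all currents identical")
    slope = np.polyfit(I, V, 1)[0]  # mV/pA = GOhm
    return slope * 1000.0


def input_resistance_vc(voltages_mV, currents_pA) -> float:
    """Input resistance (MOhm) as 1/slope of I against V.

    A perfectly flat I-V (zero slope) is declared non-measurable and
    returns +inf rather than raising.
    """
    V = np.asarray(voltages_mV, dtype=float)
    I = np.asarray(currents_pA, dtype=float)
    if V.size < 2 or V.size != I.size:
        raise ValueError("need >= 2 matching (V, I) points")
    if np.ptp(V) == 0:
        raise ValueError("singular design: all voltages identical")
    slope = np.polyfit(V, I, 1)[0]  # pA/mV = nS
    if slope == 0:
        return math.inf
    return 1000.0 / slope  # 1/nS = GOhm -> MOhm


def steady_state_value(trace: Trace, t0: float, t1: float,
                       fraction: float = 0.05) -> float:
    """Mean of the last ``fraction`` of the window [t0, t1]."""
    win = trace.window(t0, t1)
    n = max(1, int(round(fraction * len(win.signal))))
    return float(win.signal[-n:].mean())


def sag_amplitude(trace: Trace, window: tuple[float, float]) -> float:
    """V_steady - V_peak over a hyperpolarizing step window (>= 0 if sag)."""
    win = trace.window(*window)
    peak = float(win.signal.min())
    n = max(1, int(round(0.05 * len(win.signal))))
    steady = float(win.signal[-n:].mean())
    return steady - peak


def isolate_by_subtraction(before: Trace, after: Trace) -> Trace:
    """Pointwise before - after; emulates pharmacological isolation."""
    if before.time.shape != after.time.shape or \
            not np.allclose(before.time, after.time, rtol=0, atol=1e-9):
        raise TraceError("traces have mismatching time grids")
    if before.kind != after.kind:
        raise TraceError("traces have mismatching kinds")
    return before.copy(signal=before.signal - after.signal,
                       channel=f"{before.channel}-diff",
                       meta={**before.meta, "subtraction": True})


def slope_conductance(voltages_mV, currents_pA,
                      vrange: tuple[float, float] | None = None) -> float:
    """Least-squares slope of I on V over a window, in nS."""
    V = np.asarray(voltages_mV, dtype=float)
    I = np.asarray(currents_pA, dtype=float)
    if vrange is not None:
        lo, hi = min(vrange), max(vrange)
        mask = (V >= lo - 1e-9) & (V <= hi + 1e-9)
        V, I = V[mask], I[mask]
    if V.size < 2:
        raise ValueError("fewer than 2 I-V points in the requested window")
    return float(np.polyfit(V, I, 1)[0])  # pA/mV = nS


def _pair_smooth(x: np.ndarray) -> np.ndarray:
    """Two-sample smoothing (mean of adjacent samples)."""
    if len(x) < 2:
        return x
    return 0.5 * (x[1:] + x[:-1])


def tail_activation_curve(traces: list[Trace], peak_window_ms: float = 50.0):
    """Normalized tail-current activation curve from voltage-clamp steps.

    Each trace must carry ``step_mV``, ``pre_ms``, ``step_ms`` and
    ``tail_ms`` metadata (as written by the voltage-clamp step runner)
    and should be the isolated current of interest (e.g. the subtraction
    of runs with and without the conductance).  The tail amplitude is
    the peak absolute current within ``peak_window_ms`` after
    repolarization, after two-sample smoothing; the curve is normalized
    to its maximum.

    Returns (step_V, activation) sorted by step potential.
    """
    Vs, amps = [], []
    for tr in traces:
        meta = tr.meta
        for key in ("step_mV", "pre_ms", "step_ms", "tail_ms"):
            if key not in meta:
                raise TraceError(f"trace missing {key!r} metadata")
        if meta["tail_ms"] <= 0:
            raise TraceError("trace has no repolarization segment")
        t_repol = meta["pre_ms"] + meta["step_ms"]
        win = tr.window(t_repol, min(t_repol + peak_window_ms,
                                     tr.time[-1]))
        smoothed = _pair_smooth(win.signal)
        amps.append(float(np.max(np.abs(smoothed))))
        Vs.append(float(meta["step_mV"]))
    Vs = np.asarray(Vs)
    amps = np.asarray(amps)
    order = np.argsort(Vs)
    Vs, amps = Vs[order], amps[order]
    peak = amps.max()
    if peak == 0:
        raise ValueError("all tail currents are zero; nothing to normalize")
    return Vs, amps / peak


def boltzmann_fit(voltages_mV, activation, fit_offset: bool = False,
                  slope_init: float = 8.0) -> BoltzmannFit:
    """Nonlinear least-squares Boltzmann fit of an activation curve.

    Initialization: v_half from the half-maximum crossing, bounded
    parameters.  Raises :class:`FitError` with diagnostics on
    non-convergence; never fails silently.
    """
    V = np.asarray(voltages_mV, dtype=float)
    a = np.asarray(activation, dtype=float)
    if V.size < 4:
        raise ValueError("need >= 4 points for a Boltzmann fit")
    if V.size != a.size:
        raise ValueError("mismatching array lengths")
    order = np.argsort(V)
    V, a = V[order], a[order]
    half = 0.5 * (a.max() + a.min())
    v0 = float(np.interp(half, a[::-1], V[::-1]))  # a decreasing in V
    if not (V.min() <= v0 <= V.max()):
        v0 = float(V[np.argmin(np.abs(a - half))])

    span = a.max() - a.min()

    if fit_offset:
        model = lambda V, vh, k, amp, c: amp / (1.0 + np.exp((V - vh) / k)) + c
        p0 = [v0, slope_init, span, a.min()]
        bounds = ([V.min() - 100, 0.5, 1e-6, -10 * abs(a).max() - 1],
                  [V.max() + 100, 60.0, 10 * span + 1, 10 * abs(a).max() + 1])
    else:
        model = lambda V, vh, k, amp: amp / (1.0 + np.exp((V - vh) / k))
        p0 = [v0, slope_init, a.max()]
        bounds = ([V.min() - 100, 0.5, 1e-6], [V.max() + 100, 60.0, 10 * span + 1])

    try:
        popt, _ = optimize.curve_fit(model, V, a, p0=p0, bounds=bounds,
                                     maxfev=20000)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"Boltzmann fit failed: {exc}; p0={p0}, "
                       f"V range [{V.min()}, {V.max()}]") from exc
    resid = a - model(V, *popt)
    offset = popt[3] if fit_offset else 0.0
    return BoltzmannFit(v_half=float(popt[0]), slope=float(popt[1]),
                        amplitude=float(popt[2]), offset=float(offset),
                        residual_norm=float(np.linalg.norm(resid)))


def biexponential_fit(time_ms, signal, min_samples: int = 50) -> BiexponentialFit:
    """Fit A_f exp(-t/tau_f) + A_s exp(-t/tau_s) + C to a trace segment.

    The segment should be monotone-trending (a relaxation).  tau_fast <
    tau_slow is enforced by ordering; a time-constant ratio below 1.5 is
    flagged degenerate rather than raising.  Initialization splits the
    segment and log-fits the tail for the slow component.
    """
    t = np.asarray(time_ms, dtype=float)
    y = np.asarray(signal, dtype=float)
    if t.size < min_samples:
        raise ValueError(f"need >= {min_samples} samples, got {t.size}")
    if t.size != y.size:
        raise ValueError("mismatching array lengths")
    t = t - t[0]

    # crude trend check: start and end should differ beyond local noise
    smooth_n = max(1, t.size // 20)
    y_start = y[:smooth_n].mean()
    y_end = y[-smooth_n:].mean()
    if y_start == y_end:
        raise ValueError("segment has no net relaxation to fit")

    c0 = y_end
    amp = y_start - y_end
    # log-linear estimate of the slow tau from the second half
    half = t.size // 2
    resid_tail = y[half:] - c0
    sign = np.sign(amp) or 1.0
    pos = sign * resid_tail
    mask = pos > max(1e-12, 1e-4 * abs(amp))
    if mask.sum() >= 2:
        coef = np.polyfit(t[half:][mask], np.log(pos[mask]), 1)
        tau_s0 = -1.0 / coef[0] if coef[0] < 0 else (t[-1] / 2)
    else:
        tau_s0 = t[-1] / 2
    tau_s0 = min(max(tau_s0, t[1] - t[0]), 50 * t[-1])
    tau_f0 = tau_s0 / 6.0

    def model(t, af, tf, as_, ts, c):
        return af * np.exp(-t / tf) + as_ * np.exp(-t / ts) + c

    p0 = [amp / 2, tau_f0, amp / 2, tau_s0, c0]
    span = abs(amp) + abs(c0) + 1e-9
    bounds = ([-10 * span, 1e-6, -10 * span, 1e-6, -10 * span],
              [10 * span, 1e4 * t[-1], 10 * span, 1e4 * t[-1], 10 * span])
    try:
        popt, _ = optimize.curve_fit(model, t, y, p0=p0, bounds=bounds,
                                     maxfev=40000)
    except RuntimeError as exc:
        raise FitError(f"bi-exponential fit failed: {exc}; p0={p0}") from exc
    af, tf, as_, ts, c = popt
    if tf > ts:
        af, as_, tf, ts = as_, af, ts, tf
    resid = y - model(t, af, tf, as_, ts, c)
    return BiexponentialFit(
        tau_fast=float(tf), tau_slow=float(ts), amp_fast=float(af),
        amp_slow=float(as_), offset=float(c),
        residual_norm=float(np.linalg.norm(resid)),
        degenerate=bool(ts / tf < 1.5))


def ljp_correct(trace: Trace, offset_mV: float = 10.0) -> Trace:
    """Subtract the liquid-junction potential from a voltage trace.

    Convention: true V = measured V - offset (K-gluconate internal).
    The correction is recorded in the metadata; correcting twice raises.
    """
    if trace.kind != "voltage":
        raise TraceError("LJP correction applies to voltage traces only")
    if trace.meta.get("ljp_corrected"):
        raise TraceError("trace is already LJP-corrected")
    out = trace.copy(signal=trace.signal - offset_mV)
    out.meta["ljp_corrected"] = True
    out.meta["ljp_offset_mV"] = offset_mV
    return out


# ---------------------------------------------------------------------------
# Conductance estimators on isolated (subtracted) currents
# ---------------------------------------------------------------------------

def ih_conductance_from_subtraction(step_V_mV, delta_I_ss_pA, activation,
                                    E_h: float = -43.0) -> float:
    """Chord-conductance estimate of g_h (nS) from isolated steady currents.

    ``delta_I_ss_pA`` are the steady-state blocker-sensitive currents at
    the step potentials; ``activation`` the steady-state activation at
    those potentials (from the fitted Boltzmann or the model curve).
    Averages the per-step chord estimates g = I / (a * (V - E_h)).
    """
    V = np.asarray(step_V_mV, dtype=float)
    I = np.asarray(delta_I_ss_pA, dtype=float)
    a = np.asarray(activation, dtype=float)
    drive = a * (V - E_h)
    mask = np.abs(drive) > 1e-6
    if not np.any(mask):
        raise ValueError("no step with usable driving force")
    return float(np.mean(I[mask] / drive[mask]))


def ih_from_onset_difference(trace: Trace, t_step: float, t_end: float,
                             onset_ms: float = 20.0) -> float:
    """Alternative I_h magnitude: steady-state minus onset current (pA).

    The onset is the current just after the capacitive/fast-rectifier
    settling at the start of the step; the difference with the end-of-
    step steady state is the slowly developing (HCN) component.
    """
    win = trace.window(t_step, t_end)
    n_on = max(1, int(round(onset_ms / win.dt)))
    onset = float(win.signal[:n_on].mean())
    n_ss = max(1, int(round(0.05 * len(win.signal))))
    steady = float(win.signal[-n_ss:].mean())
    return steady - onset


def linear_regression(x, y):
    """Slope, intercept, r^2 and p-value (slope F-test) of a simple fit."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 points for regression")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance predictor")
    res = stats.linregress(x, y)
    return {"slope": res.slope, "intercept": res.intercept,
            "r2": res.rvalue ** 2, "p": res.pvalue}
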