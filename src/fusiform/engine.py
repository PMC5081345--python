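"""Fixed-step integration of the model under the standard protocols.

The integrator uses exponential Euler for the gating variables and for
the membrane potential (writing the ionic currents in conductance form
``c_m dV/dt = -G_tot (V - V_inf)``), at the model's native time step of
0.1 ms from an initial potential of -65 mV with gates initialized at
their steady state.  Exponential Euler is exact for the passive RC case
and unconditionally stable through the fast sodium transient of a spike.
A fourth-order Runge-Kutta mode is available for cross-checks on
subthreshold (non-stiff) configurations.

Protocols follow the experimental conventions: a 4 s settle phase
precedes every measurement window; resting potential is read at the end
of a 1 s sweep with both sodium conductances removed; spontaneous
activity is 1 s with no injected current; voltage-clamp is ideal (zero
series resistance) and reports the membrane current needed to hold the
command; dynamic clamp adds an artificial HCN conductance of absolute
size ``g_art`` (nS) with the native kinetics and reversal.

The low-level core is vectorized over batches of cells, which the
parameter-space scans and the synthetic-population generator rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import ChannelKinetics, DEFAULT_KINETICS
from .model import V_MIN, V_MAX
from .parameters import ModelParameters
from .trace import Trace

__all__ = [
    "Segment",
    "ProtocolSpec",
    "SimulationError",
    "integrate",
    "run_rmp_protocol",
    "run_spontaneous",
    "run_dynamic_clamp",
    "run_current_clamp_steps",
    "run_voltage_clamp_steps",
    "integrate_rk4",
    "detect_spikes",
    "SPIKE_THRESHOLD_MV",
    "SPIKE_REFRACTORY_MS",
]

SPIKE_THRESHOLD_MV = -10.0
SPIKE_REFRACTORY_MS = 1.0


class SimulationError(RuntimeError):
    """Numerical blow-up or invalid protocol."""


@dataclass(frozen=True)
class Segment:
    """One piece of a piecewise-constant command.

    ``level`` is an injected current in pA (current clamp) or a command
    potential in mV (voltage clamp).  It may be an array to run a batch
    of cells with different levels.
    """

    duration: float  # ms
    level: float | np.ndarray = 0.0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("segment duration must be > 0")


@dataclass(frozen=True)
class ProtocolSpec:
    """Mode, timing and command description of one protocol run."""

    mode: str  # 'current-clamp' | 'voltage-clamp' | 'spontaneous' | 'dynamic-clamp'
    segments: tuple = ()
    dt: float = 0.1             # ms
    settle: float = 4000.0      # ms, excluded from the recorded window
    v_init: float = -65.0       # mV
    holding: float = 0.0        # pA (cc/dynamic) or mV (vc) during settle
    g_art_nS: float = 0.0       # dynamic clamp only
    record_stride: int = 1

    def __post_init__(self):
        if self.mode not in ("current-clamp", "voltage-clamp",
                             "spontaneous", "dynamic-clamp"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.settle < 0:
            raise ValueError("settle must be >= 0")
        if self.mode == "dynamic-clamp" and self.g_art_nS < 0:
            raise ValueError("artificial conductance must be >= 0")
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def duration(self) -> float:
        return sum(s.duration for s in self.segments)

    def describe(self) -> dict:
        return {
            "mode": self.mode, "dt": self.dt, "settle": self.settle,
            "v_init": self.v_init, "holding": self.holding,
            "g_art_nS": self.g_art_nS,
            "segments": [(s.duration, np.asarray(s.level).tolist())
                         for s in self.segments],
        }


def spontaneous_protocol(duration: float = 1000.0, **kw) -> ProtocolSpec:
    return ProtocolSpec(mode="spontaneous", segments=(Segment(duration, 0.0),), **kw)


def rmp_protocol(sweep: float = 1000.0, **kw) -> ProtocolSpec:
    return ProtocolSpec(mode="current-clamp", segments=(Segment(sweep, 0.0),), **kw)


# ---------------------------------------------------------------------------
# Vectorized core
# ---------------------------------------------------------------------------

def _as_batch(params: ModelParameters | dict, n: int | None = None) -> dict:
    """Normalize parameters to a dict of float arrays of a common length."""
    if isinstance(params, ModelParameters):
        d = params.to_dict()
    else:
        d = dict(params)
    lengths = {np.size(v) for v in d.values()}
    width = max(lengths | ({n} if n else set()))
    return {k: np.broadcast_to(np.asarray(v, dtype=float), (width,)).copy()
            for k, v in d.items()}, width


def _simulate_core(pd: dict, width: int, kinetics: ChannelKinetics,
                   protocol: ProtocolSpec, on_blowup: str = "raise"):
    """Run one protocol on a batch of cells.

    Returns (time, recorded, spike_times, final_V) where ``recorded`` has
    shape (n_samples, width): membrane potential (mV) in current-clamp
    modes, total membrane current (pA, outward positive) in voltage clamp.
    Blown-up cells are NaN when on_blowup='mask'.
    """
    dt = protocol.dt
    vc = protocol.mode == "voltage-clamp"
    area = np.pi * (pd["diameter"] * 1e-4) * (pd["length"] * 1e-4)  # cm^2
    cm = pd["c_m"]
    tau_kir = float(pd["tau_Kir"][0])
    g_art = (protocol.g_art_nS * 1e-6 / area
             if protocol.mode == "dynamic-clamp" else np.zeros(width))

    gNa, gKd, gh, gNaP, gKir, gleak = (
        pd["g_Na"], pd["g_Kd"], pd["g_h"], pd["g_NaP"], pd["g_Kir"], pd["g_leak"])
    ENa, EK, Eh, El = pd["E_Na"], pd["E_K"], pd["E_h"], pd["E_leak"]

    # command per step: (settle, then segments)
    steps = [(int(round(protocol.settle / dt)), np.broadcast_to(
        np.asarray(protocol.holding, dtype=float), (width,)))]
    for seg in protocol.segments:
        steps.append((int(round(seg.duration / dt)),
                      np.broadcast_to(np.asarray(seg.level, dtype=float), (width,))))
    n_settle = steps[0][0]
    n_total = sum(ns for ns, _ in steps)
    n_meas = n_total - n_settle

    stride = protocol.record_stride
    n_rec = (n_meas + stride - 1) // stride
    recorded = np.empty((n_rec, width))
    time = (np.arange(n_rec) * stride) * dt

    V = np.full(width, float(protocol.v_init))
    if vc:
        V = np.broadcast_to(np.asarray(protocol.holding, dtype=float),
                            (width,)).astype(float).copy()
    gates = kinetics.steady_states(V)
    m, h, nn, p, w, a1, a2 = (gates[i].copy() for i in range(7))

    alive = np.ones(width, dtype=bool)
    spike_times: list[list[float]] = [[] for _ in range(width)]
    last_spike = np.full(width, -np.inf)

    step_idx = 0
    rec_idx = 0
    for ns, level in steps:
        in_meas = step_idx >= n_settle
        i_inj = np.zeros(width)
        if not vc:
            i_inj = level * 1e-6 / area  # pA -> uA/cm^2
        for _ in range(ns):
            # gate relaxation (exponential Euler)
            minf = kinetics.m_inf(V); hinf = kinetics.h_inf(V)
            ninf = kinetics.n_inf(V); pinf = kinetics.p_inf(V)
            winf = kinetics.w_inf(V); ainf = kinetics.a_inf(V)
            m = minf + (m - minf) * np.exp(-dt / kinetics.tau_m(V))
            h = hinf + (h - hinf) * np.exp(-dt / kinetics.tau_h(V))
            nn = ninf + (nn - ninf) * np.exp(-dt / kinetics.tau_n(V))
            p = pinf + (p - pinf) * np.exp(-dt / kinetics.nap_tau)
            w = winf + (w - winf) * np.exp(-dt / tau_kir)
            t1 = 100.0 + np.exp((V + 183.6) / 30.48)
            t2 = 700.0 + np.exp((V + 188.6) / 11.0) / (1.0 + np.exp((V + 105.0) / 5.5))
            a1 = ainf + (a1 - ainf) * np.exp(-dt / t1)
            a2 = ainf + (a2 - ainf) * np.exp(-dt / t2)

            G_na = gNa * m ** 3 * h + gNaP * p
            G_k = gKd * nn ** 4 + gKir * w
            G_h = (gh + g_art) * (0.5 * a1 + 0.5 * a2)
            G_tot = G_na + G_k + G_h + gleak

            if vc:
                V = level.astype(float)
                i_ion = (G_na * (V - ENa) + G_k * (V - EK)
                         + G_h * (V - Eh) + gleak * (V - El))
                out_val = i_ion * area * 1e6  # uA/cm^2 -> pA
            else:
                B = G_na * ENa + G_k * EK + G_h * Eh + gleak * El
                prev = V
                with np.errstate(divide="ignore", invalid="ignore"):
                    V_inf = (B + i_inj) / G_tot
                    V_new = V_inf + (V - V_inf) * np.exp(-dt * G_tot / cm)
                passive = G_tot <= 1e-14
                if np.any(passive):
                    V_new = np.where(passive, V + dt * i_inj / cm, V_new)
                V = np.where(alive, V_new, V)
                out_val = V
                blown = alive & ((V < V_MIN) | (V > V_MAX) | ~np.isfinite(V))
                if np.any(blown):
                    if on_blowup == "raise":
                        idx = int(np.argmax(blown))
                        raise SimulationError(
                            f"membrane potential out of [{V_MIN}, {V_MAX}] mV "
                            f"at step {step_idx} (cell {idx}, V={V[idx]:.1f})"
                        )
                    alive &= ~blown
                    V = np.where(alive, V, np.nan)
                if in_meas:
                    t_now = (step_idx - n_settle) * dt
                    crossed = (alive & (prev < SPIKE_THRESHOLD_MV)
                               & (V >= SPIKE_THRESHOLD_MV)
                               & (t_now - last_spike >= SPIKE_REFRACTORY_MS))
                    if np.any(crossed):
                        for ci in np.nonzero(crossed)[0]:
                            spike_times[ci].append(t_now)
                        last_spike = np.where(crossed, t_now, last_spike)

            if in_meas and (step_idx - n_settle) % stride == 0:
                recorded[rec_idx] = np.where(alive, out_val, np.nan)
                rec_idx += 1
            step_idx += 1

    return time, recorded[:rec_idx], spike_times, V


def _run(params, protocol, kinetics=DEFAULT_KINETICS, on_blowup="raise"):
    n_levels = max([np.size(s.level) for s in protocol.segments]
                   + [np.size(protocol.holding)])
    pd, width = _as_batch(params, n=n_levels)
    return _simulate_core(pd, width, kinetics, protocol, on_blowup)


# ---------------------------------------------------------------------------
# Public protocol runners (single cell)
# ---------------------------------------------------------------------------

def integrate(params: ModelParameters, protocol: ProtocolSpec,
              kinetics: ChannelKinetics = DEFAULT_KINETICS) -> Trace:
    """Run one protocol on one cell and return the recorded trace."""
    time, rec, spikes, _ = _run(params, protocol, kinetics)
    vc = protocol.mode == "voltage-clamp"
    tr = Trace(time=time, signal=rec[:, 0],
               kind="current" if vc else "voltage",
               units="pA" if vc else "mV",
               channel="I_m" if vc else "V_m",
               meta={"protocol": protocol.describe(),
                     "spike_times_ms": list(spikes[0])})
    return tr


def run_rmp_protocol(params: ModelParameters, sweep: float = 1000.0,
                     kinetics: ChannelKinetics = DEFAULT_KINETICS,
                     return_trace: bool = False, **kw):
    """Resting membrane potential with both sodium conductances removed.

    Integrates with no injected current and returns the potential at the
    end of a 1 s sweep following the settle phase.
    """
    p = params.sodium_zeroed()
    protocol = rmp_protocol(sweep=sweep, **kw)
    tr = integrate(p, protocol, kinetics)
    rmp = float(tr.signal[-1])
    return (rmp, tr) if return_trace else rmp


def run_spontaneous(params: ModelParameters, duration: float = 1000.0,
                    kinetics: ChannelKinetics = DEFAULT_KINETICS, **kw):
    """1 s of activity with no injected current: (trace, spike times)."""
    protocol = spontaneous_protocol(duration=duration, **kw)
    tr = integrate(params, protocol, kinetics)
    return tr, list(tr.meta["spike_times_ms"])


def run_dynamic_clamp(params: ModelParameters, g_art_nS: float,
                      segments, kinetics: ChannelKinetics = DEFAULT_KINETICS,
                      **kw) -> Trace:
    """Current clamp with an added artificial HCN conductance (nS)."""
    if g_art_nS < 0:
        raise ValueError("artificial conductance must be >= 0")
    protocol = ProtocolSpec(mode="dynamic-clamp", segments=tuple(segments),
                            g_art_nS=g_art_nS, **kw)
    return integrate(params, protocol, kinetics)


def run_current_clamp_steps(params: ModelParameters, amplitudes_pA,
                            step: float = 1500.0, post: float = 0.0,
                            kinetics: ChannelKinetics = DEFAULT_KINETICS,
                            **kw) -> list[Trace]:
    """Family of current steps from rest (one trace per amplitude)."""
    amplitudes = np.asarray(amplitudes_pA, dtype=float)
    segs = [Segment(step, amplitudes)]
    if post > 0:
        segs.append(Segment(post, 0.0))
    protocol = ProtocolSpec(mode="current-clamp", segments=tuple(segs), **kw)
    time, rec, spikes, _ = _run(params, protocol, kinetics)
    return [Trace(time=time, signal=rec[:, i], kind="voltage", units="mV",
                  channel="V_m",
                  meta={"protocol": protocol.describe(),
                        "amplitude_pA": float(amplitudes[i]),
                        "spike_times_ms": list(spikes[i])})
            for i in range(len(amplitudes))]


def run_voltage_clamp_steps(params: ModelParameters, step_mV,
                            holding: float = -65.0, step: float = 8500.0,
                            tail: float = 1500.0, pre: float = 200.0,
                            kinetics: ChannelKinetics = DEFAULT_KINETICS,
                            **kw) -> list[Trace]:
    """Voltage-clamp step family with a repolarizing tail at the holding level.

    Each trace records the membrane current (pA) over pre-step baseline,
    the conditioning step and the tail after repolarization; the step
    command is stored in the metadata.
    """
    steps = np.asarray(step_mV, dtype=float)
    segs = [Segment(pre, holding), Segment(step, steps)]
    if tail > 0:
        segs.append(Segment(tail, holding))
    protocol = ProtocolSpec(mode="voltage-clamp", segments=tuple(segs),
                            holding=holding, **kw)
    time, rec, _, _ = _run(params, protocol, kinetics)
    out = []
    for i in range(len(steps)):
        out.append(Trace(
            time=time, signal=rec[:, i], kind="current", units="pA",
            channel="I_m",
            meta={"protocol": protocol.describe(), "holding_mV": holding,
                  "step_mV": float(steps[i]), "pre_ms": pre,
                  "step_ms": step, "tail_ms": tail}))
    return out


def integrate_rk4(params: ModelParameters, duration: float, dt: float = 0.1,
                  v_init: float = -65.0, i_inj_pA: float = 0.0,
                  kinetics: ChannelKinetics = DEFAULT_KINETICS) -> float:
    """Classical Runge-Kutta integration of one cell; returns the final V.

    Higher-order cross-check for subthreshold (non-stiff) configurations;
    not suitable for spiking models at the native time step, where the
    sodium transient makes the system stiff.
    """
    area = params.area_cm2
    i_inj = i_inj_pA * 1e-6 / area
    tau_kir = params.tau_Kir

    gNa, gKd, gh = params.g_Na, params.g_Kd, params.g_h
    gNaP, gKir, gleak = params.g_NaP, params.g_Kir, params.g_leak
    ENa, EK, Eh, El = params.E_Na, params.E_K, params.E_h, params.E_leak

    def rhs(y):
        V = y[0]
        m, h, nn, p, w, a1, a2 = y[1:]
        i_ion = (gNa * m ** 3 * h * (V - ENa) + gKd * nn ** 4 * (V - EK)
                 + gh * (0.5 * a1 + 0.5 * a2) * (V - Eh)
                 + gNaP * p * (V - ENa) + gKir * w * (V - EK)
                 + gleak * (V - El))
        inf = kinetics.steady_states(V)
        tau = kinetics.time_constants(V, tau_kir)
        out = np.empty(8)
        out[0] = (i_inj - i_ion) / params.c_m
        out[1:] = (inf - y[1:]) / tau
        return out

    y = np.empty(8)
    y[0] = v_init
    y[1:] = kinetics.steady_states(v_init)
    for _ in range(int(round(duration / dt))):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * dt * k1)
        k3 = rhs(y + 0.5 * dt * k2)
        k4 = rhs(y + dt * k3)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not (V_MIN <= y[0] <= V_MAX):
            raise SimulationError(f"RK4 blow-up at V={y[0]:.1f}")
    return float(y[0])


def detect_spikes(trace: Trace, threshold: float = SPIKE_THRESHOLD_MV,
                  refractory: float = SPIKE_REFRACTORY_MS) -> np.ndarray:
    """Upward threshold crossings with a refractory period, from a trace."""
    if trace.kind != "voltage":
        raise ValueError("spike detection requires a voltage trace")
    v = trace.signal
    crossings = np.nonzero((v[:-1] < threshold) & (v[1:] >= threshold))[0] + 1
    times = trace.time[crossings]
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= refractory:
            kept.append(float(t))
    return np.asarray(kept)


# ---------------------------------------------------------------------------
# Batched measurement helpers (used by the parameter-space scans)
# ---------------------------------------------------------------------------

def rmp_batch(param_arrays: dict, sweep: float = 1000.0,
              kinetics: ChannelKinetics = DEFAULT_KINETICS,
              on_blowup: str = "mask", **kw) -> np.ndarray:
    """Sodium-zeroed end-of-sweep potential for a batch of cells (mV)."""
    pd, width = _as_batch(param_arrays)
    pd["g_Na"][:] = 0.0
    pd["g_NaP"][:] = 0.0
    protocol = rmp_protocol(sweep=sweep, **kw)
    _, rec, _, _ = _simulate_core(pd, width, kinetics, protocol, on_blowup)
    return rec[-1]


def spontaneous_rate_batch(param_arrays: dict, duration: float = 1000.0,
                           kinetics: ChannelKinetics = DEFAULT_KINETICS,
                           on_blowup: str = "mask", **kw) -> np.ndarray:
    """Spontaneous firing rate (Hz) over the measurement window."""
    pd, width = _as_batch(param_arrays)
    protocol = spontaneous_protocol(duration=duration, record_stride=10, **kw)
    _, rec, spikes, _ = _simulate_core(pd, width, kinetics, protocol, on_blowup)
    rates = np.array([len(s) for s in spikes], dtype=float) / (duration / 1000.0)
    rates[np.isnan(rec[-1])] = np.nan
    return rates


def rin_batch(param_arrays: dict, step_pA: float = -20.0,
              kinetics: ChannelKinetics = DEFAULT_KINETICS,
              on_blowup: str = "mask", **kw) -> np.ndarray:
    """Steady-state input resistance (MOhm), sodium-zeroed current clamp.

    Rest and a single hyperpolarizing step are simulated for every cell;
    R_in = dV/dI from the steady-state deflection.
    """
    pd, width = _as_batch(param_arrays)
    pd["g_Na"][:] = 0.0
    pd["g_NaP"][:] = 0.0
    protocol = ProtocolSpec(
        mode="current-clamp",
        segments=(Segment(3000.0, 0.0), Segment(3000.0, step_pA)),
        record_stride=10, **kw)
    _, rec, _, _ = _simulate_core(pd, width, kinetics, protocol, on_blowup)
    n = rec.shape[0] // 2
    v_rest = rec[n - 1]
    v_step = rec[-1]
    return (v_step - v_rest) / step_pA * 1000.0  # mV/pA -> MOhm


def sag_batch(param_arrays: dict, step_pA: float = -100.0,
              step_ms: float = 3000.0,
              kinetics: ChannelKinetics = DEFAULT_KINETICS,
              on_blowup: str = "mask", **kw) -> np.ndarray:
    """Depolarizing sag (mV) during a hyperpolarizing step: V_ss - V_peak."""
    pd, width = _as_batch(param_arrays)
    pd["g_Na"][:] = 0.0
    pd["g_NaP"][:] = 0.0
    protocol = ProtocolSpec(
        mode="current-clamp",
        segments=(Segment(500.0, 0.0), Segment(step_ms, step_pA)),
        record_stride=5, **kw)
    _, rec, _, _ = _simulate_core(pd, width, kinetics, protocol, on_blowup)
    n0 = int(round(500.0 / (protocol.dt * protocol.record_stride)))
    seg = rec[n0:]
    peak = np.nanmin(seg, axis=0) if seg.size else np.nan
    tail_n = max(1, int(0.05 * seg.shape[0]))
    steady = np.nanmean(seg[-tail_n:], axis=0)
    return steady - peak
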