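"""Ionic current densities and the membrane ODE right-hand side.

Sign conventions: membrane (ionic) current is positive outward; injected
current is positive depolarizing.  The membrane equation is

    c_m dV/dt = I_inj - sum(I_ion)

with every ionic current of the ohmic Hodgkin-Huxley form
g * (gate product) * (V - E).  I_h distributes its conductance equally
over its two activation variables:

    I_h = g_h * (0.5 * A_h1 + 0.5 * A_h2) * (V - E_h)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .kinetics import ChannelKinetics, DEFAULT_KINETICS, GATE_NAMES
from .parameters import ModelParameters

__all__ = [
    "GatingState",
    "ih_current",
    "leak_current",
    "kir_current",
    "na_current",
    "kd_current",
    "nap_current",
    "membrane_rhs",
    "steady_state_current",
    "find_resting_potential",
]

#: Hard limits beyond which an integration is treated as numerically blown up.
V_MIN, V_MAX = -200.0, 100.0


def _check_gate(*gates) -> None:
    for g in gates:
        arr = np.asarray(g)
        if np.any(arr < 0.0) or np.any(arr > 1.0) or not np.all(np.isfinite(arr)):
            raise ValueError(f"gating variable outside [0, 1]: {g!r}")


@dataclass
class GatingState:
    """Instantaneous values of the seven gating variables."""

    m: float
    h: float
    n: float
    p: float
    w: float
    a_h1: float
    a_h2: float

    def __post_init__(self):
        _check_gate(*self.as_array())

    def as_array(self) -> np.ndarray:
        return np.array([self.m, self.h, self.n, self.p, self.w,
                         self.a_h1, self.a_h2], dtype=float)

    @classmethod
    def from_array(cls, values) -> "GatingState":
        return cls(**dict(zip(GATE_NAMES, np.asarray(values, dtype=float))))

    @classmethod
    def at_steady_state(cls, V: float,
                        kinetics: ChannelKinetics = DEFAULT_KINETICS) -> "GatingState":
        return cls.from_array(kinetics.steady_states(float(V)))


# ---------------------------------------------------------------------------
# Current densities (uA/cm^2)
# ---------------------------------------------------------------------------

def ih_current(V, a_h1, a_h2, g_h, E_h: float = -43.0):
    """HCN current density; zero at V = E_h, inward below it."""
    _check_gate(a_h1, a_h2)
    return g_h * (0.5 * np.asarray(a_h1) + 0.5 * np.asarray(a_h2)) * (np.asarray(V) - E_h)


def leak_current(V, g_leak, E_leak: float = -51.32):
    """Ohmic background leak; reversal near -51 mV (Na-permeable)."""
    if np.any(np.asarray(g_leak) < 0):
        raise ValueError("g_leak must be >= 0")
    return np.asarray(g_leak) * (np.asarray(V) - E_leak)


def kir_current(V, w, g_Kir, E_K: float = -81.5):
    """Inward-rectifier K+ current; activation w relaxes with fixed tau."""
    _check_gate(w)
    return g_Kir * np.asarray(w) * (np.asarray(V) - E_K)


def na_current(V, m, h, g_Na, E_Na: float = 50.0):
    _check_gate(m, h)
    return g_Na * np.asarray(m) ** 3 * np.asarray(h) * (np.asarray(V) - E_Na)


def kd_current(V, n, g_Kd, E_K: float = -81.5):
    _check_gate(n)
    return g_Kd * np.asarray(n) ** 4 * (np.asarray(V) - E_K)


def nap_current(V, p, g_NaP, E_Na: float = 50.0):
    _check_gate(p)
    return g_NaP * np.asarray(p) * (np.asarray(V) - E_Na)


def total_ionic_current(V, gates, params: ModelParameters):
    """Sum of all six ionic current densities for a gate array (7, ...)."""
    m, h, n, p, w, a1, a2 = gates
    return (na_current(V, m, h, params.g_Na, params.E_Na)
            + kd_current(V, n, params.g_Kd, params.E_K)
            + ih_current(V, a1, a2, params.g_h, params.E_h)
            + nap_current(V, p, params.g_NaP, params.E_Na)
            + kir_current(V, w, params.g_Kir, params.E_K)
            + leak_current(V, params.g_leak, params.E_leak))


def membrane_rhs(V: float, state: GatingState, params: ModelParameters,
                 i_inj: float = 0.0,
                 kinetics: ChannelKinetics = DEFAULT_KINETICS):
    """Time derivatives (dV/dt in mV/ms, gate derivatives in 1/ms).

    Raises if any state component is NaN (diagnostic for blow-ups).
    """
    gates = state.as_array()
    if not np.isfinite(V) or not np.all(np.isfinite(gates)):
        raise FloatingPointError(
            f"non-finite state: V={V}, gates={dict(zip(GATE_NAMES, gates))}"
        )
    i_ion = total_ionic_current(V, gates, params)
    dVdt = (i_inj - i_ion) / params.c_m
    inf = kinetics.steady_states(V)
    tau = kinetics.time_constants(V, params.tau_Kir)
    dgates = (inf - gates) / tau
    return float(dVdt), dgates


# ---------------------------------------------------------------------------
# Steady-state analysis
# ---------------------------------------------------------------------------

def steady_state_current(V, params: ModelParameters,
                         kinetics: ChannelKinetics = DEFAULT_KINETICS):
    """Total ionic current with every gate at its steady state for V."""
    V = np.asarray(V, dtype=float)
    gates = kinetics.steady_states(V)
    out = total_ionic_current(V, gates, params)
    return out if np.ndim(out) else float(out)


def find_resting_potential(params: ModelParameters,
                           kinetics: ChannelKinetics = DEFAULT_KINETICS,
                           bracket: tuple[float, float] = (-120.0, 0.0),
                           xtol: float = 1e-8) -> float:
    """Root of the steady-state current balance, by bisection.

    Serves as the independent oracle for the simulated resting potential
    of subthreshold (sodium-zeroed or otherwise non-spiking) models.  If
    the bracket does not straddle a zero crossing it is subdivided to
    locate one; multiple roots raise, since the resting state would then
    depend on initial conditions.
    """
    f = lambda V: steady_state_current(V, params, kinetics)
    grid = np.linspace(bracket[0], bracket[1], 481)
    vals = f(grid)
    sign_changes = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_changes) == 0:
        raise ValueError("no steady-state current zero crossing in bracket")
    if len(sign_changes) > 1:
        raise ValueError(
            f"{len(sign_changes)} zero crossings in bracket; resting state ambiguous"
        )
    i = sign_changes[0]
    return brentq(f, grid[i], grid[i + 1], xtol=xtol)
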