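"""Gating-variable kinetics for all six currents.

Seven first-order gates drive the model: Na activation ``m`` (cubed) and
inactivation ``h``, Kd activation ``n`` (fourth power), NaP activation
``p``, Kir activation ``w``, and the two HCN activation variables ``a_h1``
and ``a_h2``.  The two HCN gates share a single steady-state curve

    a_inf(V) = 1 / (1 + exp((V + 87) / 8.9))

but relax with different voltage-dependent time constants, producing the
bi-exponential activation/deactivation this current shows experimentally
(fast component a few hundred ms, slow component 1-2 s at strongly
hyperpolarized potentials).

The HCN kinetics are fixed properties of the current.  The remaining
channels (Na, Kd, NaP, Kir) follow standard Boltzmann steady states with
bell-shaped or fixed time constants; their parameters are configuration
data (:class:`ChannelKinetics`) so that alternative parameterizations can
be swapped in from a YAML file.  The defaults use Rothman-Manis-style
cochlear-nucleus sodium kinetics and Kd/Kir/NaP placements calibrated so
the subthreshold model reproduces its reference resting potentials and
the persistent-sodium activity threshold near -58 mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = [
    "GATE_NAMES",
    "HCNKinetics",
    "ChannelKinetics",
    "KineticsError",
    "hcn_steady_state",
    "hcn_time_constants",
    "DEFAULT_KINETICS",
]

GATE_NAMES = ("m", "h", "n", "p", "w", "a_h1", "a_h2")


class KineticsError(ValueError):
    """Raised for invalid or incomplete kinetics configuration."""


# ---------------------------------------------------------------------------
# HCN (I_h)
# ---------------------------------------------------------------------------

def hcn_steady_state(V):
    """Steady-state HCN activation, shared by both gating variables.

    Boltzmann with half-activation -87 mV and slope 8.9 mV; strictly
    decreasing in V, 1 at strong hyperpolarization, 0 at depolarization.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")
    out = 1.0 / (1.0 + np.exp((V + 87.0) / 8.9))
    return out if out.ndim else float(out)


#: Identifier of the algebraic form adopted for the two HCN time constants.
HCN_TAU_PARSE = "tau1=base+exp; tau2=base+exp-over-logistic (v1)"


def hcn_time_constants(V):
    """Voltage-dependent time constants (ms) of the two HCN gates.

    tau_h1(V) = 100 + exp((V + 183.6) / 30.48)
    tau_h2(V) = 700 + exp((V + 188.6) / 11) / (1 + exp((V + 105) / 5.5))

    Both are strictly positive everywhere; around -110 mV they evaluate to
    ~111 ms and ~1.6 s, the order of magnitude of the fast and slow
    activation components measured in fusiform neurons.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")
    tau1 = 100.0 + np.exp((V + 183.6) / 30.48)
    tau2 = 700.0 + np.exp((V + 188.6) / 11.0) / (1.0 + np.exp((V + 105.0) / 5.5))
    if tau1.ndim:
        return tau1, tau2
    return float(tau1), float(tau2)


@dataclass(frozen=True)
class HCNKinetics:
    """Half-activation/slope of the HCN steady state plus the tau parse id."""

    v_half: float = -87.0
    slope: float = 8.9
    tau_parse: str = HCN_TAU_PARSE

    def __post_init__(self):
        if self.slope <= 0:
            raise KineticsError("HCN slope must be > 0")
        # reject any tau parameterization that is not positive over the
        # whole voltage range the simulator can visit
        grid = np.linspace(-160.0, 0.0, 321)
        t1, t2 = hcn_time_constants(grid)
        if np.any(t1 <= 0) or np.any(t2 <= 0):
            raise KineticsError("HCN time constants must be positive on [-160, 0] mV")

    def steady_state(self, V):
        V = np.asarray(V, dtype=float)
        out = 1.0 / (1.0 + np.exp((V - self.v_half) / self.slope))
        return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Configurable channels: Na, Kd, NaP, Kir
# ---------------------------------------------------------------------------

_REQUIRED_FIELDS = (
    "na_m_vhalf", "na_m_slope", "na_h_vhalf", "na_h_slope",
    "kd_n_vhalf", "kd_n_slope", "nap_p_vhalf", "nap_p_slope", "nap_tau",
    "kir_w_vhalf", "kir_w_slope",
)


@dataclass(frozen=True)
class ChannelKinetics:
    """Steady-state and time-constant parameters of Na, Kd, NaP and Kir.

    Activation curves are Boltzmanns 1/(1+exp(-(V-vhalf)/slope)) (rising
    with depolarization) except Kir, which activates with
    hyperpolarization: w_inf = 1/(1+exp((V-vhalf)/slope)).  The sodium
    time constants use the Rothman-Manis (2003) cochlear-nucleus forms.
    """

    # fast Na: m^3 h
    na_m_vhalf: float = -36.0
    na_m_slope: float = 7.0
    na_h_vhalf: float = -65.0
    na_h_slope: float = 6.0
    # delayed rectifier: n^4
    kd_n_vhalf: float = -28.20
    kd_n_slope: float = 12.98
    # persistent Na: p
    nap_p_vhalf: float = -42.0
    nap_p_slope: float = 3.0
    nap_tau: float = 1.0       # ms
    # inward rectifier: w (tau comes from ModelParameters.tau_Kir)
    kir_w_vhalf: float = -83.31
    kir_w_slope: float = 10.81
    hcn: HCNKinetics = field(default_factory=HCNKinetics)

    def __post_init__(self):
        for name in ("na_m_slope", "na_h_slope", "kd_n_slope",
                     "nap_p_slope", "kir_w_slope"):
            if getattr(self, name) <= 0:
                raise KineticsError(f"{name} must be > 0")
        if self.nap_tau <= 0:
            raise KineticsError("nap_tau must be > 0")

    # -- steady states (vectorized over V and over batches) --------------
    def m_inf(self, V):
        return 1.0 / (1.0 + np.exp(-(V - self.na_m_vhalf) / self.na_m_slope))

    def h_inf(self, V):
        return 1.0 / (1.0 + np.exp((V - self.na_h_vhalf) / self.na_h_slope))

    def n_inf(self, V):
        return 1.0 / (1.0 + np.exp(-(V - self.kd_n_vhalf) / self.kd_n_slope))

    def p_inf(self, V):
        return 1.0 / (1.0 + np.exp(-(V - self.nap_p_vhalf) / self.nap_p_slope))

    def w_inf(self, V):
        return 1.0 / (1.0 + np.exp((V - self.kir_w_vhalf) / self.kir_w_slope))

    def a_inf(self, V):
        return self.hcn.steady_state(V)

    # -- time constants (ms) ---------------------------------------------
    @staticmethod
    def tau_m(V):
        return 10.0 / (5.0 * np.exp((V + 60.0) / 18.0)
                       + 36.0 * np.exp(-(V + 60.0) / 25.0)) + 0.04

    @staticmethod
    def tau_h(V):
        return 100.0 / (7.0 * np.exp((V + 60.0) / 11.0)
                        + 10.0 * np.exp(-(V + 60.0) / 25.0)) + 0.6

    @staticmethod
    def tau_n(V):
        return 0.5 + 5.0 / (np.exp((V + 40.0) / 20.0) + np.exp(-(V + 40.0) / 20.0))

    def steady_states(self, V):
        """Stack of all seven gate steady states, shape (7,) + V.shape."""
        V = np.asarray(V, dtype=float)
        a = self.a_inf(V)
        return np.stack([
            self.m_inf(V), self.h_inf(V), self.n_inf(V),
            self.p_inf(V), self.w_inf(V), a, a,
        ])

    def time_constants(self, V, tau_Kir: float = 0.5):
        """Stack of all seven gate time constants, shape (7,) + V.shape."""
        V = np.asarray(V, dtype=float)
        t1, t2 = hcn_time_constants(V)
        ones = np.ones_like(V)
        return np.stack([
            self.tau_m(V), self.tau_h(V), self.tau_n(V),
            self.nap_tau * ones, tau_Kir * ones,
            np.asarray(t1, dtype=float), np.asarray(t2, dtype=float),
        ])

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelKinetics":
        d = dict(d)
        missing = [k for k in _REQUIRED_FIELDS if k not in d]
        if missing:
            raise KineticsError(
                "incomplete kinetics configuration; missing: " + ", ".join(missing)
            )
        hcn = d.pop("hcn", None)
        if hcn is not None:
            hcn = HCNKinetics(**hcn)
            return cls(hcn=hcn, **d)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"channel_kinetics": self.to_dict()}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ChannelKinetics":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not data or "channel_kinetics" not in data:
            raise KineticsError("missing 'channel_kinetics' section in config file")
        return cls.from_dict(data["channel_kinetics"])


DEFAULT_KINETICS = ChannelKinetics()
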