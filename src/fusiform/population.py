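"""Synthetic quiet/active fusiform neurons and noisy recordings.

The generator draws per-neuron subthreshold conductances from per-class
distributions (absolute conductances in nS, converted to densities via
the membrane area), simulates 1 s of spontaneous activity to assign the
firing label, and can emulate pharmacology (blocker application as
conductance removal) and produce noisy recordings, so the entire
analysis pipeline - subtraction, conductance estimation, proportion
analysis - can be exercised against known ground truth.

Default class statistics: the HCN conductance is 5.0 nS (quiet) versus
6.9 nS (active) with per-class SD reconstructed from the cohort standard
errors; Kir is lognormal around the class preset density (0.5 mS/cm^2
active, 1.0 quiet) with 20% CV - its per-neuron spread is a declared
assumption, not a measured quantity; the leak is lognormal around the
model's baseline density (1.9 nS at the model area) with 20% CV.
Conductances are truncated at zero by resampling, not clipping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import engine
from .ephys import classify_firing
from .kinetics import ChannelKinetics, DEFAULT_KINETICS
from .parameters import (ModelParameters, active_preset, quiet_preset,
                         density_to_nS, nS_to_density)
from .trace import Trace

__all__ = [
    "ClassDistributions",
    "PopulationConfig",
    "NeuronRecord",
    "sample_population",
    "emulate_pharmacology",
    "generate_recording",
    "recover_conductances",
    "population_manifest",
    "AGENTS",
]

AGENTS = ("ZD7288", "Ba", "TTX", "low-Na")

#: Printed experimental shift of the leak reversal in low-sodium solution.
LOW_NA_ELEAK_SHIFT = -16.5  # mV

_MODEL_AREA = ModelParameters().area_cm2


def _sem_to_sd(sem: float, n: int) -> float:
    return sem * math.sqrt(n)


@dataclass(frozen=True)
class ClassDistributions:
    """Sampling distributions of one firing class (all in nS)."""

    g_h_mean: float
    g_h_sd: float
    g_Kir_mean: float
    g_Kir_cv: float        # lognormal coefficient of variation
    g_leak_mean: float
    g_leak_cv: float

    def __post_init__(self):
        for name in ("g_h_sd", "g_Kir_cv", "g_leak_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def default_class_distributions() -> dict:
    leak_nS = density_to_nS(0.15, _MODEL_AREA)  # ~1.9 nS
    return {
        "quiet": ClassDistributions(
            g_h_mean=5.0, g_h_sd=_sem_to_sd(0.5, 17),
            g_Kir_mean=density_to_nS(1.0, _MODEL_AREA), g_Kir_cv=0.20,
            g_leak_mean=leak_nS, g_leak_cv=0.20),
        "active": ClassDistributions(
            g_h_mean=6.9, g_h_sd=_sem_to_sd(0.5, 18),
            g_Kir_mean=density_to_nS(0.5, _MODEL_AREA), g_Kir_cv=0.20,
            g_leak_mean=leak_nS, g_leak_cv=0.20),
    }


@dataclass
class PopulationConfig:
    n_per_class: int = 6
    classes: dict = field(default_factory=default_class_distributions)
    conversion_area_cm2: float = _MODEL_AREA
    noise_sd_mV: float = 0.3
    noise_sd_pA: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.noise_sd_mV < 0 or self.noise_sd_pA < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.conversion_area_cm2 <= 0:
            raise ValueError("conversion area must be > 0")


@dataclass
class NeuronRecord:
    """One synthetic neuron: ground truth, label and derived quantities."""

    index: int
    drawn_class: str
    params: ModelParameters
    g_h_nS: float
    g_Kir_nS: float
    g_leak_nS: float
    rate_hz: float
    label: str               # from classify_firing on simulated activity
    seed: int
    trace_files: list = field(default_factory=list)


def _truncated_normal(rng, mean, sd, max_tries: int = 10000) -> float:
    """Normal draw resampled until positive (no point mass at zero)."""
    if sd == 0:
        if mean <= 0:
            raise ValueError("degenerate distribution entirely at <= 0")
        return mean
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if x > 0:
            return x
    raise ValueError(
        f"class empty after truncation: no positive draw from "
        f"N({mean}, {sd}) in {max_tries} tries")


def _lognormal(rng, mean, cv) -> float:
    if mean <= 0:
        raise ValueError("lognormal mean must be > 0")
    if cv == 0:
        return mean
    sigma = math.sqrt(math.log(1.0 + cv ** 2))
    mu = math.log(mean) - 0.5 * sigma ** 2
    return float(rng.lognormal(mu, sigma))


def sample_population(config: PopulationConfig,
                      base_params: ModelParameters | None = None,
                      kinetics: ChannelKinetics = DEFAULT_KINETICS,
                      dt: float = 0.1) -> list[NeuronRecord]:
    """Draw a population and label every neuron by simulated firing.

    Reproducible: the same config (including seed) yields an identical
    population.  Each neuron's spontaneous activity (1 s, full model) is
    simulated in a single batch; the label comes from the strict 0.5 Hz
    classification applied to the simulated spike times.
    """
    rng = np.random.default_rng(config.seed)
    area = config.conversion_area_cm2
    presets = {"quiet": quiet_preset(), "active": active_preset()}
    records: list[NeuronRecord] = []
    idx = 0
    for cls in ("quiet", "active"):
        dist = config.classes[cls]
        base = base_params if base_params is not None else presets[cls]
        for _ in range(config.n_per_class):
            g_h = _truncated_normal(rng, dist.g_h_mean, dist.g_h_sd)
            g_kir = _lognormal(rng, dist.g_Kir_mean, dist.g_Kir_cv)
            g_leak = _lognormal(rng, dist.g_leak_mean, dist.g_leak_cv)
            params = base.replace(
                g_h=nS_to_density(g_h, area),
                g_Kir=nS_to_density(g_kir, area),
                g_leak=nS_to_density(g_leak, area))
            records.append(NeuronRecord(
                index=idx, drawn_class=cls, params=params,
                g_h_nS=g_h, g_Kir_nS=g_kir, g_leak_nS=g_leak,
                rate_hz=float("nan"), label="", seed=config.seed))
            idx += 1

    # batched spontaneous activity for the labels
    batch = {k: np.array([getattr(r.params, k) for r in records])
             for k in records[0].params.to_dict()}
    duration = 1000.0
    rates = engine.spontaneous_rate_batch(batch, duration=duration,
                                          kinetics=kinetics, dt=dt,
                                          on_blowup="raise")
    for r, rate in zip(records, rates):
        r.rate_hz = float(rate)
        r.label = "active" if rate > 0.5 else "quiet"
    return records


def emulate_pharmacology(params: ModelParameters, agent: str,
                         elek_shift: float = LOW_NA_ELEAK_SHIFT) -> ModelParameters:
    """Blocker application as conductance removal (original untouched).

    ZD7288 removes the HCN conductance, Ba the inward rectifier, TTX
    both sodium conductances; low-Na shifts the leak reversal
    hyperpolarized by the configured amount (default -16.5 mV, the
    measured shift from -49.7 to -66.2 mV).
    """
    if agent == "ZD7288":
        return params.replace(g_h=0.0)
    if agent == "Ba":
        return params.replace(g_Kir=0.0)
    if agent == "TTX":
        return params.replace(g_Na=0.0, g_NaP=0.0)
    if agent == "low-Na":
        return params.replace(E_leak=params.E_leak + elek_shift)
    raise ValueError(f"unknown agent {agent!r}; expected one of {AGENTS}")


def generate_recording(params: ModelParameters, protocol: engine.ProtocolSpec,
                       noise_sd: float = 0.0, seed: int = 0,
                       kinetics: ChannelKinetics = DEFAULT_KINETICS,
                       out_path=None) -> Trace:
    """Simulate one protocol and add seeded Gaussian recording noise.

    ``noise_sd`` is in the units of the recorded channel (mV in current
    clamp, pA in voltage clamp).  With ``noise_sd=0`` the trace is
    identical to the clean engine output.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    tr = engine.integrate(params, protocol, kinetics)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        tr = tr.copy(signal=tr.signal + rng.normal(0.0, noise_sd,
                                                   size=tr.signal.shape))
    tr.meta.update({"noise_sd": noise_sd, "noise_seed": seed})
    if out_path is not None:
        tr.to_csv(out_path)
        tr.meta["path"] = str(out_path)
    return tr


# ---------------------------------------------------------------------------
# Known-truth recovery pipeline
# ---------------------------------------------------------------------------

_HYP_STEPS = (-120.0, -110.0, -100.0)   # chord estimates for g_h and g_Kir
_LEAK_STEPS = (-80.0, -75.0, -70.0)     # residual-leak regression window


def _vc_steady_currents(records, condition_params, steps, kinetics, dt,
                        hold_ms, holding):
    """Steady-state currents (pA) per record and step, batched."""
    n_rec, n_steps = len(records), len(steps)
    batch = {}
    for key in condition_params[0].to_dict():
        vals = np.repeat([getattr(p, key) for p in condition_params], n_steps)
        batch[key] = np.asarray(vals, dtype=float)
    levels = np.tile(np.asarray(steps, dtype=float), n_rec)
    protocol = engine.ProtocolSpec(
        mode="voltage-clamp",
        segments=(engine.Segment(hold_ms, levels),),
        settle=0.0, holding=holding, dt=dt, record_stride=20)
    pd_, width = engine._as_batch(batch)
    _, rec, _, _ = engine._simulate_core(pd_, width, kinetics, protocol)
    n_ss = max(1, int(0.05 * rec.shape[0]))
    i_ss = rec[-n_ss:].mean(axis=0)
    return i_ss.reshape(n_rec, n_steps)


def recover_conductances(records: list[NeuronRecord],
                         kinetics: ChannelKinetics = DEFAULT_KINETICS,
                         dt: float = 0.1, hold_ms: float = 8500.0,
                         holding: float = -65.0) -> pd.DataFrame:
    """Estimate every neuron's g_h, g_Kir, g_leak from emulated pharmacology.

    Reproduces the experimental sequence in silico, in voltage clamp
    with TTX present throughout: long hyperpolarizing steps are recorded
    before and after ZD7288 (g_h -> 0), then after additional Ba
    (g_Kir -> 0).  The ZD-sensitive and Ba-sensitive steady-state
    currents give chord-conductance estimates of g_h and g_Kir (divided
    by the respective steady-state activation); the residual current's
    I-V slope near rest gives g_leak, and its zero crossing E_leak.
    Returns a tidy table of estimates (nS) alongside the ground truth.
    """
    steps = list(_HYP_STEPS) + list(_LEAK_STEPS)
    p_ttx = [emulate_pharmacology(r.params, "TTX") for r in records]
    p_zd = [emulate_pharmacology(p, "ZD7288") for p in p_ttx]
    p_ba = [emulate_pharmacology(p, "Ba") for p in p_zd]

    i_ctrl = _vc_steady_currents(records, p_ttx, steps, kinetics, dt,
                                 hold_ms, holding)
    i_zd = _vc_steady_currents(records, p_zd, steps, kinetics, dt,
                               hold_ms, holding)
    i_ba = _vc_steady_currents(records, p_ba, steps, kinetics, dt,
                               hold_ms, holding)

    hyp = np.asarray(_HYP_STEPS)
    leak_v = np.asarray(_LEAK_STEPS)
    n_hyp = len(_HYP_STEPS)
    a_inf = kinetics.a_inf(hyp)
    w_inf = kinetics.w_inf(hyp)

    rows = []
    for k, r in enumerate(records):
        p = r.params
        d_ih = i_ctrl[k, :n_hyp] - i_zd[k, :n_hyp]
        d_kir = i_zd[k, :n_hyp] - i_ba[k, :n_hyp]
        gh_est = float(np.mean(d_ih / (a_inf * (hyp - p.E_h))))
        gkir_est = float(np.mean(d_kir / (w_inf * (hyp - p.E_K))))
        leak_i = i_ba[k, n_hyp:]
        slope, intercept = np.polyfit(leak_v, leak_i, 1)  # pA/mV = nS
        e_leak_est = -intercept / slope if slope != 0 else float("nan")
        rows.append({
            "index": r.index, "label": r.label,
            "g_h_true": r.g_h_nS, "g_h_est": gh_est,
            "g_Kir_true": r.g_Kir_nS, "g_Kir_est": gkir_est,
            "g_leak_true": r.g_leak_nS, "g_leak_est": float(slope),
            "E_leak_true": p.E_leak, "E_leak_est": float(e_leak_est),
        })
    return pd.DataFrame(rows)


def population_manifest(records: list[NeuronRecord]) -> pd.DataFrame:
    """One row per neuron: truth, label, seed and trace file references."""
    rows = []
    for r in records:
        row = {"index": r.index, "drawn_class": r.drawn_class,
               "label": r.label, "rate_hz": r.rate_hz,
               "g_h_nS": r.g_h_nS, "g_Kir_nS": r.g_Kir_nS,
               "g_leak_nS": r.g_leak_nS, "seed": r.seed,
               "trace_files": ";".join(map(str, r.trace_files))}
        row.update({f"param_{k}": v for k, v in r.params.to_dict().items()})
        rows.append(row)
    return pd.DataFrame(rows)
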