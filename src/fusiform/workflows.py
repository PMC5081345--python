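"""High-level analyses composed from the engine and the measurement layer.

These are the headline computations of the study: the resting-potential
operating points of the sodium-zeroed model, the firing phenotype of the
two Kir presets, the simulated HCN activation curve recovered from
tail currents, input-resistance/sag dependence on the Kir background,
and the in-silico artificial-conductance titration.  They are used by
the numbered analysis scripts and by the test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import engine
from .ephys import (boltzmann_fit, isolate_by_subtraction,
                    tail_activation_curve, BoltzmannFit)
from .kinetics import ChannelKinetics, DEFAULT_KINETICS
from . import parameters
from .parameters import ModelParameters, GH_MAP, nS_to_density

__all__ = [
    "rmp_endpoints",
    "preset_firing_rates",
    "ih_activation_from_tails",
    "rin_vs_gh",
    "sag_vs_gh",
    "gh_removal_effect",
    "artificial_gh_titration",
]


def _override_batch(base: ModelParameters, **columns) -> dict:
    width = max(np.size(v) for v in columns.values())
    batch = {k: np.full(width, float(v)) for k, v in base.to_dict().items()}
    for k, v in columns.items():
        batch[k] = np.broadcast_to(np.asarray(v, dtype=float), (width,)).copy()
    return batch


def rmp_endpoints(kinetics: ChannelKinetics = DEFAULT_KINETICS,
                  g_h: float = GH_MAP, dt: float = 0.1) -> pd.DataFrame:
    """The four reference operating points of the sodium-zeroed model.

    Varying g_Kir from 0 to 1 mS/cm^2 at g_h = 0.5 traces the Kir
    sensitivity of the resting potential; varying g_h from 0 to 1 at
    g_Kir = 0.5 traces the (much weaker) HCN sensitivity.
    """
    gh_vals = [g_h, g_h, 0.0, 1.0]
    gkir_vals = [0.0, 1.0, 0.5, 0.5]
    batch = _override_batch(ModelParameters(), g_h=gh_vals, g_Kir=gkir_vals)
    rmp = engine.rmp_batch(batch, kinetics=kinetics, dt=dt, on_blowup="raise")
    return pd.DataFrame({"g_h": gh_vals, "g_Kir": gkir_vals, "rmp_mV": rmp})


def preset_firing_rates(kinetics: ChannelKinetics = DEFAULT_KINETICS,
                        duration: float = 1000.0, dt: float = 0.1) -> dict:
    """Spontaneous rate (Hz) of the active and quiet Kir presets."""
    batch = _override_batch(ModelParameters(), g_Kir=[0.5, 1.0])
    rates = engine.spontaneous_rate_batch(batch, duration=duration,
                                          kinetics=kinetics, dt=dt,
                                          on_blowup="raise")
    return {"active": float(rates[0]), "quiet": float(rates[1])}


def ih_activation_from_tails(params: ModelParameters | None = None,
                             step_mV=None, hold_ms: float = 8500.0,
                             tail_ms: float = 1000.0,
                             kinetics: ChannelKinetics = DEFAULT_KINETICS,
                             dt: float = 0.1):
    """HCN activation curve from simulated tail currents, with Boltzmann fit.

    Long voltage-clamp steps (>= 5x the slowest HCN time constant) are
    run with and without the HCN conductance (ZD7288 emulation); the
    subtraction isolates I_h, tail peaks at the -65 mV repolarization
    are normalized and fitted.  Returns (step V, activation, fit).
    """
    if params is None:
        params = parameters.quiet_preset()
    if step_mV is None:
        step_mV = np.arange(-120.0, -49.9, 5.0)
    p = params.sodium_zeroed()
    kw = dict(step=hold_ms, tail=tail_ms, pre=100.0, settle=0.0, dt=dt,
              kinetics=kinetics)
    before = engine.run_voltage_clamp_steps(p, step_mV, **kw)
    after = engine.run_voltage_clamp_steps(p.replace(g_h=0.0), step_mV, **kw)
    diffs = []
    for a, b in zip(before, after):
        d = isolate_by_subtraction(a, b)
        d.meta.update({k: v for k, v in a.meta.items() if k != "subtraction"})
        diffs.append(d)
    V, act = tail_activation_curve(diffs)
    fit = boltzmann_fit(V, act)
    return V, act, fit


def rin_vs_gh(g_Kir: float, gh_values,
              kinetics: ChannelKinetics = DEFAULT_KINETICS,
              dt: float = 0.1) -> np.ndarray:
    """Steady-state input resistance (MOhm) across HCN densities."""
    batch = _override_batch(ModelParameters(), g_h=gh_values,
                            g_Kir=np.full(np.size(gh_values), g_Kir))
    return engine.rin_batch(batch, kinetics=kinetics, dt=dt)


def sag_vs_gh(g_Kir: float, gh_values, step_pA: float = -100.0,
              kinetics: ChannelKinetics = DEFAULT_KINETICS,
              dt: float = 0.1) -> np.ndarray:
    """Depolarization sag (mV) across HCN densities at fixed Kir."""
    batch = _override_batch(ModelParameters(), g_h=gh_values,
                            g_Kir=np.full(np.size(gh_values), g_Kir))
    return engine.sag_batch(batch, step_pA=step_pA, kinetics=kinetics, dt=dt)


def gh_removal_effect(kinetics: ChannelKinetics = DEFAULT_KINETICS,
                      dt: float = 0.1) -> pd.DataFrame:
    """Change in input resistance when the HCN conductance is removed.

    Computed for both Kir presets; the increase is expected to be much
    larger for the active preset (smaller Kir), the equalization effect.
    """
    batch = _override_batch(ModelParameters(),
                            g_Kir=[0.5, 0.5, 1.0, 1.0],
                            g_h=[parameters.GH_BASELINE, 0.0,
                                 parameters.GH_BASELINE, 0.0])
    rin = engine.rin_batch(batch, kinetics=kinetics, dt=dt)
    return pd.DataFrame({
        "preset": ["active", "quiet"],
        "rin_baseline_MOhm": [rin[0], rin[2]],
        "rin_no_gh_MOhm": [rin[1], rin[3]],
        "delta_MOhm": [rin[1] - rin[0], rin[3] - rin[2]],
    })


def artificial_gh_titration(preset_params: ModelParameters, g_art_nS_values,
                            kinetics: ChannelKinetics = DEFAULT_KINETICS,
                            dt: float = 0.1) -> pd.DataFrame:
    """Input resistance under increasing artificial HCN conductance.

    Within the model, injecting an artificial conductance with the
    native HCN kinetics and reversal is exactly equivalent to raising
    the HCN density by g_art / area, which allows the whole titration
    series to run as one batch.  Returns absolute and normalized R_in.
    """
    g_art = np.asarray(g_art_nS_values, dtype=float)
    if np.any(g_art < 0):
        raise ValueError("artificial conductance must be >= 0")
    area = preset_params.area_cm2
    gh = preset_params.g_h + np.array([nS_to_density(g, area) for g in g_art])
    batch = _override_batch(preset_params, g_h=gh)
    rin = engine.rin_batch(batch, kinetics=kinetics, dt=dt)
    base = rin[g_art == 0.0][0] if np.any(g_art == 0.0) else rin[0]
    return pd.DataFrame({"g_art_nS": g_art, "rin_MOhm": rin,
                         "rin_normalized": rin / base})
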