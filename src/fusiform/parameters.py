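"""Membrane parameters and geometry of the fusiform-cell model.

The model is a single-compartment cylinder carrying six conductances:
fast sodium (Na), delayed-rectifier potassium (Kd), hyperpolarization-
activated cation current (h, HCN), persistent sodium (NaP), inwardly
rectifying potassium (Kir) and an ohmic background leak with a
sodium-permeable (depolarized) reversal potential.

Units follow the usual single-compartment conventions: conductance
densities in mS/cm**2, potentials in mV, geometry in um, specific
capacitance in uF/cm**2, time in ms.  Current densities computed from
these are in uA/cm**2.

The quiet and active firing phenotypes differ only in the Kir density:
0.5 mS/cm**2 (active) versus 1.0 mS/cm**2 (quiet).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import yaml

__all__ = [
    "ModelParameters",
    "active_preset",
    "quiet_preset",
    "membrane_area_and_capacitance",
    "nS_to_density",
    "density_to_nS",
    "GH_BASELINE",
    "GH_MAP",
]

#: Baseline HCN conductance density used by the full spiking model (mS/cm**2).
GH_BASELINE = 0.54
#: HCN density used as the fixed point of the 2-D resting-potential maps.
GH_MAP = 0.5

_CONDUCTANCE_FIELDS = ("g_Na", "g_Kd", "g_h", "g_NaP", "g_Kir", "g_leak")


@dataclass
class ModelParameters:
    """Densities, reversal potentials and geometry of the model cell.

    Defaults are the quiet configuration (``g_Kir = 1.0``); use
    :func:`active_preset` / :func:`quiet_preset` for the named phenotypes.
    """

    g_Na: float = 80.0      # mS/cm^2
    g_Kd: float = 20.0      # mS/cm^2
    g_h: float = GH_BASELINE
    g_NaP: float = 0.1
    g_Kir: float = 1.0
    g_leak: float = 0.15
    E_Na: float = 50.0      # mV
    E_K: float = -81.5
    E_h: float = -43.0
    E_leak: float = -51.32
    diameter: float = 20.0  # um
    length: float = 20.0    # um
    c_m: float = 1.0        # uF/cm^2
    tau_Kir: float = 0.5    # ms

    def __post_init__(self) -> None:
        for name in _CONDUCTANCE_FIELDS:
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value}")
        if self.c_m <= 0:
            raise ValueError(f"c_m must be > 0, got {self.c_m}")
        if self.diameter <= 0 or self.length <= 0:
            raise ValueError("diameter and length must be > 0")
        if self.tau_Kir <= 0:
            raise ValueError(f"tau_Kir must be > 0, got {self.tau_Kir}")

    # -- geometry ---------------------------------------------------------
    @property
    def area_cm2(self) -> float:
        """Lateral cylinder area in cm**2 (no end caps)."""
        return membrane_area_and_capacitance(self.diameter, self.length, self.c_m)[0]

    @property
    def capacitance_pF(self) -> float:
        return membrane_area_and_capacitance(self.diameter, self.length, self.c_m)[1]

    # -- convenience ------------------------------------------------------
    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced (validated)."""
        return dataclasses.replace(self, **changes)

    def sodium_zeroed(self) -> "ModelParameters":
        """Copy with both sodium conductances removed (RMP measurement)."""
        return self.replace(g_Na=0.0, g_NaP=0.0)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"model_parameters": self.to_dict()}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data["model_parameters"])


def active_preset(g_h: float = GH_BASELINE) -> ModelParameters:
    """Spontaneously firing phenotype: g_Kir = 0.5 mS/cm**2."""
    return ModelParameters(g_Kir=0.5, g_h=g_h)


def quiet_preset(g_h: float = GH_BASELINE) -> ModelParameters:
    """Silent phenotype: g_Kir = 1.0 mS/cm**2."""
    return ModelParameters(g_Kir=1.0, g_h=g_h)


def membrane_area_and_capacitance(
    diameter_um: float, length_um: float, c_m: float = 1.0
) -> tuple[float, float]:
    """Lateral cylinder area (cm**2) and total capacitance (pF).

    The compartment is an open cylinder: area = pi * d * L, the
    convention of compartmental simulators for a single section.
    """
    if diameter_um <= 0 or length_um <= 0:
        raise ValueError("diameter and length must be > 0")
    if c_m <= 0:
        raise ValueError("c_m must be > 0")
    area = math.pi * (diameter_um * 1e-4) * (length_um * 1e-4)
    capacitance_pF = c_m * area * 1e6  # uF -> pF
    return area, capacitance_pF


def nS_to_density(g_nS: float, area_cm2: float) -> float:
    """Absolute conductance (nS) -> density (mS/cm**2)."""
    return g_nS * 1e-6 / area_cm2


def density_to_nS(g_density: float, area_cm2: float) -> float:
    """Density (mS/cm**2) -> absolute conductance (nS)."""
    return g_density * area_cm2 * 1e6
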