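"""2-D parameter scans, quiet/active boundary extraction and the
conductance-proportion analysis.

Scans vary two model parameters at a time (conductance densities over
[0, 2x baseline] by default, or a reversal potential) and evaluate one
metric per grid cell through the simulation engine: resting potential
(sodium-zeroed 1 s sweep), spontaneous firing rate (full model, 1 s),
steady-state input resistance or depolarization sag.  Every grid also
carries quiet/active firing labels so the phenotype boundary can be
drawn in the parameter plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from . import engine
from .kinetics import ChannelKinetics, DEFAULT_KINETICS
from .parameters import ModelParameters, density_to_nS
from .ephys import linear_regression

__all__ = [
    "ScanGrid",
    "ProportionRecord",
    "scan_2d",
    "extract_boundary",
    "scan_leak_reversal",
    "proportion_analysis",
    "default_axis",
    "METRICS",
]

METRICS = ("rmp", "firing", "rin", "sag")

_METRIC_UNITS = {"rmp": "mV", "firing": "Hz", "rin": "MOhm", "sag": "mV"}


@dataclass
class ScanGrid:
    x_name: str
    x_values: np.ndarray
    y_name: str
    y_values: np.ndarray
    metric: str
    values: np.ndarray            # shape (ny, nx)
    labels: np.ndarray            # shape (ny, nx), 'quiet'/'active' (or '')
    units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x_values = np.asarray(self.x_values, dtype=float)
        self.y_values = np.asarray(self.y_values, dtype=float)
        for name, ax in (("x", self.x_values), ("y", self.y_values)):
            if ax.ndim != 1 or (len(ax) > 1 and np.any(np.diff(ax) <= 0)):
                raise ValueError(f"{name} axis must be strictly increasing")
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.y_values), len(self.x_values))
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != expected:
            raise ValueError(f"labels shape {self.labels.shape} != {expected}")

    # -- export -----------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x_values, self.y_values)
        return pd.DataFrame({
            self.x_name: xx.ravel(), self.y_name: yy.ravel(),
            self.metric: self.values.ravel(), "label": self.labels.ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            g = f.create_group("scan")
            g.create_dataset("x_values", data=self.x_values)
            g.create_dataset("y_values", data=self.y_values)
            g.create_dataset("values", data=self.values)
            g.create_dataset("labels",
                             data=self.labels.astype("S10"))
            g.attrs["x_name"] = self.x_name
            g.attrs["y_name"] = self.y_name
            g.attrs["metric"] = self.metric
            g.attrs["units"] = self.units

    @classmethod
    def from_hdf5(cls, path) -> "ScanGrid":
        with h5py.File(path, "r") as f:
            g = f["scan"]
            return cls(
                x_name=g.attrs["x_name"], x_values=g["x_values"][:],
                y_name=g.attrs["y_name"], y_values=g["y_values"][:],
                metric=g.attrs["metric"], values=g["values"][:],
                labels=g["labels"][:].astype(str), units=g.attrs["units"])


def default_axis(params: ModelParameters, name: str, n: int = 41) -> np.ndarray:
    """Default scan axis: [0, 2 x baseline] for a conductance density."""
    base = getattr(params, name)
    if base <= 0:
        raise ValueError(f"{name} baseline is zero; give an explicit axis")
    return np.linspace(0.0, 2.0 * base, n)


def _batch_for_grid(params: ModelParameters, x_name: str, xv: np.ndarray,
                    y_name: str, yv: np.ndarray) -> dict:
    xx, yy = np.meshgrid(xv, yv)
    pd_ = params.to_dict()
    batch = {k: np.full(xx.size, float(v)) for k, v in pd_.items()}
    batch[x_name] = xx.ravel().astype(float)
    batch[y_name] = yy.ravel().astype(float)
    return batch


def _firing_labels(params, x_name, xv, y_name, yv, kinetics, dt) -> np.ndarray:
    batch = _batch_for_grid(params, x_name, xv, y_name, yv)
    rates = engine.spontaneous_rate_batch(batch, kinetics=kinetics, dt=dt)
    labels = np.where(rates > 0.5, "active", "quiet").astype(object)
    labels[np.isnan(rates)] = ""
    return labels.reshape(len(yv), len(xv))


def scan_2d(params: ModelParameters, axis_x: tuple[str, np.ndarray],
            axis_y: tuple[str, np.ndarray], metric: str,
            kinetics: ChannelKinetics = DEFAULT_KINETICS,
            dt: float = 0.1, with_labels: bool = True) -> ScanGrid:
    """Evaluate one metric over a 2-D parameter grid.

    ``axis_x``/``axis_y`` are (parameter name, values).  The resting
    potential metric uses the sodium-zeroed 1 s sweep; the firing metric
    is the spontaneous rate of the full model; input resistance and sag
    are measured on the sodium-zeroed model from rest.  Cells whose
    simulation blows up are recorded as NaN (labels empty) rather than
    aborting the scan.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    x_name, xv = axis_x
    y_name, yv = axis_y
    xv = np.asarray(xv, dtype=float)
    yv = np.asarray(yv, dtype=float)
    batch = _batch_for_grid(params, x_name, xv, y_name, yv)
    shape = (len(yv), len(xv))

    if metric == "rmp":
        vals = engine.rmp_batch(batch, kinetics=kinetics, dt=dt)
    elif metric == "firing":
        vals = engine.spontaneous_rate_batch(batch, kinetics=kinetics, dt=dt)
    elif metric == "rin":
        vals = engine.rin_batch(batch, kinetics=kinetics, dt=dt)
    else:  # sag
        vals = engine.sag_batch(batch, kinetics=kinetics, dt=dt)

    if with_labels:
        if metric == "firing":
            labels = np.where(vals > 0.5, "active", "quiet").astype(object)
            labels[np.isnan(vals)] = ""
            labels = labels.reshape(shape)
        else:
            labels = _firing_labels(params, x_name, xv, y_name, yv,
                                    kinetics, dt)
    else:
        labels = np.full(shape, "", dtype=object)

    return ScanGrid(x_name=x_name, x_values=xv, y_name=y_name, y_values=yv,
                    metric=metric, values=vals.reshape(shape), labels=labels,
                    units=_METRIC_UNITS[metric],
                    meta={"base_params": params.to_dict(), "dt": dt})


def scan_leak_reversal(params: ModelParameters, g_leak_values, E_leak_values,
                       g_Kir: float,
                       kinetics: ChannelKinetics = DEFAULT_KINETICS,
                       dt: float = 0.1, with_labels: bool = True) -> ScanGrid:
    """RMP map over (g_leak, E_leak) at a fixed Kir preset density."""
    E_leak_values = np.asarray(E_leak_values, dtype=float)
    if np.any(E_leak_values < -90) or np.any(E_leak_values > -30):
        raise ValueError("E_leak axis outside the supported [-90, -30] mV range")
    p = params.replace(g_Kir=g_Kir)
    return scan_2d(p, ("g_leak", np.asarray(g_leak_values, dtype=float)),
                   ("E_leak", E_leak_values), "rmp",
                   kinetics=kinetics, dt=dt, with_labels=with_labels)


def extract_boundary(grid: ScanGrid):
    """Quiet/active transition as points in the parameter plane.

    Walks adjacent cell pairs (vertically and horizontally); each pair
    with differing labels contributes the midpoint between the two cell
    centers.  Returns a dict with ``points`` (N, 2 array in x, y order),
    ``multivalued`` (True when a column crosses the boundary more than
    once, e.g. a checkerboard, where a simple curve is not guaranteed)
    and ``empty`` (True for a single-class grid, with a warning).
    """
    labels = grid.labels
    ny, nx = labels.shape
    present = {l for l in labels.ravel() if l}
    if len(present) < 2:
        import warnings
        warnings.warn("grid contains a single firing class; boundary is empty")
        return {"points": np.empty((0, 2)), "multivalued": False, "empty": True}

    pts = []
    col_crossings = np.zeros(nx, dtype=int)
    for j in range(nx):
        for i in range(ny - 1):
            a, b = labels[i, j], labels[i + 1, j]
            if a and b and a != b:
                pts.append((grid.x_values[j],
                            0.5 * (grid.y_values[i] + grid.y_values[i + 1])))
                col_crossings[j] += 1
    for i in range(ny):
        for j in range(nx - 1):
            a, b = labels[i, j], labels[i, j + 1]
            if a and b and a != b:
                pts.append((0.5 * (grid.x_values[j] + grid.x_values[j + 1]),
                            grid.y_values[i]))
    return {"points": np.asarray(pts, dtype=float),
            "multivalued": bool(np.any(col_crossings > 1)),
            "empty": False}


# ---------------------------------------------------------------------------
# Conductance proportions
# ---------------------------------------------------------------------------

@dataclass
class ProportionRecord:
    """Absolute subthreshold conductances (nS) of one neuron plus label."""

    g_Kir: float
    g_h: float
    g_leak: float
    firing_label: str = ""

    def __post_init__(self):
        for name in ("g_Kir", "g_h", "g_leak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.total == 0:
            raise ValueError("total subthreshold conductance is zero")

    @property
    def total(self) -> float:
        return self.g_Kir + self.g_h + self.g_leak

    @property
    def percentages(self) -> dict:
        t = self.total
        return {"g_Kir": 100.0 * self.g_Kir / t,
                "g_h": 100.0 * self.g_h / t,
                "g_leak": 100.0 * self.g_leak / t}

    @classmethod
    def from_params(cls, params: ModelParameters, firing_label: str = "") \
            -> "ProportionRecord":
        area = params.area_cm2
        return cls(g_Kir=density_to_nS(params.g_Kir, area),
                   g_h=density_to_nS(params.g_h, area),
                   g_leak=density_to_nS(params.g_leak, area),
                   firing_label=firing_label)


def classify_by_kir_share(record: ProportionRecord) -> str:
    """Quiet iff g_Kir accounts for >= 50% of the subthreshold total."""
    return "quiet" if record.percentages["g_Kir"] >= 50.0 else "active"


def proportion_analysis(records: list[ProportionRecord]) -> dict:
    """Regressions between conductance shares plus the 50% rule labels.

    Returns per-record percentage table, linear regressions (slope, r^2,
    p) of g_h% and g_leak% against g_Kir%, and the rule-based
    quiet/active labels.
    """
    if len(records) < 3:
        raise ValueError("need >= 3 records for the proportion regressions")
    pct = pd.DataFrame([r.percentages for r in records])
    pct["firing_label"] = [r.firing_label for r in records]
    pct["rule_label"] = [classify_by_kir_share(r) for r in records]
    reg_h = linear_regression(pct["g_Kir"], pct["g_h"])
    reg_leak = linear_regression(pct["g_Kir"], pct["g_leak"])
    return {"table": pct, "gh_vs_gkir": reg_h, "gleak_vs_gkir": reg_leak,
            "rule_labels": list(pct["rule_label"])}
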