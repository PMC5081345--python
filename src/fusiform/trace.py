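"""Time-series container for simulated or synthetic recordings.

A :class:`Trace` is a uniformly sampled voltage (mV) or current (pA)
signal with protocol metadata.  Traces round-trip through CSV (metadata
in ``#``-prefixed header lines) and HDF5 (``/trace/time``,
``/trace/signal`` datasets plus a ``/meta`` attribute group).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["Trace", "TraceError"]


class TraceError(ValueError):
    pass


@dataclass
class Trace:
    time: np.ndarray           # ms, uniform grid
    signal: np.ndarray         # mV or pA
    kind: str                  # 'voltage' | 'current'
    units: str                 # 'mV' | 'pA'
    channel: str = ""          # free-form label
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.ndim != 1 or self.signal.shape != self.time.shape:
            raise TraceError("time and signal must be matching 1-D arrays")
        if len(self.time) > 1:
            steps = np.diff(self.time)
            if np.any(steps <= 0):
                raise TraceError("time must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
                raise TraceError("time grid must be uniform")
        if not np.all(np.isfinite(self.signal)):
            raise TraceError("signal contains non-finite values")
        if self.kind not in ("voltage", "current"):
            raise TraceError(f"kind must be 'voltage' or 'current', got {self.kind!r}")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) > 1 else float("nan")

    def copy(self, **updates) -> "Trace":
        d = dict(time=self.time.copy(), signal=self.signal.copy(),
                 kind=self.kind, units=self.units, channel=self.channel,
                 meta=dict(self.meta))
        d.update(updates)
        return Trace(**d)

    def window(self, t0: float, t1: float) -> "Trace":
        """Sub-trace on [t0, t1]; raises if the window is outside the trace."""
        if t0 < self.time[0] - 1e-9 or t1 > self.time[-1] + 1e-9 or t1 <= t0:
            raise TraceError(
                f"window [{t0}, {t1}] outside trace span "
                f"[{self.time[0]}, {self.time[-1]}]"
            )
        mask = (self.time >= t0 - 1e-9) & (self.time <= t1 + 1e-9)
        return self.copy(time=self.time[mask], signal=self.signal[mask])

    def protocol_hash(self) -> str:
        """Stable short hash of the protocol metadata."""
        payload = json.dumps(self.meta.get("protocol", {}), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    # -- CSV --------------------------------------------------------------
    def to_csv(self, path) -> None:
        header = {
            "kind": self.kind, "units": self.units, "channel": self.channel,
            "protocol_hash": self.protocol_hash(), "meta": self.meta,
        }
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(header, default=str) + "\n")
            fh.write("time_ms,signal\n")
            np.savetxt(fh, np.column_stack([self.time, self.signal]),
                       delimiter=",", fmt="%.10g")

    @classmethod
    def from_csv(cls, path) -> "Trace":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("# "):
                raise TraceError(f"{path}: missing metadata header line")
            header = json.loads(first[2:])
            data = np.loadtxt(fh, delimiter=",", skiprows=1, ndmin=2)
        return cls(time=data[:, 0], signal=data[:, 1], kind=header["kind"],
                   units=header["units"], channel=header.get("channel", ""),
                   meta=header.get("meta", {}))

    # -- HDF5 -------------------------------------------------------------
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            grp = f.create_group("trace")
            grp.create_dataset("time", data=self.time)
            grp.create_dataset("signal", data=self.signal)
            meta = f.create_group("meta")
            meta.attrs["kind"] = self.kind
            meta.attrs["units"] = self.units
            meta.attrs["channel"] = self.channel
            meta.attrs["meta_json"] = json.dumps(self.meta, default=str)

    @classmethod
    def from_hdf5(cls, path) -> "Trace":
        with h5py.File(path, "r") as f:
            time = f["trace/time"][:]
            signal = f["trace/signal"][:]
            meta_grp = f["meta"]
            return cls(time=time, signal=signal,
                       kind=meta_grp.attrs["kind"], units=meta_grp.attrs["units"],
                       channel=meta_grp.attrs["channel"],
                       meta=json.loads(meta_grp.attrs["meta_json"]))
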