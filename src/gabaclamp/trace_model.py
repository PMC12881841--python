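"""Neutral data model and I/O for electrophysiology sweeps.

Canonical units throughout the package: membrane potential in mV, current in
pA, conductance in nS, capacitance in pF, resistance in MΩ, time in ms.  These
close under the membrane equation (nS·mV = pA and pA·ms/pF = mV), so no unit
conversion happens anywhere downstream.  The acquisition-hardware criterion of
10,000 V/s/s for spike threshold is, in these units, 10 mV/ms²; the conversion
is done once, here, and stored as :data:`THRESHOLD_CRITERION_MV_PER_MS2`.

Time convention: ``t = 0`` at the start of a sweep; the stimulus trigger time
is stored explicitly on the :class:`SweepSet` and all latencies downstream are
reported relative to it.

Two on-disk dialects are supported and round-trip all metadata:

* an HDF5 container: dataset ``/sweeps`` (sweep × sample) with attributes
  ``dt_ms``, ``unit``, ``trigger_time_ms``, ``t0_ms``, ``cell_id``, ``group``,
  ``template_id``, ``ljp_corrected``;
* a delimited-text dialect: ``#``-prefixed ``key = value`` header lines
  followed by one whitespace-separated column per sweep.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .errors import DataError, FormatError, StateError, UnitError

__all__ = [
    "THRESHOLD_CRITERION_MV_PER_MS2",
    "TimeSeries",
    "SweepSet",
    "GroupLabel",
    "GROUPS",
    "read_sweepset",
    "write_sweepset",
    "apply_ljp_correction",
    "second_derivative",
]

#: 10,000 V/s/s expressed in canonical units (1 V/s/s = 1e3 mV / 1e6 ms² ).
THRESHOLD_CRITERION_MV_PER_MS2 = 10.0

#: Units accepted on stored traces.
_IO_UNITS = ("mV", "pA", "nS")


@dataclass
class TimeSeries:
    """A uniformly sampled trace.

    Parameters
    ----------
    samples:
        Sample values; mV for voltage, pA for current, nS for conductance.
    dt:
        Sampling interval in ms (must be positive).
    t0:
        Time of the first sample in ms (defaults to 0: sweep start).
    unit:
        Unit tag; derived traces (e.g. second derivatives) may carry
        compound unit strings, but stored sweeps must use mV/pA/nS.
    """

    samples: np.ndarray
    dt: float
    t0: float = 0.0
    unit: str = "mV"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise DataError("samples must be a non-empty 1-D array")
        if not self.dt > 0:
            raise DataError(f"dt must be positive, got {self.dt}")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def t_end(self) -> float:
        return self.t0 + (self.n - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) * self.dt

    def index_at(self, t: float) -> int:
        """Nearest sample index for time ``t`` (ms)."""
        return int(round((t - self.t0) / self.dt))

    def value_at(self, t: float) -> float:
        """Linearly interpolated sample value at time ``t``."""
        return float(np.interp(t, self.times, self.samples))

    def copy(self) -> "TimeSeries":
        return TimeSeries(self.samples.copy(), self.dt, self.t0, self.unit)


_AGES = ("three_week", "adult")
_TREATMENTS = ("VEH", "PNA")


@dataclass(frozen=True)
class GroupLabel:
    """One cell of the two-by-two design: age × prenatal treatment."""

    age: str
    treatment: str

    def __post_init__(self) -> None:
        if self.age not in _AGES:
            raise FormatError(f"age must be one of {_AGES}, got {self.age!r}")
        if self.treatment not in _TREATMENTS:
            raise FormatError(
                f"treatment must be one of {_TREATMENTS}, got {self.treatment!r}"
            )

    def __str__(self) -> str:
        return f"{self.age}_{self.treatment}"

    @classmethod
    def parse(cls, label: str) -> "GroupLabel":
        age, _, treatment = label.rpartition("_")
        return cls(age, treatment)


#: The four experimental groups, in reporting order.
GROUPS = (
    GroupLabel("three_week", "VEH"),
    GroupLabel("three_week", "PNA"),
    GroupLabel("adult", "VEH"),
    GroupLabel("adult", "PNA"),
)


@dataclass
class SweepSet:
    """An ordered set of sweeps sharing sampling and stimulus metadata."""

    sweeps: list = field(default_factory=list)
    trigger_time: float = 0.0
    template_id: str | None = None
    cell_id: str | None = None
    group: GroupLabel | None = None
    ljp_corrected: bool = False

    def __post_init__(self) -> None:
        if not self.sweeps:
            raise FormatError("SweepSet requires at least one sweep")
        ref = self.sweeps[0]
        for s in self.sweeps:
            if s.n != ref.n or s.dt != ref.dt or s.unit != ref.unit:
                raise FormatError("all sweeps must share dt, length and unit")
        if not (ref.t0 <= self.trigger_time <= ref.t_end):
            raise FormatError(
                f"trigger_time {self.trigger_time} outside sweep span "
                f"[{ref.t0}, {ref.t_end}]"
            )

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)

    @property
    def dt(self) -> float:
        return self.sweeps[0].dt

    @property
    def unit(self) -> str:
        return self.sweeps[0].unit

    def as_array(self) -> np.ndarray:
        """Stack sweeps into a (n_sweeps, n_samples) array."""
        return np.stack([s.samples for s in self.sweeps])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _infer_dialect(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".h5", ".hdf5"):
        return "hdf5-container"
    if ext in (".txt", ".tsv", ".dat", ".csv"):
        return "delimited-text"
    raise FormatError(f"cannot infer dialect from extension {ext!r}")


def write_sweepset(s: SweepSet, path: str, dialect: str | None = None) -> None:
    """Write a sweep set to ``path`` in the chosen dialect (inferred from the
    extension if omitted)."""
    dialect = dialect or _infer_dialect(path)
    if s.unit not in _IO_UNITS:
        raise UnitError(f"stored sweeps must use one of {_IO_UNITS}, got {s.unit!r}")
    data = s.as_array()
    meta = {
        "dt_ms": s.dt,
        "t0_ms": s.sweeps[0].t0,
        "unit": s.unit,
        "trigger_time_ms": s.trigger_time,
        "cell_id": s.cell_id or "",
        "group": str(s.group) if s.group is not None else "",
        "template_id": s.template_id or "",
        "ljp_corrected": bool(s.ljp_corrected),
    }
    if dialect == "hdf5-container":
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("sweeps", data=data)
            for k, v in meta.items():
                ds.attrs[k] = v
    elif dialect == "delimited-text":
        header = "\n".join(f"# {k} = {v}" for k, v in meta.items())
        np.savetxt(path, data.T, header=header, comments="", fmt="%.9g")
    else:
        raise FormatError(f"unknown dialect {dialect!r}")


def _build_sweepset(data: np.ndarray, meta: dict) -> SweepSet:
    for key in ("dt_ms", "unit", "trigger_time_ms"):
        if key not in meta:
            raise FormatError(f"missing required metadata {key!r}")
    dt = float(meta["dt_ms"])
    t0 = float(meta.get("t0_ms", 0.0))
    unit = str(meta["unit"])
    if unit not in _IO_UNITS:
        raise FormatError(f"unknown unit {unit!r}")
    sweeps = [TimeSeries(row, dt, t0, unit) for row in data]
    group = meta.get("group") or None
    return SweepSet(
        sweeps=sweeps,
        trigger_time=float(meta["trigger_time_ms"]),
        template_id=meta.get("template_id") or None,
        cell_id=meta.get("cell_id") or None,
        group=GroupLabel.parse(group) if group else None,
        ljp_corrected=_as_bool(meta.get("ljp_corrected", False)),
    )


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("true", "1", "yes")
    return bool(v)


def read_sweepset(path: str, dialect: str | None = None) -> SweepSet:
    """Read a sweep set written by :func:`write_sweepset`."""
    dialect = dialect or _infer_dialect(path)
    if dialect == "hdf5-container":
        with h5py.File(path, "r") as f:
            if "sweeps" not in f:
                raise FormatError("HDF5 file lacks a /sweeps dataset")
            ds = f["sweeps"]
            data = np.asarray(ds)
            meta = {k: _decode(v) for k, v in ds.attrs.items()}
    elif dialect == "delimited-text":
        meta = {}
        rows = []
        width = None
        with open(path) as f:
            for line in f:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, val = line[1:].partition("=")
                    meta[key.strip()] = val.strip()
                    continue
                parts = line.split()
                if width is None:
                    width = len(parts)
                elif len(parts) != width:
                    raise FormatError("ragged sweep lengths in text file")
                rows.append([float(p) for p in parts])
        if not rows:
            raise FormatError("no sample rows found")
        data = np.asarray(rows).T
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    if data.ndim != 2:
        raise FormatError("sweep data must be two-dimensional")
    return _build_sweepset(data, meta)


def _decode(v):
    if isinstance(v, bytes):
        return v.decode()
    return v


# ---------------------------------------------------------------------------
# Shared numerical operations
# ---------------------------------------------------------------------------

def apply_ljp_correction(s: SweepSet, ljp: float = 14.5) -> SweepSet:
    """Subtract the liquid junction potential from every voltage sample.

    The pipette/bath junction offset (14.5 mV for this solution pair) is
    subtracted once; the ``ljp_corrected`` flag guards idempotence.
    """
    if s.unit != "mV":
        raise UnitError("LJP correction applies to voltage sweeps only")
    if s.ljp_corrected:
        raise StateError("sweep set is already LJP-corrected")
    sweeps = [TimeSeries(t.samples - ljp, t.dt, t.t0, t.unit) for t in s.sweeps]
    return replace(s, sweeps=sweeps, ljp_corrected=True)


def second_derivative(ts: TimeSeries) -> TimeSeries:
    """Central-difference second derivative, same length as the input.

    Interior samples use the three-point stencil ``(v[k+1]-2v[k]+v[k-1])/dt²``;
    the two edge samples replicate their nearest interior value so masks built
    on the input align sample-for-sample with the output.
    """
    if ts.n < 5:
        raise DataError("second_derivative requires at least 5 samples")
    v = ts.samples
    d2 = np.empty_like(v)
    d2[1:-1] = (v[2:] - 2.0 * v[1:-1] + v[:-2]) / ts.dt**2
    d2[0] = d2[1]
    d2[-1] = d2[-2]
    return TimeSeries(d2, ts.dt, ts.t0, unit=f"{ts.unit}/ms2")


def parabolic_extremum(y: np.ndarray, k: int, dt: float) -> tuple[float, float]:
    """Sub-sample extremum location/value by parabolic interpolation around
    index ``k``.  Returns ``(offset_ms, value)`` with offset relative to the
    time of sample ``k``.  Falls back to the sample itself at array edges or
    degenerate curvature."""
    if k <= 0 or k >= len(y) - 1:
        return 0.0, float(y[k])
    denom = y[k - 1] - 2.0 * y[k] + y[k + 1]
    if denom == 0.0:
        return 0.0, float(y[k])
    delta = 0.5 * (y[k - 1] - y[k + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    value = y[k] - 0.25 * (y[k - 1] - y[k + 1]) * delta
    return delta * dt, float(value)
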