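"""Core containers and file I/O for field-potential and spike-train data.

All times are in seconds internally; milliseconds appear only at presentation
boundaries (correlogram lags, PETH bins). Voltages are in mV.

On-disk formats:

* LFP: HDF5 with one group per channel (``samples`` dataset, ``fs``/``t0``/
  ``label`` attributes), or a flat binary array with a JSON sidecar
  (``<path>.json``) holding ``fs``, ``t0``, ``label`` and ``dtype``.
* Spike trains: CSV with columns ``unit_id, time_s, cell_class``.
* Event tables: CSV with one row per event; per-band power metrics are
  serialized as one ``power_<band>`` column each.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "CellClass",
    "TimeSeries",
    "SpikeTrain",
    "BandDef",
    "EventTable",
    "ValidationError",
    "FormatError",
    "read_timeseries",
    "write_timeseries",
    "read_spiketrains",
    "write_spiketrains",
    "read_events",
    "write_events",
    "RIPPLE_BAND",
    "FASTRIP_POWER_BAND",
    "FASTRIP_COH_BAND",
    "MUA_BAND",
]


class ValidationError(ValueError):
    """A container invariant was violated."""


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


class CellClass(Enum):
    """Cell identity of a loose-patch recorded unit.

    PVBC: parvalbumin-expressing basket cell. PC_I / PC_II: pyramidal cells
    of firing type I (burst only during fast-ripples) or type II (burst also
    before epileptiform events).
    """

    PVBC = "PVBC"
    PC_I = "PC_I"
    PC_II = "PC_II"
    UNKNOWN = "UNKNOWN"

    @classmethod
    def from_string(cls, s: str) -> "CellClass":
        try:
            return cls(str(s).strip().upper())
        except ValueError:
            warnings.warn(f"unknown cell class {s!r}; using UNKNOWN", stacklevel=2)
            return cls.UNKNOWN


@dataclass
class TimeSeries:
    """A uniformly sampled voltage trace.

    The time of sample ``i`` is exactly ``t0 + i / fs``; there are no
    per-sample timestamps.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValidationError(f"fs must be > 0, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValidationError("samples must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples contain non-finite values")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + (self.samples.size - 1) / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def index_of(self, t: float) -> int:
        """Nearest sample index for time ``t`` (clipped to the trace)."""
        i = int(round((t - self.t0) * self.fs))
        return min(max(i, 0), self.samples.size - 1)

    def with_samples(self, samples: np.ndarray, label: str | None = None) -> "TimeSeries":
        return TimeSeries(samples, self.fs, self.t0, self.label if label is None else label)


@dataclass
class SpikeTrain:
    """Sorted spike times of one unit with a cell-class label."""

    times: np.ndarray
    unit_id: str = ""
    cell_class: CellClass = CellClass.UNKNOWN

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValidationError("spike times must be a 1-D array")
        if self.times.size and not np.all(np.isfinite(self.times)):
            raise ValidationError("spike times contain non-finite values")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError(
                f"spike times of unit {self.unit_id!r} must be strictly increasing"
            )

    def __len__(self) -> int:
        return self.times.size

    def shifted(self, dt: float) -> "SpikeTrain":
        return SpikeTrain(self.times + dt, self.unit_id, self.cell_class)

    def restrict(self, t_start: float, t_stop: float) -> "SpikeTrain":
        m = (self.times >= t_start) & (self.times < t_stop)
        return SpikeTrain(self.times[m], self.unit_id, self.cell_class)


@dataclass(frozen=True)
class BandDef:
    """A named frequency band; ``f_high = inf`` denotes a pure high-pass."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high):
            raise ValidationError(f"need 0 < f_low < f_high, got {self}")

    @property
    def is_highpass(self) -> bool:
        return math.isinf(self.f_high)


RIPPLE_BAND = BandDef("ripple", 150.0, 250.0)
#: Band used for fast-ripple power / IED peak definition.
FASTRIP_POWER_BAND = BandDef("fastrip_power", 200.0, 500.0)
#: Band used for fast-ripple coherence statistics.
FASTRIP_COH_BAND = BandDef("fastrip_coh", 250.0, 500.0)
MUA_BAND = BandDef("mua", 500.0, math.inf)

_EVENT_BASE_COLS = ["kind", "peak_time", "trigger_time", "onset_time"]
#: Default minimum gap between events of the same kind (s).
DEFAULT_REFRACTORY = {"SWR": 0.05, "IED": 0.2}


class EventTable:
    """Detected SWR / IED events.

    Thin wrapper around a :class:`pandas.DataFrame` with columns ``kind``
    (``"SWR"`` or ``"IED"``), ``peak_time``, ``trigger_time``, ``onset_time``
    (NaN when unknown), plus one ``power_<band>`` column per stored band
    power metric. Rows are kept sorted by ``peak_time``.
    """

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=_EVENT_BASE_COLS)
        df = df.copy()
        for c in _EVENT_BASE_COLS:
            if c not in df.columns:
                df[c] = np.nan if c != "kind" else ""
        order = _EVENT_BASE_COLS + [c for c in df.columns if c not in _EVENT_BASE_COLS]
        df = df[order]
        if len(df):
            df = df.sort_values("peak_time", kind="stable").reset_index(drop=True)
            bad = df["onset_time"].notna() & (df["onset_time"] > df["peak_time"])
            if bad.any():
                raise ValidationError("onset_time must not exceed peak_time")
        self.df = df

    @classmethod
    def from_records(cls, records: list[dict]) -> "EventTable":
        return cls(pd.DataFrame.from_records(records))

    def __len__(self) -> int:
        return len(self.df)

    def of_kind(self, kind: str) -> "EventTable":
        return EventTable(self.df[self.df["kind"] == kind])

    @property
    def peak_times(self) -> np.ndarray:
        return self.df["peak_time"].to_numpy(dtype=float)

    @property
    def trigger_times(self) -> np.ndarray:
        return self.df["trigger_time"].to_numpy(dtype=float)

    @property
    def onset_times(self) -> np.ndarray:
        return self.df["onset_time"].to_numpy(dtype=float)

    def validate_refractory(self, gaps: dict[str, float] | None = None) -> None:
        gaps = DEFAULT_REFRACTORY if gaps is None else gaps
        for kind, gap in gaps.items():
            t = np.sort(self.of_kind(kind).peak_times)
            if t.size > 1 and np.min(np.diff(t)) < gap:
                raise ValidationError(
                    f"two {kind} events closer than the {gap * 1e3:.0f} ms refractory gap"
                )

    def concat(self, other: "EventTable") -> "EventTable":
        return EventTable(pd.concat([self.df, other.df], ignore_index=True))

    def shifted(self, dt: float) -> "EventTable":
        df = self.df.copy()
        for c in ("peak_time", "trigger_time", "onset_time"):
            df[c] = df[c] + dt
        return EventTable(df)


# ---------------------------------------------------------------------------
# Time-series I/O

def _infer_format(path: Path) -> str:
    if path.suffix.lower() in (".h5", ".hdf5"):
        return "hdf5"
    return "binary"


def write_timeseries(ts: TimeSeries, path: str | Path, fmt: str | None = None) -> None:
    """Write one channel; HDF5 appends/overwrites a group named by its label."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "hdf5":
        with h5py.File(path, "a") as f:
            name = ts.label or "ch0"
            if name in f:
                del f[name]
            g = f.create_group(name)
            g.create_dataset("samples", data=ts.samples)
            g.attrs["fs"] = float(ts.fs)
            g.attrs["t0"] = float(ts.t0)
            g.attrs["label"] = ts.label
    elif fmt == "binary":
        data = ts.samples.astype(np.float64)
        data.tofile(path)
        sidecar = {"fs": ts.fs, "t0": ts.t0, "label": ts.label, "dtype": "float64"}
        Path(str(path) + ".json").write_text(json.dumps(sidecar))
    else:
        raise FormatError(f"unknown time-series format {fmt!r}")


def read_timeseries(path: str | Path, fmt: str | None = None,
                    channel: str | None = None) -> TimeSeries:
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            names = sorted(f.keys())
            if not names:
                raise FormatError(f"{path}: no channel groups")
            name = channel if channel is not None else names[0]
            if name not in f:
                raise FormatError(f"{path}: no channel {name!r}")
            g = f[name]
            if "fs" not in g.attrs:
                raise FormatError(f"{path}:{name}: missing fs attribute")
            return TimeSeries(
                np.asarray(g["samples"]), float(g.attrs["fs"]),
                float(g.attrs.get("t0", 0.0)), str(g.attrs.get("label", name)),
            )
    elif fmt == "binary":
        sidecar_path = Path(str(path) + ".json")
        if not sidecar_path.exists():
            raise FormatError(f"missing JSON sidecar {sidecar_path}")
        meta = json.loads(sidecar_path.read_text())
        if "fs" not in meta:
            raise FormatError(f"{sidecar_path}: missing fs")
        data = np.fromfile(path, dtype=np.dtype(meta.get("dtype", "float64")))
        return TimeSeries(data.astype(float), float(meta["fs"]),
                          float(meta.get("t0", 0.0)), str(meta.get("label", "")))
    raise FormatError(f"unknown time-series format {fmt!r}")


def read_all_channels(path: str | Path) -> list[TimeSeries]:
    path = Path(path)
    with h5py.File(path, "r") as f:
        names = sorted(f.keys())
    return [read_timeseries(path, "hdf5", channel=n) for n in names]


# ---------------------------------------------------------------------------
# Spike-train I/O

def write_spiketrains(trains: list[SpikeTrain], path: str | Path) -> None:
    rows = []
    for tr in trains:
        for t in tr.times:
            rows.append({"unit_id": tr.unit_id, "time_s": t,
                         "cell_class": tr.cell_class.value})
    pd.DataFrame(rows, columns=["unit_id", "time_s", "cell_class"]).to_csv(
        path, index=False)


def read_spiketrains(path: str | Path) -> list[SpikeTrain]:
    df = pd.read_csv(path, dtype={"unit_id": str})
    missing = {"unit_id", "time_s", "cell_class"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    trains = []
    for unit_id, sub in df.groupby("unit_id", sort=True):
        t = np.sort(sub["time_s"].to_numpy(dtype=float))
        if t.size > 1 and np.min(np.diff(t)) <= 0:
            raise ValidationError(f"unit {unit_id!r}: duplicate spike times")
        classes = set(sub["cell_class"].astype(str))
        cls = CellClass.from_string(classes.pop()) if len(classes) == 1 else CellClass.UNKNOWN
        trains.append(SpikeTrain(t, str(unit_id), cls))
    return trains


# ---------------------------------------------------------------------------
# Event-table I/O

def write_events(ev: EventTable, path: str | Path) -> None:
    ev.df.to_csv(path, index=False)


def read_events(path: str | Path) -> EventTable:
    df = pd.read_csv(path)
    if "peak_time" not in df.columns or "kind" not in df.columns:
        raise FormatError(f"{path}: not an event table")
    return EventTable(df)
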