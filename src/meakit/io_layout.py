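"""Interchange formats and array geometry.

Two plain, open formats move data in and out of the toolkit:

* analog voltage — HDF5 with datasets ``/analog/data`` (float32,
  channels x samples, µV) and ``/analog/channels`` (electrode labels), plus
  root attributes ``sampling_rate_hz`` and ``start_time_s``;
* spike events — CSV with header ``electrode,time,amplitude,unit``
  (time in seconds, amplitude in µV signed at the peak, unit an integer
  cluster id with −1 meaning unsorted/noise).

The :class:`Layout` maps electrode labels to physical ``(column, row)``
grid positions so spatial views can mirror the array geometry.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .errors import ElectrodeLookupError, FormatError, ValidationError

#: canonical column order of a spike table
SPIKE_COLUMNS = ["electrode", "time", "amplitude", "unit", "redundant"]

_SCHEMA_VERSION = "meakit-analog-1"


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Layout:
    """Bijection between electrode labels and (column, row) grid positions.

    Coordinates are 0-based with the origin at the top-left, given in
    ``(column, row)`` order.
    """

    rows: int
    columns: int
    _forward: dict = field(repr=False)

    def __post_init__(self) -> None:
        if self.rows < 1 or self.columns < 1:
            raise ValidationError("layout must have positive rows and columns")
        seen: dict = {}
        for label, (col, row) in self._forward.items():
            if not (0 <= col < self.columns and 0 <= row < self.rows):
                raise ValidationError(
                    f"electrode {label!r} at ({col}, {row}) outside "
                    f"{self.columns}x{self.rows} grid"
                )
            if (col, row) in seen:
                raise ValidationError(
                    f"electrodes {seen[(col, row)]!r} and {label!r} share "
                    f"coordinate ({col}, {row})"
                )
            seen[(col, row)] = label
        object.__setattr__(self, "_inverse", seen)

    @property
    def electrodes(self) -> list:
        """All electrode labels, in insertion order."""
        return list(self._forward)

    def __len__(self) -> int:
        return len(self._forward)

    def __contains__(self, electrode: str) -> bool:
        return electrode in self._forward

    def coordinates_for_electrode(self, electrode: str) -> tuple:
        """Return the ``(column, row)`` position of ``electrode``."""
        try:
            return self._forward[electrode]
        except KeyError:
            raise ElectrodeLookupError(
                f"unknown electrode {electrode!r}; valid labels: "
                f"{', '.join(self._forward)}"
            ) from None

    def electrode_for_coordinates(self, column: int, row: int) -> str:
        """Return the electrode label occupying ``(column, row)``."""
        try:
            return self._inverse[(column, row)]
        except KeyError:
            raise ElectrodeLookupError(
                f"no electrode at ({column}, {row})"
            ) from None


def coordinates_for_electrode(layout: Layout, electrode: str) -> tuple:
    """Module-level convenience wrapper around the layout method."""
    return layout.coordinates_for_electrode(electrode)


def electrode_for_coordinates(layout: Layout, column: int, row: int) -> str:
    """Module-level convenience wrapper around the layout method."""
    return layout.electrode_for_coordinates(column, row)


# Column letters skip "I" to avoid confusion with the digit 1, consistent
# with MCS-style labels such as "F8" on a 12-column array.
_COLUMN_LETTERS = "ABCDEFGHJKLMNOPQRSTUVWXYZ"


def grid_layout(rows: int, columns: int, exclude: set | None = None) -> Layout:
    """Fully-populated rectangular layout with letter+number labels.

    Labels are column letter (A, B, C, ... skipping I) followed by the
    1-based row number; ``exclude`` removes individual ``(column, row)``
    positions.
    """
    if columns > len(_COLUMN_LETTERS):
        raise ValidationError(f"at most {len(_COLUMN_LETTERS)} columns supported")
    exclude = exclude or set()
    forward = {}
    for row in range(rows):
        for col in range(columns):
            if (col, row) in exclude:
                continue
            forward[f"{_COLUMN_LETTERS[col]}{row + 1}"] = (col, row)
    return Layout(rows=rows, columns=columns, _forward=forward)


def _staircase_corners(n: int) -> set:
    """3-2-1 staircase of 6 positions at each corner of an n x n grid."""
    base = [(0, 0), (1, 0), (2, 0), (0, 1), (1, 1), (0, 2)]
    out = set()
    for col, row in base:
        out.add((col, row))
        out.add((n - 1 - col, row))
        out.add((col, n - 1 - row))
        out.add((n - 1 - col, n - 1 - row))
    return out


def default_layout() -> Layout:
    """The 120-electrode layout of a 12 x 12 MEA grid.

    144 grid positions minus a 6-position staircase at each corner leaves
    exactly 120 electrodes, matching a 120-count commercial array with
    100 µm pitch.  Columns are lettered A–M (skipping I), rows 1–12.
    """
    return grid_layout(12, 12, exclude=_staircase_corners(12))


_LAYOUT_REGISTRY = {"mcs120": default_layout}


def register_layout(name: str, factory) -> None:
    """Register a layout factory under ``name`` for lookup by the CLI."""
    _LAYOUT_REGISTRY[name] = factory


def get_layout(name: str) -> Layout:
    """Instantiate a registered layout by name."""
    try:
        return _LAYOUT_REGISTRY[name]()
    except KeyError:
        raise ElectrodeLookupError(
            f"unknown layout {name!r}; registered: {', '.join(_LAYOUT_REGISTRY)}"
        ) from None


# ---------------------------------------------------------------------------
# Analog recordings
# ---------------------------------------------------------------------------

@dataclass
class AnalogRecording:
    """Multichannel extracellular voltage matrix.

    ``data`` is channels x samples in microvolts; ``channel_ids`` carries
    one unique electrode label per row.
    """

    channel_ids: list
    data: np.ndarray
    sampling_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValidationError("data must be a channels x samples matrix")
        self.channel_ids = [str(c) for c in self.channel_ids]
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channel_ids)} channel ids for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            dupes = sorted({c for c in self.channel_ids
                            if self.channel_ids.count(c) > 1})
            raise ValidationError(f"duplicate channel labels: {dupes}")
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds (length ``n_samples``)."""
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def channel_index(self, electrode: str) -> int:
        try:
            return self.channel_ids.index(electrode)
        except ValueError:
            raise ElectrodeLookupError(
                f"electrode {electrode!r} not in recording; channels: "
                f"{', '.join(self.channel_ids)}"
            ) from None

    def channel(self, electrode: str) -> np.ndarray:
        """Single-channel sample vector for ``electrode``."""
        return self.data[self.channel_index(electrode)]


def write_analog(rec: AnalogRecording, path) -> None:
    """Write a recording to the HDF5 analog schema (float32 on disk)."""
    rec.__post_init__()  # re-validate: caller may have mutated fields
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = _SCHEMA_VERSION
        f.attrs["sampling_rate_hz"] = float(rec.sampling_rate)
        f.attrs["start_time_s"] = float(rec.start_time)
        g = f.create_group("analog")
        g.create_dataset("data", data=rec.data.astype(np.float32))
        g.create_dataset(
            "channels",
            data=np.array(rec.channel_ids, dtype=h5py.string_dtype()),
        )


def read_analog(path) -> AnalogRecording:
    """Read a recording written by :func:`write_analog`."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        for name in ("analog/data", "analog/channels"):
            if name not in f:
                raise FormatError(f"{path}: missing dataset '/{name}'")
        for attr in ("sampling_rate_hz", "start_time_s"):
            if attr not in f.attrs:
                raise FormatError(f"{path}: missing root attribute {attr!r}")
        data = np.asarray(f["analog/data"], dtype=np.float64)
        channels = [c.decode() if isinstance(c, bytes) else str(c)
                    for c in f["analog/channels"][()]]
        return AnalogRecording(
            channel_ids=channels,
            data=data,
            sampling_rate=float(f.attrs["sampling_rate_hz"]),
            start_time=float(f.attrs["start_time_s"]),
        )


# ---------------------------------------------------------------------------
# Spike tables
# ---------------------------------------------------------------------------

def spike_table(electrode=(), time=(), amplitude=(), unit=None,
                redundant=None) -> pd.DataFrame:
    """Build a normalized spike table.

    Returns a DataFrame with columns ``electrode, time, amplitude, unit,
    redundant``, globally sorted by time with ties broken by electrode
    label.  ``unit`` defaults to −1 (unsorted) and ``redundant`` to False.
    """
    n = len(time)
    df = pd.DataFrame(
        {
            "electrode": pd.Series(electrode, dtype=str),
            "time": np.asarray(time, dtype=np.float64),
            "amplitude": np.asarray(amplitude, dtype=np.float64),
            "unit": (np.full(n, -1, dtype=np.int64) if unit is None
                     else np.asarray(unit, dtype=np.int64)),
            "redundant": (np.zeros(n, dtype=bool) if redundant is None
                          else np.asarray(redundant, dtype=bool)),
        }
    )
    if n and (df["time"] < 0).any():
        raise ValidationError("spike times must be non-negative")
    df = df.sort_values(["time", "electrode"], kind="mergesort")
    return df.reset_index(drop=True)


def concat_spike_tables(tables) -> pd.DataFrame:
    """Merge several spike tables, restoring the global time sort."""
    tables = [t for t in tables if len(t)]
    if not tables:
        return spike_table()
    df = pd.concat(tables, ignore_index=True)
    df = df.sort_values(["time", "electrode"], kind="mergesort")
    return df.reset_index(drop=True)


def write_spikes(table: pd.DataFrame, path) -> None:
    """Write a spike table as CSV (``electrode,time,amplitude,unit``).

    The in-memory ``redundant`` flag is persisted as an extra column only
    when at least one spike carries it, so files produced from untagged
    tables match the minimal documented dialect.
    """
    cols = ["electrode", "time", "amplitude", "unit"]
    if "redundant" in table.columns and table["redundant"].any():
        cols.append("redundant")
    table.to_csv(path, index=False, columns=cols)


def read_spikes(path) -> pd.DataFrame:
    """Read a spike CSV, returning a time-sorted normalized table.

    A missing ``unit`` column yields −1 for every event.  Non-numeric
    time/amplitude entries raise a :class:`FormatError` naming the
    offending line (1-based, counting the header).
    """
    try:
        raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file with no header") from None
    raw.columns = [c.strip().lower() for c in raw.columns]
    for col in ("electrode", "time", "amplitude"):
        if col not in raw.columns:
            raise FormatError(f"{path}: missing required column {col!r}")

    def _numeric(col: str) -> np.ndarray:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & raw[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise FormatError(
                f"{path}: non-numeric {col} {raw[col][bad.idxmax()]!r} "
                f"on line {line}"
            )
        if vals.isna().any():
            line = int(vals.isna().idxmax()) + 2
            raise FormatError(f"{path}: missing {col} on line {line}")
        return vals.to_numpy()

    if len(raw) == 0:
        return spike_table()
    time = _numeric("time")
    amplitude = _numeric("amplitude")
    unit = (_numeric("unit").astype(np.int64)
            if "unit" in raw.columns else None)
    redundant = None
    if "redundant" in raw.columns:
        redundant = raw["redundant"].str.strip().str.lower().isin(
            ("1", "true", "t", "yes")).to_numpy()
    return spike_table(
        electrode=raw["electrode"].str.strip(),
        time=time,
        amplitude=amplitude,
        unit=unit,
        redundant=redundant,
    )
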