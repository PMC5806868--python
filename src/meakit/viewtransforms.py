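"""Pure data transforms behind the grid, raster, and flashing-spike views.

A minute of one 20 kHz channel holds 1.2 million samples but a plot column
is one pixel wide, so naive decimation (every n-th sample) loses most
spikes.  :func:`minmax_downsample` instead bins the trace into one bin per
pixel and keeps each bin's minimum and maximum, so no extremum — hence no
spike — is ever dropped from the display.

The raster and flashing-spike transforms reorganize a spike table into,
respectively, an ordered list of channel rows and a sequence of
array-shaped intensity frames for animation at reduced playback speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io_layout import Layout

#: slowest supported playback (1/1600 of real time)
MIN_PLAYBACK_FACTOR = 1.0 / 1600.0

#: hard cap on the number of frames a single call may materialize
MAX_FRAMES = 2_000_000


@dataclass
class DownsampleResult:
    """Extrema-preserving decimation of one channel."""

    times: np.ndarray   # seconds
    values: np.ndarray  # µV
    bins: int

    def __len__(self) -> int:
        return self.values.size


def minmax_downsample(signal: np.ndarray, sampling_rate: float,
                      n_p: int, *, start_time: float = 0.0) -> DownsampleResult:
    """Reduce a trace to 2 points per display pixel (bin min and max).

    The n samples are split into ``n_p`` near-equal bins (the first
    ``n mod n_p`` bins get one extra sample); each bin contributes its
    minimum and maximum, emitted in order of temporal occurrence to avoid
    phantom zig-zag artifacts.  If ``n_p >= n`` the raw samples are
    returned unchanged.
    """
    if n_p < 1:
        raise ParameterError(f"n_p must be >= 1, got {n_p}")
    x = np.asarray(signal, dtype=np.float64)
    n = x.size
    if n_p >= n:
        t = start_time + np.arange(n) / sampling_rate
        return DownsampleResult(times=t, values=x.copy(), bins=n_p)

    base, extra = divmod(n, n_p)
    sizes = np.full(n_p, base, dtype=np.int64)
    sizes[:extra] += 1
    edges = np.r_[0, np.cumsum(sizes)]

    idx = np.empty(2 * n_p, dtype=np.int64)
    for b in range(n_p):
        lo, hi = edges[b], edges[b + 1]
        seg = x[lo:hi]
        i_min = lo + int(np.argmin(seg))
        i_max = lo + int(np.argmax(seg))
        first, second = sorted((i_min, i_max))
        idx[2 * b] = first
        idx[2 * b + 1] = second
    return DownsampleResult(
        times=start_time + idx / sampling_rate,
        values=x[idx],
        bins=n_p,
    )


def pixel_duration(span: float, pixels: int) -> float:
    """Recording time represented by one display pixel, in ms.

    Reported to 2 significant figures — e.g. 3 minutes over a 1400-pixel
    monitor is ~130 ms/px, coarse enough to merge spikes within a burst.
    """
    if pixels < 1:
        raise ParameterError("pixels must be >= 1")
    if span <= 0:
        raise ParameterError("span must be positive")
    ms = span / pixels * 1e3
    return float(f"{ms:.2g}")


@dataclass
class RasterView:
    """Channel rows of a raster plot, top to bottom, with spike times."""

    order: list
    spike_times: dict
    scheme: str


_SCHEMES = ("activity", "latency", "fixed")


def order_channels(table: pd.DataFrame, scheme: str = "activity", *,
                   t0: float | None = None,
                   fixed_order: list | None = None) -> RasterView:
    """Order raster rows by activity, by latency from ``t0``, or fixed.

    ``activity`` puts the most active channel on top; ``latency`` sorts by
    each channel's first spike time at or after ``t0`` (channels silent
    after ``t0`` go last); ``fixed`` uses the given label order.  Ties are
    broken by lexicographic label order in every scheme.
    """
    if scheme not in _SCHEMES:
        raise ParameterError(f"unknown scheme {scheme!r}; one of {_SCHEMES}")
    channels = sorted(table["electrode"].unique())
    times = {c: np.sort(table.loc[table["electrode"] == c, "time"].to_numpy())
             for c in channels}

    if scheme == "activity":
        order = sorted(channels, key=lambda c: (-times[c].size, c))
    elif scheme == "latency":
        if t0 is None:
            raise ParameterError("latency ordering requires t0")

        def first_after(c: str) -> tuple:
            after = times[c][times[c] >= t0]
            return (after[0], c) if after.size else (math.inf, c)

        order = sorted(channels, key=first_after)
    else:
        if fixed_order is None:
            raise ParameterError("fixed ordering requires fixed_order")
        missing = set(channels) - set(fixed_order)
        if missing:
            raise ParameterError(
                f"fixed_order lacks channels: {sorted(missing)}"
            )
        order = [c for c in fixed_order if c in times]
    return RasterView(order=order, spike_times=times, scheme=scheme)


@dataclass
class FrameSequence:
    """Time-binned spatial intensity frames mirroring the array geometry.

    ``frames[k][row, col]`` counts flash onsets in frame ``k`` (plus any
    decayed contribution from earlier frames if ``decay`` was requested);
    ``frame_span`` is the recording time covered by one frame.
    """

    frames: np.ndarray  # n_frames x rows x columns
    frame_span: float   # seconds of recording time
    playback_factor: float
    t_start: float
    onsets: np.ndarray = field(default=None, repr=False)  # undecayed counts

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def spikes_to_frames(table: pd.DataFrame, layout: Layout,
                     t_start: float, t_end: float, *,
                     frame_rate: float = 25.0,
                     playback_factor: float = 1.0,
                     decay_frames: float = 0.0) -> FrameSequence:
    """Bin spikes into animation frames at the electrode grid positions.

    One display frame at ``frame_rate`` fps covers
    ``playback_factor / frame_rate`` seconds of recording (25 µs per frame
    at 25 fps and 1/1600 playback).  Each spike in ``[t_start, t_end)``
    increments its electrode's cell in the frame containing its time, so
    total onset intensity equals the spike count in the window.  A positive
    ``decay_frames`` adds an exponential afterglow for display smoothness;
    the ``onsets`` array always keeps the undecayed counts.
    """
    if not t_start < t_end:
        raise ParameterError("need t_start < t_end")
    if not MIN_PLAYBACK_FACTOR <= playback_factor <= 1.0:
        raise ParameterError(
            f"playback_factor must be in [1/1600, 1], got {playback_factor}"
        )
    frame_span = playback_factor / frame_rate
    n_frames = int(np.ceil((t_end - t_start) / frame_span))
    if n_frames > MAX_FRAMES:
        raise ParameterError(
            f"{n_frames} frames requested (cap {MAX_FRAMES}); shorten the "
            f"interval or raise playback_factor"
        )
    onsets = np.zeros((n_frames, layout.rows, layout.columns))

    sel = table[(table["time"] >= t_start) & (table["time"] < t_end)]
    for electrode, times in sel.groupby("electrode")["time"]:
        col, row = layout.coordinates_for_electrode(electrode)
        k = np.floor((times.to_numpy() - t_start) / frame_span).astype(np.int64)
        k = np.minimum(k, n_frames - 1)  # guard float edge at t_end
        np.add.at(onsets, (k, row, col), 1.0)

    frames = onsets
    if decay_frames > 0:
        frames = np.empty_like(onsets)
        alpha = float(np.exp(-1.0 / decay_frames))
        acc = np.zeros((layout.rows, layout.columns))
        for k in range(n_frames):
            acc = acc * alpha + onsets[k]
            frames[k] = acc
    return FrameSequence(
        frames=frames,
        frame_span=frame_span,
        playback_factor=playback_factor,
        t_start=t_start,
        onsets=onsets,
    )
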