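"""Spike detection, waveform extraction, sorting, and redundancy tagging.

Detection thresholds each channel at a multiple (default 6) of its robust
noise s.d.; an event's timestamp is placed at the signal extremum following
the threshold crossing, which gives stable alignment for averaging.
Sorting follows the classic pipeline: extract 3 ms waveforms around each
event, project onto a few principal components, and cluster densities with
OPTICS; events in no dense region are labeled −1.

A spike from one neuron is often co-detected on neighboring electrodes of
a 100 µm-pitch array.  :func:`tag_redundant` flags those duplicates, keeping
the largest-amplitude detection as the primary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import OPTICS
from sklearn.decomposition import PCA

from .errors import ParameterError
from .io_layout import spike_table

_POLARITIES = ("negative", "positive", "both")


@dataclass(frozen=True)
class DetectionConfig:
    """Threshold-detector parameters.

    threshold_multiplier
        Detection threshold as a multiple of the per-channel noise s.d.
    polarity
        Which deflections count: ``negative`` (default; somatic
        extracellular spikes are dominantly negative), ``positive``, or
        ``both``.  ``both`` will also fire on the re-polarization phase of
        large spikes — a known failure mode worth reproducing when
        evaluating detectors.
    dead_time
        Minimum interval between events on one channel, ms.
    waveform_window
        Length of the extracted waveform around each event, ms, split
        symmetrically before/after the event.
    """

    threshold_multiplier: float = 6.0
    polarity: str = "negative"
    dead_time: float = 1.0
    waveform_window: float = 3.0

    def __post_init__(self) -> None:
        if self.threshold_multiplier <= 0:
            raise ParameterError("threshold_multiplier must be > 0")
        if self.dead_time <= 0 or self.waveform_window <= 0:
            raise ParameterError("dead_time and waveform_window must be > 0")
        if self.polarity not in _POLARITIES:
            raise ParameterError(
                f"polarity must be one of {_POLARITIES}, got {self.polarity!r}"
            )


def detect_spikes(signal: np.ndarray, sampling_rate: float,
                  cfg: DetectionConfig | None = None, *,
                  sigma: float, electrode: str = "",
                  start_time: float = 0.0) -> pd.DataFrame:
    """Threshold-detect spikes on one channel.

    Returns a spike table whose timestamps sit at the local extremum of
    each crossing; consecutive events are at least ``cfg.dead_time`` apart
    and every reported amplitude is the signal value at the reported time.
    """
    cfg = cfg or DetectionConfig()
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    x = np.asarray(signal, dtype=np.float64)
    threshold = cfg.threshold_multiplier * sigma
    dead = max(int(round(cfg.dead_time * 1e-3 * sampling_rate)), 1)

    if cfg.polarity == "negative":
        over = x < -threshold
    elif cfg.polarity == "positive":
        over = x > threshold
    else:
        over = np.abs(x) > threshold
    if not over.any():
        return spike_table()

    crossings = np.flatnonzero(over & ~np.r_[False, over[:-1]])
    event_idx: list[int] = []
    last = -dead - 1
    for c in crossings:
        if c <= last + dead and event_idx:
            # still inside the dead-time window of the previous event
            continue
        stop = min(c + dead + 1, x.size)
        seg = x[c:stop]
        if cfg.polarity == "negative":
            k = int(np.argmin(seg))
        elif cfg.polarity == "positive":
            k = int(np.argmax(seg))
        else:
            k = int(np.argmax(np.abs(seg)))
        idx = c + k
        if event_idx and idx - event_idx[-1] < dead:
            continue
        event_idx.append(idx)
        last = idx

    event_idx = np.asarray(event_idx, dtype=np.int64)
    return spike_table(
        electrode=[electrode] * event_idx.size,
        time=start_time + event_idx / sampling_rate,
        amplitude=x[event_idx],
    )


@dataclass
class WaveformSet:
    """Per-electrode stack of event-aligned waveform snippets."""

    electrode: str
    events: np.ndarray          # n_events x n_samples, µV
    alignment_times: np.ndarray  # seconds, strictly increasing
    sampling_rate: float
    n_dropped: int = 0          # events whose window left the record

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    @property
    def n_samples(self) -> int:
        return self.events.shape[1]


def extract_waveforms(signal: np.ndarray, sampling_rate: float,
                      times: np.ndarray, cfg: DetectionConfig | None = None,
                      *, electrode: str = "",
                      start_time: float = 0.0) -> WaveformSet:
    """Cut a fixed window around each spike time.

    The window is ``cfg.waveform_window`` ms long, split symmetrically
    around the event (``round(window * rate) + 1`` samples).  Events whose
    window would cross the record boundary are dropped and counted in
    ``n_dropped``.
    """
    cfg = cfg or DetectionConfig()
    x = np.asarray(signal, dtype=np.float64)
    times = np.sort(np.asarray(times, dtype=np.float64))
    n = int(round(cfg.waveform_window * 1e-3 * sampling_rate))
    pre, post = n // 2, n - n // 2

    centers = np.round((times - start_time) * sampling_rate).astype(np.int64)
    ok = (centers - pre >= 0) & (centers + post < x.size)
    kept = centers[ok]
    events = np.empty((kept.size, n + 1), dtype=np.float64)
    for i, c in enumerate(kept):
        events[i] = x[c - pre:c + post + 1]
    return WaveformSet(
        electrode=electrode,
        events=events,
        alignment_times=times[ok],
        sampling_rate=sampling_rate,
        n_dropped=int((~ok).sum()),
    )


@dataclass(frozen=True)
class SortConfig:
    """PCA + OPTICS sorting parameters.

    The minimum cluster size is ``max(5, min_cluster_fraction * n_events)``;
    ``steepness`` is the OPTICS xi parameter controlling how sharp a
    reachability drop must be to open a cluster.  ``min_samples_fraction``
    sets the OPTICS core-neighborhood size (floor 10): smoothing the
    reachability over ~10% of the events keeps a single tight cluster from
    fragmenting into spurious sub-clusters.
    """

    n_components: int = 3
    min_cluster_fraction: float = 0.05
    steepness: float = 0.05
    min_samples_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ParameterError("n_components must be >= 1")
        if not 0 < self.min_cluster_fraction < 1:
            raise ParameterError("min_cluster_fraction must be in (0, 1)")

    def min_cluster_size(self, n_events: int) -> int:
        return max(5, int(np.ceil(self.min_cluster_fraction * n_events)))

    def min_samples(self, n_events: int) -> int:
        return max(10, int(np.ceil(self.min_samples_fraction * n_events)))


def project_waveforms(wfs: WaveformSet, cfg: SortConfig | None = None) -> np.ndarray:
    """PCA projection of the waveforms (n_events x n_components)."""
    cfg = cfg or SortConfig()
    n_comp = min(cfg.n_components, wfs.n_events, wfs.n_samples)
    return PCA(n_components=n_comp, svd_solver="full").fit_transform(wfs.events)


def sort_spikes(wfs: WaveformSet, cfg: SortConfig | None = None) -> np.ndarray:
    """Cluster waveforms into putative units.

    Returns one integer label per event: 0, 1, ... for clusters in order
    of first appearance, −1 for density-noise events.  Deterministic for
    fixed inputs and config.
    """
    cfg = cfg or SortConfig()
    min_size = cfg.min_cluster_size(wfs.n_events)
    if wfs.n_events < max(2, min_size):
        warnings.warn(
            f"{wfs.n_events} events is below the minimum cluster size "
            f"{min_size}; all events labeled -1", stacklevel=2,
        )
        return np.full(wfs.n_events, -1, dtype=np.int64)
    feats = project_waveforms(wfs, cfg)
    labels = OPTICS(
        min_samples=min(cfg.min_samples(wfs.n_events), wfs.n_events),
        min_cluster_size=min_size,
        xi=cfg.steepness,
        cluster_method="xi",
    ).fit_predict(feats)
    return _relabel_by_appearance(labels)


def _relabel_by_appearance(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster ids by order of first occurrence; −1 is preserved."""
    out = np.full(labels.shape, -1, dtype=np.int64)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab == -1:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def tag_redundant(table: pd.DataFrame, window: float = 0.7) -> pd.DataFrame:
    """Flag multi-electrode co-detections of the same spike.

    Any spike that has, within ``window`` ms on a *different* electrode,
    a partner with larger absolute amplitude is marked ``redundant``; the
    largest-amplitude member of each coincident group stays primary.
    Ties are broken by earlier time, then lexicographic electrode label,
    so the outcome is independent of input row order.
    """
    table = table.sort_values(["time", "electrode"], kind="mergesort")
    table = table.reset_index(drop=True)
    t = table["time"].to_numpy()
    amp = np.abs(table["amplitude"].to_numpy())
    elec = table["electrode"].to_numpy()
    w = window * 1e-3
    flags = np.zeros(len(table), dtype=bool)

    lo = 0
    for i in range(len(table)):
        while t[i] - t[lo] > w:
            lo += 1
        j = lo
        while j < len(table) and t[j] - t[i] <= w:
            if j != i and elec[j] != elec[i]:
                # does j dominate i?  (|amp| desc, time asc, label asc)
                if (amp[j], -t[j], _neg_label(elec[j])) > \
                   (amp[i], -t[i], _neg_label(elec[i])):
                    flags[i] = True
                    break
            j += 1
    out = table.copy()
    out["redundant"] = flags
    return out


def _neg_label(label: str) -> tuple:
    """Order-reversing key so that lexicographically smaller labels win."""
    return tuple(-ord(c) for c in label)
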