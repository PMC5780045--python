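"""Core data containers shared across the pipeline.

All time quantities are in milliseconds unless a name says otherwise;
sampling rates are in Hz.  Trial windows use half-open sample indexing
``[start, end)`` with the stimulus-onset sample at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

EVENT_COLUMNS = ("onset", "block", "trial_in_block", "condition", "correct")


@dataclass(frozen=True)
class Channel:
    """One recorded contact.

    role is one of ``stn-macro``, ``anterior-pfc``, ``lateral-pfc``,
    ``micro`` (or a derived role such as ``lateral-pfc-bipolar``); group
    names the referencing group the channel belongs to.
    """

    name: str
    role: str
    group: str


@dataclass
class Recording:
    """Continuous multichannel voltage data."""

    data: np.ndarray          # (n_channels, n_samples), volts (arbitrary units)
    fs: float                 # Hz
    channels: list[Channel]
    aux: dict = field(default_factory=dict)   # ground-truth extras (e.g. oscillator phase)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError("channel count mismatch between data and metadata")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.fs * 1000.0

    def channel_index(self, name: str) -> int:
        for i, c in enumerate(self.channels):
            if c.name == name:
                return i
        raise KeyError(f"no channel named {name!r}")

    def group_indices(self, group: str) -> list[int]:
        return [i for i, c in enumerate(self.channels) if c.group == group]


@dataclass
class EpochSet:
    """Trial-aligned epochs cut from a Recording, with edge buffers.

    ``data`` covers ``window[0] - buffer .. window[1] + buffer`` around each
    onset; the buffer exists only to protect the spectral transform from
    edge effects and is discarded afterwards.
    """

    data: np.ndarray          # (n_trials, n_channels, n_samples) incl. buffers
    window: tuple[float, float]   # analysis window, ms relative to onset
    buffer: float             # ms on each side
    fs: float
    channels: list[Channel]
    trial_index: np.ndarray   # row index into the source EventTable
    rejected: np.ndarray      # bool per trial
    reject_reason: dict[int, str] = field(default_factory=dict)
    events: pd.DataFrame | None = None   # the matching EventTable rows

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Time axis of ``data`` in ms (buffers included)."""
        start = self.window[0] - self.buffer
        n = self.data.shape[2]
        return start + np.arange(n) * 1000.0 / self.fs

    def good_mask(self) -> np.ndarray:
        return ~self.rejected


@dataclass
class TimeFreqTensor:
    """trials x frequencies x time array of spectral values for one channel.

    kind is one of ``complex``, ``power``, ``normpower`` (percent change
    from baseline) or ``phase`` (radians in (-pi, pi]).  ``analysis_window``
    records the nominal epoch window; ``times`` may start earlier when a
    baseline margin was kept from the buffer.
    """

    values: np.ndarray        # (n_trials, n_freqs, n_times)
    freqs: np.ndarray         # Hz
    times: np.ndarray         # ms relative to onset
    kind: str
    channel: str = ""
    trial_index: np.ndarray | None = None
    analysis_window: tuple[float, float] | None = None
    zero_magnitude: np.ndarray | None = None   # flags for phase-of-zero samples

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("TimeFreqTensor.values must be 3-D")
        if self.values.shape[1] != len(self.freqs):
            raise ValueError("frequency axis mismatch")
        if self.values.shape[2] != len(self.times):
            raise ValueError("time axis mismatch")

    @property
    def analysis_duration_ms(self) -> float:
        """Span of the analysis window covered by the time axis."""
        lo, hi = self.analysis_window if self.analysis_window is not None else (
            self.times[0], self.times[-1] + (self.times[1] - self.times[0]))
        return float(hi - lo)

    def time_slice(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask over the time axis for ``lo <= t < hi`` (ms)."""
        return (self.times >= lo) & (self.times < hi)

    def crop(self, lo: float, hi: float) -> "TimeFreqTensor":
        m = self.time_slice(lo, hi)
        if not m.any():
            raise ValueError(f"window ({lo}, {hi}) ms does not intersect time axis")
        return TimeFreqTensor(
            values=self.values[:, :, m], freqs=self.freqs, times=self.times[m],
            kind=self.kind, channel=self.channel, trial_index=self.trial_index,
            analysis_window=(lo, hi))


@dataclass
class SpikeTrain:
    """Spike times for one neuronal cluster (possibly multi-unit)."""

    spike_times: np.ndarray   # ms, absolute recording time, sorted
    cluster_id: str = "c0"
    depth_pct: float | None = None    # relative depth between nucleus borders
    paired_macro: str | None = None   # name of the associated macro channel

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size and np.any(np.diff(self.spike_times) < 0):
            raise ValueError("spike times must be sorted")
        if self.spike_times.size and self.spike_times[0] < 0:
            raise ValueError("spike times must be non-negative")
        if self.depth_pct is not None and not (0.0 <= self.depth_pct <= 100.0):
            raise ValueError("depth_pct must lie in [0, 100]")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


def validate_event_table(events: pd.DataFrame) -> pd.DataFrame:
    """Check the EventTable schema and invariants; returns the frame."""
    for col in EVENT_COLUMNS:
        if col not in events.columns:
            raise ValueError(f"event table missing column {col!r}")
    if len(events) == 0:
        return events
    onsets = events["onset"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("onsets must be strictly increasing")
    bad = set(events["condition"].unique()) - {"target", "distractor"}
    if bad:
        raise ValueError(f"unknown condition labels: {bad}")
    return events


def empty_event_table() -> pd.DataFrame:
    return pd.DataFrame({
        "onset": pd.Series(dtype=float),
        "block": pd.Series(dtype=int),
        "trial_in_block": pd.Series(dtype=int),
        "condition": pd.Series(dtype=str),
        "correct": pd.Series(dtype=bool),
    })


def make_channels(spec: Sequence[tuple[str, str, str] | Channel]) -> list[Channel]:
    out = []
    for item in spec:
        out.append(item if isinstance(item, Channel) else Channel(*item))
    return out
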