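"""Filtering, referencing and epoching of continuous recordings.

Filtering is zero-phase (forward-backward) so event latencies are not
shifted.  The stage order is filter -> downsample -> reference; epoching
uses half-open sample windows with the onset sample at t = 0.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .types import Channel, EpochSet, Recording, validate_event_table

__all__ = [
    "bandpass_notch_downsample", "rereference_common_average",
    "rereference_bipolar", "epoch", "reject_artifact_trials",
]


def bandpass_notch_downsample(rec: Recording, low: float = 1.0,
                              high: float = 500.0, notch: float = 60.0,
                              target_fs: float = 1000.0,
                              notch_q: float = 30.0) -> Recording:
    """Zero-phase bandpass + notch, then polyphase resampling to target_fs.

    If ``high`` reaches the input Nyquist frequency it is clipped to
    0.45 * fs.  Upsampling is refused.
    """
    if target_fs > rec.fs:
        raise ValueError("target_fs exceeds input rate; upsampling not supported")
    nyq = rec.fs / 2.0
    if high >= nyq:
        high = 0.45 * rec.fs
    if low >= high:
        raise ValueError("low cutoff must be below high cutoff")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    if 0 < notch < nyq:
        b, a = signal.iirnotch(notch, notch_q, fs=rec.fs)
        data = signal.filtfilt(b, a, data, axis=1)
    if target_fs != rec.fs:
        frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator, axis=1)
    return Recording(data=np.ascontiguousarray(data), fs=float(target_fs),
                     channels=list(rec.channels), aux=dict(rec.aux))


def rereference_common_average(rec: Recording, group: str) -> Recording:
    """Subtract the instantaneous mean of a channel group from its members."""
    idx = rec.group_indices(group)
    if len(idx) < 2:
        raise ValueError(f"group {group!r} needs at least 2 channels")
    data = rec.data.copy()
    data[idx] -= data[idx].mean(axis=0, keepdims=True)
    return Recording(data=data, fs=rec.fs, channels=list(rec.channels),
                     aux=dict(rec.aux))


def rereference_bipolar(rec: Recording, strip: list[str]) -> Recording:
    """n ordered contacts -> n-1 adjacent-difference channels.

    Non-strip channels are passed through unchanged; bipolar channel names
    record both parents as ``a-b``.
    """
    if len(strip) < 2:
        raise ValueError("strip needs at least 2 contacts")
    if len(set(strip)) != len(strip):
        raise ValueError("duplicate contacts in strip")
    idx = [rec.channel_index(name) for name in strip]
    strip_set = set(strip)
    out_data, out_ch = [], []
    for i, ch in enumerate(rec.channels):
        if ch.name not in strip_set:
            out_data.append(rec.data[i])
            out_ch.append(ch)
    base = rec.channels[idx[0]]
    for a, b in zip(idx[:-1], idx[1:]):
        out_data.append(rec.data[a] - rec.data[b])
        out_ch.append(Channel(f"{rec.channels[a].name}-{rec.channels[b].name}",
                              f"{base.role}-bipolar", base.group))
    return Recording(data=np.asarray(out_data), fs=rec.fs, channels=out_ch,
                     aux=dict(rec.aux))


def epoch(rec: Recording, events: pd.DataFrame,
          window: tuple[float, float] = (-250.0, 1250.0),
          buffer: float = 1000.0) -> EpochSet:
    """Cut buffered trial epochs around each event onset.

    Trials whose buffered window falls outside the recording are flagged
    rejected (reason logged) rather than raising.
    """
    validate_event_table(events)
    n_trials = len(events)
    dt = 1000.0 / rec.fs
    n_samp = int(round((window[1] - window[0] + 2 * buffer) / dt))
    data = np.zeros((n_trials, rec.data.shape[0], n_samp))
    rejected = np.zeros(n_trials, dtype=bool)
    reasons: dict[int, str] = {}
    onsets = events["onset"].to_numpy(dtype=float)
    for t in range(n_trials):
        start = int(round((onsets[t] + window[0] - buffer) / dt))
        stop = start + n_samp
        if start < 0 or stop > rec.n_samples:
            rejected[t] = True
            reasons[t] = "window out of recording bounds"
            continue
        data[t] = rec.data[:, start:stop]
    return EpochSet(data=data, window=window, buffer=buffer, fs=rec.fs,
                    channels=list(rec.channels),
                    trial_index=np.asarray(events.index),
                    rejected=rejected, reject_reason=reasons,
                    events=events.reset_index(drop=True))


def reject_artifact_trials(epochs: EpochSet, z_thresh: float = 6.0) -> EpochSet:
    """Flag trials whose peak |amplitude| is an extreme outlier.

    Per channel, the distribution of per-trial peak absolute amplitudes
    (within the analysis window, buffers excluded) is summarised by its
    median and a robust SD (1.4826 * MAD); a trial is flagged when any
    channel's peak exceeds median + z_thresh robust-SDs.  Flags only —
    data are retained.
    """
    if epochs.n_trials < 2:
        raise ValueError("need at least 2 trials")
    times = epochs.times
    m = (times >= epochs.window[0]) & (times < epochs.window[1])
    peaks = np.abs(epochs.data[:, :, m]).max(axis=2)          # trials x channels
    med = np.median(peaks, axis=0)
    mad = np.median(np.abs(peaks - med), axis=0)
    robust_sd = 1.4826 * mad
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(robust_sd > 0, (peaks - med) / robust_sd, 0.0)
    bad = np.isfinite(z).all(axis=1) & (z > z_thresh).any(axis=1)
    rejected = epochs.rejected | bad
    reasons = dict(epochs.reject_reason)
    for t in np.flatnonzero(bad):
        reasons.setdefault(int(t), f"amplitude outlier (z > {z_thresh})")
    return EpochSet(data=epochs.data, window=epochs.window, buffer=epochs.buffer,
                    fs=epochs.fs, channels=epochs.channels,
                    trial_index=epochs.trial_index, rejected=rejected,
                    reject_reason=reasons, events=epochs.events)
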