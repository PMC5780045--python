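"""Morlet wavelet decomposition, percent-change normalization, bands.

Wavelet: complex exponential times a Gaussian with sigma_t =
wavenumber / (2*pi*f), truncated at +/-4 sigma.  Amplitude scaling is
chosen so a unit-amplitude sinusoid at a grid frequency yields unit peak
coefficient magnitude (hence power 1).  Convolution runs over the
buffered epoch; buffers are cropped afterwards, optionally keeping a
pre-onset margin so the 500 ms baseline is available even when the
analysis window starts at -250 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .types import EpochSet, TimeFreqTensor

__all__ = [
    "WaveletBank", "build_wavelet_bank", "wavelet_transform", "power",
    "normalize_to_baseline", "band_average", "instantaneous_phase",
    "THETA_BAND", "BETA_BAND",
]

THETA_BAND = (2.0, 8.0)
BETA_BAND = (15.0, 30.0)


@dataclass(frozen=True)
class WaveletBank:
    """Logarithmically spaced Morlet center frequencies."""

    frequencies: np.ndarray = field(repr=False)
    wavenumber: float = 6.0
    scales_per_octave: int = 8

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", f)

    def __len__(self) -> int:
        return len(self.frequencies)

    def sigma_t(self, f: float) -> float:
        """Gaussian time SD in seconds at frequency f."""
        return self.wavenumber / (2.0 * np.pi * f)


def build_wavelet_bank(fmin: float = 2.0, scales_per_octave: int = 8,
                       n: int = 47, wavenumber: float = 6.0) -> WaveletBank:
    """f_k = fmin * 2**(k / scales_per_octave), k = 0..n-1.

    Defaults give 47 frequencies from 2 Hz to ~107.6 Hz.
    """
    if fmin <= 0 or n < 1:
        raise ValueError("fmin must be positive and n >= 1")
    k = np.arange(n)
    freqs = fmin * 2.0 ** (k / scales_per_octave)
    return WaveletBank(frequencies=freqs, wavenumber=wavenumber,
                       scales_per_octave=scales_per_octave)


def _morlet_kernel(f: float, fs: float, wavenumber: float) -> np.ndarray:
    sigma = wavenumber / (2.0 * np.pi * f)          # seconds
    half = int(np.ceil(4.0 * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    kernel = np.exp(2j * np.pi * f * t) * np.exp(-t**2 / (2.0 * sigma**2))
    # unit sinusoid at f -> unit |coefficient|
    kernel *= 2.0 / (sigma * np.sqrt(2.0 * np.pi) * fs)
    return kernel


def wavelet_transform(epochs: EpochSet, bank: WaveletBank, channel=None,
                      baseline_margin: float = 250.0,
                      dtype=np.complex64) -> TimeFreqTensor:
    """Complex Morlet coefficients for one channel of a buffered EpochSet.

    The output time axis runs from ``window[0] - baseline_margin`` to
    ``window[1]``; the margin is taken from the edge buffer so baseline
    statistics over the 500 ms pre-onset period remain computable while
    the nominal analysis window stays ``epochs.window``.
    """
    if np.max(bank.frequencies) > epochs.fs / 2.0:
        raise ValueError("bank contains frequencies above Nyquist")
    if baseline_margin > epochs.buffer:
        raise ValueError("baseline_margin cannot exceed the buffer")
    if isinstance(channel, str):
        ch_idx = [c.name for c in epochs.channels].index(channel)
        ch_name = channel
    else:
        ch_idx = 0 if channel is None else int(channel)
        ch_name = epochs.channels[ch_idx].name if epochs.channels else str(ch_idx)

    x = epochs.data[:, ch_idx, :]                      # trials x buffered samples
    times = epochs.times
    keep = (times >= epochs.window[0] - baseline_margin) & (times < epochs.window[1])
    n_keep = int(keep.sum())
    out = np.empty((x.shape[0], len(bank), n_keep), dtype=dtype)
    for k, f in enumerate(bank.frequencies):
        kernel = _morlet_kernel(f, epochs.fs, bank.wavenumber)
        coeff = fftconvolve(x, kernel[np.newaxis, :], mode="same", axes=1)
        out[:, k, :] = coeff[:, keep]
    return TimeFreqTensor(values=out, freqs=bank.frequencies.copy(),
                          times=times[keep].copy(), kind="complex",
                          channel=ch_name,
                          trial_index=epochs.trial_index.copy(),
                          analysis_window=epochs.window)


def power(tensor: TimeFreqTensor) -> TimeFreqTensor:
    """Squared coefficient magnitude."""
    if tensor.kind != "complex":
        raise ValueError("power() expects a complex tensor")
    return TimeFreqTensor(values=np.abs(tensor.values).astype(np.float64) ** 2,
                          freqs=tensor.freqs, times=tensor.times, kind="power",
                          channel=tensor.channel, trial_index=tensor.trial_index,
                          analysis_window=tensor.analysis_window)


def normalize_to_baseline(power_t: TimeFreqTensor,
                          baseline: tuple[float, float] = (-500.0, 0.0),
                          per_trial: bool = False) -> TimeFreqTensor:
    """Percent change from the pre-stimulus baseline mean.

    value = 100 * (P - Pbar_base) / Pbar_base per frequency.  By default
    Pbar_base pools the baseline mean across trials (per channel and
    frequency); ``per_trial=True`` uses each trial's own baseline mean
    instead.  The pooled default is deliberate: a single 500 ms baseline
    holds only a handful of independent samples of a narrowband process,
    and dividing by that noisy estimate inflates post-stimulus percent
    change by tens of percent (Jensen bias), destroying vs-baseline
    calibration.
    """
    if power_t.kind != "power":
        raise ValueError("normalize_to_baseline expects kind='power'")
    m = power_t.time_slice(*baseline)
    if not m.any():
        raise ValueError("baseline window outside tensor time axis")
    base = power_t.values[:, :, m].mean(axis=2, keepdims=True)   # trials x F x 1
    if not per_trial:
        base = base.mean(axis=0, keepdims=True)
    base = np.asarray(base, dtype=np.float64)
    if np.any(base <= 0):
        raise ValueError("degenerate input: zero baseline power")
    vals = 100.0 * (power_t.values - base) / base
    return TimeFreqTensor(values=vals, freqs=power_t.freqs, times=power_t.times,
                          kind="normpower", channel=power_t.channel,
                          trial_index=power_t.trial_index,
                          analysis_window=power_t.analysis_window)


def band_average(tensor: TimeFreqTensor, band: tuple[float, float]) -> np.ndarray:
    """Unweighted mean over grid frequencies in [band_lo, band_hi].

    Returns a trials x time array sharing the tensor's time axis.
    """
    lo, hi = band
    if lo > hi:
        raise ValueError("band bounds out of order")
    m = (tensor.freqs >= lo) & (tensor.freqs <= hi)
    if not m.any():
        raise ValueError(f"band ({lo}, {hi}) Hz does not intersect the bank")
    return tensor.values[:, m, :].mean(axis=1)


def instantaneous_phase(tensor: TimeFreqTensor,
                        zero_tol: float = 0.0) -> TimeFreqTensor:
    """Coefficient angle in (-pi, pi]; magnitude-zero samples are flagged."""
    if tensor.kind != "complex":
        raise ValueError("instantaneous_phase expects a complex tensor")
    vals = np.angle(tensor.values.astype(np.complex128))
    # np.angle returns [-pi, pi]; fold -pi onto pi for the half-open range
    vals[vals == -np.pi] = np.pi
    zero = np.abs(tensor.values) <= zero_tol
    out = TimeFreqTensor(values=vals, freqs=tensor.freqs, times=tensor.times,
                         kind="phase", channel=tensor.channel,
                         trial_index=tensor.trial_index,
                         analysis_window=tensor.analysis_window)
    out.zero_magnitude = zero
    return out
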