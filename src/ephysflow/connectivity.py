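"""Trial-wise sliding-window cortico-subcortical coupling measures.

Coherence per trial/frequency/window: |<Wa Wb*>| / sqrt(<|Wa|^2><|Wb|^2>)
over 250 ms sliding windows (the square root in the denominator keeps the
statistic in [0, 1]).  Phase synchrony drops magnitude: the window-mean of
the unit cross-spectrum.  Power correlation is the across-trial Spearman
rho of 250 ms-smoothed power, per time-frequency point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .perm_stats import ClusterResult, StatMap, cluster_correct, \
    label_permutation_test
from .types import TimeFreqTensor

__all__ = [
    "CoherencePanel", "sliding_coherence", "normalize_coherence",
    "phase_synchrony", "power_correlation", "coherence_condition_contrast",
]


@dataclass
class CoherencePanel:
    """trials x frequencies x window-centers coupling values in [0, 1]."""

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray          # window-center times, ms
    kind: str                  # coherence | phase_synchrony | normalized variants
    window_ms: float = 250.0
    step_ms: float = 1.0

    def time_slice(self, lo: float, hi: float) -> np.ndarray:
        return (self.times >= lo) & (self.times < hi)


def _check_aligned(a: TimeFreqTensor, b: TimeFreqTensor) -> None:
    if a.values.shape != b.values.shape:
        raise ValueError("tensors must share trial/freq/time axes")
    if not (np.allclose(a.freqs, b.freqs) and np.allclose(a.times, b.times)):
        raise ValueError("tensors must share frequency and time axes")


def _window_params(times: np.ndarray, window: float, step: float):
    dt = float(np.median(np.diff(times)))
    w = int(round(window / dt))
    if w > times.size:
        raise ValueError("sliding window exceeds the epoch span")
    s = max(int(round(step / dt)), 1)
    centers = times[:times.size - w + 1][::s] + (w - 1) * dt / 2.0
    return w, s, centers


def _moving_mean(x: np.ndarray, w: int, s: int) -> np.ndarray:
    """Mean over length-w windows starting every s samples (last axis)."""
    cs = np.cumsum(x, axis=-1, dtype=x.dtype if np.iscomplexobj(x) else np.float64)
    cs = np.concatenate([np.zeros(x.shape[:-1] + (1,), dtype=cs.dtype), cs], axis=-1)
    out = (cs[..., w:] - cs[..., :-w]) / w
    return out[..., ::s]


def sliding_coherence(complex_a: TimeFreqTensor, complex_b: TimeFreqTensor,
                      window: float = 250.0, step: float = 1.0) -> CoherencePanel:
    """Magnitude coherence over sliding windows, per trial and frequency."""
    if complex_a.kind != "complex" or complex_b.kind != "complex":
        raise ValueError("sliding_coherence expects complex tensors")
    _check_aligned(complex_a, complex_b)
    wa = complex_a.values.astype(np.complex128)
    wb = complex_b.values.astype(np.complex128)
    w, s, centers = _window_params(complex_a.times, window, step)
    cross = _moving_mean(wa * np.conj(wb), w, s)
    pa = _moving_mean(np.abs(wa) ** 2, w, s)
    pb = _moving_mean(np.abs(wb) ** 2, w, s)
    denom = np.sqrt(pa * pb)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(denom > 0, np.abs(cross) / denom, 0.0)
    return CoherencePanel(values=np.clip(coh, 0.0, 1.0), freqs=complex_a.freqs,
                          times=centers, kind="coherence",
                          window_ms=window, step_ms=step)


def phase_synchrony(complex_a: TimeFreqTensor, complex_b: TimeFreqTensor,
                    window: float = 250.0, step: float = 1.0) -> CoherencePanel:
    """Window-resolved phase-locking of the cross-spectrum angle.

    The unit-magnitude cross-spectrum exp(i*(phi_a - phi_b)) is averaged
    over each window; its magnitude is amplitude-insensitive synchrony.
    """
    if complex_a.kind != "complex" or complex_b.kind != "complex":
        raise ValueError("phase_synchrony expects complex tensors")
    _check_aligned(complex_a, complex_b)
    cross = complex_a.values.astype(np.complex128) * \
        np.conj(complex_b.values.astype(np.complex128))
    mag = np.abs(cross)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(mag > 0, cross / mag, 0.0)
    w, s, centers = _window_params(complex_a.times, window, step)
    plv = np.abs(_moving_mean(unit, w, s))
    return CoherencePanel(values=np.clip(plv, 0.0, 1.0), freqs=complex_a.freqs,
                          times=centers, kind="phase_synchrony",
                          window_ms=window, step_ms=step)


def normalize_coherence(panel: CoherencePanel,
                        baseline: tuple[float, float] = (-500.0, 0.0)) -> CoherencePanel:
    """Percent change from the baseline-window mean, per trial and frequency."""
    m = panel.time_slice(*baseline)
    if not m.any():
        raise ValueError("baseline window outside panel time axis")
    base = panel.values[:, :, m].mean(axis=2, keepdims=True)
    if np.any(base <= 0):
        raise ValueError("zero baseline coherence")
    vals = 100.0 * (panel.values - base) / base
    return CoherencePanel(values=vals, freqs=panel.freqs, times=panel.times,
                          kind=f"normalized_{panel.kind}",
                          window_ms=panel.window_ms, step_ms=panel.step_ms)


def power_correlation(power_a: TimeFreqTensor, power_b: TimeFreqTensor,
                      smooth: float = 250.0) -> np.ndarray:
    """Across-trial Spearman correlation of smoothed power, per (f, t).

    Each trial's power series is convolved with a ``smooth``-ms boxcar;
    points where either channel is constant across trials are NaN.
    """
    if power_a.values.shape != power_b.values.shape:
        raise ValueError("tensors must share trial/freq/time axes")
    n_trials = power_a.values.shape[0]
    if n_trials < 10:
        raise ValueError("need at least 10 trials")
    dt = float(np.median(np.diff(power_a.times)))
    w = max(int(round(smooth / dt)), 1)

    def smooth_arr(v):
        cs = np.cumsum(np.asarray(v, dtype=float), axis=-1)
        cs = np.concatenate([np.zeros(v.shape[:-1] + (1,)), cs], axis=-1)
        half_lo = w // 2
        # centered moving average with shrinking edges
        n = v.shape[-1]
        starts = np.clip(np.arange(n) - half_lo, 0, n)
        stops = np.clip(np.arange(n) - half_lo + w, 0, n)
        out = (cs[..., stops] - cs[..., starts]) / np.maximum(stops - starts, 1)
        return out

    sa = smooth_arr(power_a.values)
    sb = smooth_arr(power_b.values)
    ra = rankdata(sa, axis=0)
    rb = rankdata(sb, axis=0)
    ra -= ra.mean(axis=0)
    rb -= rb.mean(axis=0)
    num = (ra * rb).sum(axis=0)
    denom = np.sqrt((ra ** 2).sum(axis=0) * (rb ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, num / denom, np.nan)
    return rho


def coherence_condition_contrast(panels_target: list[np.ndarray],
                                 panels_distractor: list[np.ndarray],
                                 n_perm: int = 200, seed: int = 0,
                                 threshold: float = 0.05,
                                 alpha: float = 0.05) -> tuple[StatMap, ClusterResult]:
    """Session-level label permutation + cluster correction on per-session
    condition-average coupling maps (normalized coherence, phase synchrony
    or power correlation)."""
    a = np.asarray(panels_target, dtype=float)
    b = np.asarray(panels_distractor, dtype=float)
    sm = label_permutation_test(a, b, n_perm=n_perm, seed=seed, paired=True)
    return sm, cluster_correct(sm, threshold=threshold, alpha=alpha)
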