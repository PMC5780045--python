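"""Trial-wise spike handling, kernel rates, and spike-phase locking.

The trial extraction window defaults to (-500, +1000) ms around onset —
1500 ms of spiking per trial covering the 500 ms rate baseline and the
1000 ms task epoch.  Rates use 1 ms bins smoothed with a 50 ms-SD
Gaussian truncated at +/-4 SD; edge mass is renormalized per spike so the
time-integral of each trial's rate equals its interior spike count
exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .perm_stats import ClusterResult, StatMap, cluster_correct, \
    label_permutation_test, signflip_test
from .types import SpikeTrain, TimeFreqTensor, validate_event_table

log = logging.getLogger(__name__)

__all__ = [
    "TrialSpikes", "RateSeries", "SpikePhaseResult", "extract_trial_spikes",
    "continuous_rate", "normalize_rate", "cluster_rate_tests",
    "spike_phase_locking", "population_R_test",
]


@dataclass
class TrialSpikes:
    """Per-trial spike times relative to stimulus onset (ms)."""

    spikes: list[np.ndarray]
    window: tuple[float, float]
    excluded: np.ndarray                  # bool per trial
    reasons: dict[int, str] = field(default_factory=dict)
    cluster_id: str = "c0"
    paired_macro: str | None = None
    conditions: np.ndarray | None = None  # per-trial 'target'/'distractor'

    @property
    def n_trials(self) -> int:
        return len(self.spikes)

    def good_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.excluded)


@dataclass
class RateSeries:
    rates: np.ndarray        # (n_trials, n_bins), spikes/s
    times: np.ndarray        # bin centers, ms relative to onset
    bin_ms: float
    excluded: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]


@dataclass
class SpikePhaseResult:
    """Mean vector length and its trial-scramble normalization."""

    r: np.ndarray              # per frequency, in [0, 1]
    surrogate_r: np.ndarray    # (n_surr, n_freqs)
    R: np.ndarray              # (r - mean surr) / SD surr
    freqs: np.ndarray
    window: tuple[float, float]
    n_spikes: int
    cluster_id: str = "c0"


def extract_trial_spikes(train: SpikeTrain, events: pd.DataFrame,
                         span: float = 1500.0, offset: float = -500.0,
                         recording_duration_ms: float | None = None,
                         outlier_sd: float = 10.0) -> TrialSpikes:
    """Re-reference spikes to trial onsets and drop rate-outlier trials.

    The per-trial window is [offset, offset + span) ms around onset.
    Trials whose raw mean rate deviates from the across-trial mean by more
    than ``outlier_sd`` standard deviations are flagged excluded; trials
    whose window extends past the recording end are flagged too (logged).
    """
    validate_event_table(events)
    onsets = events["onset"].to_numpy(dtype=float)
    lo, hi = offset, offset + span
    spikes, oob = [], np.zeros(len(onsets), dtype=bool)
    st = train.spike_times
    for t, onset in enumerate(onsets):
        if recording_duration_ms is not None and onset + hi > recording_duration_ms:
            oob[t] = True
            spikes.append(np.empty(0))
            log.info("trial %d dropped: window past recording end", t)
            continue
        rel = st[(st >= onset + lo) & (st < onset + hi)] - onset
        spikes.append(rel)
    counts = np.array([s.size for s in spikes], dtype=float)
    excluded = oob.copy()
    reasons = {int(t): "window past recording end" for t in np.flatnonzero(oob)}
    valid = ~oob
    if valid.sum() >= 2:
        mu, sd = counts[valid].mean(), counts[valid].std(ddof=0)
        if sd > 0:
            out = valid & (np.abs(counts - mu) > outlier_sd * sd)
            for t in np.flatnonzero(out):
                excluded[t] = True
                reasons[int(t)] = f"mean rate beyond {outlier_sd} SD"
    cond = events["condition"].to_numpy() if "condition" in events else None
    return TrialSpikes(spikes=spikes, window=(lo, hi), excluded=excluded,
                       reasons=reasons, cluster_id=train.cluster_id,
                       paired_macro=train.paired_macro, conditions=cond)


def continuous_rate(trial_spikes: TrialSpikes, kernel_sd: float = 50.0,
                    bin_ms: float = 1.0) -> RateSeries:
    """Gaussian-kernel firing rate per trial, spikes/s.

    Each spike contributes a unit-mass Gaussian bump truncated to the
    trial span (truncation + per-spike renormalization, so the integral
    over the trial equals the interior spike count exactly).
    """
    if bin_ms > kernel_sd:
        raise ValueError("bin must not exceed kernel SD")
    lo, hi = trial_spikes.window
    n_bins = int(round((hi - lo) / bin_ms))
    times = lo + (np.arange(n_bins) + 0.5) * bin_ms
    half = int(np.ceil(4.0 * kernel_sd / bin_ms))
    k = np.exp(-0.5 * ((np.arange(-half, half + 1) * bin_ms) / kernel_sd) ** 2)
    k /= k.sum()
    # per-position available kernel mass (for edge renormalization)
    avail = np.convolve(np.ones(n_bins), k, mode="same")
    rates = np.zeros((trial_spikes.n_trials, n_bins))
    bin_s = bin_ms / 1000.0
    for t, sp in enumerate(trial_spikes.spikes):
        if sp.size == 0:
            continue
        idx = np.clip(((sp - lo) / bin_ms).astype(np.intp), 0, n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins).astype(float)
        rates[t] = np.convolve(counts / avail, k, mode="same") / bin_s
    return RateSeries(rates=rates, times=times, bin_ms=bin_ms,
                      excluded=trial_spikes.excluded.copy())


def normalize_rate(rate: RateSeries, baseline: tuple[float, float] = (-500.0, 0.0)):
    """Per-trial z-scored rates and their across-trial average.

    z = (rate - baseline mean) / baseline SD per trial; trials with zero
    baseline SD (silent baseline) are flagged and excluded from the
    average, as are trials already excluded upstream.

    Returns (mean_z, per_trial_z, valid_mask).
    """
    m = (rate.times >= baseline[0]) & (rate.times < baseline[1])
    if not m.any():
        raise ValueError("baseline window not covered by the extraction span")
    base = rate.rates[:, m]
    mu = base.mean(axis=1, keepdims=True)
    sd = base.std(axis=1, ddof=0, keepdims=True)
    # a trial that is constant at its baseline mean everywhere is z == 0 and
    # stays valid; a flat baseline with deviation elsewhere is degenerate
    flat = sd[:, 0] == 0
    const_ok = flat & np.all(rate.rates == mu, axis=1)
    valid = (~flat | const_ok) & ~rate.excluded
    for t in np.flatnonzero(flat & ~const_ok & ~rate.excluded):
        log.info("trial %d excluded from rate average: silent baseline", t)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (rate.rates - mu) / np.where(sd > 0, sd, np.inf)
    mean_z = z[valid].mean(axis=0) if valid.any() else np.full(rate.rates.shape[1], np.nan)
    return mean_z, z, valid


def cluster_rate_tests(per_cluster_z: list[np.ndarray],
                       per_cluster_conditions: list[np.ndarray] | None = None,
                       n_perm: int = 200, seed: int = 0,
                       threshold: float = 0.05, alpha: float = 0.05) -> dict:
    """Population and per-cluster rate tests on z-scored rate series.

    per_cluster_z[i] is a trials x time array of per-trial z rates for one
    cluster (excluded trials already removed).  Returns a dict with the
    population vs-baseline ClusterResult (units = clusters), per-cluster
    vs-baseline and target-vs-distractor results (units = trials),
    fraction-significant-vs-time curves, and the up/down partition of
    clusters with a significant baseline contrast.
    """
    for i, z in enumerate(per_cluster_z):
        if z.shape[0] < 10:
            raise ValueError(f"cluster {i}: fewer than 10 trials")
    if len(per_cluster_z) >= 2:
        pop_units = np.stack([z.mean(axis=0) for z in per_cluster_z])
        pop_sm = signflip_test(pop_units, n_perm=n_perm, seed=seed)
        pop_cr = cluster_correct(pop_sm, threshold=threshold, alpha=alpha)
    else:
        pop_sm = pop_cr = None

    per_cluster, frac_base, frac_cond = [], [], []
    direction = []
    for i, z in enumerate(per_cluster_z):
        sm = signflip_test(z, n_perm=n_perm, seed=seed + 31 * i + 1)
        cr = cluster_correct(sm, threshold=threshold, alpha=alpha)
        entry = {"baseline": (sm, cr), "condition": None}
        frac_base.append(sm.p < threshold)
        if cr.any_significant:
            direction.append(1 if cr.significant[0].sign > 0 else -1)
        else:
            direction.append(0)
        if per_cluster_conditions is not None:
            labels = np.asarray(per_cluster_conditions[i])
            is_t = labels == "target"
            if 2 <= is_t.sum() and 2 <= (~is_t).sum():
                sm_c = label_permutation_test(z[is_t], z[~is_t], paired=False,
                                              n_perm=n_perm,
                                              seed=seed + 31 * i + 2)
                cr_c = cluster_correct(sm_c, threshold=threshold, alpha=alpha)
                entry["condition"] = (sm_c, cr_c)
                frac_cond.append(sm_c.p < threshold)
        per_cluster.append(entry)
    out = {
        "population": (pop_sm, pop_cr),
        "per_cluster": per_cluster,
        "direction": np.asarray(direction),          # +1 up, -1 down, 0 ns
        "fraction_significant_baseline": np.mean(frac_base, axis=0),
    }
    if frac_cond:
        out["fraction_significant_condition"] = np.mean(frac_cond, axis=0)
    return out


def spike_phase_locking(trial_spikes: TrialSpikes, phase: TimeFreqTensor,
                        window: tuple[float, float] = (0.0, 1000.0),
                        n_surr: int = 200, seed: int = 0,
                        min_spikes: int = 50,
                        chunk: int = 25) -> SpikePhaseResult:
    """Surrogate-normalized spike-phase locking per frequency.

    r(f) = |mean over all in-window spikes (pooled across trials) of
    exp(i*phi)| with phi read from the paired macro channel's phase tensor
    at the spike's nearest millisecond.  Each surrogate reassigns every
    spike the phase at its own time point in a uniformly drawn *other*
    trial (with replacement); R standardizes r against that ensemble.
    """
    if phase.kind != "phase":
        raise ValueError("spike_phase_locking expects a phase tensor")
    if trial_spikes.paired_macro is None:
        raise ValueError("cluster has no paired macro channel")
    good = trial_spikes.good_indices()
    n_trials = good.size
    if n_trials < 2:
        raise ValueError("need at least 2 usable trials")
    dt = float(np.median(np.diff(phase.times)))
    t0 = float(phase.times[0])
    n_times = phase.times.size
    trial_of, idx_of = [], []
    for row, t in enumerate(good):
        sp = trial_spikes.spikes[t]
        sp = sp[(sp >= window[0]) & (sp < window[1])]
        idx = np.round((sp - t0) / dt).astype(np.intp)
        keep = (idx >= 0) & (idx < n_times)
        idx_of.append(idx[keep])
        trial_of.append(np.full(keep.sum(), row, dtype=np.intp))
    trial_of = np.concatenate(trial_of) if trial_of else np.empty(0, np.intp)
    idx_of = np.concatenate(idx_of) if idx_of else np.empty(0, np.intp)
    n_spikes = trial_of.size
    if n_spikes < min_spikes:
        raise ValueError(f"only {n_spikes} spikes in window (< {min_spikes})")

    vals = phase.values[good]                      # (n_trials, F, T)
    true_ph = vals[trial_of, :, idx_of]            # (n_spikes, F)
    r = np.abs(np.exp(1j * true_ph).mean(axis=0))

    rng = np.random.default_rng(seed)
    surr_r = np.empty((n_surr, vals.shape[1]))
    for s0 in range(0, n_surr, chunk):
        s1 = min(s0 + chunk, n_surr)
        draws = rng.integers(0, n_trials - 1, size=(s1 - s0, n_spikes))
        draws += draws >= trial_of[np.newaxis, :]   # skip the spike's own trial
        ph = vals[draws, :, idx_of[np.newaxis, :]]  # (chunk, n_spikes, F)
        surr_r[s0:s1] = np.abs(np.exp(1j * ph).mean(axis=1))
    mu = surr_r.mean(axis=0)
    sd = surr_r.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(sd > 0, (r - mu) / sd, 0.0)
    return SpikePhaseResult(r=r, surrogate_r=surr_r, R=R, freqs=phase.freqs,
                            window=window, n_spikes=int(n_spikes),
                            cluster_id=trial_spikes.cluster_id)


def population_R_test(R: np.ndarray, n_perm: int = 200, seed: int = 0,
                      threshold: float = 0.05,
                      alpha: float = 0.05) -> tuple[StatMap, ClusterResult]:
    """Sign-flip test of mean R across clusters with 1D frequency clustering."""
    R = np.asarray(R, dtype=float)
    if R.ndim != 2:
        raise ValueError("R must be clusters x frequencies")
    if R.shape[0] < 2:
        raise ValueError("need at least 2 clusters")
    sm = signflip_test(R, n_perm=n_perm, seed=seed)
    return sm, cluster_correct(sm, threshold=threshold, alpha=alpha)
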