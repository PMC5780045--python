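"""Synthetic task, signal and spike generation with known ground truth.

The generator emulates the statistical structure the analysis chain
assumes: blocks of interleaved target/distractor trials, stimulus-locked
beta-band amplitude drops with condition-dependent rebound latency, theta
gain, a progressive within-block beta decline, a shared beta source
coupling one subcortical and one cortical channel, and subthalamic spike
trains with rate modulation and beta-phase locking.

Conventions (the source study describes the effects only qualitatively):
effect sizes default to values giving comfortable statistical power at
~90 trials per condition; oscillators are narrowband Gaussian processes,
so trial-to-trial phase is random; envelope transitions are smoothed with
a 25 ms Gaussian to avoid spectral splatter.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import hilbert
from scipy.special import i0

from .types import (Channel, Recording, SpikeTrain, empty_event_table,
                    make_channels, validate_event_table)

__all__ = [
    "TaskConfig", "GroundTruth", "generate_task_events", "synthesize_lfp",
    "synthesize_spikes", "null_dataset", "default_channels",
]

#: lead time before the first stimulus onset, ms.  Leaves room for the
#: 500 ms baseline plus the 1000 ms spectral buffer plus margin.
LEAD_MS = 3000.0
#: recording continues this long after the last trial window, ms.
TAIL_MS = 2500.0


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the block-structured encoding task."""

    n_blocks: int = 30
    trials_per_block: int = 8
    n_target_per_block: int = 4
    stim_duration: float = 500.0     # ms
    isi_mean: float = 500.0          # ms
    isi_jitter: float = 100.0        # ms, uniform +/- bound
    error_fraction: float = 0.0      # fraction of target trials marked incorrect
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_target_per_block > self.trials_per_block:
            raise ValueError("n_target_per_block must not exceed trials_per_block")
        if min(self.stim_duration, self.isi_mean) <= 0:
            raise ValueError("durations must be positive")
        if self.isi_jitter < 0:
            raise ValueError("isi_jitter must be non-negative")
        if not 0.0 <= self.error_fraction <= 1.0:
            raise ValueError("error_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Known effect parameters injected into the synthetic signals.

    Amplitude effects are fractional: erd_depth 0.5 halves the beta
    amplitude (so band power drops by 75%).  spike_rate_modulation is the
    signed fractional change of the firing rate inside the trial epoch.
    """

    beta_freq: float = 20.0            # Hz
    erd_depth_target: float = 0.35
    erd_depth_distractor: float = 0.35
    rebound_latency_target: float = 1000.0     # ms post-onset
    rebound_latency_distractor: float = 500.0
    theta_gain: float = 0.3
    block_slope: float = 0.04          # fractional beta decline per trial-in-block
    coupling_phase_lag: float = 0.5    # radians
    coupling_strength: float = 0.4     # in [0, 1]
    coupling_gain_target: float = 0.0      # fractional in-task change of coupling
    coupling_gain_distractor: float = 0.0
    spike_base_rate: float = 36.0      # spikes/s
    spike_rate_modulation: float = -0.4
    kappa: float = 0.6                 # von Mises concentration, >= 0
    preferred_phase: float = 0.0       # radians
    noise_exponent: float = 1.0        # 1/f power-spectral slope
    beta_amp: float = 1.0
    theta_amp: float = 0.7
    theta_freq: float = 5.0
    noise_amp: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        for name in ("erd_depth_target", "erd_depth_distractor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.spike_base_rate < 0:
            raise ValueError("spike_base_rate must be non-negative")

    @classmethod
    def null(cls, **overrides) -> "GroundTruth":
        """All effect parameters zero: both conditions share one law."""
        params = dict(
            erd_depth_target=0.0, erd_depth_distractor=0.0,
            rebound_latency_target=500.0, rebound_latency_distractor=500.0,
            theta_gain=0.0, block_slope=0.0, coupling_strength=0.0,
            coupling_gain_target=0.0, coupling_gain_distractor=0.0,
            spike_rate_modulation=0.0, kappa=0.0,
        )
        params.update(overrides)
        return cls(**params)

    def to_dict(self) -> dict:
        return asdict(self)


def generate_task_events(config: TaskConfig) -> pd.DataFrame:
    """Seeded EventTable: blocks of randomly interleaved target/distractor
    trials with inter-onset interval stim_duration + isi_mean +/- jitter."""
    if config.n_blocks <= 0:
        return empty_event_table()
    rng = np.random.default_rng(config.seed)
    rows = []
    t = LEAD_MS
    n_t, n_p = config.n_target_per_block, config.trials_per_block
    for block in range(config.n_blocks):
        labels = np.array(["target"] * n_t + ["distractor"] * (n_p - n_t))
        rng.shuffle(labels)
        for tib, cond in enumerate(labels, start=1):
            rows.append((t, block, tib, cond, True))
            t += config.stim_duration + config.isi_mean + rng.uniform(
                -config.isi_jitter, config.isi_jitter)
    events = pd.DataFrame(rows, columns=["onset", "block", "trial_in_block",
                                         "condition", "correct"])
    if config.error_fraction > 0:
        tgt = np.flatnonzero((events["condition"] == "target").to_numpy())
        n_err = int(round(config.error_fraction * tgt.size))
        if n_err:
            bad = rng.choice(tgt, size=n_err, replace=False)
            events.loc[bad, "correct"] = False
    return validate_event_table(events)


def default_channels(n_stn: int = 3, n_lat: int = 8, n_ant: int = 6) -> list[Channel]:
    chans = [Channel(f"stn{i}", "stn-macro", "stn") for i in range(n_stn)]
    chans += [Channel(f"lat{i}", "lateral-pfc", "lat") for i in range(n_lat)]
    chans += [Channel(f"ant{i}", "anterior-pfc", "ant") for i in range(n_ant)]
    return chans


def _one_over_f(rng: np.random.Generator, n: int, fs: float, exponent: float) -> np.ndarray:
    """Unit-SD noise with power spectral density ~ 1/f**exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.empty_like(f)
    gain[1:] = f[1:] ** (-exponent / 2.0)
    gain[0] = 0.0
    x = np.fft.irfft(spec * gain, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _narrowband(rng: np.random.Generator, n: int, fs: float,
                center: float, bw: float) -> np.ndarray:
    """Unit-SD Gaussian process band-limited around `center` Hz (Gaussian
    spectral mask, SD `bw`); trial-to-trial phase is therefore random."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = np.exp(-0.5 * ((f - center) / bw) ** 2)
    x = np.fft.irfft(spec * mask, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _effective_condition(row) -> str:
    # incorrect target trials carry the distractor physiology
    if row.condition == "target" and not row.correct:
        return "distractor"
    return str(row.condition)


def _beta_envelope(events: pd.DataFrame, truth: GroundTruth, n: int, fs: float,
                   smooth_ms: float = 25.0) -> np.ndarray:
    """Per-sample multiplicative envelope for the beta oscillator."""
    env = np.ones(n)
    if (truth.block_slope == 0.0 and truth.erd_depth_target == 0.0
            and truth.erd_depth_distractor == 0.0):
        return env
    dt = 1000.0 / fs
    onsets = events["onset"].to_numpy(dtype=float)
    # piecewise-constant block-decline scale; each trial's scale holds from
    # its onset until the next onset, so the 0..1000 ms epoch carries it
    edges = np.empty(len(events) + 1)
    edges[:-1] = onsets
    edges[-1] = n * dt
    for i, row in enumerate(events.itertuples()):
        scale = max(0.0, 1.0 - truth.block_slope * (row.trial_in_block - 1))
        a, b = int(edges[i] / dt), int(edges[i + 1] / dt)
        env[a:b] = scale
        cond = _effective_condition(row)
        depth = getattr(truth, f"erd_depth_{cond}")
        latency = getattr(truth, f"rebound_latency_{cond}")
        if depth > 0 and latency > 0:
            s = int(row.onset / dt)
            e = min(int((row.onset + latency) / dt), n)
            env[s:e] *= (1.0 - depth)
    if smooth_ms > 0:
        env = gaussian_filter1d(env, smooth_ms / dt)
    return env


def _theta_envelope(events: pd.DataFrame, truth: GroundTruth, n: int, fs: float,
                    epoch_ms: float = 1000.0, smooth_ms: float = 25.0) -> np.ndarray:
    env = np.ones(n)
    if truth.theta_gain == 0.0:
        return env
    dt = 1000.0 / fs
    for row in events.itertuples():
        s = int(row.onset / dt)
        e = min(int((row.onset + epoch_ms) / dt), n)
        env[s:e] = 1.0 + truth.theta_gain
    if smooth_ms > 0:
        env = gaussian_filter1d(env, smooth_ms / dt)
    return env


def _coupling_series(events: pd.DataFrame, truth: GroundTruth, n: int, fs: float,
                     epoch_ms: float = 1000.0, smooth_ms: float = 25.0) -> np.ndarray:
    """Time-resolved coupling strength c(t) in [0, 1]."""
    c = np.full(n, truth.coupling_strength)
    if truth.coupling_gain_target == 0.0 and truth.coupling_gain_distractor == 0.0:
        return c
    dt = 1000.0 / fs
    for row in events.itertuples():
        cond = _effective_condition(row)
        gain = getattr(truth, f"coupling_gain_{cond}")
        if gain:
            s = int(row.onset / dt)
            e = min(int((row.onset + epoch_ms) / dt), n)
            c[s:e] = truth.coupling_strength * (1.0 + gain)
    if smooth_ms > 0:
        c = gaussian_filter1d(c, smooth_ms / dt)
    return np.clip(c, 0.0, 1.0)


def synthesize_lfp(events: pd.DataFrame, truth: GroundTruth,
                   channels: list[Channel] | list[tuple[str, str, str]] | None = None,
                   fs: float = 1000.0, seed: int = 0,
                   coupling_pair: tuple[str, str] | None = None,
                   phase_channels: list[str] | None = None) -> Recording:
    """Generate a continuous multichannel recording.

    Each channel is 1/f noise plus theta and beta narrowband oscillators
    whose envelopes carry the injected effects.  The two channels named in
    ``coupling_pair`` share a common beta source with weight
    ``coupling_strength``; the second member's shared component is delayed
    by ``coupling_phase_lag`` radians of the beta cycle.

    ``aux['beta_phase']`` stores the instantaneous phase (radians) of the
    clean beta component for the channels in ``phase_channels`` (default:
    all stn-macro channels) — the spike generator's ground-truth phase.
    """
    if fs < 4.0 * truth.beta_freq:
        raise ValueError("fs must be at least 4x beta_freq")
    validate_event_table(events)
    if channels is None:
        channels = default_channels()
    channels = make_channels(channels)
    names = [c.name for c in channels]
    if coupling_pair is None and {"stn0", "lat0"} <= set(names):
        coupling_pair = ("stn0", "lat0")
    if coupling_pair is not None:
        missing = [nm for nm in coupling_pair if nm not in names]
        if missing:
            raise ValueError(f"coupling_pair names undefined channels: {missing}")
    if phase_channels is None:
        phase_channels = [c.name for c in channels if c.role == "stn-macro"]

    if len(events):
        dur_ms = float(events["onset"].iloc[-1]) + TAIL_MS
    else:
        dur_ms = LEAD_MS + TAIL_MS
    n = int(round(dur_ms * fs / 1000.0))
    rng = np.random.default_rng(seed)

    beta_env = _beta_envelope(events, truth, n, fs)
    theta_env = _theta_envelope(events, truth, n, fs)
    beta_bw = 2.0
    # shared beta source and its phase-lagged copy (narrowband => a time
    # shift of lag/(2*pi*f) realises the requested phase lag)
    shared = _narrowband(rng, n, fs, truth.beta_freq, beta_bw)
    lag_samples = truth.coupling_phase_lag / (2.0 * np.pi * truth.beta_freq) * fs
    shift = int(round(lag_samples))
    shared_lagged = np.roll(shared, shift)
    c_t = _coupling_series(events, truth, n, fs)
    w_shared = np.sqrt(c_t)
    w_own = np.sqrt(1.0 - c_t)

    data = np.empty((len(channels), n))
    phase_aux: dict[str, np.ndarray] = {}
    for i, ch in enumerate(channels):
        own = _narrowband(rng, n, fs, truth.beta_freq, beta_bw)
        if coupling_pair is not None and ch.name == coupling_pair[0]:
            carrier = w_shared * shared + w_own * own
        elif coupling_pair is not None and ch.name == coupling_pair[1]:
            carrier = w_shared * shared_lagged + w_own * own
        else:
            carrier = own
        beta = truth.beta_amp * beta_env * carrier
        theta = truth.theta_amp * theta_env * _narrowband(
            rng, n, fs, truth.theta_freq, 1.5)
        noise = truth.noise_amp * _one_over_f(rng, n, fs, truth.noise_exponent)
        data[i] = beta + theta + noise
        if ch.name in phase_channels:
            phase_aux[ch.name] = np.angle(hilbert(beta)).astype(np.float32)

    return Recording(data=data, fs=fs, channels=channels,
                     aux={"beta_phase": phase_aux, "fs": fs,
                          "truth": truth.to_dict()})


def _trial_bump(events: pd.DataFrame, n: int, fs: float, shape: str,
                epoch_ms: float = 1000.0) -> np.ndarray:
    """Within-trial modulation profile g(t) in [0, 1]; zero between trials."""
    g = np.zeros(n)
    dt = 1000.0 / fs
    for onset in events["onset"].to_numpy(dtype=float):
        s = int(onset / dt)
        e = min(int((onset + epoch_ms) / dt), n)
        if shape == "boxcar":
            g[s:e] = 1.0
        elif shape == "hann":
            u = np.arange(e - s) / max(e - s - 1, 1)
            g[s:e] = np.sin(np.pi * u) ** 2
        else:
            raise ValueError(f"unknown bump shape {shape!r}")
    return g


def synthesize_spikes(events: pd.DataFrame, beta_phase: np.ndarray,
                      truth: GroundTruth, seed: int = 0, fs: float = 1000.0,
                      cluster_id: str = "c0", depth_pct: float | None = 50.0,
                      paired_macro: str | None = "stn0",
                      bump: str = "hann") -> SpikeTrain:
    """Inhomogeneous Poisson spikes with von Mises phase preference.

    Intensity lambda(t) = r(t) * exp(kappa*cos(phi(t) - phi0)) / I0(kappa)
    with r(t) = spike_base_rate * (1 + spike_rate_modulation * g(t)); the
    I0 normalisation keeps the phase factor mean-1 over uniform phase, so
    the time-averaged rate is governed by r(t) alone.  Sampling is by
    thinning of a homogeneous process at the intensity ceiling; phase is
    looked up at the nearest sample of ``beta_phase``.
    """
    if truth.spike_base_rate < 0:
        raise ValueError("spike_base_rate must be non-negative")
    validate_event_table(events)
    beta_phase = np.asarray(beta_phase, dtype=float)
    n = beta_phase.size
    if len(events):
        need = (float(events["onset"].iloc[-1]) + 1500.0) * fs / 1000.0
        if n < need:
            raise ValueError("beta_phase does not cover all trial windows")
    rng = np.random.default_rng(seed)
    dur_s = n / fs
    mod = truth.spike_rate_modulation
    r_max = truth.spike_base_rate * (1.0 + max(mod, 0.0))
    lam_max = r_max * np.exp(truth.kappa) / i0(truth.kappa)
    if lam_max <= 0:
        return SpikeTrain(np.empty(0), cluster_id, depth_pct, paired_macro)
    n_cand = rng.poisson(lam_max * dur_s)
    t_cand = np.sort(rng.uniform(0.0, dur_s, size=n_cand))   # seconds
    g = _trial_bump(events, n, fs, bump)
    idx = np.minimum((t_cand * fs).astype(np.intp), n - 1)
    r_t = truth.spike_base_rate * (1.0 + mod * g[idx])
    lam = r_t * np.exp(truth.kappa * np.cos(beta_phase[idx] - truth.preferred_phase)) \
        / i0(truth.kappa)
    keep = rng.uniform(0.0, lam_max, size=n_cand) < lam
    times_ms = t_cand[keep] * 1000.0
    return SpikeTrain(times_ms, cluster_id, depth_pct, paired_macro)


def null_dataset(config: TaskConfig, seed: int = 0,
                 channels: list[Channel] | None = None,
                 fs: float = 1000.0) -> tuple[Recording, pd.DataFrame, SpikeTrain]:
    """Dataset with every effect parameter zero, for type-I calibration."""
    truth = GroundTruth.null()
    events = generate_task_events(config)
    if channels is None:
        channels = [Channel("stn0", "stn-macro", "stn"),
                    Channel("lat0", "lateral-pfc", "lat")]
    rec = synthesize_lfp(events, truth, channels, fs=fs, seed=seed,
                         coupling_pair=None)
    phase = rec.aux["beta_phase"].get("stn0")
    if phase is None:
        phase = np.zeros(rec.n_samples, dtype=np.float32)
    spikes = synthesize_spikes(events, phase, truth, seed=seed + 1, fs=fs)
    return rec, events, spikes
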