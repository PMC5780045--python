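"""End-to-end orchestration: simulate -> preprocess -> spectral -> stats ->
connectivity -> spiking, with per-stage artifacts and a JSON report.

Every random draw is derived from the single top-level seed through
``derive_seed(seed, stage, index)`` so stages are independently
reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .connectivity import coherence_condition_contrast, normalize_coherence, \
    phase_synchrony, power_correlation, sliding_coherence
from .io import write_events, write_json, write_recording, write_spikes
from .perm_stats import band_cluster_test, cluster_correct, \
    label_permutation_test, per_electrode_tests, regress_band_vs_trialnum, \
    rm_anova_trialnum, signflip_test
from .preprocess import bandpass_notch_downsample, epoch, \
    rereference_bipolar, rereference_common_average, reject_artifact_trials
from .spectral import build_wavelet_bank, instantaneous_phase, \
    normalize_to_baseline, power, wavelet_transform
from .spiking import continuous_rate, extract_trial_spikes, normalize_rate, \
    population_R_test, spike_phase_locking
from .synthetic_data import GroundTruth, TaskConfig, generate_task_events, \
    synthesize_lfp, synthesize_spikes
from .types import Channel

log = logging.getLogger("ephysflow.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def derive_seed(seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage/per-session sub-seed from the master seed."""
    tag = int.from_bytes(stage.encode()[:4].ljust(4, b"\0"), "little")
    ss = np.random.SeedSequence([int(seed), tag, int(index)])
    return int(ss.generate_state(1)[0])


def _cluster_summary(cr) -> dict:
    return {"n_clusters": len(cr.clusters),
            "n_significant": len(cr.significant),
            "min_p": min((c.p_corrected for c in cr.clusters), default=None),
            "clusters": cr.to_dict()["clusters"]}


def simulate_session(cfg: RunConfig, session: int):
    """One synthetic session: events, recording, and a spike train."""
    task = TaskConfig(seed=derive_seed(cfg.seed, "task", session),
                      **cfg.task.model_dump())
    truth = GroundTruth(**cfg.truth.model_dump())
    events = generate_task_events(task)
    channels = [Channel(f"stn{i}", "stn-macro", "stn")
                for i in range(cfg.simulate.n_stn)]
    channels += [Channel(f"lat{i}", "lateral-pfc", "lat")
                 for i in range(cfg.simulate.n_lat)]
    fs = 1502.4 if cfg.simulate.generate_at_1500 else cfg.simulate.fs
    rec = synthesize_lfp(events, truth, channels, fs=fs,
                         seed=derive_seed(cfg.seed, "lfp", session),
                         coupling_pair=("stn0", "lat0"))
    phase = rec.aux["beta_phase"]["stn0"]
    spikes = synthesize_spikes(events, phase, truth,
                               seed=derive_seed(cfg.seed, "spk", session),
                               fs=fs, cluster_id=f"s{session}",
                               paired_macro="stn0")
    return rec, events, spikes, truth


def analyze_session(cfg: RunConfig, rec, events, spikes, session: int) -> dict:
    """Preprocess + spectral + connectivity + spiking for one session."""
    pp = cfg.preprocess
    rec = bandpass_notch_downsample(rec, pp.low, pp.high, pp.notch,
                                    min(pp.target_fs, rec.fs))
    rec = rereference_common_average(rec, "stn")
    lat_names = [c.name for c in rec.channels if c.group == "lat"]
    rec = rereference_bipolar(rec, lat_names)
    epochs = epoch(rec, events, tuple(pp.window), pp.buffer)
    epochs = reject_artifact_trials(epochs, pp.artifact_z)
    good = epochs.good_mask()
    if good.sum() < 10:
        raise StageError("preprocess", f"session {session}: too few clean trials")

    sp = cfg.spectral
    bank = build_wavelet_bank(sp.fmin, sp.scales_per_octave, sp.n_freqs,
                              sp.wavenumber)
    stn_names = [c.name for c in rec.channels if c.group == "stn"]
    bip_names = [c.name for c in rec.channels if c.group == "lat"]
    conditions = epochs.events["condition"].to_numpy()[good]
    tib = epochs.events["trial_in_block"].to_numpy()[good]

    region_norm: dict[str, np.ndarray] = {}
    contact_maps: dict[str, np.ndarray] = {}
    contact_conditions: dict[str, np.ndarray] = {}
    keep_complex = {}
    freqs = times = None
    analysis_mask = None
    for region, names in (("stn", stn_names), ("lat", bip_names)):
        acc = None
        for name in names:
            wt = wavelet_transform(epochs, bank, channel=name,
                                   baseline_margin=sp.baseline_margin)
            if name in (stn_names[0], bip_names[0]):
                keep_complex[region] = wt
            np_t = normalize_to_baseline(power(wt), tuple(sp.baseline),
                                         per_trial=sp.per_trial_baseline)
            vals = np_t.values[good]
            acc = vals if acc is None else acc + vals
            if region == "lat":
                contact_maps[name] = vals
                contact_conditions[name] = conditions
            if freqs is None:
                freqs, times = np_t.freqs, np_t.times
                analysis_mask = np_t.time_slice(*epochs.window)
        region_norm[region] = acc / len(names)

    st = cfg.stats
    bands = {"beta": st.beta_band, "theta": st.theta_band}
    # a reduced bank may not cover every band; skip those (logged)
    bands = {name: b for name, b in bands.items()
             if ((freqs >= b[0]) & (freqs <= b[1])).any()}
    for name in {"beta", "theta"} - set(bands):
        log.info("band %s does not intersect the bank; skipped", name)
    out = {"session": session, "freqs": freqs, "times": times,
           "analysis_mask": analysis_mask, "conditions": conditions,
           "bands": sorted(bands),
           "n_trials_good": int(good.sum()),
           "n_trials_rejected": int((~good).sum())}
    for region in ("stn", "lat"):
        vals = region_norm[region]
        out[f"{region}_map_all"] = vals.mean(axis=0)
        for cond in ("target", "distractor"):
            out[f"{region}_map_{cond}"] = vals[conditions == cond].mean(axis=0)
        for name, band in bands.items():
            series = band_average_like(vals, freqs, band)
            out[f"{region}_{name}_all"] = series.mean(axis=0)
            for cond in ("target", "distractor"):
                out[f"{region}_{name}_{cond}"] = \
                    series[conditions == cond].mean(axis=0)
            if name == "beta":
                # mean beta over the trial epoch (0..1000 ms) per position
                task_m = (times >= 0.0) & (times < 1000.0)
                trial_means = series[:, task_m].mean(axis=1)
                out[f"{region}_beta_by_position"] = np.array(
                    [trial_means[tib == j + 1].mean()
                     if np.any(tib == j + 1) else np.nan
                     for j in range(cfg.task.trials_per_block)])
                # error contrast: correctly vs incorrectly encoded targets
                correct = epochs.events["correct"].to_numpy()[good]
                err = (conditions == "target") & ~correct
                ok = (conditions == "target") & correct
                if err.sum() >= 5 and ok.sum() >= 5:
                    out[f"{region}_beta_target_correct"] = \
                        series[ok].mean(axis=0)
                    out[f"{region}_beta_target_error"] = \
                        series[err].mean(axis=0)
    out["contact_maps"] = contact_maps
    out["contact_conditions"] = contact_conditions

    if cfg.stages.connect:
        cn = cfg.connect
        wa, wb = keep_complex["stn"], keep_complex["lat"]
        coh = normalize_coherence(sliding_coherence(wa, wb, cn.window, cn.step),
                                  tuple(sp.baseline))
        plv = normalize_coherence(phase_synchrony(wa, wb, cn.window, cn.step),
                                  tuple(sp.baseline))
        pa, pb = power(wa), power(wb)
        out["coherence_times"] = coh.times
        for cond in ("target", "distractor"):
            m = good.copy()
            m[good] = conditions == cond
            out[f"coh_{cond}"] = coh.values[good][conditions == cond].mean(axis=0)
            out[f"plv_{cond}"] = plv.values[good][conditions == cond].mean(axis=0)
            out[f"powcorr_{cond}"] = power_correlation(
                _subset_tensor(pa, m), _subset_tensor(pb, m), cn.smooth)

    if cfg.stages.spikes:
        sk = cfg.spikes
        ts = extract_trial_spikes(spikes, events,
                                  recording_duration_ms=rec.duration_ms)
        # align excluded trials with epoch rejections
        ts.excluded |= ~epochs.good_mask()
        rate = continuous_rate(ts, sk.kernel_sd, sk.bin_ms)
        mean_z, z, valid = normalize_rate(rate)
        out["rate_times"] = rate.times
        out["rate_mean_z"] = mean_z
        out["rate_trial_z"] = z[valid]
        out["rate_conditions"] = events["condition"].to_numpy()[valid]
        phase_t = instantaneous_phase(keep_complex["stn"])
        phase_good = _subset_tensor(phase_t, epochs.good_mask())
        ts_good = _subset_trials(ts, epochs.good_mask())
        try:
            spr = spike_phase_locking(ts_good, phase_good,
                                      tuple(sk.locking_window), sk.n_surr,
                                      seed=derive_seed(cfg.seed, "sfl", session))
            out["R"] = spr.R
            out["spike_r"] = spr.r
            out["n_spikes"] = spr.n_spikes
        except ValueError as e:
            log.info("session %d: spike-phase locking skipped (%s)", session, e)
    return out


def band_average_like(values: np.ndarray, freqs: np.ndarray,
                      band: tuple[float, float]) -> np.ndarray:
    m = (freqs >= band[0]) & (freqs <= band[1])
    if not m.any():
        raise ValueError(f"band {band} does not intersect the bank")
    return values[:, m, :].mean(axis=1)


def _subset_tensor(tensor, mask):
    from .types import TimeFreqTensor
    out = TimeFreqTensor(values=tensor.values[mask], freqs=tensor.freqs,
                         times=tensor.times, kind=tensor.kind,
                         channel=tensor.channel,
                         trial_index=(tensor.trial_index[mask]
                                      if tensor.trial_index is not None else None),
                         analysis_window=tensor.analysis_window)
    return out


def _subset_trials(ts, mask):
    from .spiking import TrialSpikes
    idx = np.flatnonzero(mask)
    return TrialSpikes(spikes=[ts.spikes[i] for i in idx], window=ts.window,
                       excluded=ts.excluded[idx],
                       cluster_id=ts.cluster_id, paired_macro=ts.paired_macro,
                       conditions=(ts.conditions[idx]
                                   if ts.conditions is not None else None))


def group_statistics(cfg: RunConfig, sessions: list[dict]) -> dict:
    """Across-session (random-effects) tests on the session summaries."""
    st = cfg.stats
    report: dict = {}
    freqs = sessions[0]["freqs"]
    times = sessions[0]["times"]
    task_axis = (times >= 0.0) & (times < 1000.0)
    seed0 = derive_seed(cfg.seed, "stat")
    for region in ("stn", "lat"):
        maps = np.stack([s[f"{region}_map_all"] for s in sessions])
        sm = signflip_test(maps[:, :, task_axis], n_perm=st.n_perm, seed=seed0)
        cr = cluster_correct(sm, st.threshold, st.alpha)
        report[f"{region}_vs_baseline"] = _cluster_summary(cr)
        for band_name in sessions[0]["bands"]:
            series = np.stack([s[f"{region}_{band_name}_all"] for s in sessions])
            _, cr_b = band_cluster_test(series[:, task_axis], n_perm=st.n_perm,
                                        seed=seed0 + 1, threshold=st.threshold,
                                        alpha=st.alpha)
            report[f"{region}_{band_name}_vs_baseline"] = _cluster_summary(cr_b)
            a = np.stack([s[f"{region}_{band_name}_target"] for s in sessions])
            b = np.stack([s[f"{region}_{band_name}_distractor"] for s in sessions])
            _, cr_c = band_cluster_test(a[:, task_axis], b[:, task_axis],
                                        n_perm=st.n_perm, seed=seed0 + 2,
                                        threshold=st.threshold, alpha=st.alpha)
            report[f"{region}_{band_name}_condition"] = _cluster_summary(cr_c)
        # hemisphere contrast: alternate sessions are left/right recordings
        # of the same participant; paired label permutation over pairs
        n_pairs = len(sessions) // 2
        if n_pairs >= 2 and "beta" in sessions[0]["bands"]:
            left = np.stack([sessions[2 * i][f"{region}_beta_all"]
                             for i in range(n_pairs)])
            right = np.stack([sessions[2 * i + 1][f"{region}_beta_all"]
                              for i in range(n_pairs)])
            sm_h = label_permutation_test(left[:, task_axis],
                                          right[:, task_axis],
                                          n_perm=st.n_perm, seed=seed0 + 6,
                                          paired=True)
            report[f"{region}_beta_hemisphere"] = _cluster_summary(
                cluster_correct(sm_h, st.threshold, st.alpha))
        # error contrast: correct vs incorrect target trials, across the
        # sessions that have enough error trials
        err_a = [s[f"{region}_beta_target_correct"] for s in sessions
                 if f"{region}_beta_target_error" in s]
        err_b = [s[f"{region}_beta_target_error"] for s in sessions
                 if f"{region}_beta_target_error" in s]
        if len(err_a) >= 2:
            sm_e = label_permutation_test(np.stack(err_a)[:, task_axis],
                                          np.stack(err_b)[:, task_axis],
                                          n_perm=st.n_perm, seed=seed0 + 7,
                                          paired=True)
            report[f"{region}_beta_error"] = _cluster_summary(
                cluster_correct(sm_e, st.threshold, st.alpha))
        # progressive within-block decline
        bm = np.stack([s[f"{region}_beta_by_position"] for s in sessions])
        if not np.isnan(bm).any():
            rhos, t, p = regress_band_vs_trialnum(bm)
            report[f"{region}_beta_trend"] = {
                "rho_mean": float(np.mean(rhos)), "t": t, "p": p}
            anova = rm_anova_trialnum(bm)
            report[f"{region}_beta_rm_anova"] = anova
    # per-contact tests pooled over sessions
    n_sig = n_total = 0
    for s in sessions:
        tbl = per_electrode_tests(s["contact_maps"], s["contact_conditions"],
                                  n_perm=st.n_perm,
                                  seed=derive_seed(cfg.seed, "elec", s["session"]))
        n_sig += int(tbl["sig_baseline"].sum())
        n_total += int(tbl["testable"].sum())
    report["contacts_significant_vs_baseline"] = {"k": n_sig, "n": n_total}
    if cfg.stages.connect and "coh_target" in sessions[0]:
        for key in ("coh", "plv", "powcorr"):
            a = [s[f"{key}_target"] for s in sessions]
            b = [s[f"{key}_distractor"] for s in sessions]
            a, b = np.stack(a), np.stack(b)
            ok = ~(np.isnan(a) | np.isnan(b))
            a = np.where(ok, a, 0.0)
            b = np.where(ok, b, 0.0)
            _, cr = coherence_condition_contrast(a, b, n_perm=st.n_perm,
                                                 seed=seed0 + 3,
                                                 threshold=st.threshold,
                                                 alpha=st.alpha)
            report[f"{key}_condition"] = _cluster_summary(cr)
    if cfg.stages.spikes:
        zs = [s["rate_mean_z"] for s in sessions if "rate_mean_z" in s]
        if len(zs) >= 2:
            sm = signflip_test(np.stack(zs), n_perm=st.n_perm, seed=seed0 + 4)
            cr = cluster_correct(sm, st.threshold, st.alpha)
            report["population_rate_vs_baseline"] = _cluster_summary(cr)
        Rs = [s["R"] for s in sessions if "R" in s]
        if len(Rs) >= 2:
            _, cr = population_R_test(np.stack(Rs), n_perm=st.n_perm,
                                      seed=seed0 + 5, threshold=st.threshold,
                                      alpha=st.alpha)
            report["population_R"] = _cluster_summary(cr)
            sig = cr.significant_mask()
            report["population_R_frequencies"] = freqs[sig].tolist()
    return report


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages and write artifacts + report under cfg.out."""
    t0 = time.time()
    out_dir = Path(cfg.out)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "run_config.json").write_text(
        json.dumps(cfg.model_dump(), indent=2))
    report: dict = {"version": __version__, "seed": cfg.seed,
                    "stages": cfg.stages.model_dump()}
    if not cfg.stages.simulate:
        report["note"] = "all stages disabled; config echo only"
        write_json(out_dir / "run_report.json", report)
        return report
    sessions_data = []
    for i in range(cfg.simulate.n_sessions):
        try:
            rec, events, spikes, truth = simulate_session(cfg, i)
        except Exception as e:           # noqa: BLE001
            raise StageError("simulate", f"session {i}: {e}") from e
        sdir = out_dir / f"session{i:02d}"
        sdir.mkdir(exist_ok=True)
        write_recording(sdir / "signals.h5", rec)
        write_events(sdir / "events.tsv", events)
        write_spikes(sdir / "spikes.tsv", [spikes])
        write_json(sdir / "ground_truth.json", truth.to_dict())
        sessions_data.append((rec, events, spikes))
    report["simulate"] = {"n_sessions": len(sessions_data),
                          "n_trials": len(sessions_data[0][1])}
    if cfg.stages.preprocess and cfg.stages.spectral:
        summaries = []
        for i, (rec, events, spikes) in enumerate(sessions_data):
            try:
                summaries.append(analyze_session(cfg, rec, events, spikes, i))
            except StageError:
                raise
            except Exception as e:       # noqa: BLE001
                raise StageError("analyze", f"session {i}: {e}") from e
        report["sessions"] = [{k: s[k] for k in
                               ("session", "n_trials_good", "n_trials_rejected")}
                              for s in summaries]
        if cfg.stages.stats:
            if len(summaries) < 2:
                report["group_note"] = ("across-session statistics need "
                                        "at least 2 sessions; skipped")
            else:
                try:
                    report["group"] = group_statistics(cfg, summaries)
                except Exception as e:   # noqa: BLE001
                    raise StageError("stats", str(e)) from e
    report["wall_clock_s"] = round(time.time() - t0, 2)
    write_json(out_dir / "run_report.json", report)
    return report
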