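"""Tests for trial spikes, kernel rates, rate tests, and phase locking."""

import numpy as np
import pandas as pd
import pytest

import ephysflow as ef
from ephysflow.spiking import (TrialSpikes, cluster_rate_tests,
                               continuous_rate, extract_trial_spikes,
                               normalize_rate, population_R_test,
                               spike_phase_locking)
from ephysflow.perm_stats import signflip_test
from ephysflow.types import SpikeTrain, TimeFreqTensor

from test_preprocess import _events


def poisson_train(rate_hz, duration_ms, seed=0, **kw):
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate_hz * duration_ms / 1000.0)
    return SpikeTrain(np.sort(rng.uniform(0, duration_ms, n)), **kw)


def _phase_tensor(rng, n_trials=40, n_freqs=6, n_times=1000, locked_freq=None,
                  freqs=None):
    """Per-trial random-offset linear 20 Hz phase ramps per frequency."""
    if freqs is None:
        freqs = 10.0 * 2 ** (np.arange(n_freqs) / 8)
    times = np.arange(n_times, dtype=float)     # 0..999 ms
    vals = rng.uniform(-np.pi, np.pi, (n_trials, len(freqs), n_times))
    if locked_freq is not None:
        k = int(np.argmin(np.abs(np.asarray(freqs) - locked_freq)))
        offsets = rng.uniform(-np.pi, np.pi, n_trials)
        ramp = 2 * np.pi * locked_freq * times / 1000.0
        vals[:, k, :] = np.angle(np.exp(1j * (ramp + offsets[:, None])))
    return TimeFreqTensor(values=vals, freqs=np.asarray(freqs, dtype=float),
                          times=times, kind="phase"), freqs


class TestExtractTrialSpikes:
    def test_homogeneous_counts_and_no_exclusion(self):
        onsets = [3000.0 + 1600.0 * i for i in range(240)]
        dur = onsets[-1] + 3000.0
        tr = poisson_train(36.0, dur, seed=1)
        ts = extract_trial_spikes(tr, _events(onsets))
        counts = [s.size for s in ts.spikes]
        assert np.mean(counts) == pytest.approx(54.0, rel=0.05)
        assert ts.excluded.sum() == 0

    def test_stuffed_trial_excluded(self):
        # 100x spike count in one of 240 trials; needs a realistic trial
        # count because the outlier itself inflates the across-trial SD
        onsets = [3000.0 + 1600.0 * i for i in range(240)]
        dur = onsets[-1] + 3000.0
        tr = poisson_train(20.0, dur, seed=2)
        stuffed = np.sort(np.concatenate(
            [tr.spike_times, np.random.default_rng(0).uniform(
                onsets[7], onsets[7] + 1000.0, 3000)]))
        ts = extract_trial_spikes(SpikeTrain(stuffed), _events(onsets))
        assert ts.excluded[7]
        assert "SD" in ts.reasons[7]

    def test_span_past_recording_end_dropped(self, caplog):
        onsets = [3000.0, 4600.0]
        tr = poisson_train(30.0, 5000.0, seed=3)
        ts = extract_trial_spikes(tr, _events(onsets),
                                  recording_duration_ms=5000.0)
        assert ts.excluded[1] and not ts.excluded[0]
        assert "recording end" in ts.reasons[1]

    def test_empty_train_valid(self):
        ts = extract_trial_spikes(SpikeTrain(np.empty(0)), _events([3000.0]))
        assert ts.n_trials == 1
        assert ts.spikes[0].size == 0

    def test_spikes_rereferenced_to_onset(self):
        tr = SpikeTrain(np.array([2900.0, 3100.0, 3900.0]))
        ts = extract_trial_spikes(tr, _events([3000.0]))
        np.testing.assert_allclose(ts.spikes[0], [-100.0, 100.0, 900.0])


class TestContinuousRate:
    def _single(self, spikes, window=(-500.0, 1000.0)):
        return TrialSpikes(spikes=[np.asarray(spikes, dtype=float)],
                           window=window,
                           excluded=np.zeros(1, dtype=bool))

    def test_single_spike_unit_mass_gaussian(self):
        rs = continuous_rate(self._single([250.0]))
        integral = rs.rates.sum() * rs.bin_ms / 1000.0
        assert integral == pytest.approx(1.0, abs=1e-9)
        peak_t = rs.times[np.argmax(rs.rates[0])]
        assert peak_t == pytest.approx(250.0, abs=1.0)

    def test_empty_trial_zero_rate(self):
        rs = continuous_rate(self._single([]))
        np.testing.assert_array_equal(rs.rates, 0.0)

    def test_uniform_spikes_mean_rate(self, rng):
        sp = np.sort(rng.uniform(-500.0, 1000.0, 100))
        rs = continuous_rate(self._single(sp))
        mean_rate = rs.rates.mean()
        assert mean_rate == pytest.approx(100.0 / 1.5, rel=0.05)

    def test_mass_conservation_exact(self, rng):
        # edge spikes included: truncation + renormalization keeps the
        # integral equal to the spike count to float tolerance
        sp = np.sort(rng.uniform(-500.0, 1000.0, 57))
        sp[0], sp[-1] = -499.5, 999.5
        rs = continuous_rate(self._single(sp))
        integral = rs.rates.sum() * rs.bin_ms / 1000.0
        assert integral == pytest.approx(57.0, abs=1e-9)

    def test_bin_larger_than_kernel_error(self):
        with pytest.raises(ValueError):
            continuous_rate(self._single([0.0]), kernel_sd=5.0, bin_ms=10.0)


class TestNormalizeRate:
    def _rates(self, rates):
        from ephysflow.spiking import RateSeries
        rates = np.asarray(rates, dtype=float)
        times = -500.0 + np.arange(rates.shape[1]) + 0.5
        return RateSeries(rates=rates, times=times, bin_ms=1.0,
                          excluded=np.zeros(rates.shape[0], dtype=bool))

    def test_constant_rate_z_zero_and_valid(self):
        rs = self._rates(np.full((3, 1500), 12.0))
        mean_z, z, valid = normalize_rate(rs)
        np.testing.assert_allclose(z, 0.0)
        assert valid.all()

    def test_silent_baseline_with_deviation_flagged(self):
        rates = np.zeros((2, 1500))
        rates[0, 800:] = 5.0     # silent baseline, active task
        rates[1, :] = 1.0
        mean_z, z, valid = normalize_rate(self._rates(rates))
        assert not valid[0] and valid[1]

    def test_stationary_poisson_mean_z_small(self):
        rng = np.random.default_rng(4)
        ts = TrialSpikes(
            spikes=[np.sort(rng.uniform(-500, 1000, rng.poisson(54)))
                    for _ in range(240)],
            window=(-500.0, 1000.0), excluded=np.zeros(240, dtype=bool))
        rs = continuous_rate(ts)
        mean_z, _, valid = normalize_rate(rs)
        task = mean_z[(rs.times >= 0) & (rs.times < 1000)]
        assert np.abs(task.mean()) < 0.2

    def test_injected_drop_negative_z(self):
        rng = np.random.default_rng(5)
        spikes = []
        for _ in range(100):
            base = rng.uniform(-500, 0, rng.poisson(18))      # 36 Hz baseline
            task = rng.uniform(0, 1000, rng.poisson(18))      # 18 Hz in task
            spikes.append(np.sort(np.concatenate([base, task])))
        ts = TrialSpikes(spikes=spikes, window=(-500.0, 1000.0),
                         excluded=np.zeros(100, dtype=bool))
        mean_z, _, _ = normalize_rate(continuous_rate(ts))
        rs_times = continuous_rate(ts).times
        task_z = mean_z[(rs_times >= 200) & (rs_times < 800)].mean()
        assert task_z < -0.5


class TestClusterRateTests:
    def _z_rates(self, rng, n_trials=60, n_times=300, shift=0.0):
        z = rng.standard_normal((n_trials, n_times))
        if shift:
            z[:, 100:250] += shift
        return z

    def test_partition_recovery_15_down_8_up_25_null(self):
        correct = total = 0
        for run in range(4):
            rng = np.random.default_rng(2000 + run)
            zs, truth = [], []
            for _ in range(15):
                zs.append(self._z_rates(rng, shift=-0.6)); truth.append(-1)
            for _ in range(8):
                zs.append(self._z_rates(rng, shift=+0.6)); truth.append(1)
            for _ in range(25):
                zs.append(self._z_rates(rng)); truth.append(0)
            res = cluster_rate_tests(zs, n_perm=200, seed=run)
            correct += (res["direction"] == np.asarray(truth)).sum()
            total += 48
        assert correct / total >= 0.9

    def test_null_fraction_significant_near_alpha(self):
        rng = np.random.default_rng(3)
        zs = [self._z_rates(rng) for _ in range(30)]
        res = cluster_rate_tests(zs, n_perm=200, seed=0)
        frac = res["fraction_significant_baseline"]
        assert 0.0 <= frac.mean() < 0.12

    def test_identical_condition_sets_not_significant(self):
        rng = np.random.default_rng(6)
        z = np.tile(rng.standard_normal((1, 200)), (40, 1))
        cond = np.array(["target", "distractor"] * 20)
        res = cluster_rate_tests([z], [cond], n_perm=100, seed=0)
        sm_c, cr_c = res["per_cluster"][0]["condition"]
        assert not cr_c.any_significant

    def test_population_test_present(self):
        rng = np.random.default_rng(7)
        zs = [self._z_rates(rng, shift=-0.5) for _ in range(12)]
        res = cluster_rate_tests(zs, n_perm=200, seed=1)
        _, pop_cr = res["population"]
        assert pop_cr.any_significant
        assert pop_cr.significant[0].sign == -1

    def test_too_few_trials_error(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError, match="10 trials"):
            cluster_rate_tests([rng.standard_normal((5, 100))], n_perm=50)


class TestSpikePhaseLocking:
    def _trial_spikes(self, spikes_per_trial, n_trials, rng, window=(0., 1000.)):
        spikes = [np.sort(rng.uniform(window[0], window[1], spikes_per_trial))
                  for _ in range(n_trials)]
        return TrialSpikes(spikes=spikes, window=(-500.0, 1000.0),
                           excluded=np.zeros(n_trials, dtype=bool),
                           paired_macro="stn0")

    def test_trough_locked_spikes_high_r_large_R(self, rng):
        phase, freqs = _phase_tensor(rng, locked_freq=20.0)
        k = int(np.argmin(np.abs(phase.freqs - 20.0)))
        # place spikes exactly where each trial's 20 Hz phase crosses pi
        spikes = []
        for t in range(phase.values.shape[0]):
            at_trough = np.flatnonzero(np.abs(
                np.angle(np.exp(1j * (phase.values[t, k] - np.pi)))) < 0.15)
            spikes.append(at_trough.astype(float))
        ts = TrialSpikes(spikes=spikes, window=(-500.0, 1000.0),
                         excluded=np.zeros(len(spikes), dtype=bool),
                         paired_macro="stn0")
        res = spike_phase_locking(ts, phase, n_surr=200, seed=0)
        assert res.r[k] > 0.95
        assert res.R[k] > 5.0

    def test_surrogate_count(self, rng):
        phase, _ = _phase_tensor(rng)
        ts = self._trial_spikes(10, 40, rng)
        res = spike_phase_locking(ts, phase, n_surr=200, seed=1)
        assert res.surrogate_r.shape == (200, len(phase.freqs))

    def test_r_invariant_to_global_rotation(self, rng):
        phase, _ = _phase_tensor(rng, locked_freq=20.0)
        ts = self._trial_spikes(15, 40, rng)
        r1 = spike_phase_locking(ts, phase, n_surr=10, seed=2).r
        rot = TimeFreqTensor(
            values=np.angle(np.exp(1j * (phase.values + 1.1))),
            freqs=phase.freqs, times=phase.times, kind="phase")
        r2 = spike_phase_locking(ts, rot, n_surr=10, seed=2).r
        np.testing.assert_allclose(r1, r2, atol=1e-10)

    def test_r_invariant_to_trial_order(self, rng):
        phase, _ = _phase_tensor(rng)
        ts = self._trial_spikes(15, 30, rng)
        perm = rng.permutation(30)
        phase_p = TimeFreqTensor(values=phase.values[perm], freqs=phase.freqs,
                                 times=phase.times, kind="phase")
        ts_p = TrialSpikes(spikes=[ts.spikes[i] for i in perm],
                           window=ts.window, excluded=ts.excluded[perm],
                           paired_macro="stn0")
        r1 = spike_phase_locking(ts, phase, n_surr=10, seed=0).r
        r2 = spike_phase_locking(ts_p, phase_p, n_surr=10, seed=0).r
        np.testing.assert_allclose(r1, r2, atol=1e-10)

    def test_min_spikes_enforced(self, rng):
        phase, _ = _phase_tensor(rng)
        ts = self._trial_spikes(1, 30, rng)
        with pytest.raises(ValueError, match="spikes"):
            spike_phase_locking(ts, phase, n_surr=20, seed=0)

    def test_no_paired_macro_error(self, rng):
        phase, _ = _phase_tensor(rng)
        ts = self._trial_spikes(10, 30, rng)
        ts.paired_macro = None
        with pytest.raises(ValueError, match="macro"):
            spike_phase_locking(ts, phase, n_surr=20, seed=0)

    def test_expected_r_nondecreasing_in_kappa(self):
        # generator + measurement monotonicity over kappa
        from ephysflow.synthetic_data import GroundTruth, synthesize_spikes
        from ephysflow.types import empty_event_table
        fs = 1000.0
        t = np.arange(600_000) / fs
        phase = np.angle(np.exp(1j * 2 * np.pi * 20.0 * t))
        means = []
        for kappa in (0.0, 0.5, 1.0, 2.0):
            rs = []
            for seed in range(8):
                tr = synthesize_spikes(empty_event_table(), phase,
                                       GroundTruth(kappa=kappa,
                                                   spike_rate_modulation=0),
                                       seed=seed, fs=fs)
                ph = phase[np.minimum(tr.spike_times.astype(int),
                                      phase.size - 1)]
                rs.append(np.abs(np.exp(1j * ph).mean()))
            means.append(np.mean(rs))
        assert all(b >= a for a, b in zip(means, means[1:]))


class TestPopulationR:
    def test_locked_population_beta_cluster(self, rng):
        R = rng.standard_normal((10, 12))
        R[:, 5:8] += 2.0
        sm, cr = population_R_test(R, n_perm=200, seed=0)
        mask = cr.significant_mask()
        assert mask[5:8].all()

    def test_unlocked_population_rarely_significant(self):
        hits = 0
        for run in range(20):
            rng = np.random.default_rng(4000 + run)
            sm, cr = population_R_test(rng.standard_normal((8, 12)),
                                       n_perm=200, seed=run)
            hits += cr.any_significant
        assert hits <= 2

    def test_single_frequency_degenerates_to_signflip(self, rng):
        R = rng.standard_normal((9, 1)) + 0.8
        sm, cr = population_R_test(R, n_perm=300, seed=5)
        sm_ref = signflip_test(R, n_perm=300, seed=5)
        np.testing.assert_allclose(sm.z, sm_ref.z, atol=1e-12)

    def test_two_cluster_minimum(self):
        with pytest.raises(ValueError):
            population_R_test(np.ones((1, 5)), n_perm=50)
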