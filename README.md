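# ephysflow

Simulation and analysis pipeline for task-locked intracranial
electrophysiology. The package generates synthetic multichannel LFP/iEEG
recordings and subthalamic spike trains with parameterized, known
ground-truth effects, and implements the full analysis chain used to
recover them:

- **`synthetic_data`** — block-structured task events (8 trials/block,
  4 targets + 4 distractors, randomly interleaved, ~1000 ± 100 ms
  inter-onset), 1/f-coloured signals with narrowband theta and beta
  oscillators carrying stimulus-locked beta desynchronization
  (condition-dependent rebound latency), theta gain, a progressive
  within-block beta decline, a shared beta source coupling one
  subcortical and one cortical channel, and inhomogeneous-Poisson spike
  trains with von Mises beta-phase locking.
- **`preprocess`** — zero-phase bandpass (1–500 Hz) + 60 Hz notch
  filtering, polyphase downsampling to 1 kHz, common-average referencing
  (macro group), bipolar referencing (strip contacts), buffered epoching
  (−250..1250 ms, 1000 ms buffers), automatic amplitude-outlier trial
  flagging.
- **`spectral`** — complex Morlet bank (wavenumber 6; default 47
  log-spaced frequencies, 8 scales/octave from 2 Hz), power and phase
  extraction, percent-change baseline normalization (500 ms pre-stimulus,
  pooled across trials by default), theta/beta band averaging.
- **`perm_stats`** — two-level permutation framework: sign-flip and
  condition-label surrogates, z/p maps via the normal CDF of the
  surrogate-standardized statistic, exceedance-mass cluster correction
  (sum-of-z cluster statistic against the permutation distribution of
  maximum cluster statistics; 2D time-frequency and 1D band variants),
  per-electrode trial-level tests, band-power-vs-trial-position
  regression, and repeated-measures ANOVA.
- **`connectivity`** — trial-wise sliding-window (250 ms, 1 ms step)
  magnitude coherence, phase synchrony (window-mean unit cross-spectrum),
  across-trial Spearman power correlation, baseline normalization, and
  session-level condition contrasts.
- **`spiking`** — trial spike extraction with 10-SD outlier-trial
  exclusion, Gaussian-kernel (50 ms SD) continuous firing rates with
  exact mass conservation, baseline z-normalization, per-cluster and
  population rate tests, and surrogate-normalized spike-phase locking
  (mean vector length r; trial-scramble surrogates; normalized R) with a
  population frequency-cluster test.
- **`pipeline` / `cli` / `config`** — schema-validated TOML/JSON run
  configuration, deterministic seed fan-out, stage orchestration with
  HDF5/TSV/JSON artifacts and a JSON run report.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria; the type-I
calibration test (200 repetitions × 20 sessions) takes several minutes,
everything else is fast.

## CLI

```bash
ephysflow run --seed 1 --out out/            # all stages, default config
ephysflow simulate --config cfg.toml --seed 2 --out out/
ephysflow report --out out/
```

Subcommands `simulate`, `preprocess`, `spectral`, `stats`, `connect`,
`spikes` run the pipeline through the named stage. A config file may set
any subsection, e.g.:

```toml
seed = 7

[task]
n_blocks = 30

[truth]
erd_depth_target = 0.35
rebound_latency_distractor = 500.0

[stats]
n_perm = 200
```

Exit codes: 0 success, 2 configuration error, 1 stage failure.

## Reproducibility

All randomness derives from a single top-level seed via a documented
per-stage/per-session derivation (`ephysflow.pipeline.derive_seed`);
identical configs reproduce statistics bit-for-bit.
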