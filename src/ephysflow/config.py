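"""Run configuration: schema-checked parameters with study defaults.

Unknown keys are rejected; units are ms and Hz throughout.  A config file
may be TOML or JSON; an empty file yields the full default configuration.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TaskSection(_Strict):
    n_blocks: int = 30
    trials_per_block: int = Field(8, gt=0)
    n_target_per_block: int = Field(4, ge=0)
    stim_duration: float = Field(500.0, gt=0)
    isi_mean: float = Field(500.0, gt=0)
    isi_jitter: float = Field(100.0, ge=0)
    error_fraction: float = Field(0.0, ge=0.0, le=1.0)


class TruthSection(_Strict):
    beta_freq: float = Field(20.0, gt=0)
    erd_depth_target: float = Field(0.35, ge=0, le=1)
    erd_depth_distractor: float = Field(0.35, ge=0, le=1)
    rebound_latency_target: float = Field(1000.0, ge=0)
    rebound_latency_distractor: float = Field(500.0, ge=0)
    theta_gain: float = 0.3
    block_slope: float = 0.04
    coupling_phase_lag: float = 0.5
    coupling_strength: float = Field(0.4, ge=0, le=1)
    coupling_gain_target: float = 0.0
    coupling_gain_distractor: float = 0.0
    spike_base_rate: float = Field(36.0, ge=0)
    spike_rate_modulation: float = -0.4
    kappa: float = Field(0.6, ge=0)
    preferred_phase: float = 0.0
    noise_exponent: float = 1.0
    beta_amp: float = 1.0
    theta_amp: float = 0.7
    theta_freq: float = 5.0
    noise_amp: float = 1.0


class SimulateSection(_Strict):
    n_sessions: int = Field(4, gt=0)
    fs: float = Field(1000.0, gt=0)
    generate_at_1500: bool = False     # exercise the decimation path
    n_stn: int = Field(3, ge=1)
    n_lat: int = Field(3, ge=2)


class PreprocessSection(_Strict):
    low: float = Field(1.0, gt=0)
    high: float = Field(500.0, gt=0)
    notch: float = Field(60.0, ge=0)
    target_fs: float = Field(1000.0, gt=0)
    window: tuple[float, float] = (-250.0, 1250.0)
    buffer: float = Field(1000.0, ge=0)
    artifact_z: float = Field(6.0, gt=0)


class SpectralSection(_Strict):
    fmin: float = Field(2.0, gt=0)
    scales_per_octave: int = Field(8, gt=0)
    n_freqs: int = Field(47, gt=0)
    wavenumber: float = Field(6.0, gt=0)
    baseline: tuple[float, float] = (-500.0, 0.0)
    baseline_margin: float = Field(250.0, ge=0)
    per_trial_baseline: bool = False


class StatsSection(_Strict):
    n_perm: int = Field(200, gt=0)
    threshold: float = Field(0.05, gt=0, lt=1)
    alpha: float = Field(0.05, gt=0, lt=1)
    theta_band: tuple[float, float] = (2.0, 8.0)
    beta_band: tuple[float, float] = (15.0, 30.0)

    @field_validator("theta_band", "beta_band")
    @classmethod
    def _ordered(cls, v):
        if v[0] >= v[1]:
            raise ValueError(f"band bounds out of order: {v}")
        return v


class ConnectSection(_Strict):
    window: float = Field(250.0, gt=0)
    step: float = Field(1.0, gt=0)
    smooth: float = Field(250.0, gt=0)
    select_significant_contacts: bool = True


class SpikesSection(_Strict):
    kernel_sd: float = Field(50.0, gt=0)
    bin_ms: float = Field(1.0, gt=0)
    n_surr: int = Field(200, gt=0)
    locking_window: tuple[float, float] = (0.0, 1000.0)


class StagesSection(_Strict):
    simulate: bool = True
    preprocess: bool = True
    spectral: bool = True
    stats: bool = True
    connect: bool = True
    spikes: bool = True


class RunConfig(_Strict):
    seed: int = 0
    out: str = "ephysflow_out"
    task: TaskSection = TaskSection()
    truth: TruthSection = TruthSection()
    simulate: SimulateSection = SimulateSection()
    preprocess: PreprocessSection = PreprocessSection()
    spectral: SpectralSection = SpectralSection()
    stats: StatsSection = StatsSection()
    connect: ConnectSection = ConnectSection()
    spikes: SpikesSection = SpikesSection()
    stages: StagesSection = StagesSection()


def validate_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load and schema-check a TOML or JSON config file.

    Unknown keys, wrong types and out-of-range values raise
    ``pydantic.ValidationError`` naming the offending field.
    """
    data: dict = {}
    if path is not None:
        path = Path(path)
        text = path.read_text()
        if not text.strip():
            data = {}
        elif path.suffix == ".json":
            data = json.loads(text)
        else:
            data = tomllib.loads(text)
    data.update(overrides)
    return RunConfig.model_validate(data)
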