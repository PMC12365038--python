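"""Validated pipeline configuration.

Defaults mirror the task and analysis parameters of the experiment the
pipeline models: 16 s trials with rest every 10, gamma(4, 0.3) target counts,
16 fT/sqrt(Hz) bad-channel floor over 5-150 Hz, 3x-SD trial rejection, 5%
Tikhonov regularisation, 1-48 Hz and 13-30 Hz bands, a 3-state HMM binarised
at 2/3, and BH correction at q = 5%.  The ``profile`` switches between the
full-scale acquisition geometry (1200 Hz, 64 sensors, 78 regions) and the
desk-scale one used for fast validation runs (200 Hz, 8 sensors, 4 regions).
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParadigmConfig(_Strict):
    n_trials: int = Field(80, ge=0)
    rest_every: int = Field(10, ge=1)
    gamma_shape: float = Field(4.0, gt=0)
    gamma_scale: float = Field(0.3, gt=0)
    response_error_rate: float = Field(0.05, ge=0, le=1)

    @model_validator(mode="after")
    def _balanced(self):
        if self.n_trials % 2:
            raise ValueError("paradigm.n_trials must be even (balanced cues)")
        return self


class BurstConfig(_Strict):
    baseline_rate: float = Field(1.2, gt=0)
    duration_mu: float = Field(-1.386, description="log-normal mu, log-seconds")
    duration_sigma: float = Field(0.4, gt=0)
    amplitude: float = Field(20e-9, gt=0)
    alpha_weight: float = Field(1.0, ge=0)
    beta_weight: float = Field(0.6, ge=0)
    attended_rate_factor: float = Field(0.65, ge=0, le=1)
    stim_suppression_factor: float = Field(0.5, ge=0, le=1)


class SimulationConfig(_Strict):
    n_sensors: int = Field(8, ge=4)
    helmet_radius: float = Field(0.12, gt=0)
    n_regions: int = Field(4, ge=2)
    fs: float = Field(200.0, ge=200)
    noise_sd: float = Field(1.5e-13, ge=0)
    drift_amplitude: float = Field(5e-12, ge=0)
    burst: BurstConfig = BurstConfig()


class PreprocessConfig(_Strict):
    floor_fT: float = Field(16.0, gt=0)
    band: tuple[float, float] = (5.0, 150.0)
    sd_k: float = Field(3.0, gt=0)
    welch_segment_s: float = Field(2.0, gt=0)
    qc_duration_s: float | None = Field(
        120.0, gt=0,
        description="PSD-based channel QC uses at most this much data (None = all)")

    @model_validator(mode="after")
    def _band_ok(self):
        if not self.band[0] < self.band[1]:
            raise ValueError("preprocess.band must satisfy f_lo < f_hi")
        return self


class BeamformerConfig(_Strict):
    broadband: tuple[float, float] = (1.0, 48.0)
    beta_band: tuple[float, float] = (13.0, 30.0)

    @model_validator(mode="after")
    def _bands_ok(self):
        for name in ("broadband", "beta_band"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ValueError(f"beamformer.{name} must satisfy 0 < f_lo < f_hi")
        return self


class HMMConfig(_Strict):
    k: int = Field(3, ge=1)
    n_lags: int = Field(11, ge=3)
    target_fs: float = Field(50.0, gt=0)
    pca_dims: int | None = 6
    threshold: float = Field(2.0 / 3.0, gt=0, le=1)
    n_restarts: int = Field(1, ge=1)
    max_iter: int = Field(20, ge=1)
    tol: float = Field(2e-4, gt=0)


class StatsConfig(_Strict):
    q: float = Field(0.05, gt=0, lt=1)
    merge_families: bool = False


class PipelineConfig(_Strict):
    n_subjects: int = Field(8, ge=1)
    seed: int = 0
    paradigm: ParadigmConfig = ParadigmConfig()
    simulation: SimulationConfig = SimulationConfig()
    preprocess: PreprocessConfig = PreprocessConfig()
    beamformer: BeamformerConfig = BeamformerConfig()
    hmm: HMMConfig = HMMConfig()
    stats: StatsConfig = StatsConfig()

    @model_validator(mode="after")
    def _cross_checks(self):
        if self.hmm.target_fs > self.simulation.fs:
            raise ValueError("hmm.target_fs must not exceed simulation.fs")
        if self.beamformer.broadband[1] >= self.simulation.fs / 2:
            raise ValueError("beamformer.broadband upper edge must be below Nyquist")
        return self


def full_scale_config(**overrides) -> PipelineConfig:
    """The full acquisition-scale profile (slow; for real-size runs)."""
    cfg = PipelineConfig(
        simulation=SimulationConfig(n_sensors=64, n_regions=78, fs=1200.0),
        hmm=HMMConfig(n_lags=15, target_fs=100.0, pca_dims=None, n_restarts=5,
                      max_iter=100),
        n_subjects=16,
    )
    return cfg.model_copy(update=overrides) if overrides else cfg


def validate_config(source: str | Path | dict | None = None) -> PipelineConfig:
    """Parse + range-check a YAML config; unknown keys are rejected.

    ``source`` may be a path, YAML text, a dict, or None/empty for the full
    default configuration.
    """
    if source is None:
        return PipelineConfig()
    if isinstance(source, dict):
        raw = source
    else:
        text = Path(source).read_text() if Path(str(source)).is_file() else str(source)
        raw = yaml.safe_load(text)
        if raw is None:
            return PipelineConfig()
        if not isinstance(raw, dict):
            raise ValueError("config must be a YAML mapping")
    return PipelineConfig(**raw)
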