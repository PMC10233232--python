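"""Run configuration: a JSON-schema-validated bundle of stage settings.

Defaults mirror the study conditions (49 subjects, 1,500 tones per entropy
condition, 6x6 sensor grid); examples and tests pass smaller explicit
values.  Unknown keys are rejected.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

from .simulate import DEFAULT_BETA, CohortConfig, SensorGrid


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParadigmSettings(_Strict):
    n_tones: int = 1500
    soa_s: float = 1.0 / 3.0
    ordered_residual: str = "self"


class SimulationSettings(_Strict):
    n_subjects: int = 49
    grid_nx: int = 6
    grid_ny: int = 6
    beta: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_BETA))
    noise_sd: float = 1.0
    subject_intercept_sd: float = 0.1
    g_pred_low: float = 0.0
    g_pred_high: float = 1.0
    leak: float = 0.3
    speech_duration_s: float = 180.0


class DecodingSettings(_Strict):
    dval_scale: str = "softmax"
    centering: str = "per_timepoint"
    window_lo_s: float = -0.3
    window_hi_s: float = 0.3


class EnvelopeSettings(_Strict):
    fmin_hz: float = 100.0
    fmax_hz: float = 10000.0
    n_bands: int = 9
    combine: str = "mean"
    antialias_hz: float = 45.0


class TRFSettings(_Strict):
    lag_lo_s: float = -0.1
    lag_hi_s: float = 0.5
    k_folds: int = 4
    step_fraction: float = 0.005
    patience: int = 10
    validation_fraction: float = 0.2


class StatsSettings(_Strict):
    draws: int = 1000
    warmup: int = 500
    n_chains: int = 4
    hdi_prob: float = 0.94
    min_neighbors: int = 2
    formula: str = "main"


class RunConfig(_Strict):
    seed: int = 0
    paradigm: ParadigmSettings = Field(default_factory=ParadigmSettings)
    simulation: SimulationSettings = Field(default_factory=SimulationSettings)
    decoding: DecodingSettings = Field(default_factory=DecodingSettings)
    envelope: EnvelopeSettings = Field(default_factory=EnvelopeSettings)
    trf: TRFSettings = Field(default_factory=TRFSettings)
    stats: StatsSettings = Field(default_factory=StatsSettings)

    def cohort_config(self) -> CohortConfig:
        sim = self.simulation
        return CohortConfig(
            n_subjects=sim.n_subjects,
            grid=SensorGrid(nx=sim.grid_nx, ny=sim.grid_ny),
            n_tones=self.paradigm.n_tones,
            soa_s=self.paradigm.soa_s,
            speech_duration_s=sim.speech_duration_s,
            beta=dict(sim.beta),
            noise_sd=sim.noise_sd,
            subject_intercept_sd=sim.subject_intercept_sd,
            g_pred_low=sim.g_pred_low,
            g_pred_high=sim.g_pred_high,
            leak=sim.leak,
            ordered_residual=self.paradigm.ordered_residual,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))
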