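"""Run configuration for the synthetic two-arm hypotension trial.

All tunables of the cohort generator live in :class:`SimConfig`; the
decision-protocol cut-offs live in :class:`ProtocolThresholds`.  Both can be
loaded from a flat YAML mapping so that a whole pipeline run is reproducible
from a single config file plus a seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Tuple

import yaml
from pydantic import BaseModel, Field, model_validator


class SimConfig(BaseModel):
    """Parameters of the synthetic cohort generator.

    The defaults encode the monitored-trial setting the downstream analysis
    assumes: vitals sampled every 20 s, a predictive index alarming above 85,
    clinicians acting within 2 min of an alarm in the guided arm and reacting
    to observed MAP < 65 mmHg in the standard-of-care arm.
    """

    n_per_arm: int = Field(default=30, ge=1)
    seed: int = Field(default=0, ge=0)
    cadence_s: float = Field(default=20.0, gt=0)

    # patient baseline MAP distribution (mmHg)
    baseline_map_mean: float = 85.0
    baseline_map_sd: float = Field(default=6.0, ge=0)

    # mean-reverting (OU) dynamics of the MAP path
    ou_reversion_rate: float = Field(default=0.2, ge=0, description="1/min")
    ou_noise_sd: float = Field(default=1.5, ge=0, description="mmHg/sqrt(min)")

    # hypotensive provocations (vasodilation, bleeding, ...)
    provocation_rate: float = Field(default=1.5, ge=0, description="events/hour")
    provocation_depth_range: Tuple[float, float] = (-38.0, -22.0)
    provocation_duration_mean: float = Field(default=10.0, gt=0, description="min")
    provocation_ramp_min: float = Field(default=3.0, gt=0)

    # predictive index / alarm behaviour
    index_alarm_threshold: float = Field(default=85.0, gt=0, lt=100)
    index_noise_sd: float = Field(default=2.0, ge=0)
    index_horizon_min: float = Field(default=15.0, gt=0)
    # risk discount applied to projected dips more than a minute away
    # (mmHg per min of remoteness): remote dips look shallower, so the alarm
    # fires minutes, not the full horizon, ahead of the event
    index_risk_discount: float = Field(default=1.0, ge=0)

    # clinician response latencies
    intervention_response_delay_s: float = Field(default=110.0, gt=0, le=120)
    control_detection_delay_s: float = Field(default=45.0, gt=0)

    # treatment pharmacodynamics: dose is titrated to the projected pressure
    # deficit, clipped to this absolute range (mmHg)
    treatment_effect_amplitude_range: Tuple[float, float] = (10.0, 40.0)
    treatment_effect_decay_min: float = Field(default=20.0, gt=0)
    fluid_ramp_min: float = Field(default=5.0, gt=0)

    # surgical duration: log-normal in minutes, clipped below
    duration_lognorm_params: Tuple[float, float] = (6.194, 0.39)
    duration_min_floor: float = Field(default=240.0, gt=0)

    # event analytics
    merge_window_min: float = Field(default=15.0, gt=0)

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check_ranges(self) -> "SimConfig":
        lo, hi = self.provocation_depth_range
        if not (lo <= hi <= 0):
            raise ValueError("provocation_depth_range must be negative offsets (lo <= hi <= 0)")
        alo, ahi = self.treatment_effect_amplitude_range
        if not (0 <= alo <= ahi):
            raise ValueError("treatment_effect_amplitude_range must be non-negative and ordered")
        return self

    def config_hash(self) -> str:
        """Stable digest of the full configuration (includes the seed)."""
        payload = json.dumps(self.model_dump(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()


class ProtocolThresholds(BaseModel):
    """Cut-offs of the hemodynamic diagnostic table.

    The published protocol prints its cut-offs only in a figure, so these are
    configurable surrogates following the usual goal-directed-therapy values:
    stroke volume variation above ~13 % flags preload responsiveness, dynamic
    arterial elastance below ~0.9 flags that volume alone will not raise
    pressure, and low systemic vascular resistance / systolic slope flag
    vasoplegia and depressed contractility.
    """

    svv_high: float = Field(default=13.0, gt=0, description="%")
    eadyn_high: float = Field(default=0.9, gt=0, description="ratio")
    svr_low: float = Field(default=800.0, gt=0, description="dyn*s/cm^5")
    dpdtmax_low: float = Field(default=500.0, gt=0, description="mmHg/s")

    model_config = {"frozen": True}


class ConfigError(ValueError):
    """Raised when a config file cannot be parsed or validated."""


def load_config(path: str | Path) -> tuple[SimConfig, ProtocolThresholds]:
    """Load a flat YAML config; unknown keys are rejected.

    Keys matching SimConfig fields configure the generator; keys matching
    ProtocolThresholds configure the decision table.
    """
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a flat mapping")

    sim_keys = set(SimConfig.model_fields)
    proto_keys = set(ProtocolThresholds.model_fields)
    unknown = set(raw) - sim_keys - proto_keys
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        sim = SimConfig(**{k: v for k, v in raw.items() if k in sim_keys})
        proto = ProtocolThresholds(**{k: v for k, v in raw.items() if k in proto_keys})
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    return sim, proto
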