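"""Experiment configuration: validated, serializable, hash-stamped.

Every parameter the source circuit leaves open (gains, thresholds, reset
time constants, associative fan-out, calibration anchors) lives here, so
replications and sensitivity analyses need no code changes.  Unknown keys
are rejected with a message naming the key; a SHA-256 hash of the
canonical serialization is embedded in every output file for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Dict, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .circuit import ARTParams

__all__ = ["ExperimentConfig", "load_config", "save_config"]

_ART_FLOAT_FIELDS = {
    f.name
    for f in dataclasses.fields(ARTParams)
    if f.type in ("float", float)
}


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class StimulusConfig(_Strict):
    """Hue-array geometry and word-grid conventions."""

    hue_width: int = Field(4, ge=1)
    fan_out: int = Field(2, ge=1)
    gap: int = Field(2, ge=0)
    margin: int = Field(2, ge=0)
    bump_shape: str = "boxcar"

    @field_validator("bump_shape")
    @classmethod
    def _shape(cls, v):
        if v not in ("boxcar", "halfcos"):
            raise ValueError("bump_shape must be 'boxcar' or 'halfcos'")
        return v


class ResponseConfig(_Strict):
    """Comparison layers and leaky-competing-accumulator response units."""

    c1_threshold: float = 1.2  # elevated AND threshold over F2+F5 input
    c2_threshold: float = 0.2  # per-node OR threshold
    diff_input_gate: float = 1.5  # Different unit needs two active C2 nodes
    same_gain: float = 2.0
    diff_gain: float = 3.0
    leak: float = 1.0
    mutual_inhibition: float = 0.5
    time_constant: float = 5.0
    motor_threshold: float = Field(0.5, gt=0.0)
    mismatch_veto_scale: float = 0.2  # comparison vetoed while category in doubt
    noise_sd: float = 0.0  # optional accumulator noise; off for replication


class TimingConfig(_Strict):
    """Integration step and trial-phase durations (simulation time units)."""

    dt: float = Field(0.01, gt=0.0)
    reference_phase: float = 40.0
    word_phase: float = 40.0
    target_onset: float = 40.0
    max_duration: float = 250.0
    fmri_duration: float = 40.0


class CalibrationConfig(_Strict):
    """Affine simulation-time -> millisecond map, anchored once per batch.

    The slope is fixed so the medium-speed interference equals
    ``anchor_interference_ms``; the intercept places the neutral reaction
    time at ``neutral_rt_ms`` (cosmetic: contrasts are intercept-free).
    """

    anchor_interference_ms: float = 60.0
    neutral_rt_ms: float = 500.0


class FmriConfig(_Strict):
    """Metabolic-proxy settings for the four task conditions."""

    passive_g1_extra: float = 8.0  # extra gain-node drive in passive perception
    floor_fraction: float = Field(0.05, gt=0.0, lt=1.0)


class ExperimentConfig(_Strict):
    """Top-level configuration of the full replication experiment."""

    stimuli: StimulusConfig = Field(default_factory=StimulusConfig)
    response: ResponseConfig = Field(default_factory=ResponseConfig)
    timing: TimingConfig = Field(default_factory=TimingConfig)
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    fmri: FmriConfig = Field(default_factory=FmriConfig)
    vigilance_color: float = Field(0.8, gt=0.0, le=1.0)
    vigilance_word: float = Field(0.8, gt=0.0, le=1.0)
    priming_gain: float = Field(0.85, ge=0.0)
    r_tau_fast: float = Field(4.0, gt=0.0)
    r_tau_medium: float = Field(8.0, gt=0.0)
    r_tau_slow: float = Field(16.0, gt=0.0)
    #: Named overrides of ARTParams float fields for either module.
    color_overrides: Dict[str, float] = Field(default_factory=dict)
    #: The word module runs a many-candidate category race (every committed
    #: word receives some bottom-up support), so its choice layer needs a
    #: stronger bottom-up gain to ignite before the gain control throttles
    #: the matching layer.
    word_overrides: Dict[str, float] = Field(
        default_factory=lambda: {"f2_from_f1": 0.6}
    )
    noise_seed: Optional[int] = None

    @field_validator("color_overrides", "word_overrides")
    @classmethod
    def _known_art_fields(cls, v):
        for key in v:
            if key not in _ART_FLOAT_FIELDS:
                raise ValueError(
                    f"unknown ART parameter {key!r}; valid keys: "
                    f"{sorted(_ART_FLOAT_FIELDS)}"
                )
        return v

    def r_time_constants(self) -> Dict[str, float]:
        taus = {
            "fast": self.r_tau_fast,
            "medium": self.r_tau_medium,
            "slow": self.r_tau_slow,
        }
        if not taus["fast"] < taus["medium"] < taus["slow"]:
            raise ValueError("require r_tau_fast < r_tau_medium < r_tau_slow")
        return taus

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML config; defaults fill anything omitted."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    try:
        return ExperimentConfig(**data)
    except Exception as exc:  # re-raise with the offending file named
        raise ValueError(f"invalid experiment config {path}: {exc}") from exc


def save_config(config: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)
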