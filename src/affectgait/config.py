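"""Configuration models (pydantic) with YAML/JSON round-tripping.

The default metric-to-PAD matrix is a documented stand-in, not a canonical
published mapping: each PAD row reads a disjoint subset of the five metrics,

    pleasure  = 0.5 + 0.5 * (excitement - frustration)
    arousal   = 0.5 + 0.5 * (engagement - meditation)
    dominance = 1.0 - boredom

so the map is midpoint-centred, sign-interpretable, and exactly invertible on
the whole [0,1]^3 cube (which the synthetic generator relies on). Replace the
matrix wholesale if a calibrated mapping for a specific headset is available.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ConfigurationError
from .types import DIMENSIONS, METRICS, N_REGIONS

_DEFAULT_WEIGHTS = (
    # engagement, boredom, excitement, frustration, meditation
    (0.0, 0.0, 0.5, -0.5, 0.0),   # pleasure
    (0.5, 0.0, 0.0, 0.0, -0.5),   # arousal
    (0.0, -1.0, 0.0, 0.0, 0.0),   # dominance
)
_DEFAULT_OFFSETS = (0.5, 0.5, 1.0)


class MappingConfig(BaseModel):
    """Affine metric-to-PAD map: PAD = clip(weights @ metrics + offsets)."""

    weights: tuple[tuple[float, float, float, float, float],
                   tuple[float, float, float, float, float],
                   tuple[float, float, float, float, float]] = _DEFAULT_WEIGHTS
    offsets: tuple[float, float, float] = _DEFAULT_OFFSETS
    clip: bool = True

    @model_validator(mode="after")
    def _check_range(self) -> "MappingConfig":
        if not self.clip:
            # Without clipping the map must keep the unit cube inside [0,1]^3;
            # check the extreme corners row by row (affine => corners suffice).
            w = np.asarray(self.weights)
            o = np.asarray(self.offsets)
            lo = o + np.where(w < 0, w, 0.0).sum(axis=1)
            hi = o + np.where(w > 0, w, 0.0).sum(axis=1)
            if (lo < -1e-12).any() or (hi > 1 + 1e-12).any():
                raise ValueError(
                    "mapping can leave [0,1]^3 and clip is disabled"
                )
        return self

    def weight_matrix(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)

    def offset_vector(self) -> np.ndarray:
        return np.asarray(self.offsets, dtype=float)


class SyntheticConfig(BaseModel):
    """Conditions for one simulated therapy session.

    Defaults emulate a ~33-minute robot-assisted gait therapy session with
    skewed region occupancy (mostly "unsatisfied" pleasure, "wide-awake"
    arousal, low dominance), eight video reviewers who annotate perceived
    changes imperfectly, and mildly noisy EEG metric streams.
    """

    seed: int = 0
    session_length_s: float = Field(default=1959.0, gt=0)
    sample_rate_hz: float = Field(default=1.0, gt=0)
    region_stationary_probs: dict[str, tuple[float, float, float, float, float]] = {
        "pleasure": (0.02, 0.62, 0.03, 0.31, 0.02),
        "arousal": (0.02, 0.31, 0.03, 0.62, 0.02),
        "dominance": (0.03, 0.90, 0.03, 0.02, 0.02),
    }
    mean_dwell_s: float = Field(default=60.0, gt=0)
    metric_noise_sd: float = Field(default=0.05, ge=0)
    n_reviewers: int = Field(default=8, ge=1)
    p_detect: float = Field(default=0.8, ge=0, le=1)
    p_agree: float = Field(default=0.85, ge=0, le=1)
    jitter_sd_s: float = Field(default=2.0, ge=0)

    @field_validator("region_stationary_probs")
    @classmethod
    def _check_probs(cls, v):
        if set(v) != set(DIMENSIONS):
            raise ValueError(f"need probabilities for exactly {DIMENSIONS}")
        for dim, probs in v.items():
            arr = np.asarray(probs, dtype=float)
            if arr.shape != (N_REGIONS,):
                raise ValueError(f"{dim}: need {N_REGIONS} probabilities")
            if (arr < 0).any():
                raise ValueError(f"{dim}: negative probability")
            if abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"{dim}: probabilities sum to {arr.sum()}, not 1")
        return v

    def stationary(self, dimension: str) -> np.ndarray:
        return np.asarray(self.region_stationary_probs[dimension], dtype=float)


class AlignmentConfig(BaseModel):
    """Interval-matching options.

    Every overlapping machine/human interval pair is one match; the optional
    ``min_overlap_s`` threshold and duration weighting are off by default.
    """

    min_overlap_s: float = Field(default=0.0, ge=0)
    weight_by_duration: bool = False


class PipelineConfig(BaseModel):
    """Top-level configuration for the end-to-end pipeline."""

    mapping: MappingConfig = MappingConfig()
    alignment: AlignmentConfig = AlignmentConfig()
    synthetic: SyntheticConfig = SyntheticConfig()
    n_sessions: int = Field(default=8, ge=1)
    output_dir: str = "affectgait-out"
    log_level: Literal["DEBUG", "INFO", "WARNING", "ERROR"] = "INFO"


def load_config(path: str | Path, model=PipelineConfig):
    """Load a pydantic config from a YAML or JSON file (by extension)."""
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        return model.model_validate(data or {})
    except (OSError, ValueError, yaml.YAMLError) as exc:
        raise ConfigurationError(f"cannot load config {path}: {exc}") from exc


def save_config(cfg: BaseModel, path: str | Path) -> None:
    path = Path(path)
    data = json.loads(cfg.model_dump_json())
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")
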