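"""Run configuration with strict key validation.

A ``RunConfig`` is a flat-ish mapping: a ``stage`` name, a ``seed``, and a
``params`` block whose allowed keys depend on the stage.  Unknown keys are
rejected; physical quantities carry explicit unit suffixes in their key
names (``_uM``, ``_M``, ``_s``, ``_hz``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

SCHEMA_VERSION = "1"

STAGE_PARAMS: dict[str, set[str]] = {
    "titration": {
        "kd_uM", "f_min", "f_max", "top_conc_uM", "n_dilutions", "factor",
        "replicates", "cv", "additive_floor", "direction", "fix_hill",
    },
    "ca_titration": {
        "kd_uM", "f_min", "f_max", "top_conc_uM", "n_dilutions", "factor",
        "replicates", "cv", "additive_floor", "direction", "fix_hill",
    },
    "ph_calibration": {
        "amplitude", "steepness", "midpoint", "direction", "ph_min", "ph_max",
        "n_points", "replicates", "cv",
    },
    "split_association": {
        "kd_binder_M", "kd_fragments_uM", "partner_total_uM", "p_folded",
        "titrant_max_uM", "n_points", "cv",
    },
    "kinetics": {"plateau", "k_obs_s", "start", "t_step_s", "t_end_s", "cv"},
    "bleach": {"h", "k_per_frame", "n_frames", "frame_rate_hz", "cv"},
    "roi_cohort": {
        "n_rois", "stim_frame", "amplitude_mean", "amplitude_sd", "sign",
        "n_frames", "frame_rate_hz", "cv",
    },
}


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    stage: str
    seed: int = 0
    params: dict = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.stage not in STAGE_PARAMS:
            raise ConfigError(
                f"unknown stage {self.stage!r}; valid: {sorted(STAGE_PARAMS)}"
            )
        unknown = set(self.params) - STAGE_PARAMS[self.stage]
        if unknown:
            raise ConfigError(
                f"unknown parameter key(s) for stage {self.stage!r}: {sorted(unknown)}"
            )
        if self.schema_version != SCHEMA_VERSION:
            raise ConfigError(
                f"schema version {self.schema_version!r} != {SCHEMA_VERSION!r}"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        allowed = {"stage", "seed", "params", "schema_version"}
        unknown = set(d) - allowed
        if unknown:
            raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
        if "stage" not in d:
            raise ConfigError("config requires a 'stage' key")
        return cls(
            stage=d["stage"],
            seed=int(d.get("seed", 0)),
            params=dict(d.get("params", {})),
            schema_version=str(d.get("schema_version", SCHEMA_VERSION)),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
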