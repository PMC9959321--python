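"""Pipeline configuration: YAML-loadable, strictly validated."""

from __future__ import annotations

from dataclasses import fields as dc_fields
from pathlib import Path
from typing import Any, Dict, Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .errors import ConfigError
from .simulate import SimConfig

_SIM_FIELDS = {f.name for f in dc_fields(SimConfig)}


class PipelineConfig(BaseModel):
    """End-to-end run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    out_dir: Path = Path("mpra_run")
    seed: int = 0
    simulation: Dict[str, Any] = {}
    hcdnv_fdr: float = 0.2
    hcdnv_abs_lfc: float = 0.1
    motif_p: float = 1e-5
    activity_fdr: float = 0.05
    annotation_family_size: Optional[int] = None
    motif_file: Optional[Path] = None
    motif_granularity: float = 1e-3

    @field_validator("hcdnv_fdr", "activity_fdr")
    @classmethod
    def _fdr_range(cls, v, info):
        if not (0 < v <= 1):
            raise ValueError(f"{info.field_name} must lie in (0, 1], got {v}")
        return v

    @field_validator("motif_p")
    @classmethod
    def _motif_p_range(cls, v):
        if not (0 < v < 1):
            raise ValueError(f"motif_p must lie in (0, 1), got {v}")
        return v

    @field_validator("hcdnv_abs_lfc")
    @classmethod
    def _lfc_range(cls, v):
        if v < 0:
            raise ValueError(f"hcdnv_abs_lfc must be non-negative, got {v}")
        return v

    @field_validator("motif_granularity")
    @classmethod
    def _gran_range(cls, v):
        if not (0 < v <= 0.1):
            raise ValueError(f"motif_granularity must lie in (0, 0.1], got {v}")
        return v

    @field_validator("simulation")
    @classmethod
    def _sim_keys(cls, v):
        unknown = set(v) - _SIM_FIELDS
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        if "seed" in v:
            raise ValueError("set the top-level seed, not simulation.seed")
        return v

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    def sim_config(self) -> SimConfig:
        try:
            return SimConfig(seed=self.seed, **self.simulation)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        d = self.model_dump()
        d["out_dir"] = str(d["out_dir"])
        if d.get("motif_file") is not None:
            d["motif_file"] = str(d["motif_file"])
        return d
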