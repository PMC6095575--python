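"""Validated configuration objects for the pipeline."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class PkConstants(BaseModel):
    """Fixed constants of the signal-to-concentration conversion.

    Defaults are the published analysis constants for 3T renal DCE-MRI:
    gadoterate relaxivity 2.8 L mmol^-1 s^-1, arterial blood T1 1664 ms,
    cortical kidney T1 1142 ms, flip angle 20 deg.  The TWIST repetition
    time is not part of the published protocol description; 4 ms is a
    typical value for a 3D TWIST acquisition and is configurable.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    relaxivity_r1: float = Field(2.8, gt=0, description="L mmol^-1 s^-1")
    t1_blood_s: float = Field(1.664, gt=0)
    t1_tissue_s: float = Field(1.142, gt=0)
    flip_angle_deg: float = Field(20.0, gt=0, le=90)
    tr_repetition_s: float = Field(0.004, gt=0)
    hematocrit: float = Field(0.42, ge=0, lt=1)
    apply_hematocrit: bool = True
    linear_concentration: bool = False  # linear dS ~ dR1 approximation instead of SPGR inversion


class RunConfig(BaseModel):
    """Top-level pipeline configuration (one YAML/JSON file)."""

    model_config = ConfigDict(extra="forbid")

    workspace: Path
    out_dir: Optional[Path] = None
    pk: PkConstants = PkConstants()
    enhancement_threshold: float = Field(0.05, ge=0)
    bic_sigma0: float = Field(0.05, ge=0)
    onset_frame: int = Field(5, ge=0)
    dce_exclusions: list[str] = Field(default_factory=list)
    seed: int = 0
    stages: list[str] = Field(
        default_factory=lambda: ["adc", "dce-semiquant", "dce-pk", "volumes", "correlate"]
    )

    @model_validator(mode="after")
    def _check_stages(self) -> "RunConfig":
        known = {"simulate", "adc", "dce-semiquant", "dce-pk", "volumes", "correlate"}
        bad = set(self.stages) - known
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
        return cls.model_validate(data)

    def config_hash(self) -> str:
        payload = self.model_dump_json(exclude={"out_dir"})
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
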