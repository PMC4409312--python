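"""Run configuration: a validated, serializable description of one run.

Every command writes its resolved configuration (all defaults filled in)
next to its outputs, so an artifact directory plus the package version is
sufficient to regenerate it exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, Field

from .models import (ELIFParams, PassiveLIFParams, HHParams, ModelParams)

__all__ = ["RunConfig", "ModelBlock", "NoiseBlock", "ProtocolBlock",
           "load_config"]


class ModelBlock(BaseModel):
    kind: Literal["elif", "passive_lif", "hh"] = "elif"
    params: dict = Field(default_factory=dict,
                         description="field overrides for the model kind")

    def build(self) -> ModelParams:
        cls = {"elif": ELIFParams, "passive_lif": PassiveLIFParams,
               "hh": HHParams}[self.kind]
        params = dict(self.params)
        for key in ("act_m", "act_n", "act_p"):
            if key in params:
                params[key] = tuple(params[key])
        return cls(**params)


class NoiseBlock(BaseModel):
    f_cut_Hz: float = 100.0
    target_sd_mV: float = 2.41
    coefficient: Optional[float] = None   # None: calibrate at run time
    seed: int = 0


class ProtocolBlock(BaseModel):
    step_amplitudes_pA: Optional[list[float]] = None
    amp_start_pA: float = 0.0
    amp_stop_pA: float = 600.0
    amp_step_pA: float = 25.0
    step_duration_ms: float = 1000.0
    pre_step_settle_ms: float = 1000.0
    repeats: int = 1
    dt_ms: float = 0.01

    def amplitudes(self):
        import numpy as np
        if self.step_amplitudes_pA is not None:
            return np.asarray(self.step_amplitudes_pA, dtype=float)
        return np.arange(self.amp_start_pA,
                         self.amp_stop_pA + 0.5 * self.amp_step_pA,
                         self.amp_step_pA)


class RunConfig(BaseModel):
    model: ModelBlock = Field(default_factory=ModelBlock)
    noise: NoiseBlock = Field(default_factory=NoiseBlock)
    protocol: ProtocolBlock = Field(default_factory=ProtocolBlock)
    analysis: dict = Field(default_factory=dict)
    outdir: str = "results"

    def write_resolved(self, directory) -> None:
        path = Path(directory) / "resolved_config.json"
        path.write_text(self.model_dump_json(indent=2))


def load_config(path: Optional[str]) -> RunConfig:
    """Load a JSON or YAML config file; missing path gives defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    if str(path).endswith((".yml", ".yaml")):
        import yaml
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return RunConfig.model_validate(data)
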