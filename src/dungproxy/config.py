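"""Structured run configuration driving every pipeline stage.

One YAML file parameterises the simulator, the intensity grid and kernel,
and the calibration stage; unknown keys are rejected so silent typos
cannot change a run.  CLI flags override config values, and the effective
configuration is echoed into each run's output directory.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .synthetic import SimConfig


class GridBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cell_size_m: float = Field(default=1.0, gt=0)


class KernelBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    bandwidth_m: float = Field(default=300.0, gt=0)


class CalibrationBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: str = "footprint_mean"            # or "center"
    ks: list[int] = Field(default_factory=lambda: [1, 2, 3, 4, 5, 6])
    exclude_june_same_month: bool = False   # drop the (June, k=1) pairing
    exclude_months: list[int] = Field(default_factory=list)
    riverbed_threshold: float = Field(default=0.5, gt=0, le=1)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sim: SimConfig = Field(default_factory=SimConfig)
    grid: GridBlock = Field(default_factory=GridBlock)
    kernel: KernelBlock = Field(default_factory=KernelBlock)
    calibration: CalibrationBlock = Field(default_factory=CalibrationBlock)
    outdir: str = "runs/default"
    seed: int | None = None   # overrides sim.seed when set

    def effective_sim(self) -> SimConfig:
        sim = self.sim
        if self.seed is not None:
            sim = sim.model_copy(update={"seed": self.seed})
        if self.kernel.bandwidth_m != sim.kernel_bandwidth_m:
            sim = sim.model_copy(update={"kernel_bandwidth_m": self.kernel.bandwidth_m})
        return sim


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def dump_run_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(mode="json")))
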