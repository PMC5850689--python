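"""Run configuration: validated YAML round-tripping to the model records.

The canonical configuration dialect is YAML.  An empty file (or no
file) yields the full baseline configuration; unknown keys are
rejected.  The model is deterministic, so a configuration carries no
random-number state and identical configurations produce identical
outputs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .params import ModelParameters
from .ode import ModelVariants, SolverOptions

__all__ = ["RunConfig", "load_config", "dump_config"]


class _ParamsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n: int = 4
    L_max: int = 10
    l_pi_min: int = 7
    l_pi_max: int = 10
    K_R_plus: float = 4.2e-7
    K_R_minus: float = 8e-9
    K_P_plus: float = 2.8e-21
    K_P_minus: float = 4e-11
    k_P1_plus: float = 0.1
    Z: float = 1e6
    h_R: float = 1e6
    k_step: float = 4e-5
    lambda_: float = Field(0.15, alias="lambda")
    k_t: float = 1.0
    rho_p: float = 1e-3
    rho_r: float = 1e-3

    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    def to_params(self) -> ModelParameters:
        return ModelParameters(**self.model_dump())


class _SolverBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    method: str = "BDF"
    rtol: float = 1e-8
    atol: float = 1e-40
    t_cap: float = 1e13
    window: float = 1e9
    delta: float = 1e-6
    eps: float = 1e-30
    save_per_chunk: int = 0

    def to_options(self) -> SolverOptions:
        return SolverOptions(**self.model_dump())


class _VariantsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    conservation_weights: Literal["class-count", "literal"] = \
        ModelVariants().conservation_weights
    binding_lengths: Literal["active", "all"] = ModelVariants().binding_lengths
    binding_classes: Literal["alpha", "all"] = ModelVariants().binding_classes
    alpha_catalysis: bool = ModelVariants().alpha_catalysis
    stabilization_inflow: Literal["by-length", "fragment"] = \
        ModelVariants().stabilization_inflow

    def to_variants(self) -> ModelVariants:
        return ModelVariants(**self.model_dump())


class _ExperimentBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    driver: Literal["simulate", "critical", "taupol", "krsweep", "tables"] = \
        "simulate"
    mode: Literal["joint", "rho_r"] = "joint"
    bracket: tuple[float, float] = (2e-4, 1e-2)
    tol: float = 5e-5
    rho: Optional[float] = None
    tau_grid: Optional[list[float]] = None
    kr_minus_grid: Optional[list[float]] = None
    table: int = 1
    fast: bool = False


class _OutputBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    directory: str = "."
    trajectory: str = "trajectory.tsv"
    summary: str = "summary.tsv"
    format: Literal["tsv", "csv"] = "tsv"


class RunConfig(BaseModel):
    """Full, validated run configuration with baseline defaults."""

    model_config = ConfigDict(extra="forbid")

    parameters: _ParamsBlock = Field(default_factory=_ParamsBlock)
    solver: _SolverBlock = Field(default_factory=_SolverBlock)
    variants: _VariantsBlock = Field(default_factory=_VariantsBlock)
    experiment: _ExperimentBlock = Field(default_factory=_ExperimentBlock)
    output: _OutputBlock = Field(default_factory=_OutputBlock)

    @model_validator(mode="after")
    def _check_params(self):
        # construct the runtime records now so that invariant breaches
        # surface as configuration errors naming the offending block
        try:
            self.parameters.to_params()
        except ValueError as err:
            raise ValueError(f"parameters: {err}") from err
        return self

    def to_runtime(self):
        return (self.parameters.to_params(), self.solver.to_options(),
                self.variants.to_variants())


def load_config(path: str | Path | None) -> RunConfig:
    """Parse and validate a YAML run configuration.

    ``None`` or an empty file produces the all-defaults (baseline)
    configuration.
    """
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return RunConfig.model_validate(data)


def dump_config(config: RunConfig) -> str:
    """Serialize the effective configuration back to canonical YAML."""
    data = config.model_dump(by_alias=True)
    return yaml.safe_dump(data, sort_keys=False)
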