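"""Scenario configuration: schema, validation, serialization.

A scenario is one self-contained experiment definition — world,
estimator bank, loop, inversion, channel and drive settings plus a root
seed — stored as a single human-editable file (YAML accepted, JSON
canonical).  The schema is strict: unknown keys are rejected, and
validation errors name the offending key with its dotted path.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .dialogue import ChannelConfig
from .drive import DriveConfig
from .estimator import EstimatorBank, make_component
from .inversion import InversionConfig
from .loop import LoopConfig
from .world import Bump, WorldConfig

__all__ = [
    "ConfigError",
    "ScenarioConfig",
    "load_config",
    "write_config",
]


class ConfigError(ValueError):
    """A scenario file failed schema validation."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BumpModel(_Strict):
    center: list[float]
    height: float = Field(gt=0)
    width: float = Field(gt=0)


class WorldModel(_Strict):
    dim_form: int = Field(ge=1)
    dim_env: int = Field(default=0, ge=0)
    landscape: list[BumpModel] = Field(min_length=1)
    env_timescale: float = Field(default=100.0, gt=0)
    env_sd: float = Field(default=1.0, ge=0)
    obs_noise_sd: float = Field(default=0.0, ge=0)
    dt: float = Field(default=0.01, gt=0)
    init_scale: float = Field(default=1.0, ge=0)
    env_gate: float = 0.0

    def build(self) -> WorldConfig:
        return WorldConfig(
            dim_form=self.dim_form,
            dim_env=self.dim_env,
            landscape=tuple(
                Bump(center=tuple(b.center), height=b.height, width=b.width)
                for b in self.landscape
            ),
            env_timescale=self.env_timescale,
            env_sd=self.env_sd,
            obs_noise_sd=self.obs_noise_sd,
            dt=self.dt,
            init_scale=self.init_scale,
            env_gate=self.env_gate,
        )


class ComponentModel(_Strict):
    id: str = "comp"
    m: int = Field(ge=1)
    n: int = Field(ge=1)
    kind: Literal["linear_monotone", "blackbox"] = "linear_monotone"
    ensemble: Literal["gaussian", "identity"] = "gaussian"
    nonlinearity: Literal["identity", "softplus_floor"] = "softplus_floor"
    scale: float = Field(default=1.0, gt=0)
    drift_timescale: float = Field(default=100.0, gt=0)
    drift_sd: float = Field(default=0.0, ge=0)
    cond_cap: float = Field(default=1e4, gt=1)
    # explicit parameters override the random ensemble when given
    A: Optional[list[list[float]]] = None
    b: Optional[list[float]] = None

    def build(self, seed: int):
        comp = make_component(self.model_dump(exclude={"A", "b"}), seed)
        if self.A is not None or self.b is not None:
            from dataclasses import replace

            A = np.asarray(self.A, dtype=float) if self.A is not None else comp.A
            b = np.asarray(self.b, dtype=float) if self.b is not None else comp.b
            comp = replace(comp, A=A, b=b, A_ref=A.copy(), b_ref=b.copy())
        return comp


class BankModel(_Strict):
    components: list[ComponentModel] = Field(min_length=1)
    weights: Optional[list[float]] = None
    output_map: Literal["softplus", "relu"] = "softplus"

    def build(self, seed: int) -> EstimatorBank:
        comps = tuple(c.build(seed + i) for i, c in enumerate(self.components))
        w = None if self.weights is None else np.asarray(self.weights, dtype=float)
        return EstimatorBank(components=comps, weights=w, output_map=self.output_map)


class InversionModel(_Strict):
    gain: float = Field(default=100.0, gt=0)
    preconditioner: Literal["auto", "identity", "transpose_linearization"] = "auto"
    mode: Literal["fixed_point", "dynamical"] = "fixed_point"
    damping: float = Field(default=0.5, gt=0, le=1)
    tol: float = Field(default=1e-10, gt=0)
    max_iter: int = Field(default=10_000, ge=1)
    delay_steps: int = Field(default=0, ge=0)
    relax_step: float = Field(default=0.002, gt=0)
    fd_step: float = Field(default=1e-6, gt=0)

    def build(self) -> InversionConfig:
        return InversionConfig(**self.model_dump())


class LoopModel(_Strict):
    cycle_period: float = Field(default=0.1, gt=0)
    duty: float = Field(default=0.5, gt=0, lt=1)
    mode: Literal["external_input", "internal_dialogue"] = "external_input"
    drift_within_cycle: bool = False

    def build(self, inversion: InversionConfig) -> LoopConfig:
        return LoopConfig(inversion=inversion, **self.model_dump())


class ChannelModel(_Strict):
    noise_sd: float = Field(default=0.0, ge=0)
    gain_loss: float = Field(default=1.0, gt=0, le=1)

    def build(self) -> ChannelConfig:
        return ChannelConfig(**self.model_dump())


class DriveModel(_Strict):
    sigma_max: float = Field(default=0.25, ge=0)
    modulation_family: Literal["hill", "exponential"] = "hill"
    x_half: float = Field(default=0.15, gt=0)
    steepness: float = Field(default=4.0, gt=0)
    horizon_steps: int = Field(default=4000, ge=1)
    estimate_noise_sd: float = Field(default=0.0, ge=0)
    n_seeds: int = Field(default=20, ge=1)
    control: Literal["matched_mean_sigma", "fixed_sigma"] = "matched_mean_sigma"
    fixed_sigma: Optional[float] = None
    f_plus_window_frac: float = Field(default=0.2, gt=0, le=1)
    estimate_source: Literal["noisy_truth", "estimator_bank"] = "noisy_truth"

    def build(self) -> DriveConfig:
        return DriveConfig(**self.model_dump())


class OutputsModel(_Strict):
    directory: str = "."
    formats: list[Literal["csv", "json"]] = Field(
        default_factory=lambda: ["csv", "json"]
    )


class ScenarioConfig(_Strict):
    """The full scenario file.

    ``scenario`` selects the experiment kind the runner dispatches on;
    sections irrelevant to a kind may be omitted.
    """

    scenario: Literal[
        "invert", "loop", "internal_dialogue", "dialogue", "drive", "stability"
    ]
    id: str = "scenario"
    seed: int = 0
    world: Optional[WorldModel] = None
    bank: Optional[BankModel] = None
    loop: LoopModel = Field(default_factory=LoopModel)
    inversion: InversionModel = Field(default_factory=InversionModel)
    channel: ChannelModel = Field(default_factory=ChannelModel)
    drive: DriveModel = Field(default_factory=DriveModel)
    gains: Optional[list[float]] = None
    delays: Optional[list[int]] = None
    probe: Optional[list[float]] = None
    u_init: Optional[list[float]] = None
    n_cycles: int = Field(default=200, ge=0)
    n_turns: int = Field(default=20, ge=1)
    n_seeds: int = Field(default=20, ge=2)
    mismatch_delta: float = Field(default=0.0, ge=0)
    outputs: OutputsModel = Field(default_factory=OutputsModel)

    def config_hash(self) -> str:
        import hashlib

        canonical = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def _dotted(loc) -> str:
    return ".".join(str(p) for p in loc)


def _validate(raw: dict) -> ScenarioConfig:
    try:
        return ScenarioConfig.model_validate(raw)
    except ValidationError as exc:
        msgs = [f"{_dotted(e['loc'])}: {e['msg']}" for e in exc.errors()]
        raise ConfigError("invalid scenario config — " + "; ".join(msgs)) from exc


def load_config(path: str | Path) -> ScenarioConfig:
    """Parse and validate a scenario file (YAML or JSON)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    return _validate(raw)


def write_config(config: ScenarioConfig, path: str | Path) -> Path:
    """Serialize a scenario (canonical JSON, or YAML by extension)."""
    path = Path(path)
    data = config.model_dump(mode="json")
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    return path
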