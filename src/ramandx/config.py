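"""Run configuration: a validated YAML/JSON schema covering every stage.

Unknown keys are rejected with a field path; defaults reproduce the study
conditions (804-sample cohort, 7:3 split, the fixed CNN architecture).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from . import preprocess as _pp
from . import synth as _synth
from .cnn import CNNSpec
from .errors import ConfigError
from .evaluate import ModelGrids


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PeakSettings(_Strict):
    center: float
    width: float = Field(gt=0)
    base_amplitude: float = Field(ge=0)
    class_multipliers: dict[str, float] = Field(default_factory=dict)


class GeneratorSettings(_Strict):
    n_per_class: dict[str, int] = Field(
        default_factory=lambda: {"HC": 241, "BC": 463, "DCIS": 100}
    )
    peaks: Optional[list[PeakSettings]] = None  # None -> default 11-band set
    baseline_coeffs: list[float] = list(_synth.DEFAULT_BASELINE_COEFFS)
    noise_sd: float = Field(default=0.01, ge=0)
    jitter_sd: float = Field(default=0.08, ge=0)
    replicates: int = Field(default=5, ge=1)
    axis_start: float = 400.0
    axis_stop: float = 4000.0
    axis_points: int = Field(default=1698, ge=8)

    def to_domain(self, seed: int) -> _synth.GeneratorConfig:
        peaks = (
            _synth.default_peaks()
            if self.peaks is None
            else [
                _synth.PeakSpec(
                    center=p.center,
                    width=p.width,
                    base_amplitude=p.base_amplitude,
                    class_multipliers=p.class_multipliers or {c: 1.0 for c in ("HC", "BC", "DCIS")},
                )
                for p in self.peaks
            ]
        )
        return _synth.GeneratorConfig(
            n_per_class=self.n_per_class,
            peaks=peaks,
            baseline_coeffs=tuple(self.baseline_coeffs),
            noise_sd=self.noise_sd,
            jitter_sd=self.jitter_sd,
            replicates=self.replicates,
            seed=seed,
            axis_start=self.axis_start,
            axis_stop=self.axis_stop,
            axis_points=self.axis_points,
        )


class PreprocessSettings(_Strict):
    sg_window: int = 11
    sg_order: int = 3
    airpls_lambda: float = Field(default=1e5, gt=0)
    airpls_ratio: float = Field(default=1e-3, gt=0, lt=1)
    airpls_maxiter: int = Field(default=30, ge=1)

    @field_validator("sg_window")
    @classmethod
    def _odd(cls, v: int) -> int:
        if v % 2 == 0:
            raise ValueError("sg_window must be odd")
        return v

    def to_domain(self) -> _pp.PreprocessConfig:
        return _pp.PreprocessConfig(
            sg_window=self.sg_window,
            sg_order=self.sg_order,
            airpls_lambda=self.airpls_lambda,
            airpls_ratio=self.airpls_ratio,
            airpls_maxiter=self.airpls_maxiter,
        )


class CNNSettings(_Strict):
    conv_channels: list[int] = [8, 16]
    kernel_len: int = 3
    pool_len: int = 3
    hidden_activation: str = "tanh"
    batch_size: int = 16
    epochs: int = Field(default=100, ge=0)
    learning_rate: float = Field(default=1e-3, gt=0)
    optimizer: str = "adam"


class ModelSettings(_Strict):
    k_grid: list[int] = [1, 3, 5, 7, 9, 11, 13, 15]
    n_trees_grid: list[int] = [100, 200, 500]
    depth_grid: list[Optional[int]] = [5, 10, None]
    c_grid: list[float] = [0.1, 1.0, 10.0, 100.0]
    gamma_grid: list[float] = [1e-4, 1e-3, 1e-2, 1e-1, 1.0]
    cnn: CNNSettings = Field(default_factory=CNNSettings)
    cnn_cv: bool = True

    def to_domain(self, input_len: int, n_classes: int = 3) -> ModelGrids:
        cnn_spec = CNNSpec(
            input_len=input_len,
            conv_channels=tuple(self.cnn.conv_channels),
            kernel_len=self.cnn.kernel_len,
            pool_len=self.cnn.pool_len,
            hidden_activation=self.cnn.hidden_activation,
            n_classes=n_classes,
            batch_size=self.cnn.batch_size,
            epochs=self.cnn.epochs,
            learning_rate=self.cnn.learning_rate,
            optimizer=self.cnn.optimizer,
        )
        return ModelGrids(
            k_grid=self.k_grid,
            n_trees_grid=self.n_trees_grid,
            depth_grid=self.depth_grid,
            c_grid=self.c_grid,
            gamma_grid=self.gamma_grid,
            cnn=cnn_spec,
            cnn_cv=self.cnn_cv,
        )


class SplitSettings(_Strict):
    train_frac: float = Field(default=0.7, gt=0, lt=1)


class OutputSettings(_Strict):
    directory: str = "ramandx-out"
    dialect: str = "wide"

    @field_validator("dialect")
    @classmethod
    def _known(cls, v: str) -> str:
        if v not in ("wide", "perfile"):
            raise ValueError("dialect must be 'wide' or 'perfile'")
        return v


class RunConfig(_Strict):
    """Root configuration object; every field has a documented default."""

    seed: int = 0
    generator: GeneratorSettings = Field(default_factory=GeneratorSettings)
    preprocess: PreprocessSettings = Field(default_factory=PreprocessSettings)
    models: ModelSettings = Field(default_factory=ModelSettings)
    split: SplitSettings = Field(default_factory=SplitSettings)
    output: OutputSettings = Field(default_factory=OutputSettings)

    def config_hash(self) -> str:
        # output location does not alter the experiment, so it is not hashed
        payload = json.dumps(self.model_dump(mode="json", exclude={"output"}), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: Optional[str | Path] = None, overrides: Optional[dict] = None) -> RunConfig:
    """Load and validate a YAML/JSON config file; ``None`` gives pure defaults.

    Schema violations raise :class:`ConfigError` carrying the field path.
    """
    data: dict = {}
    if path is not None:
        try:
            loaded = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError(f"{path}: top level must be a mapping")
            data = loaded
    if overrides:
        data.update(overrides)
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"] for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration: {locs}") from exc
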