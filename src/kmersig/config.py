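"""Pipeline configuration: YAML schema, defaults, validation.

Defaults reproduce the reference settings: 5 stratified folds, SMOTE with
5 neighbors inside each training fold, LASSO penalty by internal CV, PCA
to 16 dimensions, the four base models with their fixed configurations,
and proportional AUC weighting for the ensemble. Unknown keys are
rejected with the offending key path.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .errors import ConfigError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SmoteCfg(_Strict):
    enabled: bool = True
    neighbors: int = Field(default=5, ge=1)


class LassoCfg(_Strict):
    rule: Union[Literal["cv"], float] = "cv"
    link: Literal["logistic", "linear"] = "logistic"


class PcaCfg(_Strict):
    dims: int = Field(default=16, ge=1)


class PreprocessCfg(_Strict):
    smote: SmoteCfg = SmoteCfg()
    lasso: LassoCfg = LassoCfg()
    pca: PcaCfg = PcaCfg()
    scope: Literal["per-fold", "global"] = "per-fold"


class FfnnCfg(_Strict):
    max_epochs: int = Field(default=50, ge=1)
    patience: int = Field(default=10, ge=1)
    val_fraction: float = Field(default=0.1, gt=0.0, lt=0.5)


class ModelsCfg(_Strict):
    lr_max_iterations: int = Field(default=1000, ge=1)
    svm_C: float = Field(default=1.0, gt=0)
    nb_var_smoothing: float = Field(default=1e-9, gt=0)
    ffnn: FfnnCfg = FfnnCfg()


class EnsembleCfg(_Strict):
    weight_rule: Literal["proportional", "excess"] = "proportional"
    auc_source: Literal["inner-validation", "fold-validation"] = "inner-validation"
    soft: bool = False


class EvaluationCfg(_Strict):
    folds: int = Field(default=5, ge=2)
    bootstrap_reps: int = Field(default=1000, ge=0)
    ci_level: float = Field(default=0.95, gt=0.0, lt=1.0)


class TaskCfg(_Strict):
    """Binary label mapping, e.g. positive [CD, UC], negative [NC] for NC-vs-IBD."""

    name: str = "binary"
    positive: list[str]
    negative: list[str]

    @field_validator("positive", "negative")
    @classmethod
    def _nonempty(cls, v: list[str]) -> list[str]:
        if not v:
            raise ValueError("label set must not be empty")
        return v


class PathsCfg(_Strict):
    manifest: str | None = None
    feature_table: str | None = None
    outdir: str = "results"


class PipelineConfig(_Strict):
    seed: int = 0
    k: list[int] = Field(default_factory=lambda: [3])
    task: TaskCfg
    paths: PathsCfg = PathsCfg()
    preprocess: PreprocessCfg = PreprocessCfg()
    models: ModelsCfg = ModelsCfg()
    ensemble: EnsembleCfg = EnsembleCfg()
    evaluation: EvaluationCfg = EvaluationCfg()
    workers: int = Field(default=1, ge=1)
    plots: bool = False

    @field_validator("k")
    @classmethod
    def _k_range(cls, v: list[int]) -> list[int]:
        if not v:
            raise ValueError("k list must not be empty")
        for k in v:
            if not 1 <= k <= 12:
                raise ValueError(f"k must be in [1, 12], got {k}")
        return v

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v: int) -> int:
        return v % (2**31)


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a pipeline YAML, filling documented defaults."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML: {exc}") from None
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return validate_config(raw)


def validate_config(raw: dict) -> PipelineConfig:
    try:
        return PipelineConfig(**raw)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"])
            lines.append(f"{loc}: {err['msg']}")
        raise ConfigError("invalid pipeline config: " + "; ".join(lines)) from None
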