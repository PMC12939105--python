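"""Schema-validated run configuration.

A run is described by one JSON (or YAML) document with a section per stage;
unknown keys are rejected so typos fail loudly, and every stochastic stage
has an explicit seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .filters import DEFAULT_LOG_SIGMAS_MM, DEFAULT_WAVELET
from .nn import FTTransformerConfig


@dataclass
class PreprocessSection:
    target_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    window_level: float = -600.0
    window_width: float = 1500.0
    crop_margin_voxels: int = 2


@dataclass
class FiltersSection:
    log_sigmas_mm: tuple[float, ...] = DEFAULT_LOG_SIGMAS_MM
    wavelet_name: str = DEFAULT_WAVELET


@dataclass
class ExtractionSection:
    bin_width_hu: float = 25.0
    gldm_alpha: int = 0


@dataclass
class LassoSection:
    n_folds: int = 5
    n_lambdas: int = 30
    seed: int = 0


@dataclass
class ModelSection:
    token_dim: int = 64
    n_layers: int = 3
    n_heads: int = 4
    ffn_multiplier: int = 4
    dropout: float = 0.1
    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 20
    seed: int = 0

    def to_transformer_config(self) -> FTTransformerConfig:
        return FTTransformerConfig(
            token_dim=self.token_dim, n_layers=self.n_layers,
            n_heads=self.n_heads, ffn_multiplier=self.ffn_multiplier,
            dropout=self.dropout, learning_rate=self.learning_rate,
            batch_size=self.batch_size, max_epochs=self.max_epochs,
            patience=self.patience, seed=self.seed)


@dataclass
class SelfTrainingSection:
    enabled: bool = True
    tau_lo: float = 0.2
    tau_hi: float = 0.8
    fine_tune_lr_factor: float = 0.1
    pseudo_weight: float = 1.0


@dataclass
class EvaluationSection:
    target_sensitivity: float = 0.7
    n_boot: int = 2000
    n_calibration_bins: int = 10
    seed: int = 0


@dataclass
class SurvivalSection:
    min_group_fraction: float = 0.1
    enabled: bool = True


@dataclass
class RunConfig:
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    filters: FiltersSection = field(default_factory=FiltersSection)
    extraction: ExtractionSection = field(default_factory=ExtractionSection)
    lasso: LassoSection = field(default_factory=LassoSection)
    model: ModelSection = field(default_factory=ModelSection)
    self_training: SelfTrainingSection = field(
        default_factory=SelfTrainingSection)
    evaluation: EvaluationSection = field(default_factory=EvaluationSection)
    survival: SurvivalSection = field(default_factory=SurvivalSection)
    split_seed: int = 0
    train_fraction: float = 0.8


_SECTIONS = {f.name: f.type for f in dataclasses.fields(RunConfig)}


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            if isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
    return cls(**kwargs)


def load_config(source) -> RunConfig:
    """Build a validated RunConfig from a dict or a JSON/YAML file path."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        data = (json.loads(text) if str(source).endswith(".json")
                else yaml.safe_load(text))
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {}
    defaults = RunConfig()
    for name in _SECTIONS:
        if name not in data:
            continue
        if name in ("split_seed", "train_fraction"):
            kwargs[name] = data[name]
        else:
            kwargs[name] = _build(type(getattr(defaults, name)),
                                  data[name], name)
    return RunConfig(**kwargs)


def config_to_dict(cfg: RunConfig) -> dict:
    return dataclasses.asdict(cfg)
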