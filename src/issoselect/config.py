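"""Pipeline configuration: optimizer, classifier and preprocessing settings.

Defaults follow the published experimental settings for the heart-disease
study: a population of 30 squirrels run for 50 iterations, fitness weights
alpha = 0.9 / beta = 0.1, bit-flip probability 0.01, predator probability
0.1, seasonal check every 10 iterations, a 100-tree Gini random forest,
10-fold cross-validation and an 80/20 train/test split.  The gliding
constants (Gc = 1.9, dg decaying linearly from 1.11 to 0.5) come from the
original squirrel-search literature; the study names an adaptive gliding
distance without printing a formula.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError, ValidationError

__all__ = [
    "ISSOConfig",
    "ForestConfig",
    "PreprocessConfig",
    "PipelineConfig",
    "load_config",
]


@dataclass
class ISSOConfig:
    """Squirrel-search optimizer constants."""

    n_squirrels: int = 30
    n_iterations: int = 50
    alpha: float = 0.9
    beta: float = 0.1
    p_mutation: float = 0.01
    p_predator: float = 0.1
    season_interval: int = 10
    glide_constant: float = 1.9
    dg_max: float = 1.11
    dg_min: float = 0.5
    binarize_threshold: float = 0.5
    granularity: str = "group"
    seed: int = 0

    def validate(self) -> None:
        if self.n_squirrels < 2:
            raise ValidationError("n_squirrels must be >= 2")
        if self.n_iterations < 0:
            raise ValidationError("n_iterations must be >= 0")
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("p_mutation", "p_predator", "binarize_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.season_interval < 1:
            raise ValidationError("season_interval must be >= 1")
        if not self.dg_max >= self.dg_min > 0:
            raise ValidationError("need dg_max >= dg_min > 0")
        if self.glide_constant <= 0:
            raise ValidationError("glide_constant must be positive")
        if self.granularity not in ("group", "column"):
            raise ValidationError("granularity must be 'group' or 'column'")


@dataclass
class ForestConfig:
    """Random-forest fitness/final-model settings."""

    n_trees: int = 100
    criterion: str = "gini"
    bootstrap: bool = True
    max_depth: int | None = None

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if self.criterion not in ("gini", "entropy", "log_loss"):
            raise ValidationError(f"unknown criterion {self.criterion!r}")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValidationError("max_depth must be >= 1 or null")


@dataclass
class PreprocessConfig:
    """Settings for the impute/normalize/encode/balance/prune chain."""

    knn_k: int = 5
    zscore_threshold: float = 3.0
    corr_threshold: float = 0.85
    smote_k: int = 5
    use_smote: bool = True
    prune_correlated: bool = True

    def validate(self) -> None:
        if self.knn_k < 1 or self.smote_k < 1:
            raise ValidationError("knn_k and smote_k must be >= 1")
        if self.zscore_threshold <= 0:
            raise ValidationError("zscore_threshold must be positive")
        if not 0.0 < self.corr_threshold <= 1.0:
            raise ValidationError("corr_threshold must be in (0, 1]")


@dataclass
class PipelineConfig:
    optimizer: ISSOConfig = field(default_factory=ISSOConfig)
    classifier: ForestConfig = field(default_factory=ForestConfig)
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    split_fraction: float = 0.8
    cv_folds: int = 10
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValidationError("split_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        self.optimizer.validate()
        self.classifier.validate()
        self.preprocessing.validate()


_SECTIONS = {
    "optimizer": ISSOConfig,
    "classifier": ForestConfig,
    "preprocessing": PreprocessConfig,
}
_TOP_KEYS = {"split_fraction", "cv_folds", "seed"}


def _build_section(cls, mapping: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - valid
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section {section!r}"
        )
    return cls(**mapping)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config file; unspecified keys take the study defaults.

    An empty (or absent) file yields the full default configuration.
    Unknown keys raise :class:`ConfigError` naming the key; out-of-range
    values raise :class:`ValidationError`.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping at top level")
        raw = loaded

    unknown = set(raw) - set(_SECTIONS) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")

    kwargs: dict = {}
    for section, cls in _SECTIONS.items():
        body = raw.get(section, {})
        if not isinstance(body, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        kwargs[section] = _build_section(cls, body, section)
    for key in _TOP_KEYS:
        if key in raw:
            kwargs[key] = raw[key]
    cfg = PipelineConfig(**kwargs)
    # optimizer seed follows the pipeline seed unless set explicitly
    if "seed" in raw and "seed" not in raw.get("optimizer", {}):
        cfg.optimizer.seed = cfg.seed
    cfg.validate()
    return cfg
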