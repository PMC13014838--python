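"""Pipeline configuration: one YAML file, validated strictly on load.

Every stage default mirrors the analysis settings: 10/30/70/90 percentile
bins, eight Markov chains, 500 burn-in / 100 retained samples thinned by
5, silhouette threshold 0.1, loading threshold 0.5 with a (0.5, 0.4, 0.3)
sensitivity sweep, genome-wide significance 1e-8, and greedy clumping at
r^2 0.1 within 500 kb.  Unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = ["PipelineConfig", "ConfigValidationError", "load_config"]


class ConfigValidationError(ValueError):
    pass


@dataclass
class SimulateConfig:
    n_participants: int = 1000
    n_features: int = 20
    n_levels_per_feature: int = 5
    K_true: int = 5
    topic_sharpness: float = 0.2
    alpha_gen: float = 0.3
    missing_rates: float = 0.0
    n_variants: int = 100
    maf_min: float = 0.05
    maf_max: float = 0.5
    ld_block_size: int = 5
    ld_strength: float = 0.8
    platform_fractions: tuple = (0.12, 0.45, 0.43)
    disease_specs: list = field(default_factory=lambda: [
        {"name": "kidney_disease", "baseline": -3.0,
         "topic_weights": [3.0, 3.0, 0.0, -3.0, -3.0]},
        {"name": "t2dm", "baseline": -3.0,
         "topic_weights": [3.0, 3.0, 0.0, -3.0, -3.0]},
        {"name": "cvd", "baseline": -3.0,
         "topic_weights": [3.0, 3.0, 0.0, -3.0, -3.0]},
    ])
    genetic_effects: list = field(default_factory=lambda: [
        {"variant": 0, "topic": 0, "gamma": 0.4},
        {"variant": 25, "topic": 1, "gamma": 0.4},
        {"variant": 50, "topic": 0, "gamma": -0.4},
    ])


@dataclass
class DiscretizeConfig:
    percentiles: tuple = (10.0, 30.0, 70.0, 90.0)


@dataclass
class FitConfig:
    K: int = 5
    select_K: bool = False
    K_grid: tuple = (2, 3, 4, 5, 6, 7, 8)
    train_fraction: float = 1.0 / 3.0
    n_chains: int = 8
    alpha: float | None = None
    beta_h: float = 0.1
    n_burn: int = 500
    n_samples: int = 100
    thin: int = 5


@dataclass
class AlignConfig:
    silhouette_threshold: float = 0.1
    credible: float = 0.95


@dataclass
class AssociateConfig:
    loading_threshold: float = 0.5
    sensitivity: tuple = (0.5, 0.4, 0.3)
    alpha_family: float = 0.05
    diseases: tuple = ("kidney_disease", "t2dm", "cvd")
    covariates: tuple = ("age", "sex", "smoking", "bmi", "whr", "weight")


@dataclass
class GwasConfig:
    p_threshold: float = 1e-8
    r2_threshold: float = 0.1
    window_bp: int = 500_000
    demographics: tuple = ("age", "sex", "smoking")
    anthropometrics: tuple = ("bmi", "whr", "weight")


@dataclass
class PrsConfig:
    validation_seed_offset: int = 10_000
    validation_n: int | None = None
    method: str = "logistic"


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    discretize: DiscretizeConfig = field(default_factory=DiscretizeConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    align: AlignConfig = field(default_factory=AlignConfig)
    associate: AssociateConfig = field(default_factory=AssociateConfig)
    gwas: GwasConfig = field(default_factory=GwasConfig)
    prs: PrsConfig = field(default_factory=PrsConfig)

    def validate(self) -> None:
        if self.fit.n_chains < 1 or self.fit.K < 1:
            raise ConfigValidationError("fit.n_chains and fit.K must be >= 1")
        if not (0 < self.associate.loading_threshold <= 1):
            raise ConfigValidationError("loading_threshold must be in (0, 1]")
        for t in self.associate.sensitivity:
            if not (0 < t <= 1):
                raise ConfigValidationError("sensitivity thresholds must be in (0, 1]")
        if not (0 < self.gwas.p_threshold < 1):
            raise ConfigValidationError("gwas.p_threshold must be in (0, 1)")
        if not (0 <= self.gwas.r2_threshold <= 1):
            raise ConfigValidationError("gwas.r2_threshold must be in [0, 1]")
        if not (0 < self.fit.train_fraction < 1):
            raise ConfigValidationError("train_fraction must be in (0, 1)")
        if not (0 < self.align.credible < 1):
            raise ConfigValidationError("align.credible must be in (0, 1)")


def _build(cls, data, path=""):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigValidationError(f"{path or 'config'} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigValidationError(f"unknown keys at {path or 'top level'}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        if dataclasses.is_dataclass(_resolve(cls, name)):
            kwargs[name] = _build(_resolve(cls, name), value, f"{path}{name}.")
        elif isinstance(value, list) and name not in ("disease_specs", "genetic_effects"):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
        del ftype
    return cls(**kwargs)


def _resolve(cls, name):
    f = {f.name: f for f in dataclasses.fields(cls)}[name]
    if f.default_factory is not dataclasses.MISSING:  # type: ignore[misc]
        d = f.default_factory()
        if dataclasses.is_dataclass(d):
            return type(d)
    return type(f.default) if f.default is not dataclasses.MISSING else None


def load_config(path_or_text) -> PipelineConfig:
    """Load and validate a pipeline YAML config (unknown keys rejected)."""
    text = path_or_text
    try:
        import os

        if os.path.exists(str(path_or_text)):
            with open(path_or_text) as fh:
                text = fh.read()
    except OSError:
        pass
    data = yaml.safe_load(text) or {}
    cfg = _build(PipelineConfig, data)
    cfg.validate()
    return cfg
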