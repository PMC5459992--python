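"""Run configuration: one structured object holding every threshold the
pipeline uses, serialisable to/from YAML losslessly."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import yaml

from .behavior import ClassifierConfig
from .errors import ConfigurationError
from .methylome import FilterConfig
from .synthetic import BehaviorSimConfig, MethylSimConfig


@dataclass(frozen=True)
class Thresholds:
    alpha: float = 0.05
    use_fdr: bool = True
    promoter_window: int = 2000
    top_fraction: float = 0.25
    bottom_fraction: float = 0.40
    min_samples_detected: int = 7
    min_coverage: int = 5
    hypo_threshold: float = 0.3
    min_fold_change: float = 2.0
    max_de_p: float = 0.05

    def validate(self) -> None:
        if not 0 < self.alpha <= 1 or not 0 < self.max_de_p <= 1:
            raise ConfigurationError("alpha and max_de_p must lie in (0, 1]")
        if not 0 <= self.hypo_threshold <= 1:
            raise ConfigurationError("hypo_threshold must lie in [0, 1]")
        if self.promoter_window < 0 or self.min_fold_change < 1:
            raise ConfigurationError("promoter_window >= 0 and min_fold_change >= 1 required")
        ClassifierConfig(self.top_fraction, self.bottom_fraction)
        FilterConfig(self.min_samples_detected, self.min_coverage)


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    coord_base: int = 1
    behavior: BehaviorSimConfig = field(default_factory=BehaviorSimConfig)
    methylome: MethylSimConfig = field(default_factory=MethylSimConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)

    def validate(self) -> None:
        if self.coord_base not in (0, 1):
            raise ConfigurationError("coord_base must be 0 or 1")
        self.behavior.validate()
        self.methylome.validate()
        self.thresholds.validate()

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(
            self,
            seed=seed,
            behavior=replace(self.behavior, seed=seed),
            methylome=replace(self.methylome, seed=seed),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["methylome"]["beta_hypo"] = list(d["methylome"]["beta_hypo"])
        d["methylome"]["beta_hyper"] = list(d["methylome"]["beta_hyper"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        beh = BehaviorSimConfig(**d.pop("behavior", {}))
        met = d.pop("methylome", {})
        for k in ("beta_hypo", "beta_hyper"):
            if k in met:
                met[k] = tuple(met[k])
        met = MethylSimConfig(**met)
        thr = Thresholds(**d.pop("thresholds", {}))
        return cls(behavior=beh, methylome=met, thresholds=thr, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
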