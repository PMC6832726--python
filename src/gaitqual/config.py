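"""Run configuration for the batch pipeline (YAML-backed)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .features import CompositeWeights, FeatureConfig


@dataclass
class RunConfig:
    """Everything the end-to-end pipeline needs, loadable from YAML.

    ``episodes`` points at an episode CSV (header
    subject,week,day,t,acc_vt,acc_ml,acc_ap); when absent, ``simulate``
    holds arguments for the synthetic episode generator instead.
    """

    out_dir: str = "gaitqual_out"
    episodes: str | None = None
    simulate: dict = field(default_factory=dict)
    column_map: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"
    epoch_s: float = 10.0
    min_episode_s: float = 10.0
    min_epochs: int = 10
    units: str = "m/s2"
    leg_length: float | None = None
    features: list | None = None
    feature_params: dict = field(default_factory=dict)
    composite: dict = field(default_factory=dict)
    power: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        known_inputs = set(CompositeWeights().inputs)
        for section in ("weights", "means", "sds"):
            for name in self.composite.get(section, {}):
                if name not in known_inputs and section == "weights" \
                        and name not in self.composite.get("inputs", {}):
                    raise ValueError(
                        f"composite.{section} refers to unknown characteristic "
                        f"{name!r}; known inputs: {sorted(known_inputs)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def feature_config(self) -> FeatureConfig:
        comp_kwargs = {k: v for k, v in self.composite.items()
                       if k in ("inputs", "weights", "means", "sds")}
        defaults = CompositeWeights()
        if "inputs" in comp_kwargs:
            comp_kwargs["inputs"] = {**defaults.inputs, **comp_kwargs["inputs"]}
        if "weights" in comp_kwargs:
            comp_kwargs["weights"] = {**defaults.weights, **comp_kwargs["weights"]}
        cfg = FeatureConfig(
            epoch_s=self.epoch_s, min_episode_s=self.min_episode_s,
            units=self.units, composite=CompositeWeights(**comp_kwargs),
            features=tuple(self.features) if self.features else None,
            **self.feature_params)
        if self.leg_length:
            cfg.leg_length_default = self.leg_length
        return cfg
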