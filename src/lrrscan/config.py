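"""Pipeline configuration with lossless YAML round-tripping."""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .scanner import ResidueClassConfig


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved settings for a pipeline run.

    Every run report embeds the fully resolved configuration so results
    can be reproduced byte-identically.
    """

    residue_classes: ResidueClassConfig = field(default_factory=ResidueClassConfig)
    vs_max_len: int = 7
    adjacency_max: int = 30
    mask_rule: str = "union"
    threshold_a: float = 0.0
    threshold_b: float = 0.0
    baseline: str = "none"
    baseline_window: int | None = None
    growth_mode: str = "two_point"
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "residue_classes": self.residue_classes.to_dict(),
            "vs_max_len": self.vs_max_len,
            "adjacency_max": self.adjacency_max,
            "mask_rule": self.mask_rule,
            "threshold_a": self.threshold_a,
            "threshold_b": self.threshold_b,
            "baseline": self.baseline,
            "baseline_window": self.baseline_window,
            "growth_mode": self.growth_mode,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        classes = d.pop("residue_classes", None)
        rcc = ResidueClassConfig.from_dict(classes) if classes \
            else ResidueClassConfig()
        return cls(residue_classes=rcc, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
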