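"""Pipeline configuration: validated defaults, YAML/JSON round trip."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunable settings of the pipeline with their printed defaults.

    Box sizes run r_max..r_min (10..2), the slope window has at least
    min_window points, proportional thresholding keeps threshold_fraction of
    pairs (0.2), the permutation test runs n_perm iterations (1000) on
    subsamples of 10 per group at alpha 0.05.
    """

    r_max: int = 10
    r_min: int = 2
    min_window: int = 4
    threshold_fraction: float = 0.2
    method: str = "pearson"
    intra_mode: str = "weight"
    n_perm: int = 1000
    subsample: int = 10
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.r_min < 1 or self.r_max < self.r_min:
            raise ValueError("need 1 <= r_min <= r_max")
        if self.min_window < 2 or self.min_window > self.r_max - self.r_min + 1:
            raise ValueError("min_window must fit inside the box-size schedule")
        if not 0 < self.threshold_fraction <= 1:
            raise ValueError("threshold_fraction must lie in (0, 1]")
        if self.method not in ("pearson", "spearman"):
            raise ValueError(f"unknown correlation method {self.method!r}")
        if self.intra_mode not in ("weight", "literal"):
            raise ValueError(f"unknown intra-lobular mode {self.intra_mode!r}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.subsample < 3:
            raise ValueError("subsample must be >= 3 (correlation needs 3 subjects)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)
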