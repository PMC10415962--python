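"""Single-file pipeline configuration with a reproducible hash.

One YAML document carries the preprocessing grid, both training configurations,
and the sarcopenia thresholds/coefficients, so every run can embed a hash of
the exact constants it used.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .io_prep import PreprocessConfig
from .morphometry import SarcopeniaConfig
from .segment import TrainingConfig


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tuples_to_lists(v) for v in obj]
    return obj


@dataclass(frozen=True)
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    slice_training: TrainingConfig = field(default_factory=TrainingConfig)
    seg_training: TrainingConfig = field(default_factory=TrainingConfig)
    sarcopenia: SarcopeniaConfig = field(default_factory=SarcopeniaConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return _tuples_to_lists({
            "preprocess": asdict(self.preprocess),
            "slice_training": asdict(self.slice_training),
            "seg_training": asdict(self.seg_training),
            "sarcopenia": asdict(self.sarcopenia),
            "seed": self.seed,
        })

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(self.to_yaml())
        return path

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def _tup(d, key, n=2):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])[:n] if n else tuple(d[key])
            return d

        kwargs = {}
        if "preprocess" in data:
            d = _tup(_tup(_tup(dict(data["preprocess"]), "hu_window"),
                          "target_inplane_spacing"), "crop_shape")
            kwargs["preprocess"] = PreprocessConfig(**d)
        for key in ("slice_training", "seg_training"):
            if key in data:
                d = _tup(dict(data[key]), "augmentation")
                kwargs[key] = TrainingConfig(**d)
        if "sarcopenia" in data:
            kwargs["sarcopenia"] = SarcopeniaConfig(**data["sarcopenia"])
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        return cls(**kwargs)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed,
                       slice_training=replace(self.slice_training, seed=seed),
                       seg_training=replace(self.seg_training, seed=seed))
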