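"""Serializable run configuration tying the pipeline stages together.

A ``RunConfig`` bundles the stream recipe, augmentation, network and
training settings, the monitor parameters, a global seed and an output
directory, and round-trips through YAML so every run can be reproduced
from the config file written beside its outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .monitor import MonitorConfig
from .nnet import NetworkSpec, TrainConfig
from .preprocess import AugmentationConfig
from .synth import StreamSpec

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    stream: StreamSpec = field(
        default_factory=lambda: StreamSpec(total_frames=1000, entry_index=500)
    )
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    training: TrainConfig = field(default_factory=TrainConfig)
    monitor: MonitorConfig = field(default_factory=MonitorConfig)
    seed: int = 0
    output_dir: str = "runs"

    def to_dict(self) -> dict:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [listify(v) for v in obj]
            return obj

        return {
            "stream": self.stream.to_dict(),
            "augmentation": listify(asdict(self.augmentation)),
            "network": listify(asdict(self.network)),
            "training": asdict(self.training),
            "monitor": asdict(self.monitor),
            "seed": self.seed,
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = {}
        if "stream" in d:
            kw["stream"] = StreamSpec.from_dict(d["stream"])
        if "augmentation" in d:
            a = dict(d["augmentation"])
            for key in ("contrast_range", "brightness_range"):
                if key in a:
                    a[key] = tuple(a[key])
            kw["augmentation"] = AugmentationConfig(**a)
        if "network" in d:
            nd = dict(d["network"])
            for key in ("conv_filters", "fc_widths"):
                if key in nd:
                    nd[key] = tuple(nd[key])
            kw["network"] = NetworkSpec(**nd)
        if "training" in d:
            kw["training"] = TrainConfig(**d["training"])
        if "monitor" in d:
            kw["monitor"] = MonitorConfig(**d["monitor"])
        if "seed" in d:
            kw["seed"] = int(d["seed"])
        if "output_dir" in d:
            kw["output_dir"] = str(d["output_dir"])
        return cls(**kw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def write_beside(self, output_dir) -> Path:
        """Drop the resolved config next to a command's outputs."""
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "run_config.yaml"
        self.to_yaml(path)
        return path
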