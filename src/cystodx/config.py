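"""Run configuration: one seeded, validated object driving every stage."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

DEFAULT_CLASSES = ("HGC", "LGC", "NST", "NTL")

BRANCH_NAMES = ("CNN", "GAN", "XDL")


@dataclass
class GanConfig:
    latent_dim: int = 32
    n_synthetic_per_class: int | None = None  # None -> match real class size
    steps: int = 400
    batch_size: int = 16
    lr: float = 0.05


@dataclass
class XdlConfig:
    crop_threshold: float = 0.5
    crop_margin_px: int = 4
    cam_layer: str | None = None  # None -> last conv layer
    width_multiplier: float = 0.125
    patience: int = 3
    lr: float = 1e-3
    optimizer: str = "adam"  # deep unnormalized stack: Adam, not plain SGD


@dataclass
class RunConfig:
    seed: int = 0
    class_names: tuple[str, ...] = DEFAULT_CLASSES
    image_size_per_branch: dict = field(
        default_factory=lambda: {"CNN": (32, 32), "GAN": (32, 32), "XDL": (64, 64)})
    epochs: int = 10
    learning_rate: float = 0.01
    batch_size: int = 32
    momentum: float = 0.9
    gan: GanConfig = field(default_factory=GanConfig)
    xdl: XdlConfig = field(default_factory=XdlConfig)
    voting_mode: str = "overall"
    iqr_multiplier: float = 1.5
    outlier_feature: str = "mean_brightness"

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def __post_init__(self) -> None:
        self.class_names = tuple(self.class_names)
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.xdl.crop_threshold <= 1:
            raise ValueError("crop_threshold must be in (0, 1]")
        if self.iqr_multiplier <= 0:
            raise ValueError("iqr_multiplier must be > 0")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if len(set(self.class_names)) != self.n_classes:
            raise ValueError("class_names must be unique")
        if self.voting_mode not in ("overall", "per_class"):
            raise ValueError(f"unknown voting_mode {self.voting_mode!r}")
        if self.outlier_feature not in ("mean_brightness", "embedding"):
            raise ValueError(f"unknown outlier_feature {self.outlier_feature!r}")
        self.image_size_per_branch = {
            k: tuple(v) for k, v in self.image_size_per_branch.items()}

    def branch_size(self, branch: str) -> tuple[int, int]:
        return self.image_size_per_branch[branch]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["class_names"] = list(self.class_names)
        d["image_size_per_branch"] = {k: list(v) for k, v in self.image_size_per_branch.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "gan" in d and isinstance(d["gan"], dict):
            d["gan"] = GanConfig(**d["gan"])
        if "xdl" in d and isinstance(d["xdl"], dict):
            d["xdl"] = XdlConfig(**d["xdl"])
        return cls(**d)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML file mirroring RunConfig; unknown keys are an error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    try:
        return RunConfig.from_dict(raw)
    except TypeError as exc:
        raise ValueError(f"invalid config {path}: {exc}") from exc


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
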