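"""Synthetic endoscopic-like image fixtures.

Generates four tissue classes whose distinguishing structure mirrors what the
diagnosis pipeline needs to be testable end-to-end:

* ``NTL`` — smooth low-frequency background only (no lesion, no texture);
* ``NST`` — background plus a fine high-frequency grating texture;
* ``LGC`` — background plus one bright disc lesion with a smooth boundary and
  moderate contrast (ground-truth mask = the disc);
* ``HGC`` — background plus an irregular blob lesion (disc with a radial
  sinusoidal boundary perturbation), higher contrast and interior speckle
  (mask = the blob).

Clean images are constructed with mean brightness inside [0.35, 0.65]
(tightly clustered around 0.5), and a configurable fraction of records is
replaced by over-/under-exposed frames (mean >= 0.95 or <= 0.05) flagged
``is_outlier_truth`` — these are what the IQR rejection stage must catch.
No attempt is made to imitate real cystoscopy appearance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .config import RunConfig, DEFAULT_CLASSES
from .data import (
    DatasetManifest,
    ManifestRecord,
    load_split_arrays,
    save_image,
    save_manifest,
    split_manifest,
)

DEFAULT_CONTRAST = {"NTL": 0.0, "NST": 0.2, "LGC": 0.25, "HGC": 0.4}


@dataclass
class FixtureConfig:
    n_per_class: int = 100
    image_size: tuple[int, int] = (64, 64)
    outlier_fraction: float = 0.0
    lesion_radius_range: tuple[float, float] = (8.0, 14.0)
    contrast: dict = field(default_factory=lambda: dict(DEFAULT_CONTRAST))
    noise_sigma: float = 0.02
    seed: int = 0
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15)

    def __post_init__(self) -> None:
        h, w = self.image_size
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must be in [0, 1)")
        if self.lesion_radius_range[1] >= min(h, w) / 2:
            raise ValueError("r_max must be < min(H, W)/2")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _low_freq_background(rng: np.random.Generator, size: tuple[int, int]) -> np.ndarray:
    h, w = size
    coarse = rng.normal(0.0, 1.0, size=(8, 8))
    bg = ndimage.zoom(coarse, (h / 8, w / 8), order=1, grid_mode=True, mode="nearest")
    return 0.05 * bg / max(np.abs(bg).max(), 1e-9)


def _grating(rng: np.random.Generator, size: tuple[int, int], amplitude: float) -> np.ndarray:
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w]
    theta = rng.uniform(0, np.pi)
    # ~0.7 rad/px: fine relative to the lesion scale yet coarse enough to
    # survive a 2x bilinear downsample to the CNN branch resolution
    freq = rng.uniform(0.85, 1.15) * 0.7
    phase = rng.uniform(0, 2 * np.pi)
    return amplitude * np.sin(freq * (np.cos(theta) * xx + np.sin(theta) * yy) + phase)


def _lesion(
    rng: np.random.Generator,
    size: tuple[int, int],
    radius_range: tuple[float, float],
    contrast: float,
    irregular: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (additive lesion profile, binary mask).

    The profile equals the full contrast everywhere inside the mask and ramps
    to zero over ~2 px *outside* it, so the mean intensity inside the mask
    exceeds the background by the full contrast (minus zero-mean speckle).
    """
    h, w = size
    r0 = rng.uniform(*radius_range)
    cy = rng.uniform(r0 * 1.3, h - r0 * 1.3)
    cx = rng.uniform(r0 * 1.3, w - r0 * 1.3)
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(yy - cy, xx - cx)
    if irregular:
        ang = np.arctan2(yy - cy, xx - cx)
        k = rng.integers(4, 7)
        phi = rng.uniform(0, 2 * np.pi)
        boundary = r0 * (1.0 + 0.25 * np.sin(k * ang + phi))
    else:
        boundary = np.full_like(dist, r0)
    mask = (dist <= boundary).astype(np.uint8)
    profile = contrast * np.clip((boundary + 2.0 - dist) / 2.0, 0.0, 1.0)
    if irregular:
        speckle = contrast * 0.25 * rng.uniform(-1.0, 1.0, size=(h, w))
        profile = profile + speckle * mask
    return profile, mask


def _render_clean(
    rng: np.random.Generator, cfg: FixtureConfig, label: str
) -> tuple[np.ndarray, np.ndarray | None]:
    h, w = cfg.image_size
    contrast = cfg.contrast.get(label, 0.0)
    base = _low_freq_background(rng, cfg.image_size)
    mask = None
    if label == "NST":
        base = base + _grating(rng, cfg.image_size, contrast * 0.5)
    elif label in ("LGC", "HGC"):
        profile, mask = _lesion(rng, cfg.image_size, cfg.lesion_radius_range,
                                contrast, irregular=(label == "HGC"))
        base = base + profile
    # slight zero-sum channel tints so images are genuinely 3-channel
    tint = np.array([0.02, 0.0, -0.02])
    img = base[:, :, None] + tint[None, None, :]
    img = img + rng.normal(0.0, cfg.noise_sigma, size=img.shape)
    target_mean = rng.uniform(0.45, 0.55)
    img = img + (target_mean - img.mean())
    return np.clip(img, 0.02, 0.98), mask


def _render_outlier(rng: np.random.Generator, cfg: FixtureConfig) -> np.ndarray:
    h, w = cfg.image_size
    bright = rng.random() < 0.5
    level = 0.975 if bright else 0.025
    img = level + rng.normal(0.0, 0.005, size=(h, w, 3))
    return np.clip(img, 0.96, 1.0) if bright else np.clip(img, 0.0, 0.04)


def generate_dataset(config: FixtureConfig, out_dir: str | Path) -> DatasetManifest:
    """Write ``n_per_class`` PNGs per class (plus lesion masks) and a manifest.

    A fraction ``outlier_fraction`` of the records, spread round-robin across
    classes, is replaced by exposure outliers (label retained, mask dropped,
    ``is_outlier_truth=True``). Splits are assigned stratified by label using
    the config seed. Fully deterministic for a fixed config.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "images").mkdir(exist_ok=True)
        (out_dir / "masks").mkdir(exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out_dir}: {exc}") from exc
    rng = np.random.default_rng(config.seed)
    classes = [c for c in DEFAULT_CLASSES if c in config.contrast] or list(DEFAULT_CLASSES)
    total = config.n_per_class * len(classes)
    n_outliers = int(config.outlier_fraction * total)
    # spread outliers across classes round-robin: class i gets slot i % C
    outlier_slots = {
        (classes[i % len(classes)], i // len(classes)) for i in range(n_outliers)}
    records = []
    for label in classes:
        for i in range(config.n_per_class):
            name = f"{label}_{i:04d}"
            img_path = out_dir / "images" / f"{name}.png"
            if (label, i) in outlier_slots:
                save_image(_render_outlier(rng, config), img_path)
                records.append(ManifestRecord(str(img_path), label, "train",
                                              is_outlier_truth=True))
                continue
            img, mask = _render_clean(rng, config, label)
            save_image(img, img_path)
            mask_path = None
            if mask is not None:
                mask_path = out_dir / "masks" / f"{name}_mask.png"
                save_image(np.repeat(mask[:, :, None], 3, axis=2).astype(float), mask_path)
            records.append(ManifestRecord(str(img_path), label, "train",
                                          is_outlier_truth=False,
                                          mask_path=str(mask_path) if mask_path else None))
    manifest = DatasetManifest(records, tuple(classes))
    manifest = split_manifest(manifest, config.split_fractions, config.seed)
    save_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def separability_probe(manifest: DatasetManifest, seed: int = 0, epochs: int = 10) -> float:
    """Fixture quality gate: train a single-conv classifier, return clean-test accuracy.

    Requires >= 25 clean images per class. Only used by tests — a fixture set
    a tiny model cannot separate would make every downstream check vacuous.
    """
    from .nn import Conv2D, Dense, Flatten, MaxPool2, ReLU, Sequential
    from .nn.train import evaluate_accuracy, fit_classifier

    classes = manifest.class_names or tuple(sorted(set(manifest.labels())))
    clean_counts = {c: 0 for c in classes}
    for r in manifest.records:
        if not r.is_outlier_truth:
            clean_counts[r.label] += 1
    bad = {c: n for c, n in clean_counts.items() if n < 25}
    if bad:
        raise ValueError(f"separability probe needs >= 25 clean images per class; got {bad}")

    size = (64, 64)
    x_tr, y_tr, _ = load_split_arrays(manifest, "train", size, classes)
    clean_test = DatasetManifest(
        [r for r in manifest.subset("test") if not r.is_outlier_truth], classes)
    x_te = np.stack([_load(r.image_path, size) for r in clean_test.records])
    y_te = np.array([classes.index(r.label) for r in clean_test.records])

    x_tr = (x_tr - 0.5).astype(np.float32)
    x_te = (x_te - 0.5).astype(np.float32)
    rng = np.random.default_rng(seed)
    net = Sequential([
        Conv2D(3, 8, 5, rng=rng), ReLU(), MaxPool2(), Flatten(),
        Dense(30 * 30 * 8, len(classes), rng=rng),
    ])
    fit_classifier(net, x_tr, y_tr, x_te, y_te, epochs=epochs, lr=0.01,
                   batch_size=32, momentum=0.9, rng=rng)
    return evaluate_accuracy(net, x_te, y_te)


def _load(path, size):
    from .data import load_image

    return load_image(path, size).astype(np.float32)


def clean_records(manifest: DatasetManifest, split: str | None = None):
    recs = manifest.records if split is None else manifest.subset(split)
    return [r for r in recs if not r.is_outlier_truth]
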