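"""Canonical data types and I/O: labeled images, dataset manifests, splits.

The manifest CSV is the record of truth for the whole pipeline:
``image_path,label,split[,is_outlier_truth][,mask_path][,synthetic]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

SPLITS = ("train", "validation", "test")


@dataclass
class LabeledImage:
    """An RGB image in [0,1] with its tissue-class label.

    ``mask`` (optional) marks lesion support pixels and is used to score
    saliency localization on synthetic data.
    """

    id: str
    pixels: np.ndarray  # H x W x 3, float in [0, 1]
    label: str
    mask: np.ndarray | None = None
    source_path: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError(f"pixels must be HxWx3, got {p.shape}")
        if p.shape[0] < 8 or p.shape[1] < 8:
            raise ValueError(f"image too small: {p.shape[:2]}")
        if p.min() < 0 or p.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")
        if self.mask is not None and self.mask.shape != p.shape[:2]:
            raise ValueError(
                f"mask shape {self.mask.shape} != image shape {p.shape[:2]}")


@dataclass(frozen=True)
class ManifestRecord:
    image_path: str
    label: str
    split: str
    is_outlier_truth: bool | None = None
    mask_path: str | None = None
    synthetic: bool = False


@dataclass
class DatasetManifest:
    """Validated list of image records partitioned into train/validation/test."""

    records: list[ManifestRecord]
    class_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.class_names:
            self.class_names = tuple(self.class_names)
            for i, r in enumerate(self.records):
                if r.label not in self.class_names:
                    raise ValueError(
                        f"row {i + 1}: unknown label {r.label!r} "
                        f"(expected one of {self.class_names})")
        paths = [r.image_path for r in self.records]
        if len(set(paths)) != len(paths):
            dup = next(p for p in paths if paths.count(p) > 1)
            raise ValueError(f"duplicate image_path {dup!r}")
        for i, r in enumerate(self.records):
            if r.split not in SPLITS:
                raise ValueError(f"row {i + 1}: unknown split {r.split!r}")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split: str) -> list[ManifestRecord]:
        return [r for r in self.records if r.split == split]

    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "image_path": [r.image_path for r in self.records],
                "label": [r.label for r in self.records],
                "split": [r.split for r in self.records],
                "is_outlier_truth": [r.is_outlier_truth for r in self.records],
                "mask_path": [r.mask_path for r in self.records],
                "synthetic": [r.synthetic for r in self.records],
            }
        )


def save_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    df = manifest.to_frame()
    # drop all-empty optional columns for a clean minimal CSV
    if df["is_outlier_truth"].isna().all():
        df = df.drop(columns=["is_outlier_truth"])
    if df["mask_path"].isna().all():
        df = df.drop(columns=["mask_path"])
    if not df["synthetic"].any():
        df = df.drop(columns=["synthetic"])
    df.to_csv(path, index=False)


def load_manifest(path: str | Path, class_names: tuple[str, ...] = ()) -> DatasetManifest:
    """Read a manifest CSV, enforcing label membership and path uniqueness."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    required = {"image_path", "label", "split"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns {sorted(missing)}")

    def _opt_bool(row, col):
        if col not in df.columns or pd.isna(row[col]):
            return None
        v = row[col]
        if isinstance(v, str):
            return v.strip().lower() in ("true", "1", "yes")
        return bool(v)

    records = []
    for _, row in df.iterrows():
        records.append(
            ManifestRecord(
                image_path=str(row["image_path"]),
                label=str(row["label"]),
                split=str(row["split"]),
                is_outlier_truth=_opt_bool(row, "is_outlier_truth"),
                mask_path=(str(row["mask_path"])
                           if "mask_path" in df.columns and pd.notna(row["mask_path"])
                           else None),
                synthetic=bool(_opt_bool(row, "synthetic") or False),
            )
        )
    return DatasetManifest(records, class_names)


def load_image(path: str | Path, target_size: tuple[int, int] | None = None) -> np.ndarray:
    """Load a PNG/JPEG as an HxWx3 float array in [0,1], bilinearly resized.

    Grayscale inputs are replicated across the three channels.
    """
    try:
        img = Image.open(path)
        img.load()
    except (OSError, SyntaxError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    img = img.convert("RGB")
    if target_size is not None:
        h, w = target_size
        img = img.resize((w, h), Image.BILINEAR)
    return np.asarray(img, dtype=np.float32) / 255.0


def save_image(pixels: np.ndarray, path: str | Path) -> None:
    arr = np.clip(np.asarray(pixels), 0.0, 1.0)
    Image.fromarray((arr * 255.0).round().astype(np.uint8)).save(path)


def load_mask(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr > 127).astype(np.uint8)


def split_manifest(
    manifest: DatasetManifest,
    fractions: tuple[float, float, float],
    seed: int,
) -> DatasetManifest:
    """Assign train/validation/test splits, stratified by label.

    Per class, records are shuffled with the given seed and cut at the
    cumulative fractions (largest-remainder rounding), so the same seed always
    yields the same assignment.
    """
    if any(f <= 0 for f in fractions):
        raise ValueError(f"fractions must be positive, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for i, r in enumerate(manifest.records):
        by_class.setdefault(r.label, []).append(i)
    assignment: dict[int, str] = {}
    for label in sorted(by_class):
        idxs = np.array(by_class[label])
        if len(idxs) < 3:
            raise ValueError(
                f"class {label!r} has {len(idxs)} records; need >= 3 to fill all splits")
        rng.shuffle(idxs)
        n = len(idxs)
        counts = _largest_remainder(n, fractions)
        start = 0
        for split, cnt in zip(SPLITS, counts):
            for i in idxs[start:start + cnt]:
                assignment[int(i)] = split
            start += cnt
    records = [replace(r, split=assignment[i]) for i, r in enumerate(manifest.records)]
    return DatasetManifest(records, manifest.class_names)


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Integer counts summing to n, each >= 1, proportional to fractions."""
    raw = [f * n for f in fractions]
    counts = [int(x) for x in raw]
    rema = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    i = 0
    while sum(counts) < n:
        counts[rema[i % len(rema)]] += 1
        i += 1
    # every split non-empty when n allows it
    for j in range(len(counts)):
        if counts[j] == 0:
            k = int(np.argmax(counts))
            counts[k] -= 1
            counts[j] += 1
    return counts


def load_split_arrays(
    manifest: DatasetManifest,
    split: str,
    target_size: tuple[int, int],
    class_names: tuple[str, ...],
) -> tuple[np.ndarray, np.ndarray, list[ManifestRecord]]:
    """Materialize one split as (images NHWC, integer labels, records)."""
    recs = manifest.subset(split)
    if not recs:
        raise ValueError(f"manifest has no records in split {split!r}")
    label_to_idx = {c: i for i, c in enumerate(class_names)}
    x = np.stack([load_image(r.image_path, target_size) for r in recs])
    y = np.array([label_to_idx[r.label] for r in recs], dtype=np.int64)
    return x.astype(np.float32), y, recs
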