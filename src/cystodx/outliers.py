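"""IQR-based outlier rejection applied before any training.

Each image is reduced to one scalar feature (mean brightness by default, or
the L2 norm of a convolutional embedding), quartiles QI1/QI3 are taken over
the whole dataset, and anything outside

    [QI1 - m * IQR, QI3 + m * IQR],  IQR = QI3 - QI1,  m = 1.5 by default

is rejected. The interval is closed: values exactly on a fence are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import DatasetManifest, LabeledImage, load_image

log = logging.getLogger(__name__)

FEATURE_METHODS = ("mean_brightness", "embedding")


@dataclass(frozen=True)
class IQRBounds:
    """Quartiles and rejection fences for one feature distribution."""

    q1: float
    q3: float
    iqr: float
    multiplier: float
    lower: float
    upper: float


@dataclass
class RejectedRecord:
    image_path: str
    feature_value: float
    reason: str  # below_lower | above_upper


@dataclass
class RejectionReport:
    kept: DatasetManifest
    rejected: list[RejectedRecord]
    bounds: IQRBounds
    feature_name: str

    def summary(self) -> dict:
        return {
            "feature": self.feature_name,
            "n_kept": len(self.kept),
            "n_rejected": len(self.rejected),
            "bounds": {
                "q1": self.bounds.q1, "q3": self.bounds.q3, "iqr": self.bounds.iqr,
                "multiplier": self.bounds.multiplier,
                "lower": self.bounds.lower, "upper": self.bounds.upper,
            },
            "rejected": [
                {"image_path": r.image_path, "feature_value": r.feature_value,
                 "reason": r.reason}
                for r in self.rejected
            ],
        }


_EMBED_NET = None


def _embedding_net():
    """Fixed-seed untrained conv encoder used as a random-projection feature map."""
    global _EMBED_NET
    if _EMBED_NET is None:
        from .nn import Conv2D, GlobalAvgPool, MaxPool2, ReLU, Sequential

        rng = np.random.default_rng(12345)
        _EMBED_NET = Sequential([
            Conv2D(3, 8, 3, padding="same", rng=rng), ReLU(), MaxPool2(),
            Conv2D(8, 16, 3, padding="same", rng=rng), ReLU(), MaxPool2(),
            GlobalAvgPool(),
        ])
    return _EMBED_NET


def extract_feature(image: LabeledImage | np.ndarray, method: str = "mean_brightness"):
    """Scalar (mean_brightness) or vector (embedding) feature for one image."""
    pixels = image.pixels if isinstance(image, LabeledImage) else np.asarray(image)
    if method == "mean_brightness":
        return float(pixels.mean())
    if method == "embedding":
        x = (pixels.astype(np.float32) - 0.5)[None]
        return _embedding_net().forward(x)[0]
    raise ValueError(f"unknown feature method {method!r}; expected one of {FEATURE_METHODS}")


def feature_scalar(image: LabeledImage | np.ndarray, method: str = "mean_brightness") -> float:
    """Feature reduced to the scalar the IQR fence is applied to."""
    f = extract_feature(image, method)
    if np.ndim(f) == 0:
        return float(f)
    return float(np.linalg.norm(f))


def compute_iqr_bounds(values, multiplier: float = 1.5) -> IQRBounds:
    """Quartiles by sorted linear interpolation at position p*(n-1), then fences."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError(f"need >= 4 values for quartiles, got {v.size}")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite feature values")
    if multiplier <= 0:
        raise ValueError("multiplier must be > 0")
    q1, q3 = np.percentile(v, [25, 75])  # linear interpolation convention
    iqr = q3 - q1
    return IQRBounds(
        q1=float(q1), q3=float(q3), iqr=float(iqr), multiplier=float(multiplier),
        lower=float(q1 - multiplier * iqr), upper=float(q3 + multiplier * iqr))


class IQROutlierFilter:
    """Estimator-style interface: fit fences on feature values, filter samples.

    fit(X) with X a 1-D array of scalar features (or an (n, h, w, 3) image
    stack, reduced via ``feature_method``) computes the fences; ``predict``
    returns +1 for inliers and -1 for outliers, matching the convention of
    scikit-learn outlier detectors.
    """

    def __init__(self, multiplier: float = 1.5, feature_method: str = "mean_brightness"):
        self.multiplier = multiplier
        self.feature_method = feature_method

    def get_params(self, deep: bool = True) -> dict:
        return {"multiplier": self.multiplier, "feature_method": self.feature_method}

    def set_params(self, **params) -> "IQROutlierFilter":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _features(self, X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim == 1:
            return X.astype(float)
        if X.ndim == 4:
            return np.array([feature_scalar(x, self.feature_method) for x in X])
        raise ValueError(f"X must be 1-D features or NHWC images, got ndim={X.ndim}")

    def fit(self, X, y=None) -> "IQROutlierFilter":
        feats = self._features(X)
        self.bounds_ = compute_iqr_bounds(feats, self.multiplier)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "bounds_"):
            raise ValueError("IQROutlierFilter is not fitted")
        feats = self._features(X)
        inlier = (feats >= self.bounds_.lower) & (feats <= self.bounds_.upper)
        return np.where(inlier, 1, -1)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict(X)


def filter_outliers(
    manifest: DatasetManifest,
    feature_name: str = "mean_brightness",
    multiplier: float = 1.5,
) -> RejectionReport:
    """Reject manifest records whose feature falls outside the IQR fences.

    Fences are computed over every record in the manifest (the gate sits in
    front of the split/train pipeline). Boundary values are kept.
    """
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    feats = []
    for rec in manifest.records:
        try:
            pixels = load_image(rec.image_path)
            feats.append(feature_scalar(pixels, feature_name))
        except OSError as exc:
            raise OSError(f"feature extraction failed for {rec.image_path}: {exc}") from exc
    bounds = compute_iqr_bounds(feats, multiplier)
    kept_records, rejected = [], []
    for rec, f in zip(manifest.records, feats):
        if f < bounds.lower:
            rejected.append(RejectedRecord(rec.image_path, f, "below_lower"))
        elif f > bounds.upper:
            rejected.append(RejectedRecord(rec.image_path, f, "above_upper"))
        else:
            kept_records.append(rec)
    if rejected:
        log.info("IQR rejection: %d of %d images rejected (%s)",
                 len(rejected), len(manifest), feature_name)
    kept = DatasetManifest(kept_records, manifest.class_names)
    return RejectionReport(kept=kept, rejected=rejected, bounds=bounds,
                           feature_name=feature_name)
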