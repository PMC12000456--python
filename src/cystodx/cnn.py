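"""First ensemble member: a small convolutional classifier.

Default architecture: 32x32x3 input, two 5x5 valid convolutions (8 and 16
filters) with ReLU, each followed by 2x2 max pooling (32 -> 28 -> 14 -> 10
-> 5), then a dense head 400 -> 120 -> 84 -> n_classes with softmax output.
Also hosts the scalar ReLU / softmax reference functions and the checkpoint
format shared by all branches.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .config import RunConfig
from .data import DatasetManifest, load_split_arrays
from .nn.train import evaluate_accuracy, fit_classifier, predict_probs


# ---------------------------------------------------------------------------
# Reference activation functions
# ---------------------------------------------------------------------------

def relu(z: float) -> float:
    """Rectified linear unit: z for z > 0, else 0."""
    if not math.isfinite(z):
        raise ValueError(f"relu requires finite input, got {z}")
    return z if z > 0 else 0.0


@dataclass(frozen=True)
class ProbVector:
    logits: np.ndarray
    probs: np.ndarray

    @property
    def x(self) -> int:
        return len(self.probs)


def softmax(logits) -> ProbVector:
    """Standard softmax sigma(R)_i = e^{r_i} / sum_j e^{r_j}.

    Computed with max-subtraction so arbitrarily large logits stay finite.
    """
    r = np.asarray(logits, dtype=float)
    if r.ndim != 1 or r.size < 2:
        raise ValueError(f"softmax needs a 1-D vector of length >= 2, got shape {r.shape}")
    if not np.all(np.isfinite(r)):
        raise ValueError("softmax requires finite logits")
    p = nn.stable_softmax(r[None])[0]
    return ProbVector(logits=r, probs=p)


# ---------------------------------------------------------------------------
# Architecture specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    kind: str  # conv | pool | dense | softmax
    input_shape: tuple
    output_shape: tuple
    kernel: int | None = None


@dataclass
class ArchSpec:
    layers: list[LayerSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in zip(self.layers, self.layers[1:]):
            ok = a.output_shape == b.input_shape
            if not ok and b.kind == "dense":
                # dense layers flatten their input implicitly
                ok = int(np.prod(a.output_shape)) == int(np.prod(b.input_shape))
            if not ok:
                raise ValueError(
                    f"shape chain broken between {a.kind}{a.output_shape} "
                    f"and {b.kind}{b.input_shape}")

    def shapes(self) -> list[tuple]:
        return [self.layers[0].input_shape] + [l.output_shape for l in self.layers]

    def to_dict(self) -> list[dict]:
        return [
            {"kind": l.kind, "input_shape": list(l.input_shape),
             "output_shape": list(l.output_shape), "kernel": l.kernel}
            for l in self.layers
        ]

    @classmethod
    def from_dict(cls, d: list[dict]) -> "ArchSpec":
        return cls([
            LayerSpec(e["kind"], tuple(e["input_shape"]), tuple(e["output_shape"]),
                      e.get("kernel"))
            for e in d
        ])


def default_cnn_arch(input_size: tuple[int, int] = (32, 32), n_classes: int = 4,
                     dense_widths: tuple[int, ...] = (120, 84)) -> ArchSpec:
    """The default conv/pool chain at any input size divisible by 4 after
    two 5x5 valid convolutions; at 32x32 it reproduces 32->28->14->10->5."""
    h, w = input_size
    layers = []
    shapes = [(h, w, 3)]
    for out_ch in (8, 16):
        h2, w2 = h - 4, w - 4
        layers.append(LayerSpec("conv", (h, w, shapes[-1][2]), (h2, w2, out_ch), kernel=5))
        shapes.append((h2, w2, out_ch))
        if h2 % 2 or w2 % 2:
            raise ValueError(f"conv output {h2}x{w2} not poolable")
        h, w = h2 // 2, w2 // 2
        layers.append(LayerSpec("pool", (h2, w2, out_ch), (h, w, out_ch), kernel=2))
        shapes.append((h, w, out_ch))
    flat = h * w * 16
    widths = list(dense_widths) + [n_classes]
    prev = flat
    for wd in widths:
        layers.append(LayerSpec("dense", (prev,), (wd,)))
        prev = wd
    layers.append(LayerSpec("softmax", (n_classes,), (n_classes,)))
    return ArchSpec(layers)


def build_cnn(spec: ArchSpec, n_classes: int, seed: int) -> nn.Sequential:
    """Materialize an ArchSpec as a network with seed-deterministic weights."""
    final_dense = max(i for i, l in enumerate(spec.layers) if l.kind == "dense")
    if spec.layers[final_dense].output_shape != (n_classes,):
        raise ValueError(
            f"final dense width {spec.layers[final_dense].output_shape} != n_classes {n_classes}")
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    flattened = False
    for i, l in enumerate(spec.layers):
        if l.kind == "conv":
            padding = "same" if l.output_shape[:2] == l.input_shape[:2] else "valid"
            layers.append(nn.Conv2D(l.input_shape[2], l.output_shape[2], l.kernel or 5,
                                    padding=padding, rng=rng))
            layers.append(nn.ReLU())
        elif l.kind == "pool":
            layers.append(nn.MaxPool2())
        elif l.kind == "gap":
            layers.append(nn.GlobalAvgPool())
            flattened = True
        elif l.kind == "dense":
            if not flattened:
                layers.append(nn.Flatten())
                flattened = True
            layers.append(nn.Dense(int(np.prod(l.input_shape)), l.output_shape[0], rng=rng))
            if i != final_dense:
                layers.append(nn.ReLU())
        elif l.kind == "softmax":
            pass  # applied by the loss / predict path
        else:
            raise ValueError(f"unknown layer kind {l.kind!r}")
    return nn.Sequential(layers)


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class CNNClassifier(BaseEstimator, ClassifierMixin):
    """Small CNN tissue classifier with the scikit-learn fit/predict contract.

    X is an (n, H, W, 3) float stack in [0, 1]; inputs are centered to
    [-0.5, 0.5] internally. Trained with softmax cross-entropy and SGD with
    classical momentum.
    """

    branch_name = "CNN"

    def __init__(self, input_size=(32, 32), epochs: int = 10, lr: float = 0.01,
                 batch_size: int = 32, momentum: float = 0.9, seed: int = 0,
                 dense_widths: tuple[int, ...] = (120, 84), optimizer: str = "sgd"):
        self.input_size = input_size
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.momentum = momentum
        self.seed = seed
        self.dense_widths = dense_widths
        self.optimizer = optimizer

    # -- internals ----------------------------------------------------------
    def _build(self, n_classes: int):
        self.arch_ = default_cnn_arch(tuple(self.input_size), n_classes,
                                      tuple(self.dense_widths))
        return build_cnn(self.arch_, n_classes, self.seed)

    @staticmethod
    def _center(x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float32) - 0.5)

    def _check_x(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[1:3] != tuple(self.input_size) or X.shape[3] != 3:
            raise ValueError(
                f"X must be (n, {self.input_size[0]}, {self.input_size[1]}, 3), "
                f"got {X.shape}")
        return X

    # -- sklearn surface ----------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None) -> "CNNClassifier":
        X = self._check_x(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if X_val is None:
            X_val, yv_idx = X, y_idx
        else:
            X_val = self._check_x(X_val)
            yv_idx = np.searchsorted(self.classes_, np.asarray(y_val))
        self.net_ = self._build(len(self.classes_))
        rng = np.random.default_rng(self.seed)
        result = fit_classifier(
            self.net_, self._center(X), y_idx, self._center(X_val), yv_idx,
            epochs=self.epochs, lr=self.lr, batch_size=self.batch_size,
            momentum=self.momentum, rng=rng, optimizer=self.optimizer)
        self.history_ = result.history
        self.validation_accuracy_ = result.history[-1].validation_accuracy
        val_pred = self._predict_idx(X_val)
        self.per_class_validation_recall_ = _per_class_recall(
            yv_idx, val_pred, len(self.classes_))
        return self

    def _predict_idx(self, X) -> np.ndarray:
        return predict_probs(self.net_, self._center(X)).argmax(axis=1)

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise ValueError(f"{type(self).__name__} is not fitted")
        return predict_probs(self.net_, self._center(self._check_x(X)))

    def predict(self, X) -> np.ndarray:
        # argmax ties resolve to the lowest class index
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def score(self, X, y) -> float:
        return float((self.predict(X) == np.asarray(y)).mean())


def _per_class_recall(y_true_idx, y_pred_idx, n_classes: int) -> np.ndarray:
    rec = np.zeros(n_classes)
    for c in range(n_classes):
        m = y_true_idx == c
        rec[c] = (y_pred_idx[m] == c).mean() if m.any() else 0.0
    return rec


# ---------------------------------------------------------------------------
# Trained-branch container and checkpoints
# ---------------------------------------------------------------------------

@dataclass
class TrainedClassifier:
    """A trained branch plus the sidecar metadata the voting stage consumes."""

    name: str  # CNN | GAN | XDL
    arch: ArchSpec
    net: nn.Sequential
    class_names: tuple[str, ...]
    seed: int
    input_size: tuple[int, int]
    validation_accuracy: float
    per_class_validation_recall: np.ndarray
    history: list
    center_input: bool = True

    def predict_image(self, pixels: np.ndarray):
        """(ProbVector, predicted label) for one [0,1] image at branch size."""
        x = np.asarray(pixels, dtype=np.float32)[None]
        if self.center_input:
            x = x - 0.5
        logits = self.net.forward(x)[0]
        pv = softmax(logits)
        return pv, self.class_names[int(np.argmax(pv.probs))]

    def predict_batch(self, x: np.ndarray) -> np.ndarray:
        xx = x.astype(np.float32) - 0.5 if self.center_input else x.astype(np.float32)
        idx = predict_probs(self.net, xx).argmax(axis=1)
        return np.array([self.class_names[i] for i in idx])

    def save(self, path: str | Path) -> None:
        """Weights as .npz next to a JSON sidecar with the vote metadata."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.net.state_dict())
        sidecar = {
            "name": self.name,
            "arch": self.arch.to_dict(),
            "seed": self.seed,
            "input_size": list(self.input_size),
            "epochs": len(self.history),
            "validation_accuracy": self.validation_accuracy,
            "per_class_validation_recall": [float(v) for v in self.per_class_validation_recall],
            "class_names": list(self.class_names),
            "history": [
                {"epoch": h.epoch, "train_loss": h.train_loss,
                 "validation_accuracy": h.validation_accuracy}
                for h in self.history
            ],
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path: str | Path, builder=None) -> TrainedClassifier:
    """Rebuild a TrainedClassifier from .npz weights + .json sidecar."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    arch = ArchSpec.from_dict(sidecar["arch"])
    n_classes = len(sidecar["class_names"])
    if builder is None:
        builder = build_cnn  # ArchSpec fully determines every branch's network
    net = builder(arch, n_classes, sidecar["seed"])
    with np.load(path.with_suffix(".npz")) as z:
        net.load_state_dict(dict(z))
    hist = [nn.EpochRecord(h["epoch"], h["train_loss"], h["validation_accuracy"])
            for h in sidecar["history"]]
    return TrainedClassifier(
        name=sidecar["name"], arch=arch, net=net,
        class_names=tuple(sidecar["class_names"]), seed=sidecar["seed"],
        input_size=tuple(sidecar["input_size"]),
        validation_accuracy=sidecar["validation_accuracy"],
        per_class_validation_recall=np.array(sidecar["per_class_validation_recall"]),
        history=hist)


def train_classifier(
    manifest: DatasetManifest,
    config: RunConfig,
    branch: str = "CNN",
    estimator: CNNClassifier | None = None,
) -> TrainedClassifier:
    """Fit a branch classifier on a manifest's train split, validate on its
    validation split, and package the result with its vote sidecar."""
    size = config.branch_size(branch)
    classes = config.class_names
    x_tr, y_tr, _ = load_split_arrays(manifest, "train", size, classes)
    x_va, y_va, _ = load_split_arrays(manifest, "validation", size, classes)
    est = estimator or CNNClassifier(
        input_size=size, epochs=config.epochs, lr=config.learning_rate,
        batch_size=config.batch_size, momentum=config.momentum, seed=config.seed)
    est.fit(x_tr, np.array(classes)[y_tr], x_va, np.array(classes)[y_va])
    return TrainedClassifier(
        name=branch, arch=est.arch_, net=est.net_, class_names=tuple(est.classes_),
        seed=est.seed, input_size=tuple(size),
        validation_accuracy=est.validation_accuracy_,
        per_class_validation_recall=est.per_class_validation_recall_,
        history=est.history_)


def predict(model: TrainedClassifier, pixels: np.ndarray):
    """Module-level wrapper: (ProbVector, label) for one branch-sized image."""
    expected = tuple(model.input_size) + (3,)
    if tuple(np.shape(pixels)) != expected:
        raise ValueError(f"image shape {np.shape(pixels)} != branch input {expected}")
    return model.predict_image(pixels)
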