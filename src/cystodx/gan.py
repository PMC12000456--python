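"""Second ensemble member: per-class GAN augmentation + the shared CNN.

One unconditional GAN is trained per tissue class (so every generated image
carries a sound label), its samples are appended to the training split only,
and the resulting augmented set trains a classifier identical to the CNN
branch. The adversarial value function is the two-player minimax objective

    V(D, G) = E_{A~Pd}[log D(A)] + E_{s~Ps}[log(1 - D(G(s)))]

with the generator trained on the standard non-saturating surrogate
(maximize log D(G(s))).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .config import GanConfig, RunConfig
from .data import DatasetManifest, ManifestRecord, load_split_arrays, save_image
from .nn.layers import Layer

log = logging.getLogger(__name__)

EPS = 1e-7


@dataclass(frozen=True)
class GanValue:
    """Empirical value of the minimax game at one batch."""

    v: float
    e_real: float
    e_fake: float


def gan_value(d_real, d_fake) -> GanValue:
    """Empirical V(D,G): mean log D(real) + mean log(1 - D(fake)).

    Inputs are clamped to [EPS, 1-EPS] so the logs stay finite; the value is
    always <= 0 and equals -2*log(2) at the classic equilibrium D == 1/2.
    """
    d_real = np.asarray(d_real, dtype=float)
    d_fake = np.asarray(d_fake, dtype=float)
    if d_real.size == 0 or d_fake.size == 0:
        raise ValueError("gan_value requires non-empty discriminator outputs")
    d_real = np.clip(d_real, EPS, 1 - EPS)
    d_fake = np.clip(d_fake, EPS, 1 - EPS)
    e_real = float(np.log(d_real).mean())
    e_fake = float(np.log(1.0 - d_fake).mean())
    return GanValue(v=e_real + e_fake, e_real=e_real, e_fake=e_fake)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]) -> None:
        super().__init__()
        self.shape = shape

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._inshape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._inshape)


def _build_generator(latent_dim: int, size: int, rng: np.random.Generator) -> nn.Sequential:
    s0 = size // 4
    return nn.Sequential([
        nn.Dense(latent_dim, s0 * s0 * 16, rng=rng), nn.ReLU(),
        Reshape((s0, s0, 16)),
        nn.Upsample2(), nn.Conv2D(16, 8, 3, padding="same", rng=rng), nn.ReLU(),
        nn.Upsample2(), nn.Conv2D(8, 3, 3, padding="same", rng=rng), nn.Sigmoid(),
    ])


def _build_discriminator(size: int, rng: np.random.Generator) -> nn.Sequential:
    s2 = size // 4
    return nn.Sequential([
        nn.Conv2D(3, 8, 3, padding="same", rng=rng), nn.ReLU(), nn.MaxPool2(),
        nn.Conv2D(8, 16, 3, padding="same", rng=rng), nn.ReLU(), nn.MaxPool2(),
        nn.Flatten(), nn.Dense(s2 * s2 * 16, 1, rng=rng), nn.Sigmoid(),
    ])


@dataclass
class GanPair:
    """Trained generator/discriminator for one tissue class."""

    generator: nn.Sequential
    discriminator: nn.Sequential
    class_label: str
    latent_dim: int
    image_size: int
    seed: int
    value_trace: list[float] = field(default_factory=list)
    d_heldout_accuracy_early: float = float("nan")
    d_heldout_accuracy_final: float = float("nan")

    def sample(self, n: int, seed: int | None = None) -> np.ndarray:
        """Generate n images in [0,1]; deterministic for a given seed."""
        rng = np.random.default_rng(self.seed if seed is None else seed)
        s = rng.standard_normal((n, self.latent_dim)).astype(np.float32)
        return np.clip(self.generator.forward(s), 0.0, 1.0)

    def discriminate(self, x: np.ndarray) -> np.ndarray:
        out = self.discriminator.forward(x.astype(np.float32) - 0.5)[:, 0]
        return np.clip(out, EPS, 1 - EPS)


def train_gan(
    images: np.ndarray,
    class_label: str,
    config: GanConfig,
    seed: int = 0,
) -> GanPair:
    """Alternating-update adversarial training on one class's train images.

    One discriminator ascent step on [real; fake] with binary cross-entropy,
    then one generator step on the non-saturating objective. The minimax
    value V(D,G) is recorded at every step. A held-out fifth of the real
    images tracks discriminator accuracy early vs. at the end of training.
    """
    images = np.asarray(images, dtype=np.float32)
    if images.ndim != 4 or len(images) < 16:
        raise ValueError(
            f"class {class_label!r}: need >= 16 training images for GAN, got {len(images)}")
    size = images.shape[1]
    rng = np.random.default_rng(seed)
    gen = _build_generator(config.latent_dim, size, rng)
    disc = _build_discriminator(size, rng)
    pair = GanPair(gen, disc, class_label, config.latent_dim, size, seed)

    n_hold = max(4, len(images) // 5)
    perm = rng.permutation(len(images))
    hold, train = images[perm[:n_hold]], images[perm[n_hold:]]

    opt_d = nn.SGD(disc, lr=config.lr)
    opt_g = nn.SGD(gen, lr=config.lr)
    early_step = max(1, config.steps // 20)

    def d_forward(x: np.ndarray) -> np.ndarray:
        return disc.forward(x - 0.5)[:, 0]

    for step in range(1, config.steps + 1):
        idx = rng.integers(0, len(train), size=config.batch_size)
        real = train[idx]
        z = rng.standard_normal((config.batch_size, config.latent_dim)).astype(np.float32)
        fake = gen.forward(z)

        # --- discriminator step: minimize BCE(real->1, fake->0)
        batch = np.concatenate([real, fake], axis=0)
        target = np.concatenate([np.ones(len(real)), np.zeros(len(fake))])
        y = np.clip(d_forward(batch), EPS, 1 - EPS)
        # d(BCE)/d(sigmoid input) computed via chain through the Sigmoid layer:
        # dL/dy = (y - t) / (y (1-y)) / n
        gy = ((y - target) / (y * (1.0 - y)) / len(y)).astype(np.float32)
        disc.backward(gy[:, None])
        opt_d.step()

        pair.value_trace.append(
            gan_value(y[: len(real)], y[len(real):]).v)

        # --- generator step: maximize log D(G(z)) (non-saturating)
        z = rng.standard_normal((config.batch_size, config.latent_dim)).astype(np.float32)
        fake = gen.forward(z)
        y = np.clip(d_forward(fake), EPS, 1 - EPS)
        gy = (-(1.0 - y) / (y * (1.0 - y)) / len(y)).astype(np.float32)  # d(-log y)/dy
        dx, _ = disc.backward(gy[:, None])
        gen.backward(dx)
        opt_g.step()

        if step == early_step or step == config.steps:
            fake_h = pair.sample(n_hold, seed=seed + 1)
            yh = np.concatenate([d_forward(hold), d_forward(fake_h)])
            th = np.concatenate([np.ones(n_hold), np.zeros(n_hold)])
            acc = float(((yh > 0.5) == th).mean())
            if step == early_step:
                pair.d_heldout_accuracy_early = acc
            pair.d_heldout_accuracy_final = acc
    log.info("GAN[%s]: %d steps, final V=%.3f, D held-out acc %.2f -> %.2f",
             class_label, config.steps, pair.value_trace[-1],
             pair.d_heldout_accuracy_early, pair.d_heldout_accuracy_final)
    return pair


class GANAugmentedClassifier:
    """Estimator surface for the GAN branch: per-class GANs augment the
    training set of a CNN identical to the plain branch.

    fit(X, y, X_val, y_val) trains one GAN per class on that class's rows of
    X, samples ``n_synthetic_per_class`` images from each (labelled with the
    generator's class), and fits the CNN on the union. Validation data is
    never augmented.
    """

    branch_name = "GAN"

    def __init__(self, input_size=(32, 32), epochs: int = 10, lr: float = 0.01,
                 batch_size: int = 32, momentum: float = 0.9, seed: int = 0,
                 gan_config: GanConfig | None = None,
                 n_synthetic_per_class: int | None = None):
        self.input_size = input_size
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.momentum = momentum
        self.seed = seed
        self.gan_config = gan_config
        self.n_synthetic_per_class = n_synthetic_per_class

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "input_size", "epochs", "lr", "batch_size", "momentum", "seed",
            "gan_config", "n_synthetic_per_class")}

    def set_params(self, **params) -> "GANAugmentedClassifier":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y, X_val=None, y_val=None) -> "GANAugmentedClassifier":
        from .cnn import CNNClassifier

        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        classes = np.unique(y)
        gcfg = self.gan_config or GanConfig()
        self.gan_pairs_ = {}
        for ci, label in enumerate(classes):
            self.gan_pairs_[str(label)] = train_gan(
                X[y == label], str(label), gcfg, seed=self.seed + 101 + ci)
        n_syn = self.n_synthetic_per_class
        if n_syn is None:
            n_syn = int(min((y == c).sum() for c in classes))
        if n_syn > 0:
            x_syn = np.concatenate(
                [self.gan_pairs_[str(c)].sample(n_syn) for c in classes])
            y_syn = np.repeat(classes, n_syn)
            X = np.concatenate([X, x_syn])
            y = np.concatenate([y, y_syn])
        self.cnn_ = CNNClassifier(
            input_size=self.input_size, epochs=self.epochs, lr=self.lr,
            batch_size=self.batch_size, momentum=self.momentum, seed=self.seed)
        self.cnn_.fit(X, y, X_val, y_val)
        self.classes_ = self.cnn_.classes_
        self.net_ = self.cnn_.net_
        self.history_ = self.cnn_.history_
        self.validation_accuracy_ = self.cnn_.validation_accuracy_
        self.per_class_validation_recall_ = self.cnn_.per_class_validation_recall_
        return self

    def predict(self, X):
        return self.cnn_.predict(X)

    def predict_proba(self, X):
        return self.cnn_.predict_proba(X)

    def score(self, X, y) -> float:
        return self.cnn_.score(X, y)


def train_gans_per_class(
    manifest: DatasetManifest, config: RunConfig
) -> dict[str, GanPair]:
    size = config.branch_size("GAN")
    x, y, _ = load_split_arrays(manifest, "train", size, config.class_names)
    pairs = {}
    for ci, label in enumerate(config.class_names):
        pairs[label] = train_gan(x[y == ci], label, config.gan,
                                 seed=config.seed + 101 + ci)
    return pairs


def augment_dataset(
    manifest: DatasetManifest,
    gan_pairs: dict[str, GanPair],
    n_synthetic_per_class: int,
    out_dir: str | Path,
) -> DatasetManifest:
    """Append generated images (train split only) to the manifest.

    Synthetic records are flagged; validation/test are untouched.
    """
    classes = manifest.class_names or tuple(sorted(set(manifest.labels())))
    train_labels = {r.label for r in manifest.subset("train")}
    missing = train_labels - set(gan_pairs)
    if missing:
        raise ValueError(f"no trained GAN for classes {sorted(missing)}")
    if n_synthetic_per_class == 0:
        return manifest
    out_dir = Path(out_dir) / "synthetic"
    out_dir.mkdir(parents=True, exist_ok=True)
    new_records = list(manifest.records)
    for label in classes:
        if label not in gan_pairs:
            raise ValueError(f"no trained GAN for class {label!r}")
        samples = gan_pairs[label].sample(n_synthetic_per_class)
        for i, img in enumerate(samples):
            p = out_dir / f"{label}_synthetic_{i:04d}.png"
            save_image(img, p)
            new_records.append(ManifestRecord(str(p), label, "train", synthetic=True))
    return DatasetManifest(new_records, manifest.class_names)


def train_gan_branch(manifest: DatasetManifest, config: RunConfig,
                     work_dir: str | Path):
    """Full GAN branch: per-class GANs -> augmentation -> CNN training.

    Returns (TrainedClassifier named GAN, augmented manifest, gan_pairs).
    """
    from .cnn import train_classifier

    pairs = train_gans_per_class(manifest, config)
    n_per_class = config.gan.n_synthetic_per_class
    if n_per_class is None:
        counts = [sum(1 for r in manifest.subset("train") if r.label == c)
                  for c in config.class_names]
        n_per_class = min(counts)
    augmented = augment_dataset(manifest, pairs, n_per_class, work_dir)
    trained = train_classifier(augmented, config, branch="GAN")
    return trained, augmented, pairs
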