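"""Third ensemble member: explainable VGG-style classifier.

A VGG16-shaped backbone (13 same-padded 3x3 convolutions in five blocks with
2x2 max pooling, channel widths scalable by a width multiplier) feeds Global
Average Pooling and a dense softmax head. Explanations come from:

* **Grad-CAM** — per-map weights w_k^c = spatial mean of d y^c / d A^k over
  the chosen convolutional layer's maps A^k, combined as
  ReLU(sum_k w_k^c A^k); y^c is the pre-softmax class score.
* **Guided backpropagation** — the input gradient of y^c where every ReLU
  passes gradient only at positions with positive forward activation *and*
  positive incoming gradient; the result is clipped at zero and reduced to a
  single channel by a per-pixel max over the color channels.
* **Guided Grad-CAM** — the Grad-CAM map bilinearly upsampled to input
  resolution and multiplied elementwise with the guided-backprop map.

Training uses the saliency maps as an attention-guided augmentation: from the
second epoch onward each training image is cropped around the strongest
region of its predicted-class Guided Grad-CAM map and the network trains on
originals plus crops, with early stopping on validation accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .cnn import (
    ArchSpec,
    CNNClassifier,
    LayerSpec,
    TrainedClassifier,
    _per_class_recall,
    build_cnn,
)
from .config import RunConfig
from .data import DatasetManifest, load_split_arrays
from .nn.train import evaluate_accuracy, fit_classifier, predict_probs

log = logging.getLogger(__name__)

VGG_BLOCKS = ((64, 2), (128, 2), (256, 3), (512, 3), (512, 3))


# ---------------------------------------------------------------------------
# Backbone
# ---------------------------------------------------------------------------

def vgg_arch(input_size: tuple[int, int], width_multiplier: float,
             n_classes: int) -> ArchSpec:
    h, w = input_size
    if min(h, w) < 32:
        raise ValueError(f"input {h}x{w} too small for five 2x2 poolings")
    if not 0 < width_multiplier <= 1:
        raise ValueError("width_multiplier must be in (0, 1]")
    layers = []
    in_ch = 3
    for width, n_conv in VGG_BLOCKS:
        out_ch = max(1, round(width * width_multiplier))
        for _ in range(n_conv):
            layers.append(LayerSpec("conv", (h, w, in_ch), (h, w, out_ch), kernel=3))
            in_ch = out_ch
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims {h}x{w} not divisible by 2 at pooling")
        layers.append(LayerSpec("pool", (h, w, in_ch), (h // 2, w // 2, in_ch), kernel=2))
        h, w = h // 2, w // 2
    layers.append(LayerSpec("gap", (h, w, in_ch), (in_ch,)))
    layers.append(LayerSpec("dense", (in_ch,), (n_classes,)))
    layers.append(LayerSpec("softmax", (n_classes,), (n_classes,)))
    return ArchSpec(layers)


def build_backbone(input_size: tuple[int, int], width_multiplier: float,
                   n_classes: int, seed: int) -> nn.Sequential:
    """VGG16-shaped network; at multiplier 1 and 224x224 input the spatial
    chain is 224 -> 112 -> 56 -> 28 -> 14 -> 7 with widths 64...512."""
    return build_cnn(vgg_arch(input_size, width_multiplier, n_classes), n_classes, seed)


def default_cam_layer(net: nn.Sequential) -> str:
    """The ReLU immediately after the last convolution (its output maps A^k)."""
    last_conv = max(i for i, l in enumerate(net.layers) if isinstance(l, nn.Conv2D))
    return net.names[last_conv + 1]


# ---------------------------------------------------------------------------
# Saliency data types
# ---------------------------------------------------------------------------

@dataclass
class FeatureMaps:
    maps: np.ndarray  # H x W x K
    layer_name: str

    def __post_init__(self) -> None:
        if self.maps.ndim != 3 or self.maps.shape[2] < 1:
            raise ValueError(f"feature maps must be HxWxK, got {self.maps.shape}")


@dataclass
class Heatmap:
    kind: str  # grad_cam | guided_backprop | guided_grad_cam | aggregated
    values: np.ndarray  # 2-D
    class_c: int | None = None
    n_classes_C: int | None = None


def global_average_pool(maps: FeatureMaps | np.ndarray) -> np.ndarray:
    """Spatial mean of each feature map: (H, W, K) -> (K,)."""
    a = maps.maps if isinstance(maps, FeatureMaps) else np.asarray(maps)
    if a.ndim == 2:
        a = a[:, :, None]
    return a.mean(axis=(0, 1))


def bilinear_resize(arr: np.ndarray, out_size: tuple[int, int]) -> np.ndarray:
    """Align-corners bilinear upsampling of a 2-D map (exact, testable)."""
    h, w = arr.shape
    oh, ow = out_size
    if (h, w) == (oh, ow):
        return arr.astype(float)
    ys = np.linspace(0, h - 1, oh) if h > 1 else np.zeros(oh)
    xs = np.linspace(0, w - 1, ow) if w > 1 else np.zeros(ow)
    y0 = np.clip(np.floor(ys).astype(int), 0, h - 1)
    x0 = np.clip(np.floor(xs).astype(int), 0, w - 1)
    y1 = np.clip(y0 + 1, 0, h - 1)
    x1 = np.clip(x0 + 1, 0, w - 1)
    fy = (ys - y0)[:, None]
    fx = (xs - x0)[None, :]
    a = arr[np.ix_(y0, x0)]
    b = arr[np.ix_(y0, x1)]
    c = arr[np.ix_(y1, x0)]
    d = arr[np.ix_(y1, x1)]
    return (a * (1 - fy) * (1 - fx) + b * (1 - fy) * fx
            + c * fy * (1 - fx) + d * fy * fx)


# ---------------------------------------------------------------------------
# Saliency computation
# ---------------------------------------------------------------------------

def _onehot_grad(n: int, class_idx: np.ndarray, n_classes: int) -> np.ndarray:
    g = np.zeros((n, n_classes), np.float32)
    g[np.arange(n), class_idx] = 1.0
    return g


def _saliency_batch(net: nn.Sequential, x_centered: np.ndarray,
                    class_idx: np.ndarray, cam_layer: str):
    """Batched Grad-CAM + guided-backprop maps for each sample's class.

    Returns (cam maps (N, h, w), guided maps (N, H, W)). One forward pass is
    shared; the plain backward (for CAM weights) runs before the guided one
    so the ReLU gating never contaminates the gradient means.
    """
    logits, acts = net.forward(x_centered, capture=cam_layer)
    n, n_classes = logits.shape
    onehot = _onehot_grad(n, class_idx, n_classes)
    _, d_acts = net.backward(onehot, capture=cam_layer, to_input=False)
    w = d_acts.mean(axis=(1, 2))  # (N, K): spatial mean per map
    cam = np.maximum((acts * w[:, None, None, :]).sum(axis=3), 0.0)

    net.set_guided(True)
    try:
        gin, _ = net.backward(onehot)
    finally:
        net.set_guided(False)
    gbp = np.maximum(gin, 0.0).max(axis=3)
    return cam, gbp


def grad_cam(model, pixels: np.ndarray, class_c: int,
             layer_name: str | None = None) -> Heatmap:
    """Grad-CAM map for one [0,1] image and one class (pre-softmax score)."""
    net, x = _net_and_input(model, pixels)
    layer = layer_name or default_cam_layer(net)
    logits, acts = net.forward(x, capture=layer)
    if acts.ndim != 4:
        raise ValueError(f"layer {layer!r} does not produce spatial feature maps")
    onehot = _onehot_grad(1, np.array([class_c]), logits.shape[1])
    _, d_acts = net.backward(onehot, capture=layer, to_input=False)
    w = d_acts[0].mean(axis=(0, 1))
    cam = np.maximum((acts[0] * w[None, None, :]).sum(axis=2), 0.0)
    return Heatmap(kind="grad_cam", values=cam, class_c=class_c)


def cam_weights(model, pixels: np.ndarray, class_c: int,
                layer_name: str | None = None) -> np.ndarray:
    """The Grad-CAM weights w_k^c (spatial means of the gradient maps)."""
    net, x = _net_and_input(model, pixels)
    layer = layer_name or default_cam_layer(net)
    logits, _ = net.forward(x, capture=layer)
    onehot = _onehot_grad(1, np.array([class_c]), logits.shape[1])
    _, d_acts = net.backward(onehot, capture=layer, to_input=False)
    return d_acts[0].mean(axis=(0, 1))


def guided_backprop(model, pixels: np.ndarray, class_c: int) -> Heatmap:
    """Guided-backpropagation saliency for one image and class."""
    net, x = _net_and_input(model, pixels)
    if not net.has_relu():
        raise ValueError("guided backprop requires a network with ReLU layers")
    logits = net.forward(x)
    onehot = _onehot_grad(1, np.array([class_c]), logits.shape[1])
    net.set_guided(True)
    try:
        gin, _ = net.backward(onehot)
    finally:
        net.set_guided(False)
    values = np.maximum(gin[0], 0.0)
    if values.ndim == 3:
        values = values.max(axis=2)
    return Heatmap(kind="guided_backprop", values=values, class_c=class_c)


def guided_grad_cam(cam: Heatmap, gbp: Heatmap,
                    input_size: tuple[int, int] | None = None) -> Heatmap:
    """Elementwise product of the upsampled Grad-CAM and guided-backprop maps."""
    if cam.kind != "grad_cam" or gbp.kind != "guided_backprop":
        raise ValueError("expected a grad_cam and a guided_backprop heatmap")
    if cam.class_c is not None and gbp.class_c is not None and cam.class_c != gbp.class_c:
        raise ValueError(f"class mismatch: {cam.class_c} vs {gbp.class_c}")
    size = input_size or gbp.values.shape
    up = bilinear_resize(cam.values, size)
    return Heatmap(kind="guided_grad_cam", values=up * gbp.values, class_c=cam.class_c)


def aggregate_guided_grad_cam(per_class_maps: list[Heatmap | np.ndarray]) -> Heatmap:
    """Mean over the C per-class Guided Grad-CAM maps."""
    arrs = [m.values if isinstance(m, Heatmap) else np.asarray(m) for m in per_class_maps]
    if len(arrs) < 2:
        raise ValueError("need maps for at least 2 classes")
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch across class maps: {shapes}")
    return Heatmap(kind="aggregated", values=np.mean(arrs, axis=0),
                   n_classes_C=len(arrs))


def _net_and_input(model, pixels: np.ndarray):
    """Accept a raw Sequential (input used as-is), an estimator, or a
    TrainedClassifier (both center [0,1] pixels to [-0.5, 0.5])."""
    if isinstance(model, nn.Sequential):
        net, center = model, False
    elif hasattr(model, "net_"):
        net, center = model.net_, True
    elif hasattr(model, "net"):
        net, center = model.net, getattr(model, "center_input", True)
    else:
        raise TypeError(f"cannot extract a network from {type(model).__name__}")
    x = np.asarray(pixels, dtype=np.float32)[None]
    if center:
        x = x - 0.5
    return net, x


# ---------------------------------------------------------------------------
# Attention cropping
# ---------------------------------------------------------------------------

def attention_crop(
    pixels: np.ndarray,
    heatmap: np.ndarray | Heatmap,
    threshold: float = 0.5,
    margin_px: int = 4,
    out_size: tuple[int, int] | None = None,
) -> tuple[list[np.ndarray], bool]:
    """Crop the image around the strongest heatmap region.

    The map is normalized by its max; the bounding box of pixels >= threshold
    is expanded by ``margin_px``, clipped, cropped, and resized back to
    ``out_size`` (default: the input size). Returns (crops, fallback): an
    all-zero map (or a degenerate box) falls back to the uncropped image.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    hm = heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    pixels = np.asarray(pixels)
    h, w = pixels.shape[:2]
    if hm.shape != (h, w):
        raise ValueError(f"heatmap {hm.shape} must be at input resolution {(h, w)}")
    out_size = out_size or (h, w)
    peak = hm.max()
    if peak <= 0:
        return [_resize_rgb(pixels, out_size)], True
    ys, xs = np.where(hm >= threshold * peak)
    y0 = max(int(ys.min()) - margin_px, 0)
    y1 = min(int(ys.max()) + margin_px, h - 1)
    x0 = max(int(xs.min()) - margin_px, 0)
    x1 = min(int(xs.max()) + margin_px, w - 1)
    if y1 < y0 or x1 < x0:
        log.warning("degenerate attention crop; falling back to full image")
        return [_resize_rgb(pixels, out_size)], True
    crop = pixels[y0:y1 + 1, x0:x1 + 1]
    return [_resize_rgb(crop, out_size)], False


def _resize_rgb(pixels: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    from PIL import Image

    if pixels.shape[:2] == tuple(size):
        return pixels.astype(np.float32)
    img = Image.fromarray((np.clip(pixels, 0, 1) * 255).astype(np.uint8))
    img = img.resize((size[1], size[0]), Image.BILINEAR)
    return np.asarray(img, dtype=np.float32) / 255.0


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class ExplainableVGGClassifier(CNNClassifier):
    """VGG-backbone classifier trained with attention-guided crop augmentation.

    Epoch 1 is a warm-up on the original images; every later epoch recomputes
    the Guided Grad-CAM map of each training image for its currently
    predicted class, crops around the strongest region, and trains on the
    union of originals and crops. Early stopping monitors validation
    accuracy; the best-validation weights are restored at the end.
    """

    branch_name = "XDL"

    def __init__(self, input_size=(64, 64), width_multiplier: float = 0.125,
                 epochs: int = 10, lr: float = 1e-3, batch_size: int = 32,
                 momentum: float = 0.9, seed: int = 0,
                 crop_threshold: float = 0.5, crop_margin: int = 4,
                 patience: int = 3, cam_layer: str | None = None,
                 optimizer: str = "adam"):
        self.input_size = input_size
        self.width_multiplier = width_multiplier
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.momentum = momentum
        self.seed = seed
        self.crop_threshold = crop_threshold
        self.crop_margin = crop_margin
        self.patience = patience
        self.cam_layer = cam_layer
        self.optimizer = optimizer

    def _build(self, n_classes: int):
        self.arch_ = vgg_arch(tuple(self.input_size), self.width_multiplier, n_classes)
        return build_cnn(self.arch_, n_classes, self.seed)

    def fit(self, X, y, X_val=None, y_val=None) -> "ExplainableVGGClassifier":
        X = self._check_x(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if X_val is None:
            X_val, yv_idx = X, y_idx
        else:
            X_val = self._check_x(X_val)
            yv_idx = np.searchsorted(self.classes_, np.asarray(y_val))
        self.net_ = self._build(len(self.classes_))
        layer = self.cam_layer or default_cam_layer(self.net_)
        xc = self._center(X)
        xv = self._center(X_val)
        rng = np.random.default_rng(self.seed)

        def hook(epoch):
            if epoch == 1:
                return xc, y_idx
            pred = predict_probs(self.net_, xc).argmax(axis=1)
            crops = np.empty_like(xc)
            for i0 in range(0, len(xc), 32):
                sl = slice(i0, min(i0 + 32, len(xc)))
                cam, gbp = _saliency_batch(self.net_, xc[sl], pred[sl], layer)
                for j, k in enumerate(range(sl.start, sl.stop)):
                    up = bilinear_resize(cam[j], gbp[j].shape)
                    ggc = up * gbp[j]
                    out, _ = attention_crop(
                        X[k], ggc, self.crop_threshold, self.crop_margin,
                        tuple(self.input_size))
                    crops[k] = out[0] - 0.5
            return (np.concatenate([xc, crops]), np.concatenate([y_idx, y_idx]))

        result = fit_classifier(
            self.net_, xc, y_idx, xv, yv_idx, epochs=self.epochs, lr=self.lr,
            batch_size=self.batch_size, momentum=self.momentum, rng=rng,
            keep_best=True, patience=self.patience, optimizer=self.optimizer,
            epoch_data_hook=hook)
        if result.best_state is not None:
            self.net_.load_state_dict(result.best_state)
        self.history_ = result.history
        self.validation_accuracy_ = evaluate_accuracy(self.net_, xv, yv_idx)
        val_pred = self._predict_idx(X_val)
        self.per_class_validation_recall_ = _per_class_recall(
            yv_idx, val_pred, len(self.classes_))
        return self


def train_xdl(manifest: DatasetManifest, config: RunConfig) -> TrainedClassifier:
    """Manifest-level wrapper mirroring the other branches."""
    size = config.branch_size("XDL")
    classes = config.class_names
    x_tr, y_tr, _ = load_split_arrays(manifest, "train", size, classes)
    x_va, y_va, _ = load_split_arrays(manifest, "validation", size, classes)
    est = ExplainableVGGClassifier(
        input_size=size, width_multiplier=config.xdl.width_multiplier,
        epochs=config.epochs, lr=config.xdl.lr, batch_size=config.batch_size,
        momentum=config.momentum, seed=config.seed,
        crop_threshold=config.xdl.crop_threshold, crop_margin=config.xdl.crop_margin_px,
        patience=config.xdl.patience, cam_layer=config.xdl.cam_layer,
        optimizer=config.xdl.optimizer)
    est.fit(x_tr, np.array(classes)[y_tr], x_va, np.array(classes)[y_va])
    return TrainedClassifier(
        name="XDL", arch=est.arch_, net=est.net_, class_names=tuple(est.classes_),
        seed=est.seed, input_size=tuple(size),
        validation_accuracy=est.validation_accuracy_,
        per_class_validation_recall=est.per_class_validation_recall_,
        history=est.history_)
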