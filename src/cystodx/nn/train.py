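"""Shared training loop: softmax cross-entropy objective, SGD updates,
per-epoch history. Used by every ensemble branch."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import Sequential


def stable_softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction so large logits never overflow."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.log(probs[np.arange(len(y)), y] + eps).mean())


class SGD:
    """Stochastic gradient descent with optional classical momentum."""

    def __init__(self, net: Sequential, lr: float = 0.01, momentum: float = 0.0) -> None:
        self.net = net
        self.lr = lr
        self.momentum = momentum
        self._vel: dict[str, np.ndarray] = {}

    def step(self) -> None:
        for lname, pname, arr, grad in self.net.parameters():
            key = f"{lname}.{pname}"
            if self.momentum > 0:
                v = self._vel.setdefault(key, np.zeros_like(arr))
                v *= self.momentum
                v -= self.lr * grad
                arr += v
            else:
                arr -= self.lr * grad


class Adam:
    """Adam optimizer — the default for the deep VGG branch, where plain SGD
    propagates too little signal through 13 unnormalized layers."""

    def __init__(self, net: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.net = net
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for lname, pname, arr, grad in self.net.parameters():
            key = f"{lname}.{pname}"
            m = self._m.setdefault(key, np.zeros_like(arr))
            v = self._v.setdefault(key, np.zeros_like(arr))
            m *= b1
            m += (1 - b1) * grad
            v *= b2
            v += (1 - b2) * grad * grad
            mhat = m / (1 - b1 ** self._t)
            vhat = v / (1 - b2 ** self._t)
            arr -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    validation_accuracy: float


@dataclass
class FitResult:
    history: list[EpochRecord] = field(default_factory=list)
    best_state: dict | None = None
    best_epoch: int = -1


def predict_probs(net: Sequential, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
    out = []
    for i in range(0, len(x), batch_size):
        out.append(stable_softmax(net.forward(x[i:i + batch_size])))
    return np.concatenate(out, axis=0)


def evaluate_accuracy(net: Sequential, x: np.ndarray, y: np.ndarray) -> float:
    return float((predict_probs(net, x).argmax(axis=1) == y).mean())


def fit_classifier(
    net: Sequential,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    *,
    epochs: int,
    lr: float,
    batch_size: int,
    momentum: float,
    rng: np.random.Generator,
    keep_best: bool = False,
    patience: int | None = None,
    optimizer: str = "sgd",
    epoch_data_hook=None,
) -> FitResult:
    """Train ``net`` with softmax cross-entropy.

    ``epoch_data_hook(epoch)``, when given, may return a replacement
    ``(x_train, y_train)`` for that epoch — the explainable branch uses it to
    inject attention crops from epoch 2 onward.

    Raises ``RuntimeError`` naming the epoch if the loss goes non-finite.
    """
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("empty train or validation set")
    if optimizer == "adam":
        opt = Adam(net, lr=lr)
    elif optimizer == "sgd":
        opt = SGD(net, lr=lr, momentum=momentum)
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")
    result = FitResult()
    best_acc = -1.0
    xe, ye = x_train, y_train
    for epoch in range(1, epochs + 1):
        if epoch_data_hook is not None:
            hook_out = epoch_data_hook(epoch)
            if hook_out is not None:
                xe, ye = hook_out
        order = rng.permutation(len(xe))
        losses = []
        for i in range(0, len(order), batch_size):
            idx = order[i:i + batch_size]
            xb, yb = xe[idx], ye[idx]
            probs = stable_softmax(net.forward(xb))
            losses.append(cross_entropy(probs, yb))
            # d(mean CE)/d(logits) = (softmax - onehot) / batch
            grad = probs.copy()
            grad[np.arange(len(yb)), yb] -= 1.0
            grad /= len(yb)
            net.backward(grad.astype(np.float32))
            opt.step()
        train_loss = float(np.mean(losses))
        if not np.isfinite(train_loss):
            raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
        val_acc = evaluate_accuracy(net, x_val, y_val)
        result.history.append(EpochRecord(epoch, train_loss, val_acc))
        if keep_best and val_acc > best_acc:
            best_acc = val_acc
            result.best_state = net.state_dict()
            result.best_epoch = epoch
        if patience is not None and epoch - max(result.best_epoch, 1) >= patience:
            break
    return result
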