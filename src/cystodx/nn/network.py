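"""Sequential network container with activation/gradient capture.

The capture hooks are what the saliency code relies on: a forward pass can
record any layer's output feature maps, and a backward pass can record the
gradient flowing into that layer's output, without re-running anything.
"""

from __future__ import annotations

import numpy as np

from .layers import Layer, ReLU


class Sequential:
    def __init__(self, layers: list[Layer], names: list[str] | None = None) -> None:
        self.layers = layers
        if names is None:
            names = []
            counts: dict[str, int] = {}
            for lay in layers:
                base = lay.__class__.__name__.lower()
                counts[base] = counts.get(base, 0) + 1
                names.append(f"{base}{counts[base]}")
        if len(names) != len(layers):
            raise ValueError("names/layers length mismatch")
        self.names = names
        for lay, nm in zip(layers, names):
            lay.name = nm

    # -- introspection ------------------------------------------------------
    def layer_index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ValueError(f"unknown layer {name!r}; have {self.names}") from None

    def parameters(self):
        """Yield (layer_name, param_name, array, grad) for every trainable array."""
        for lay in self.layers:
            for key, arr in lay.params.items():
                yield lay.name, key, arr, lay.grads[key]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"{lay.name}.{k}": v.copy() for lay in self.layers for k, v in lay.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for lay in self.layers:
            for k in lay.params:
                key = f"{lay.name}.{k}"
                if key not in state:
                    raise ValueError(f"checkpoint missing {key}")
                if state[key].shape != lay.params[k].shape:
                    raise ValueError(
                        f"checkpoint/arch mismatch at {key}: "
                        f"{state[key].shape} vs {lay.params[k].shape}")
                lay.params[k][...] = state[key]

    # -- execution ----------------------------------------------------------
    def forward(self, x: np.ndarray, capture: str | None = None):
        """Run the net; optionally return (output, captured layer output)."""
        captured = None
        for lay in self.layers:
            x = lay.forward(x)
            if capture is not None and lay.name == capture:
                captured = x
        if capture is not None:
            if captured is None:
                raise ValueError(f"unknown layer {capture!r}")
            return x, captured
        return x

    def backward(self, grad: np.ndarray, capture: str | None = None,
                 to_input: bool = True):
        """Backprop ``grad`` from the output.

        Returns (input_gradient, captured_gradient) where captured_gradient is
        the gradient w.r.t. the named layer's *output*. If ``to_input`` is
        False the pass stops right after the capture point.
        """
        captured = None
        idx = self.layer_index(capture) if capture is not None else -1
        for i in range(len(self.layers) - 1, -1, -1):
            if capture is not None and i == idx:
                captured = grad
                if not to_input:
                    return None, captured
            grad = self.layers[i].backward(grad)
        return grad, captured

    def set_guided(self, flag: bool) -> None:
        for lay in self.layers:
            if isinstance(lay, ReLU):
                lay.guided = flag

    def has_relu(self) -> bool:
        return any(isinstance(lay, ReLU) for lay in self.layers)
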