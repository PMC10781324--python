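"""Network containers (sequential chain and U-Net graph) plus Adam/MSE.

Both containers expose the same surface: ``forward``, ``backward``,
``layers`` (optimizer walks them), ``encoder_layers`` (freezing target) and
``shape_trace`` diagnostics.
"""

from __future__ import annotations

import copy

import numpy as np

from .layers import Layer


class Sequential:
    def __init__(self, layers: list[Layer], n_encoder_layers: int = 0) -> None:
        self.layers = layers
        self.n_encoder_layers = n_encoder_layers

    @property
    def encoder_layers(self) -> list[Layer]:
        return self.layers[: self.n_encoder_layers]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def shape_trace(self, in_shape: tuple) -> list[tuple[str, tuple]]:
        trace = [("input", in_shape)]
        shape = in_shape
        for layer in self.layers:
            shape = layer.out_shape(shape)
            trace.append((layer.describe(), shape))
        return trace


class UNet1D:
    """Encoder-decoder chain with skip concatenations wired explicitly.

    ``down`` is the contraction (conv/pool chain), ``up`` the expansion
    transposed convolutions, ``head`` the output convolution.  ``skips``
    maps each expansion layer index to the index of the contraction layer
    whose activation is concatenated onto its output (or None).
    """

    def __init__(self, down: list[Layer], up: list[Layer], head: Layer,
                 skips: list[int | None]) -> None:
        if len(skips) != len(up):
            raise ValueError("skips must align with the expansion layers")
        self.down = down
        self.up = up
        self.head = head
        self.skips = skips
        self.layers = down + up + [head]

    @property
    def encoder_layers(self) -> list[Layer]:
        return list(self.down)

    def forward(self, x: np.ndarray) -> np.ndarray:
        acts = []
        for layer in self.down:
            x = layer.forward(x)
            acts.append(x)
        self._skip_channels = []
        for layer, skip in zip(self.up, self.skips):
            x = layer.forward(x)
            if skip is not None:
                skip_act = acts[skip]
                self._skip_channels.append(skip_act.shape[2])
                x = np.concatenate([x, skip_act], axis=2)
            else:
                self._skip_channels.append(None)
        return self.head.forward(x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = self.head.backward(dout)
        skip_grads: dict[int, np.ndarray] = {}
        for layer, skip, sc in zip(
            reversed(self.up), reversed(self.skips), reversed(self._skip_channels)
        ):
            if skip is not None:
                own = dout.shape[2] - sc
                d_skip = dout[:, :, own:]
                skip_grads[skip] = skip_grads.get(skip, 0) + d_skip
                dout = dout[:, :, :own]
            dout = layer.backward(dout)
        for idx in range(len(self.down) - 1, -1, -1):
            if idx in skip_grads:
                dout = dout + skip_grads[idx]
            dout = self.down[idx].backward(dout)
        return dout

    def shape_trace(self, in_shape: tuple) -> list[tuple[str, tuple]]:
        trace = [("input", in_shape)]
        shape = in_shape
        down_shapes = []
        for layer in self.down:
            shape = layer.out_shape(shape)
            down_shapes.append(shape)
            trace.append((layer.describe(), shape))
        for layer, skip in zip(self.up, self.skips):
            shape = layer.out_shape(shape)
            trace.append((layer.describe(), shape))
            if skip is not None:
                shape = (shape[0], shape[1] + down_shapes[skip][1])
                trace.append(("concat", shape))
        shape = self.head.out_shape(shape)
        trace.append((self.head.describe(), shape))
        return trace


def n_params(network) -> int:
    return int(sum(layer.n_params for layer in network.layers))


def n_trainable_params(network) -> int:
    return int(sum(layer.n_params for layer in network.layers if not layer.frozen))


def get_weights(network) -> list[dict[str, np.ndarray]]:
    return [copy.deepcopy(layer.params) for layer in network.layers]


def set_weights(network, weights: list[dict[str, np.ndarray]]) -> None:
    for layer, w in zip(network.layers, weights):
        for key in layer.params:
            layer.params[key] = w[key].copy()


class Adam:
    """Adam over the non-frozen layers of a network."""

    def __init__(self, network, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.network = network
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        for i, layer in enumerate(self.network.layers):
            if layer.frozen:
                continue
            for name, param in layer.params.items():
                grad = layer.grads[name]
                key = (i, name)
                m = self._m.setdefault(key, np.zeros_like(param))
                v = self._v.setdefault(key, np.zeros_like(param))
                m += (1 - self.beta1) * (grad - m)
                v += (1 - self.beta2) * (grad**2 - v)
                mhat = m / (1 - self.beta1**self.t)
                vhat = v / (1 - self.beta2**self.t)
                param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient with respect to ``pred``."""
    diff = pred - target
    loss = float(np.mean(diff**2))
    return loss, 2.0 * diff / diff.size
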