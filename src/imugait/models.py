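"""The four wrist-to-lower-limb translation architectures.

Every model maps a unit-scaled 256 x 6 window (ax, ay, az, gx, gy, gz) to a
256 x 6 window at the target site.  The dense and convolutional
autoencoders and the U-Net end in a sigmoid head, so their outputs are
bounded in [0, 1]; the CNN-LSTM keeps a tanh head whose (-1, 1) range
covers the (0, 1) target band.

Architecture summaries (widths / filters, kernel 3 throughout):

* dense_ae  — Flatten(1536) -> 512 -> 256 -> 128 (encoder) -> 256 -> 512
  -> 1536 sigmoid -> Reshape(256, 6).  The output layer must produce
  256 * 6 = 1536 values for the reshape, so its width is 1536.
* cnn_ae    — Conv64/Pool/Conv128/Pool/Conv256 (encoder, lengths
  256->128->64) then transposed convolutions 256(s2)/128(s2)/64(s1) and a
  sigmoid Conv6 head (lengths 64->128->256->256).
* cnn_lstm  — Conv64 then LSTM64 and LSTM6, both returning full sequences
  so a whole window is translated in one call.
* unet      — the cnn_ae layout plus skip concatenations from the two
  contraction activations into the expansion at matching lengths.

Convolutions are length-preserving (symmetric zero padding); the
transposed-convolution strides (2, 2, 1) mirror the two pooling steps so
the decoder restores length 256.  Pooling is activation-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .signal_core import (
    N_CHANNELS,
    WINDOW_LENGTH,
    ImuWindow,
    ScalingParams,
    invert_scaler,
)

ARCHITECTURES = ("dense_ae", "cnn_ae", "cnn_lstm", "unet")

#: architectures with a pretrainable encoder/decoder split
AUTOENCODER_ARCHITECTURES = ("dense_ae", "cnn_ae", "unet")


@dataclass
class TranslationModel:
    """An architecture, its weights, and its training state."""

    architecture: str
    network: object
    layer_spec: list[dict] = field(default_factory=list)
    pretrained: bool = False
    translation_trained: bool = False

    @property
    def encoder_frozen(self) -> bool:
        enc = self.network.encoder_layers
        return bool(enc) and all(layer.frozen for layer in enc)

    @property
    def n_params(self) -> int:
        return nn.n_params(self.network)

    @property
    def n_trainable_params(self) -> int:
        return nn.n_trainable_params(self.network)

    def forward(self, windows: np.ndarray) -> np.ndarray:
        """(n, 256, 6) scaled input -> (n, 256, 6) output."""
        windows = np.asarray(windows, dtype=float)
        if windows.ndim != 3 or windows.shape[1:] != (WINDOW_LENGTH, N_CHANNELS):
            raise ValueError(
                f"expected (n, {WINDOW_LENGTH}, {N_CHANNELS}) input, got {windows.shape}"
            )
        return self.network.forward(windows)

    def shape_trace(self) -> list[tuple[str, tuple]]:
        """Per-layer output shapes from the 256 x 6 input to the output."""
        return self.network.shape_trace((WINDOW_LENGTH, N_CHANNELS))

    def save(self, path: str | Path) -> None:
        arrays = {}
        for i, layer in enumerate(self.network.layers):
            for name, param in layer.params.items():
                arrays[f"layer{i}_{name}"] = param
        manifest = json.dumps(
            {
                "architecture": self.architecture,
                "layer_spec": self.layer_spec,
                "pretrained": self.pretrained,
                "translation_trained": self.translation_trained,
            }
        )
        np.savez(path, manifest=np.array(manifest), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TranslationModel":
        with np.load(path, allow_pickle=False) as data:
            manifest = json.loads(str(data["manifest"]))
            model = build_model(manifest["architecture"])
            for i, layer in enumerate(model.network.layers):
                for name in layer.params:
                    layer.params[name] = data[f"layer{i}_{name}"].copy()
        model.pretrained = manifest["pretrained"]
        model.translation_trained = manifest["translation_trained"]
        return model


def _spec(network) -> list[dict]:
    trace = network.shape_trace((WINDOW_LENGTH, N_CHANNELS))
    return [{"layer": name, "shape": list(shape)} for name, shape in trace]


def build_dense_autoencoder(seed: int = 0) -> TranslationModel:
    """Fully connected autoencoder: 512/256/128 encoder, 256/512 decoder,
    1536-unit sigmoid output reshaped to 256 x 6."""
    rng = np.random.default_rng(seed)
    flat = WINDOW_LENGTH * N_CHANNELS
    layers = [
        nn.Flatten(),
        nn.Dense(flat, 512, "relu", rng),
        nn.Dense(512, 256, "relu", rng),
        nn.Dense(256, 128, "relu", rng),
        nn.Dense(128, 256, "relu", rng),
        nn.Dense(256, 512, "relu", rng),
        nn.Dense(512, flat, "sigmoid", rng),
        nn.Reshape(WINDOW_LENGTH, N_CHANNELS),
    ]
    net = nn.Sequential(layers, n_encoder_layers=4)  # flatten + 3 dense
    model = TranslationModel("dense_ae", net)
    model.layer_spec = _spec(net)
    return model


def build_cnn_autoencoder(seed: int = 0) -> TranslationModel:
    """Convolutional autoencoder: Conv 64/128/256 with two 2x poolings,
    then transposed convolutions 256/128/64 and a sigmoid Conv 6 head."""
    rng = np.random.default_rng(seed)
    layers = [
        nn.Conv1D(N_CHANNELS, 64, 3, "relu", rng),
        nn.MaxPool1D(2),
        nn.Conv1D(64, 128, 3, "relu", rng),
        nn.MaxPool1D(2),
        nn.Conv1D(128, 256, 3, "relu", rng),
        nn.ConvTranspose1D(256, 256, 3, 2, "relu", rng),
        nn.ConvTranspose1D(256, 128, 3, 2, "relu", rng),
        nn.ConvTranspose1D(128, 64, 3, 1, "relu", rng),
        nn.Conv1D(64, N_CHANNELS, 3, "sigmoid", rng),
    ]
    net = nn.Sequential(layers, n_encoder_layers=5)
    model = TranslationModel("cnn_ae", net)
    model.layer_spec = _spec(net)
    return model


def build_cnn_lstm(seed: int = 0) -> TranslationModel:
    """Single convolution feeding two full-sequence LSTMs (64 and 6 units)."""
    rng = np.random.default_rng(seed)
    layers = [
        nn.Conv1D(N_CHANNELS, 64, 3, "relu", rng),
        nn.LSTM(64, 64, rng),
        nn.LSTM(64, N_CHANNELS, rng),
    ]
    net = nn.Sequential(layers, n_encoder_layers=0)
    model = TranslationModel("cnn_lstm", net)
    model.layer_spec = _spec(net)
    return model


def build_unet(seed: int = 0) -> TranslationModel:
    """U-Net: the cnn_ae contraction, with the 128- and 64-filter
    activations concatenated into the expansion at matching lengths."""
    rng = np.random.default_rng(seed)
    down = [
        nn.Conv1D(N_CHANNELS, 64, 3, "relu", rng),
        nn.MaxPool1D(2),
        nn.Conv1D(64, 128, 3, "relu", rng),
        nn.MaxPool1D(2),
        nn.Conv1D(128, 256, 3, "relu", rng),
    ]
    up = [
        nn.ConvTranspose1D(256, 256, 3, 2, "relu", rng),
        # input channels 256 + 128 from the skip concatenation
        nn.ConvTranspose1D(384, 128, 3, 2, "relu", rng),
        nn.ConvTranspose1D(192, 64, 3, 1, "relu", rng),
    ]
    head = nn.Conv1D(64, N_CHANNELS, 3, "sigmoid", rng)
    # skips: first up-conv output (len 128) gets the 128-filter conv (index 2),
    # second (len 256) gets the 64-filter conv (index 0)
    net = nn.UNet1D(down, up, head, skips=[2, 0, None])
    model = TranslationModel("unet", net)
    model.layer_spec = _spec(net)
    return model


_BUILDERS = {
    "dense_ae": build_dense_autoencoder,
    "cnn_ae": build_cnn_autoencoder,
    "cnn_lstm": build_cnn_lstm,
    "unet": build_unet,
}


def build_model(architecture: str, seed: int = 0) -> TranslationModel:
    if architecture not in _BUILDERS:
        raise ValueError(f"unknown architecture {architecture!r}; choose from {ARCHITECTURES}")
    return _BUILDERS[architecture](seed)


def translate_window(
    model: TranslationModel,
    window: ImuWindow,
    target_scaling: ScalingParams,
    target_site: str = "shoe",
) -> ImuWindow:
    """Forward pass on one scaled wrist window, then rescale the output to
    physical units at the target site."""
    if not window.scaled:
        raise ValueError("translate_window requires a scaled input window")
    out = model.forward(window.values[None])[0]
    # tanh heads can leave the (0, 1) band; clip before inverse scaling
    scaled = ImuWindow(np.clip(out, 0.0, 1.0), target_site, scaled=True,
                       start_index=window.start_index)
    return invert_scaler(scaled, target_scaling)
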