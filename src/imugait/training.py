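"""Two-stage training protocol for the translation models.

The pretrainable architectures (dense_ae, cnn_ae, unet) are first trained
as autoencoders on wrist windows alone (input = label), their feature
extraction layers are frozen, and only the reconstruction layers learn the
wrist-to-tibia / wrist-to-shoe mapping.  A final fine-tuning pass unfreezes
the encoder at a ten-fold lower learning rate.  The CNN-LSTM has no
encoder/decoder split and trains directly on the paired dataset.

Loss is mean squared error throughout; the optimizer is Adam at 1e-3
(fine-tuning at 1e-4).  Datasets split 70/15/15 into train/validation/test
by a seeded permutation of window indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .models import AUTOENCODER_ARCHITECTURES, TranslationModel
from .signal_core import ScalingParams, WindowedDataset

DEFAULT_SPLIT = (0.70, 0.15, 0.15)


@dataclass
class TrainingConfig:
    """Optimization settings; loss is fixed to MSE, the optimizer to Adam."""

    learning_rate: float = 1e-3
    fine_tune_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 32
    early_stop_patience: int = 10
    split_fractions: tuple[float, float, float] = DEFAULT_SPLIT
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.learning_rate <= 0 or self.fine_tune_rate <= 0:
            raise ValueError("learning rates must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class PairedDataset:
    """Index-aligned wrist/target window pairs, both unit-scaled with their
    own site's scaler."""

    wrist: np.ndarray
    target: np.ndarray
    target_site: str
    wrist_scaling: ScalingParams | None = None
    target_scaling: ScalingParams | None = None

    def __post_init__(self) -> None:
        self.wrist = np.asarray(self.wrist, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if self.wrist.shape != self.target.shape:
            raise ValueError("wrist and target stacks must have identical shapes")
        if self.target_site not in ("tibia", "shoe"):
            raise ValueError("target_site must be tibia or shoe")

    def __len__(self) -> int:
        return self.wrist.shape[0]

    def subset(self, idx: np.ndarray) -> "PairedDataset":
        return PairedDataset(
            self.wrist[idx], self.target[idx], self.target_site,
            self.wrist_scaling, self.target_scaling,
        )


@dataclass
class TrainingReport:
    stage: str
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_epoch: int = 0
    test_loss: float = float("nan")
    learning_rate: float = float("nan")

    @property
    def best_val_loss(self) -> float:
        return self.val_losses[self.best_epoch]


def split_indices(
    n: int,
    fractions: tuple[float, float, float] = DEFAULT_SPLIT,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded-permutation split into (floor(f0*n), floor(f1*n), remainder)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if n < 3:
        raise ValueError("need at least 3 items to split into three parts")
    n_train = int(np.floor(fractions[0] * n))
    n_val = int(np.floor(fractions[1] * n))
    perm = np.random.default_rng(seed).permutation(n)
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


def split_dataset(dataset, fractions=DEFAULT_SPLIT, seed: int = 0):
    """Split a WindowedDataset or PairedDataset into train/val/test parts."""
    idx = split_indices(len(dataset), fractions, seed)
    return tuple(dataset.subset(i) for i in idx)


def _iterate_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _fit(
    model: TranslationModel,
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    lr: float,
    config: TrainingConfig,
    stage: str,
) -> TrainingReport:
    """Minibatch Adam/MSE loop with early stopping on validation loss and
    best-epoch weight restoration."""
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.network, lr=lr)
    report = TrainingReport(stage=stage, learning_rate=lr)
    best_val = np.inf
    best_weights = nn.get_weights(model.network)
    since_best = 0
    for epoch in range(config.epochs):
        epoch_losses = []
        for batch in _iterate_batches(len(X), config.batch_size, rng):
            pred = model.network.forward(X[batch])
            loss, grad = nn.mse_loss(pred, y[batch])
            model.network.backward(grad)
            opt.step()
            epoch_losses.append(loss)
        train_loss = float(np.mean(epoch_losses))
        if len(X_val):
            val_pred = model.network.forward(X_val)
            val_loss = float(np.mean((val_pred - y_val) ** 2))
        else:
            # tiny datasets can floor the 15% validation share to zero;
            # fall back to monitoring the training loss
            val_loss = train_loss
        report.train_losses.append(train_loss)
        report.val_losses.append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = nn.get_weights(model.network)
            report.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.early_stop_patience:
                break
    nn.set_weights(model.network, best_weights)
    return report


def _check_scaled(values: np.ndarray, what: str) -> None:
    if values.min() < -1e-9 or values.max() > 1 + 1e-9:
        raise ValueError(f"{what} must be unit-scaled to [0, 1] before training")


def pretrain_autoencoder(
    model: TranslationModel,
    wrist_dataset: WindowedDataset | np.ndarray,
    config: TrainingConfig,
) -> TrainingReport:
    """Unsupervised wrist pretraining: wrist windows are both inputs and
    labels.  Not applicable to the CNN-LSTM, which trains directly on the
    translation pairs."""
    if model.architecture not in AUTOENCODER_ARCHITECTURES:
        raise ValueError(
            f"{model.architecture} has no pretrainable encoder; "
            "it is trained directly on the translation dataset"
        )
    values = wrist_dataset.values if isinstance(wrist_dataset, WindowedDataset) else np.asarray(wrist_dataset)
    _check_scaled(values, "wrist pretraining data")
    tr, va, te = split_indices(len(values), config.split_fractions, config.seed)
    report = _fit(model, values[tr], values[tr], values[va], values[va],
                  config.learning_rate, config, stage="pretrain")
    test_pred = model.network.forward(values[te])
    report.test_loss = float(np.mean((test_pred - values[te]) ** 2))
    model.pretrained = True
    return report


def freeze_encoder(model: TranslationModel) -> TranslationModel:
    """Mark the feature-extraction (contraction) layers non-trainable."""
    if model.architecture not in AUTOENCODER_ARCHITECTURES:
        raise ValueError(f"{model.architecture} has no encoder to freeze")
    if not model.pretrained:
        raise ValueError("freeze_encoder requires a pretrained encoder")
    for layer in model.network.encoder_layers:
        layer.frozen = True
    return model


def train_translation(
    model: TranslationModel,
    paired: PairedDataset,
    config: TrainingConfig,
) -> TrainingReport:
    """Supervised wrist-to-target training (reconstruction layers only for
    the frozen-encoder architectures; the whole CNN-LSTM otherwise)."""
    if model.architecture in AUTOENCODER_ARCHITECTURES and not model.encoder_frozen:
        raise ValueError("pretrain and freeze the encoder before translation training")
    _check_scaled(paired.wrist, "wrist windows")
    _check_scaled(paired.target, "target windows")
    train, val, test = split_dataset(paired, config.split_fractions, config.seed)
    report = _fit(model, train.wrist, train.target, val.wrist, val.target,
                  config.learning_rate, config, stage="translate")
    test_pred = model.network.forward(test.wrist)
    report.test_loss = float(np.mean((test_pred - test.target) ** 2))
    model.translation_trained = True
    return report


def fine_tune(
    model: TranslationModel,
    paired: PairedDataset,
    config: TrainingConfig,
) -> TrainingReport:
    """Unfreeze the encoder and continue translation training at the lower
    fine-tuning learning rate."""
    if model.architecture not in AUTOENCODER_ARCHITECTURES:
        raise ValueError(f"{model.architecture} has no frozen stage to fine-tune")
    if not (model.translation_trained and model.encoder_frozen):
        raise ValueError("fine_tune requires a model trained with a frozen encoder")
    for layer in model.network.layers:
        layer.frozen = False
    train, val, test = split_dataset(paired, config.split_fractions, config.seed)
    report = _fit(model, train.wrist, train.target, val.wrist, val.target,
                  config.fine_tune_rate, config, stage="fine_tune")
    test_pred = model.network.forward(test.wrist)
    report.test_loss = float(np.mean((test_pred - test.target) ** 2))
    return report


def reports_to_rows(reports: list[TrainingReport]) -> list[dict]:
    """Flatten reports into CSV-ready rows (epoch, train_loss, val_loss, stage)."""
    rows = []
    for report in reports:
        for epoch, (tr, va) in enumerate(zip(report.train_losses, report.val_losses)):
            rows.append({"stage": report.stage, "epoch": epoch,
                         "train_loss": tr, "val_loss": va})
    return rows
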