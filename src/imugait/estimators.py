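"""scikit-learn style estimators wrapping the translation pipeline.

Each translator is a regressor over window stacks: ``fit(X, y)`` takes
unit-scaled wrist windows ``X`` and target-site windows ``y`` of shape
(n, 256, 6) and runs the architecture's full protocol (for the
autoencoder-style models: wrist pretraining, encoder freezing, translation
training, optional fine-tuning; the CNN-LSTM trains directly).
``predict(X)`` returns scaled (n, 256, 6) translations.

These compose with sklearn model selection; ``score`` returns negative
test MSE (higher is better).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .models import AUTOENCODER_ARCHITECTURES, build_model
from .signal_core import N_CHANNELS, WINDOW_LENGTH
from .training import (
    PairedDataset,
    TrainingConfig,
    fine_tune,
    freeze_encoder,
    pretrain_autoencoder,
    train_translation,
)


class BaseTranslator(BaseEstimator, RegressorMixin):
    """Shared fit/predict machinery; subclasses pin the architecture."""

    architecture: str = ""

    def __init__(
        self,
        epochs: int = 100,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        fine_tune_rate: float = 1e-4,
        patience: int = 10,
        pretrain_epochs: int | None = None,
        fine_tune_epochs: int | None = None,
        do_fine_tune: bool = True,
        target_site: str = "shoe",
        seed: int = 0,
    ) -> None:
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.fine_tune_rate = fine_tune_rate
        self.patience = patience
        self.pretrain_epochs = pretrain_epochs
        self.fine_tune_epochs = fine_tune_epochs
        self.do_fine_tune = do_fine_tune
        self.target_site = target_site
        self.seed = seed

    def _config(self, epochs: int) -> TrainingConfig:
        return TrainingConfig(
            learning_rate=self.learning_rate,
            fine_tune_rate=self.fine_tune_rate,
            epochs=epochs,
            batch_size=self.batch_size,
            early_stop_patience=self.patience,
            seed=self.seed,
        )

    @staticmethod
    def _validate(X: np.ndarray, name: str) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1:] != (WINDOW_LENGTH, N_CHANNELS):
            raise ValueError(
                f"{name} must be (n, {WINDOW_LENGTH}, {N_CHANNELS}), got {X.shape}"
            )
        if not np.isfinite(X).all():
            raise ValueError(f"{name} contains non-finite values")
        return X

    def fit(self, X: np.ndarray, y: np.ndarray, X_pretrain: np.ndarray | None = None):
        """Run the architecture's training protocol on scaled window pairs.

        ``X_pretrain`` optionally supplies a larger wrist-only corpus for
        the unsupervised pretraining stage; it defaults to ``X``.
        """
        X = self._validate(X, "X")
        y = self._validate(y, "y")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y must hold the same number of windows")
        self.model_ = build_model(self.architecture, seed=self.seed)
        self.reports_ = []
        paired = PairedDataset(X, y, self.target_site)
        if self.architecture in AUTOENCODER_ARCHITECTURES:
            corpus = X if X_pretrain is None else self._validate(X_pretrain, "X_pretrain")
            pre_epochs = self.pretrain_epochs or self.epochs
            self.reports_.append(
                pretrain_autoencoder(self.model_, corpus, self._config(pre_epochs))
            )
            freeze_encoder(self.model_)
            self.reports_.append(
                train_translation(self.model_, paired, self._config(self.epochs))
            )
            if self.do_fine_tune:
                ft_epochs = self.fine_tune_epochs or self.epochs
                self.reports_.append(
                    fine_tune(self.model_, paired, self._config(ft_epochs))
                )
        else:
            self.reports_.append(
                train_translation(self.model_, paired, self._config(self.epochs))
            )
        self.n_params_ = self.model_.n_params
        self.test_loss_ = self.reports_[-1].test_loss
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        X = self._validate(X, "X")
        return self.model_.forward(X)

    def score(self, X: np.ndarray, y: np.ndarray, sample_weight=None) -> float:
        pred = self.predict(X)
        return -float(np.mean((pred - np.asarray(y)) ** 2))


class DenseAutoencoderTranslator(BaseTranslator):
    """Fully connected autoencoder translator (512/256/128 encoder)."""

    architecture = "dense_ae"


class ConvAutoencoderTranslator(BaseTranslator):
    """1-D convolutional autoencoder translator (64/128/256 filters)."""

    architecture = "cnn_ae"


class ConvLSTMTranslator(BaseTranslator):
    """Conv(64) + LSTM(64) + LSTM(6) translator, trained in one stage."""

    architecture = "cnn_lstm"


class UNetTranslator(BaseTranslator):
    """U-Net translator: cnn_ae layout plus skip concatenations."""

    architecture = "unet"


TRANSLATORS = {
    cls.architecture: cls
    for cls in (
        DenseAutoencoderTranslator,
        ConvAutoencoderTranslator,
        ConvLSTMTranslator,
        UNetTranslator,
    )
}
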