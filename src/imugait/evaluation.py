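"""Per-channel translation error metrics in physical units.

MAE and RMSE are reported per channel in the channel's own unit (g for
acceleration, deg/s for angular velocity), pooled over every sample of
every test window.  Metrics are always computed after inverse scaling;
errors measured in the [0, 1] scaled space are not comparable across
channels with different physical ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import TranslationModel
from .signal_core import CHANNELS, WindowScaler, WindowedDataset


def _values(ds) -> np.ndarray:
    return ds.values if isinstance(ds, WindowedDataset) else np.asarray(ds, dtype=float)


def _check_pair(pred: np.ndarray, truth: np.ndarray) -> None:
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if pred.ndim != 3 or pred.shape[2] != len(CHANNELS):
        raise ValueError("expected (n, L, 6) window stacks")


def channel_mae(predicted, truth) -> np.ndarray:
    """Mean absolute error per channel, pooled over windows and samples."""
    pred, true = _values(predicted), _values(truth)
    _check_pair(pred, true)
    return np.abs(pred - true).mean(axis=(0, 1))


def channel_rmse(predicted, truth) -> np.ndarray:
    """Root-mean-square error per channel, pooled over windows and samples."""
    pred, true = _values(predicted), _values(truth)
    _check_pair(pred, true)
    return np.sqrt(((pred - true) ** 2).mean(axis=(0, 1)))


@dataclass
class ChannelErrors:
    """Six MAE and six RMSE values in (ax, ay, az, gx, gy, gz) order."""

    mae: np.ndarray
    rmse: np.ndarray

    def __post_init__(self) -> None:
        self.mae = np.asarray(self.mae, dtype=float).reshape(len(CHANNELS))
        self.rmse = np.asarray(self.rmse, dtype=float).reshape(len(CHANNELS))
        if (self.mae < 0).any() or (self.rmse < 0).any():
            raise ValueError("error metrics must be non-negative")
        if (self.rmse + 1e-12 < self.mae).any():
            raise ValueError("RMSE must dominate MAE channel-wise")


def compute_channel_errors(predicted, truth) -> ChannelErrors:
    return ChannelErrors(channel_mae(predicted, truth), channel_rmse(predicted, truth))


@dataclass
class ArchitectureComparison:
    """Per-architecture channel errors on one shared test set."""

    site: str
    rows: dict[str, ChannelErrors]

    def to_frame(self) -> pd.DataFrame:
        """One row per (metric, architecture), columns in channel order."""
        records = []
        for metric in ("mae", "rmse"):
            for arch, errors in self.rows.items():
                rec = {"metric": metric, "architecture": arch}
                rec.update(dict(zip(CHANNELS, getattr(errors, metric))))
                records.append(rec)
        return pd.DataFrame.from_records(records)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def compare_architectures(
    models: dict[str, TranslationModel],
    paired_test,
    require_all: bool = True,
) -> ArchitectureComparison:
    """Translate a shared scaled test set with each model, invert the
    target-site scaling, and tabulate per-channel MAE/RMSE.

    ``models`` maps architecture names to trained models; ``paired_test``
    is a :class:`~imugait.training.PairedDataset` carrying the target
    scaler.  With ``require_all`` the canonical four architectures must
    all be present.
    """
    if require_all:
        missing = {"dense_ae", "cnn_ae", "cnn_lstm", "unet"} - set(models)
        if missing:
            raise ValueError(f"missing architectures: {sorted(missing)}")
    if not models:
        raise ValueError("no models to compare")
    if paired_test.target_scaling is None:
        raise ValueError("paired_test must carry the target-site scaler")
    inverse = WindowScaler.from_params(paired_test.target_scaling).inverse_transform
    truth_phys = inverse(paired_test.target)
    rows = {}
    for arch, model in models.items():
        pred = np.clip(model.forward(paired_test.wrist), 0.0, 1.0)
        rows[arch] = compute_channel_errors(inverse(pred), truth_phys)
    return ArchitectureComparison(site=paired_test.target_site, rows=rows)
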