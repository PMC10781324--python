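"""Core containers and transforms for six-channel inertial recordings.

A recording carries tri-axial acceleration in g and tri-axial angular
velocity in deg/s at a fixed sampling rate (50 Hz in the reference
hardware).  Fixed channel order everywhere: (ax, ay, az, gx, gy, gz).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

CHANNELS: tuple[str, ...] = ("ax", "ay", "az", "gx", "gy", "gz")
N_CHANNELS = 6
#: default model window: 256 samples, i.e. 5.12 s at 50 Hz
WINDOW_LENGTH = 256
SITES = ("wrist", "tibia", "shoe")


def window_duration(length: int, sample_rate: float) -> float:
    """Span of a window in seconds (256 samples at 50 Hz -> 5.12 s)."""
    return length / sample_rate


@dataclass
class ImuSeries:
    """A continuous 6-channel inertial recording tagged with a body site.

    ``data`` is an (N, 6) float array in (ax, ay, az, gx, gy, gz) order,
    acceleration in g and angular velocity in deg/s.
    """

    data: np.ndarray
    sample_rate: float
    site: str
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != N_CHANNELS:
            raise ValueError(
                f"ImuSeries data must be (N, {N_CHANNELS}), got {self.data.shape}"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}, got {self.site!r}")

    @classmethod
    def from_channels(
        cls,
        channels: dict[str, Sequence[float]],
        sample_rate: float,
        site: str,
        start_time: float = 0.0,
    ) -> "ImuSeries":
        lengths = {len(channels[c]) for c in CHANNELS}
        if len(lengths) != 1:
            raise ValueError("all six channels must have identical length")
        data = np.column_stack([np.asarray(channels[c], dtype=float) for c in CHANNELS])
        return cls(data, sample_rate, site, start_time)

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return len(self) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self)) / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, CHANNELS.index(name)]

    def gyro_resultant(self) -> np.ndarray:
        """Signal vector magnitude of the angular-velocity channels."""
        return resultant_magnitude(
            self.channel("gx"), self.channel("gy"), self.channel("gz")
        )

    def accel_resultant(self) -> np.ndarray:
        return resultant_magnitude(
            self.channel("ax"), self.channel("ay"), self.channel("az")
        )

    def to_csv(self, path: str | Path) -> None:
        """Write ``t,ax,ay,az,gx,gy,gz`` rows, t in seconds."""
        frame = pd.DataFrame(self.data, columns=list(CHANNELS))
        frame.insert(0, "t", self.times)
        frame.to_csv(path, index=False)

    @classmethod
    def read_csv(
        cls,
        path: str | Path,
        site: str,
        sample_rate: float | None = None,
    ) -> "ImuSeries":
        """Read the CSV dialect; a missing ``t`` column is reconstructed
        from ``sample_rate``."""
        frame = pd.read_csv(path)
        missing = [c for c in CHANNELS if c not in frame.columns]
        if missing:
            raise ValueError(f"CSV is missing channels {missing}")
        data = frame[list(CHANNELS)].to_numpy(dtype=float)
        if "t" in frame.columns:
            t = frame["t"].to_numpy(dtype=float)
            start = float(t[0]) if len(t) else 0.0
            if sample_rate is None:
                if len(t) < 2:
                    raise ValueError("cannot infer sample_rate from fewer than 2 rows")
                sample_rate = 1.0 / float(np.median(np.diff(t)))
        else:
            if sample_rate is None:
                raise ValueError("CSV has no t column; sample_rate is required")
            start = 0.0
        return cls(data, float(sample_rate), site, start)


@dataclass
class ImuWindow:
    """A fixed-length segment of an :class:`ImuSeries`; the unit consumed
    and produced by the translation models (256 x 6)."""

    values: np.ndarray
    site: str
    scaled: bool = False
    start_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_CHANNELS:
            raise ValueError(f"window must be (L, {N_CHANNELS}), got {self.values.shape}")
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}")
        if self.scaled and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise ValueError("scaled window has values outside [0, 1]")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class ScalingParams:
    """Per-channel min-max range used for mapping signals to [0, 1].

    Fitted on the training split only and reused verbatim for validation,
    test and inference so no information leaks across splits.
    """

    minimum: np.ndarray
    maximum: np.ndarray
    fitted_on: str = "train"

    def __post_init__(self) -> None:
        self.minimum = np.asarray(self.minimum, dtype=float).reshape(N_CHANNELS)
        self.maximum = np.asarray(self.maximum, dtype=float).reshape(N_CHANNELS)
        if np.any(self.maximum < self.minimum):
            raise ValueError("per-channel max must be >= min")

    @property
    def span(self) -> np.ndarray:
        return self.maximum - self.minimum


@dataclass
class WindowedDataset:
    """An ordered collection of same-site windows stored as (n, L, 6)."""

    values: np.ndarray
    site: str
    scaled: bool = False
    scaling: ScalingParams | None = None
    start_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != N_CHANNELS:
            raise ValueError(f"values must be (n, L, {N_CHANNELS}), got {self.values.shape}")
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}")
        if self.start_indices is None:
            self.start_indices = np.zeros(len(self), dtype=int)
        else:
            self.start_indices = np.asarray(self.start_indices, dtype=int)

    def __len__(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, i: int) -> ImuWindow:
        return ImuWindow(
            self.values[i], self.site, self.scaled, int(self.start_indices[i])
        )

    def __iter__(self) -> Iterator[ImuWindow]:
        for i in range(len(self)):
            yield self[i]

    def subset(self, indices: np.ndarray) -> "WindowedDataset":
        return WindowedDataset(
            self.values[indices],
            self.site,
            self.scaled,
            self.scaling,
            self.start_indices[indices],
        )


def window_signal(
    series: ImuSeries, length: int = WINDOW_LENGTH, hop: int = WINDOW_LENGTH
) -> WindowedDataset:
    """Cut a series into fixed-length windows.

    Produces ``floor((N - length) / hop) + 1`` windows when ``N >= length``
    and none otherwise; trailing samples that do not fill a window are
    dropped.  The default hop equals the window length (no overlap).
    """
    if length < 1 or hop < 1:
        raise ValueError("length and hop must be >= 1")
    n = len(series)
    if n == 0:
        raise ValueError("series has no samples")
    if n < length:
        values = np.empty((0, length, N_CHANNELS))
        return WindowedDataset(values, series.site, start_indices=np.empty(0, dtype=int))
    starts = np.arange(0, n - length + 1, hop)
    values = np.stack([series.data[s : s + length] for s in starts])
    return WindowedDataset(values, series.site, start_indices=starts)


class WindowScaler(BaseEstimator, TransformerMixin):
    """Per-channel min-max scaler for window stacks of shape (n, L, 6).

    ``transform`` maps each channel by (x - min) / (max - min) and clips
    to [0, 1]; channels with zero range map to 0.  ``inverse_transform``
    applies x * (max - min) + min.
    """

    def fit(self, X: np.ndarray, y: None = None) -> "WindowScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != N_CHANNELS or X.shape[0] == 0:
            raise ValueError("expected a non-empty (n, L, 6) array")
        self.data_min_ = X.min(axis=(0, 1))
        self.data_max_ = X.max(axis=(0, 1))
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = self.data_max_ - self.data_min_
        safe = np.where(span > 0, span, 1.0)
        out = (X - self.data_min_) / safe
        out = np.where(span > 0, out, 0.0)
        return np.clip(out, 0.0, 1.0)

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X * (self.data_max_ - self.data_min_) + self.data_min_

    def to_params(self, fitted_on: str = "train") -> ScalingParams:
        return ScalingParams(self.data_min_, self.data_max_, fitted_on)

    @classmethod
    def from_params(cls, params: ScalingParams) -> "WindowScaler":
        scaler = cls()
        scaler.data_min_ = params.minimum.copy()
        scaler.data_max_ = params.maximum.copy()
        return scaler


def fit_unit_scaler(dataset: WindowedDataset, fitted_on: str = "train") -> ScalingParams:
    """Per-channel min/max over all samples of all windows in the dataset."""
    if len(dataset) == 0:
        raise ValueError("cannot fit a scaler on an empty dataset")
    if dataset.scaled:
        raise ValueError("scaler must be fitted on unscaled data")
    scaler = WindowScaler().fit(dataset.values)
    return scaler.to_params(fitted_on)


def apply_scaler(window: ImuWindow, params: ScalingParams) -> ImuWindow:
    """Map a window into [0, 1] per channel, clipping out-of-range values."""
    if window.scaled:
        raise ValueError("window is already scaled")
    out = WindowScaler.from_params(params).transform(window.values[None])[0]
    return ImuWindow(out, window.site, scaled=True, start_index=window.start_index)


def invert_scaler(window: ImuWindow, params: ScalingParams) -> ImuWindow:
    """Map a [0, 1]-scaled window back to physical units."""
    if not window.scaled:
        raise ValueError("window is not scaled")
    out = WindowScaler.from_params(params).inverse_transform(window.values[None])[0]
    return ImuWindow(out, window.site, scaled=False, start_index=window.start_index)


def scale_dataset(dataset: WindowedDataset, params: ScalingParams) -> WindowedDataset:
    if dataset.scaled:
        raise ValueError("dataset is already scaled")
    values = WindowScaler.from_params(params).transform(dataset.values)
    return WindowedDataset(values, dataset.site, True, params, dataset.start_indices)


def unscale_dataset(dataset: WindowedDataset, params: ScalingParams) -> WindowedDataset:
    if not dataset.scaled:
        raise ValueError("dataset is not scaled")
    values = WindowScaler.from_params(params).inverse_transform(dataset.values)
    return WindowedDataset(values, dataset.site, False, None, dataset.start_indices)


def resultant_magnitude(x: Sequence[float], y: Sequence[float], z: Sequence[float]) -> np.ndarray:
    """Element-wise Euclidean norm sqrt(x^2 + y^2 + z^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape):
        raise ValueError("x, y, z must have identical shapes")
    return np.sqrt(x**2 + y**2 + z**2)
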