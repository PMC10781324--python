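"""Paired wrist/tibia/shoe IMU simulator with ground-truth gait events.

The generator reproduces the qualitative site contrast seen in walking
recordings: lower-limb (shoe, tibia) signals carry distinct short peaks —
sharp gyroscope spikes at toe-off and heel strike and a high acceleration
transient at each heel strike — riding on a smooth swing-phase lobe, while
the wrist signal is a heavily smoothed, attenuated, phase-lagged echo of
the leg motion plus an arm-swing sinusoid at the stride frequency, making
it sine-like.

Construction per stride: heel strikes are laid out at jittered stride
periods; each toe-off precedes its heel strike by the swing duration
(1 - stance_fraction of the stride).  Shoe gyro-y is a positive half-sine
swing lobe between toe-off and the next heel strike plus two narrow
negative Gaussian spikes (~40 ms wide, so a 50 Hz grid resolves them with
2-3 samples) at the exact toe-off and heel-strike samples.  The wrist is
derived deterministically from the shoe (low-pass -> gain -> lag ->
+ sinusoid), which guarantees a recoverable functional relation for
translation-learnability tests.  All randomness flows through a single
seeded generator, so identical seeds give identical sessions.

Event times are snapped to the sample grid and reported exactly in the
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .gait_analysis import FilterSpec, GaitEvents, lowpass
from .signal_core import (
    CHANNELS,
    ImuSeries,
    WindowedDataset,
    window_signal,
)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated walk.

    Amplitudes follow typical adult walking magnitudes at the foot: swing
    rotation ~200 deg/s, event spikes ~300 deg/s, heel-strike acceleration
    transient ~3 g on top of the 1 g gravity baseline; stride period 1.1 s
    with 60% stance.  ``noise_sd`` is the additive noise sigma in deg/s on
    the gyroscope channels (acceleration channels get 1% of it in g).
    """

    sample_rate: float = 50.0
    n_strides: int = 30
    stride_period: float = 1.1
    period_jitter_sd: float = 0.02
    stance_fraction: float = 0.6
    swing_lobe_amplitude: float = 200.0
    spike_amplitude: float = 300.0
    accel_peak_amplitude: float = 3.0
    noise_sd: float = 5.0
    wrist_smoothing_cutoff: float = 3.0
    wrist_gain: float = 0.5
    wrist_phase_lag: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.stance_fraction < 1:
            raise ValueError("stance_fraction must be in (0, 1)")
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")
        for name in ("swing_lobe_amplitude", "spike_amplitude",
                     "accel_peak_amplitude", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")


@dataclass
class SimulatedSession:
    """Synchronous wrist/tibia/shoe recordings plus ground-truth events."""

    wrist: ImuSeries
    tibia: ImuSeries
    shoe: ImuSeries
    truth: GaitEvents

    def to_csv_dir(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for site in ("wrist", "tibia", "shoe"):
            path = directory / f"{site}.csv"
            getattr(self, site).to_csv(path)
            written.append(path)
        times, labels = self.truth.merged()
        events = pd.DataFrame({"event_type": labels, "time_s": times})
        events_path = directory / "events.csv"
        events.to_csv(events_path, index=False)
        written.append(events_path)
        return written


def _gaussian_bumps(n: int, centers: np.ndarray, sigma_samples: float) -> np.ndarray:
    """Unit-amplitude Gaussian bumps at integer sample centers."""
    t = np.arange(n)
    out = np.zeros(n)
    for c in centers:
        lo = max(0, int(c - 6 * sigma_samples))
        hi = min(n, int(c + 6 * sigma_samples) + 1)
        out[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - c) / sigma_samples) ** 2)
    return out


def generate_session(config: SimulationConfig) -> SimulatedSession:
    """Build one walk with known event times; see the module docstring for
    the construction."""
    rng = np.random.default_rng(config.seed)
    sr = config.sample_rate
    lead = 1.0  # quiet seconds before the first toe-off and after the last heel strike

    periods = config.stride_period + rng.normal(0.0, config.period_jitter_sd,
                                                config.n_strides)
    periods = np.clip(periods, 0.5 * config.stride_period, 1.5 * config.stride_period)
    hs_times = lead + np.cumsum(periods)
    to_times = hs_times - (1.0 - config.stance_fraction) * periods

    n = int(round((hs_times[-1] + lead) * sr)) + 1
    hs_idx = np.round(hs_times * sr).astype(int)
    to_idx = np.round(to_times * sr).astype(int)

    # swing lobe: positive half-sine between each toe-off and its heel strike
    lobe = np.zeros(n)
    for t0, h0 in zip(to_idx, hs_idx):
        seg = np.arange(t0, h0 + 1)
        lobe[seg] += np.sin(np.pi * (seg - t0) / max(h0 - t0, 1))
    lobe *= config.swing_lobe_amplitude

    sigma = 0.02 * sr  # ~40 ms wide spikes: 2-3 samples at 50 Hz
    to_spikes = _gaussian_bumps(n, to_idx, sigma)
    hs_spikes = _gaussian_bumps(n, hs_idx, sigma)
    spikes = -(to_spikes + hs_spikes) * config.spike_amplitude

    gy = lobe + spikes
    gx = 0.30 * lobe + 0.20 * spikes
    gz = 0.20 * lobe - 0.25 * spikes

    accel_hs = _gaussian_bumps(n, hs_idx, sigma) * config.accel_peak_amplitude
    swing_sway = lobe / max(config.swing_lobe_amplitude, 1e-12)
    az = 1.0 + accel_hs + 0.25 * swing_sway
    ax = 0.40 * accel_hs + 0.30 * swing_sway
    ay = -0.25 * accel_hs + 0.15 * swing_sway

    shoe_clean = np.column_stack([ax, ay, az, gx, gy, gz])

    # tibia: attenuated (factor < 1), slightly smoothed copy of the shoe
    means = shoe_clean.mean(axis=0)
    tibia_clean = means + 0.6 * gaussian_filter1d(shoe_clean - means, sigma=1.0, axis=0)

    # wrist: low-pass -> gain -> lag -> + arm-swing sinusoid at stride rate
    lag = int(round(config.wrist_phase_lag * sr))
    t_axis = np.arange(n) / sr
    f_stride = 1.0 / config.stride_period
    spec = FilterSpec(cutoff=config.wrist_smoothing_cutoff, order=4, zero_phase=True)
    sin_amp = {"ax": 0.20, "ay": 0.15, "az": 0.25, "gx": 25.0, "gy": 30.0, "gz": 20.0}
    phases = {"ax": 0.0, "ay": 1.1, "az": 2.3, "gx": 0.7, "gy": 1.9, "gz": 3.1}
    wrist_clean = np.empty_like(shoe_clean)
    for j, name in enumerate(CHANNELS):
        smooth = lowpass(shoe_clean[:, j], sr, spec)
        lagged = np.roll(smooth, lag)
        lagged[:lag] = smooth[0]
        wrist_clean[:, j] = (
            means[j]
            + config.wrist_gain * (lagged - means[j])
            + sin_amp[name] * np.sin(2 * np.pi * f_stride * t_axis + phases[name])
        )

    gyro_noise = config.noise_sd
    accel_noise = 0.01 * config.noise_sd
    noise_scale = np.array([accel_noise] * 3 + [gyro_noise] * 3)

    def noisy(clean: np.ndarray) -> np.ndarray:
        return clean + rng.normal(0.0, 1.0, clean.shape) * noise_scale

    truth = GaitEvents(to_idx / sr, hs_idx / sr)
    return SimulatedSession(
        wrist=ImuSeries(noisy(wrist_clean), sr, "wrist"),
        tibia=ImuSeries(noisy(tibia_clean), sr, "tibia"),
        shoe=ImuSeries(noisy(shoe_clean), sr, "shoe"),
        truth=truth,
    )


def strides_for_windows(
    n_windows: int, length: int, hop: int, config: SimulationConfig
) -> int:
    """Smallest n_strides giving a session long enough for ``n_windows``."""
    needed = (n_windows - 1) * hop + length
    seconds = needed / config.sample_rate
    return int(np.ceil((seconds + 1.0) / config.stride_period)) + 2


def generate_paired_dataset(
    config: SimulationConfig,
    n_windows: int,
    target_site: str = "shoe",
    length: int = 256,
    hop: int = 256,
) -> tuple[WindowedDataset, WindowedDataset, GaitEvents]:
    """Aligned wrist/target window pairs cut from one simulated session;
    pair i of the wrist stack matches pair i of the target stack (same
    start offsets)."""
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    session = generate_session(config)
    wrist = window_signal(session.wrist, length, hop)
    target = window_signal(getattr(session, target_site), length, hop)
    if len(wrist) < n_windows:
        raise ValueError(
            f"session yields only {len(wrist)} windows; "
            f"increase n_strides (need {n_windows})"
        )
    keep = np.arange(n_windows)
    return wrist.subset(keep), target.subset(keep), session.truth


def session_for_windows(
    config: SimulationConfig, n_windows: int, length: int = 256, hop: int = 256
) -> SimulationConfig:
    """Copy of ``config`` with n_strides raised to cover ``n_windows``."""
    return replace(
        config, n_strides=max(config.n_strides,
                              strides_for_windows(n_windows, length, hop, config))
    )
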