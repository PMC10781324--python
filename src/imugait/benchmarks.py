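"""Desk-scale evaluation protocol on the synthetic gait simulator.

These routines define the package's reference experiments: a noiseless,
deterministic wrist-to-shoe translation task small enough to train the
NumPy models on one CPU core in minutes, and an event-detection study
across seeds and noise levels.  The translation task uses 96 windows
(about 8.5 minutes of walking) with a 15/40/10-epoch
pretrain/translate/fine-tune schedule; the noiseless mapping is exactly
invertible, so a sufficiently expressive model can in principle drive the
error to zero and residual MAE measures architecture capacity rather than
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import TRANSLATORS
from .gait_analysis import compute_gait_parameters, detect_events_from_series
from .signal_core import fit_unit_scaler, scale_dataset
from .synthetic_gait import (
    SimulationConfig,
    generate_paired_dataset,
    generate_session,
    session_for_windows,
)
from .training import split_indices

BENCHMARK_ARCHITECTURES = ("dense_ae", "cnn_ae", "unet")


@dataclass
class TranslationRun:
    architecture: str
    seed: int
    test_mae_scaled: float
    baseline_mae_scaled: float
    test_mse_scaled: float
    n_windows: int


@dataclass
class TranslationBenchmark:
    runs: list[TranslationRun] = field(default_factory=list)

    def mae(self, architecture: str) -> list[float]:
        return [r.test_mae_scaled for r in self.runs if r.architecture == architecture]

    def ranking_fraction(self, better=("cnn_ae", "unet"), worse="dense_ae") -> float:
        """Fraction of seeds where every ``better`` architecture has lower
        test MAE than ``worse``."""
        seeds = sorted({r.seed for r in self.runs})
        by = {(r.architecture, r.seed): r.test_mae_scaled for r in self.runs}
        wins = sum(
            all(by[(b, s)] < by[(worse, s)] for b in better) for s in seeds
        )
        return wins / len(seeds)


def run_translation_benchmark(
    seeds=(0, 1, 2),
    architectures=BENCHMARK_ARCHITECTURES,
    n_windows: int = 96,
    pretrain_epochs: int = 15,
    epochs: int = 40,
    fine_tune_epochs: int = 10,
    noise_sd: float = 0.0,
) -> TranslationBenchmark:
    """Train each architecture on the deterministic wrist-to-shoe task for
    each seed and collect scaled-unit test errors.

    The constant-mean predictor (per-sample mean of the training targets)
    serves as the baseline every model must beat.
    """
    bench = TranslationBenchmark()
    for seed in seeds:
        config = session_for_windows(
            SimulationConfig(noise_sd=noise_sd, seed=seed), n_windows
        )
        wrist, shoe, _ = generate_paired_dataset(config, n_windows)
        train_idx, _, test_idx = split_indices(n_windows, seed=seed)
        wrist_scaling = fit_unit_scaler(wrist.subset(train_idx))
        shoe_scaling = fit_unit_scaler(shoe.subset(train_idx))
        X = scale_dataset(wrist, wrist_scaling).values
        y = scale_dataset(shoe, shoe_scaling).values
        baseline_pred = y[train_idx].mean(axis=0)[None]
        baseline = float(np.abs(baseline_pred - y[test_idx]).mean())
        for arch in architectures:
            translator = TRANSLATORS[arch](
                epochs=epochs,
                pretrain_epochs=pretrain_epochs,
                fine_tune_epochs=fine_tune_epochs,
                seed=seed,
            )
            translator.fit(X, y)
            pred = translator.predict(X[test_idx])
            mae = float(np.abs(pred - y[test_idx]).mean())
            mse = float(((pred - y[test_idx]) ** 2).mean())
            bench.runs.append(
                TranslationRun(arch, seed, mae, baseline, mse, n_windows)
            )
    return bench


@dataclass
class EventBenchmark:
    noiseless_all_recovered: bool
    noiseless_max_error_samples: float
    noisy_stride_errors_s: list[float]
    n_seeds: int

    @property
    def noisy_max_stride_error_s(self) -> float:
        return max(self.noisy_stride_errors_s)


def run_event_benchmark(
    n_seeds: int = 20,
    n_strides: int = 25,
    noise_frac: float = 0.10,
    base_seed: int = 0,
) -> EventBenchmark:
    """Event-detector study: exact recovery on a noiseless session, and
    mean-stride accuracy across seeds with gyroscope noise at
    ``noise_frac`` of the swing-lobe amplitude."""
    clean_cfg = SimulationConfig(
        n_strides=n_strides, period_jitter_sd=0.0, noise_sd=0.0, seed=base_seed
    )
    session = generate_session(clean_cfg)
    events = detect_events_from_series(session.shoe)
    truth = session.truth
    recovered = len(events.toe_offs) == len(truth.toe_offs) and len(
        events.heel_strikes
    ) == len(truth.heel_strikes)
    if recovered:
        err = max(
            np.max(np.abs(events.toe_offs - truth.toe_offs)),
            np.max(np.abs(events.heel_strikes - truth.heel_strikes)),
        )
        max_err_samples = float(err * clean_cfg.sample_rate)
    else:
        max_err_samples = float("inf")

    stride_errors = []
    for seed in range(base_seed, base_seed + n_seeds):
        cfg = SimulationConfig(
            n_strides=n_strides,
            noise_sd=noise_frac * SimulationConfig().swing_lobe_amplitude,
            seed=seed,
        )
        sess = generate_session(cfg)
        params = compute_gait_parameters(detect_events_from_series(sess.shoe))
        stride_errors.append(abs(params.mean_stride_s - cfg.stride_period))
    return EventBenchmark(recovered, max_err_samples, stride_errors, n_seeds)
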