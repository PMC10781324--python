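import numpy as np
import pytest

from imugait import SimulationConfig, generate_session


@pytest.fixture(scope="session")
def noiseless_session():
    """A jitter- and noise-free walk whose events are exact by construction."""
    config = SimulationConfig(
        n_strides=12, period_jitter_sd=0.0, noise_sd=0.0, seed=3
    )
    return config, generate_session(config)


@pytest.fixture(scope="session")
def tiny_paired():
    """A small scaled wrist/shoe pair for fast training-contract tests."""
    from imugait import (
        PairedDataset,
        fit_unit_scaler,
        generate_paired_dataset,
        scale_dataset,
        split_indices,
    )
    from imugait.synthetic_gait import session_for_windows

    n = 12
    config = session_for_windows(SimulationConfig(noise_sd=0.0, seed=11), n)
    wrist, shoe, _ = generate_paired_dataset(config, n)
    train_idx, _, _ = split_indices(n, seed=11)
    wrist_scaling = fit_unit_scaler(wrist.subset(train_idx))
    shoe_scaling = fit_unit_scaler(shoe.subset(train_idx))
    return PairedDataset(
        scale_dataset(wrist, wrist_scaling).values,
        scale_dataset(shoe, shoe_scaling).values,
        "shoe",
        wrist_scaling,
        shoe_scaling,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
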