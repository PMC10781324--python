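"""Split rules, freezing contracts, determinism of the training protocol."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imugait import (
    PairedDataset,
    TrainingConfig,
    build_model,
    fine_tune,
    freeze_encoder,
    pretrain_autoencoder,
    split_indices,
    train_translation,
)
from imugait.nn import get_weights


class TestSplit:
    def test_stated_dataset_size(self):
        train, val, test = split_indices(1000)
        assert (len(train), len(val), len(test)) == (700, 150, 150)

    def test_floor_floor_remainder_rule(self):
        train, val, test = split_indices(10)
        assert (len(train), len(val), len(test)) == (7, 1, 2)

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            split_indices(2)

    def test_seed_controls_assignment(self):
        a = split_indices(50, seed=1)
        b = split_indices(50, seed=1)
        c = split_indices(50, seed=2)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)
        assert any(not np.array_equal(x, y) for x, y in zip(a, c))

    @settings(derandomize=True, max_examples=40)
    @given(n=st.integers(3, 500), seed=st.integers(0, 10))
    def test_partition_property(self, n, seed):
        parts = split_indices(n, seed=seed)
        merged = np.concatenate(parts)
        assert len(merged) == n
        assert set(merged) == set(range(n))
        assert len(parts[0]) == int(np.floor(0.70 * n))
        assert len(parts[1]) == int(np.floor(0.15 * n))


class TestConfig:
    def test_fraction_sum_enforced(self):
        with pytest.raises(ValueError):
            TrainingConfig(split_fractions=(0.5, 0.2, 0.2))

    def test_positive_rates(self):
        with pytest.raises(ValueError):
            TrainingConfig(learning_rate=0.0)


def quick_config(epochs=3, seed=0):
    return TrainingConfig(epochs=epochs, batch_size=8, seed=seed)


class TestPretrain:
    def test_cnn_lstm_rejected(self, tiny_paired):
        with pytest.raises(ValueError, match="trained directly"):
            pretrain_autoencoder(
                build_model("cnn_lstm"), tiny_paired.wrist, quick_config()
            )

    def test_loss_decreases_and_marks_pretrained(self, tiny_paired):
        model = build_model("dense_ae", seed=0)
        report = pretrain_autoencoder(model, tiny_paired.wrist, quick_config(8))
        assert model.pretrained
        assert report.train_losses[report.best_epoch] <= report.train_losses[0]
        assert report.test_loss >= 0

    def test_unscaled_data_rejected(self, tiny_paired):
        with pytest.raises(ValueError, match="unit-scaled"):
            pretrain_autoencoder(
                build_model("dense_ae"), tiny_paired.wrist * 10 - 3, quick_config()
            )

    def test_identical_seeds_identical_loss_curves(self, tiny_paired):
        reports = []
        for _ in range(2):
            model = build_model("dense_ae", seed=5)
            reports.append(
                pretrain_autoencoder(model, tiny_paired.wrist, quick_config(4, seed=5))
            )
        assert reports[0].train_losses == reports[1].train_losses
        assert reports[0].val_losses == reports[1].val_losses


class TestFreezeAndTranslate:
    @pytest.fixture
    def pretrained(self, tiny_paired):
        model = build_model("dense_ae", seed=1)
        pretrain_autoencoder(model, tiny_paired.wrist, quick_config(2, seed=1))
        return model

    def test_freeze_requires_pretraining(self):
        with pytest.raises(ValueError, match="pretrained"):
            freeze_encoder(build_model("dense_ae"))

    def test_freeze_rejected_for_cnn_lstm(self):
        with pytest.raises(ValueError, match="encoder"):
            freeze_encoder(build_model("cnn_lstm"))

    def test_translation_requires_frozen_encoder(self, pretrained, tiny_paired):
        with pytest.raises(ValueError, match="freeze"):
            train_translation(pretrained, tiny_paired, quick_config())

    def test_frozen_weights_bit_identical_after_training(self, pretrained, tiny_paired):
        freeze_encoder(pretrained)
        before = get_weights(pretrained.network)
        n_enc = len(pretrained.network.encoder_layers)
        train_translation(pretrained, tiny_paired, quick_config(3, seed=1))
        after = get_weights(pretrained.network)
        for i in range(n_enc):
            for key in before[i]:
                np.testing.assert_array_equal(before[i][key], after[i][key])
        # decoder weights must have moved
        moved = any(
            not np.array_equal(before[i][key], after[i][key])
            for i in range(n_enc, len(before))
            for key in before[i]
        )
        assert moved

    def test_trainable_count_drops_by_encoder_size(self, pretrained):
        total = pretrained.n_trainable_params
        encoder = sum(l.n_params for l in pretrained.network.encoder_layers)
        freeze_encoder(pretrained)
        assert pretrained.n_trainable_params == total - encoder

    def test_cnn_lstm_trains_without_pretraining(self, tiny_paired):
        model = build_model("cnn_lstm", seed=0)
        report = train_translation(model, tiny_paired, quick_config(2))
        assert model.translation_trained
        assert report.val_losses[report.best_epoch] <= report.val_losses[0]


class TestFineTune:
    def test_requires_frozen_training_first(self, tiny_paired):
        model = build_model("dense_ae", seed=0)
        with pytest.raises(ValueError, match="frozen"):
            fine_tune(model, tiny_paired, quick_config())

    def test_cnn_lstm_rejected(self, tiny_paired):
        with pytest.raises(ValueError, match="frozen"):
            fine_tune(build_model("cnn_lstm"), tiny_paired, quick_config())

    def test_unfreezes_and_uses_low_rate(self, tiny_paired):
        model = build_model("dense_ae", seed=2)
        pretrain_autoencoder(model, tiny_paired.wrist, quick_config(2, seed=2))
        freeze_encoder(model)
        train_translation(model, tiny_paired, quick_config(3, seed=2))
        report = fine_tune(model, tiny_paired, quick_config(3, seed=2))
        assert not model.encoder_frozen
        assert report.learning_rate == pytest.approx(1e-4)

    def test_fine_tuning_does_not_hurt_test_loss(self, tiny_paired):
        model = build_model("dense_ae", seed=3)
        pretrain_autoencoder(model, tiny_paired.wrist, quick_config(6, seed=3))
        freeze_encoder(model)
        trans = train_translation(model, tiny_paired, quick_config(8, seed=3))
        tuned = fine_tune(model, tiny_paired, quick_config(8, seed=3))
        assert tuned.test_loss <= trans.test_loss


def test_full_pipeline_reproducible(tiny_paired):
    """Identical seeds reproduce the whole pretrain/freeze/translate chain."""
    outputs = []
    for _ in range(2):
        model = build_model("cnn_ae", seed=9)
        pretrain_autoencoder(model, tiny_paired.wrist, quick_config(2, seed=9))
        freeze_encoder(model)
        train_translation(model, tiny_paired, quick_config(2, seed=9))
        outputs.append(model.forward(tiny_paired.wrist[:2]))
    np.testing.assert_array_equal(outputs[0], outputs[1])


def test_cnn_ae_learns_wrist_reconstruction():
    """Unsupervised pretraining on clean wrist windows drives the test
    reconstruction error below 0.05 scaled units (about a minute of CPU)."""
    from imugait import (
        SimulationConfig,
        fit_unit_scaler,
        generate_paired_dataset,
        scale_dataset,
    )
    from imugait.synthetic_gait import session_for_windows

    n = 96
    config = session_for_windows(SimulationConfig(noise_sd=0.0, seed=0), n)
    wrist, _, _ = generate_paired_dataset(config, n)
    train_idx, _, test_idx = split_indices(n, seed=0)
    scaled = scale_dataset(wrist, fit_unit_scaler(wrist.subset(train_idx)))
    model = build_model("cnn_ae", seed=0)
    pretrain_autoencoder(model, scaled, TrainingConfig(epochs=50, seed=0))
    recon = model.forward(scaled.values[test_idx])
    assert np.abs(recon - scaled.values[test_idx]).mean() < 0.05


def test_paired_dataset_validation():
    with pytest.raises(ValueError, match="identical shapes"):
        PairedDataset(np.zeros((2, 8, 6)), np.zeros((3, 8, 6)), "shoe")
    with pytest.raises(ValueError, match="target_site"):
        PairedDataset(np.zeros((2, 8, 6)), np.zeros((2, 8, 6)), "wrist")
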