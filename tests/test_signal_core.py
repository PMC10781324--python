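"""Windowing, unit scaling and resultant-magnitude contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imugait import (
    CHANNELS,
    ImuSeries,
    ImuWindow,
    ScalingParams,
    WindowedDataset,
    apply_scaler,
    fit_unit_scaler,
    invert_scaler,
    resultant_magnitude,
    scale_dataset,
    window_duration,
    window_signal,
)


def make_series(n, site="shoe", sample_rate=50.0, fill=None, rng=None):
    if fill is not None:
        data = np.full((n, 6), fill, dtype=float)
    else:
        rng = rng or np.random.default_rng(0)
        data = rng.normal(size=(n, 6))
    return ImuSeries(data, sample_rate, site)


def brute_force_starts(n, length, hop):
    return [s for s in range(0, n) if s % hop == 0 and s + length <= n]


class TestWindowing:
    @pytest.mark.parametrize(
        "n,length,hop,expected",
        [
            (512, 256, 256, 2),   # exact tiling
            (255, 256, 256, 0),   # one sample short of a window
            (600, 256, 128, 3),   # starts at 0, 128, 256; tail dropped
            (256, 256, 256, 1),
            (1000, 256, 256, 3),
        ],
    )
    def test_window_counts(self, n, length, hop, expected):
        dataset = window_signal(make_series(n), length, hop)
        assert len(dataset) == expected
        assert len(dataset) == len(brute_force_starts(n, length, hop))

    def test_start_offsets_and_content(self):
        series = make_series(600)
        dataset = window_signal(series, 256, 128)
        assert list(dataset.start_indices) == [0, 128, 256]
        np.testing.assert_array_equal(dataset.values[1], series.data[128:384])

    def test_site_tag_copied(self):
        dataset = window_signal(make_series(512, site="tibia"), 256, 256)
        assert dataset.site == "tibia"
        assert dataset[0].site == "tibia"

    @pytest.mark.parametrize("length,hop", [(0, 1), (1, 0), (-5, 3)])
    def test_invalid_arguments(self, length, hop):
        with pytest.raises(ValueError):
            window_signal(make_series(100), length, hop)

    @settings(derandomize=True, max_examples=60)
    @given(
        n=st.integers(1, 1000),
        length=st.integers(1, 300),
        hop=st.integers(1, 300),
    )
    def test_count_formula_matches_enumeration(self, n, length, hop):
        dataset = window_signal(make_series(n, fill=0.0), length, hop)
        assert len(dataset) == len(brute_force_starts(n, length, hop))

    def test_window_duration(self):
        assert window_duration(256, 50.0) == pytest.approx(5.12)


class TestScaling:
    def test_fit_min_max(self):
        values = np.zeros((1, 3, 6))
        values[0, :, 0] = [0.0, 5.0, 10.0]
        params = fit_unit_scaler(WindowedDataset(values, "wrist"))
        assert params.minimum[0] == 0.0 and params.maximum[0] == 10.0

    def test_fit_degenerate_constant_channel(self):
        values = np.full((2, 4, 6), 5.0)
        params = fit_unit_scaler(WindowedDataset(values, "wrist"))
        np.testing.assert_array_equal(params.minimum, params.maximum)
        window = apply_scaler(ImuWindow(values[0], "wrist"), params)
        np.testing.assert_array_equal(window.values, 0.0)

    def test_fit_matches_brute_force_scan(self, rng):
        values = rng.normal(size=(3, 16, 6))
        params = fit_unit_scaler(WindowedDataset(values, "shoe"))
        flat = values.reshape(-1, 6)
        for c in range(6):
            assert params.minimum[c] == min(flat[:, c])
            assert params.maximum[c] == max(flat[:, c])

    def test_fit_empty_errors(self):
        with pytest.raises(ValueError):
            fit_unit_scaler(WindowedDataset(np.empty((0, 8, 6)), "wrist"))

    def test_apply_known_values(self):
        params = ScalingParams([0.0] * 6, [10.0] * 6)
        values = np.zeros((3, 6))
        values[:, 0] = [0.0, 5.0, 10.0]
        window = apply_scaler(ImuWindow(values, "wrist"), params)
        np.testing.assert_allclose(window.values[:, 0], [0.0, 0.5, 1.0])
        assert window.scaled

    def test_apply_clips_out_of_range(self):
        params = ScalingParams([0.0] * 6, [10.0] * 6)
        values = np.full((2, 6), -3.0)
        window = apply_scaler(ImuWindow(values, "wrist"), params)
        np.testing.assert_array_equal(window.values, 0.0)

    def test_apply_rejects_scaled_input(self):
        params = ScalingParams([0.0] * 6, [1.0] * 6)
        window = ImuWindow(np.full((2, 6), 0.5), "wrist", scaled=True)
        with pytest.raises(ValueError):
            apply_scaler(window, params)

    def test_invert_rejects_unscaled_input(self):
        params = ScalingParams([0.0] * 6, [1.0] * 6)
        with pytest.raises(ValueError):
            invert_scaler(ImuWindow(np.zeros((2, 6)), "wrist"), params)

    def test_invert_known_values(self):
        params = ScalingParams([0.0] * 6, [10.0] * 6)
        values = np.zeros((3, 6))
        values[:, 2] = [0.0, 0.5, 1.0]
        out = invert_scaler(ImuWindow(values, "shoe", scaled=True), params)
        np.testing.assert_allclose(out.values[:, 2], [0.0, 5.0, 10.0])
        assert not out.scaled

    def test_all_zero_scaled_window_maps_to_minima(self):
        params = ScalingParams(np.arange(6.0), np.arange(6.0) + 2.0)
        out = invert_scaler(ImuWindow(np.zeros((4, 6)), "shoe", scaled=True), params)
        np.testing.assert_allclose(out.values, np.tile(np.arange(6.0), (4, 1)))

    def test_round_trip_identity(self, rng):
        values = rng.uniform(-2.0, 3.0, size=(5, 32, 6))
        dataset = WindowedDataset(values, "wrist")
        params = fit_unit_scaler(dataset)
        for window in dataset:
            back = invert_scaler(apply_scaler(window, params), params)
            np.testing.assert_allclose(back.values, window.values, rtol=1e-9, atol=1e-12)

    def test_scaled_dataset_within_unit_range(self, rng):
        values = rng.normal(size=(4, 16, 6)) * 100
        dataset = WindowedDataset(values, "shoe")
        scaled = scale_dataset(dataset, fit_unit_scaler(dataset))
        assert scaled.values.min() >= 0.0 and scaled.values.max() <= 1.0


class TestResultant:
    def test_pythagorean(self):
        np.testing.assert_allclose(resultant_magnitude([3.0], [4.0], [0.0]), [5.0])

    def test_zero(self):
        np.testing.assert_array_equal(resultant_magnitude([0.0], [0.0], [0.0]), [0.0])

    def test_matches_formula(self, rng):
        x, y, z = rng.normal(size=(3, 100))
        np.testing.assert_allclose(
            resultant_magnitude(x, y, z), np.sqrt(x**2 + y**2 + z**2)
        )

    def test_axis_permutation_and_sign_invariance(self, rng):
        x, y, z = rng.normal(size=(3, 50))
        base = resultant_magnitude(x, y, z)
        np.testing.assert_allclose(resultant_magnitude(z, x, y), base)
        np.testing.assert_allclose(resultant_magnitude(-x, y, -z), base)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            resultant_magnitude([1.0, 2.0], [1.0], [1.0])


class TestCsvDialect:
    def test_round_trip(self, tmp_path, rng):
        series = make_series(30, site="wrist", rng=rng)
        path = tmp_path / "wrist.csv"
        series.to_csv(path)
        assert path.read_text().splitlines()[0] == "t," + ",".join(CHANNELS)
        back = ImuSeries.read_csv(path, "wrist")
        np.testing.assert_allclose(back.data, series.data)
        assert back.sample_rate == pytest.approx(series.sample_rate)

    def test_missing_t_reconstructed_from_rate(self, tmp_path):
        path = tmp_path / "raw.csv"
        path.write_text(
            ",".join(CHANNELS) + "\n" + "\n".join(["0,0,1,0,0,0"] * 5) + "\n"
        )
        series = ImuSeries.read_csv(path, "shoe", sample_rate=50.0)
        assert len(series) == 5 and series.sample_rate == 50.0
        with pytest.raises(ValueError):
            ImuSeries.read_csv(path, "shoe")
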