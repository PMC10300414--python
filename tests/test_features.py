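"""Spectrogram, relative PSD normalization and the eight band features."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.signal.windows import hann

from somnoscreen import features as ft
from somnoscreen.synthetic import make_spindle, simulate_epoch

FS = 200.0
N = 6000


def dft_power_oracle(segment: np.ndarray) -> np.ndarray:
    """Windowed DFT power from the definition (no FFT)."""
    m = len(segment)
    tapered = segment * hann(m, sym=False)
    n_idx = np.arange(m)
    k_idx = np.arange(m // 2 + 1)
    basis = np.exp(-2j * np.pi * np.outer(k_idx, n_idx) / m)
    return np.abs(basis @ tapered) ** 2


class TestSpectrogram:
    def test_shape_59_windows_101_bins(self, rng):
        spec = ft.compute_spectrogram(rng.standard_normal(N), FS)
        assert spec.power.shape == (59, 101)
        assert spec.freqs[0] == 0.0 and spec.freqs[-1] == 100.0
        assert np.all(spec.power >= 0.0)

    def test_zero_epoch_zero_power(self):
        spec = ft.compute_spectrogram(np.zeros(N), FS)
        assert np.all(spec.power == 0.0)

    def test_wrong_length_rejected(self, rng):
        with pytest.raises(ValueError, match="6000"):
            ft.compute_spectrogram(rng.standard_normal(5000), FS)

    def test_matches_dft_oracle_on_random_epochs(self, rng):
        """Window powers equal a from-definition DFT on >= 20 epochs."""
        for _ in range(20):
            x = rng.standard_normal(N)
            spec = ft.compute_spectrogram(x, FS)
            for w in rng.choice(59, size=3, replace=False):
                seg = x[w * 100 : w * 100 + 200]
                expected = dft_power_oracle(seg)
                np.testing.assert_allclose(
                    spec.power[w], expected, rtol=1e-9, atol=1e-9 * expected.max()
                )

    def test_sinusoid_peak_at_its_bin(self, rng):
        t = np.arange(N) / FS
        spec = ft.compute_spectrogram(np.sin(2 * np.pi * 10 * t), FS)
        assert np.all(spec.power.argmax(axis=1) == 10)


class TestNormalization:
    def test_uniform_window_gives_1_over_50(self):
        power = np.ones((59, 101))
        spec = ft.Spectrogram(power=power, freqs=np.arange(101.0))
        rel = ft.normalize_psd(spec)
        inband = (spec.freqs > 0.5) & (spec.freqs <= 50.0)
        assert inband.sum() == 50
        assert np.allclose(rel.power[:, inband], 1 / 50)
        assert np.all(rel.power[:, ~inband] == 0.0)

    def test_in_range_sums_to_one(self, rng):
        spec = ft.compute_spectrogram(rng.standard_normal(N), FS)
        rel = ft.normalize_psd(spec)
        assert np.allclose(rel.power.sum(axis=1), 1.0, atol=1e-12)

    def test_degenerate_window_flagged_and_zero(self):
        power = np.ones((3, 101))
        power[1] = 0.0
        spec = ft.Spectrogram(power=power, freqs=np.arange(101.0))
        rel = ft.normalize_psd(spec)
        assert rel.degenerate_windows.tolist() == [False, True, False]
        assert np.all(rel.power[1] == 0.0)

    def test_sinusoid_relative_power_matches_oracle(self, rng):
        t = np.arange(N) / FS
        x = np.sin(2 * np.pi * 10 * t) + 0.01 * rng.standard_normal(N)
        rel = ft.normalize_psd(ft.compute_spectrogram(x, FS))
        seg = x[:200]
        oracle = dft_power_oracle(seg)
        inband = (np.arange(101) > 0.5) & (np.arange(101) <= 50)
        expected = oracle[10] / oracle[inband].sum()
        assert rel.power[0, 10] == pytest.approx(expected, rel=1e-9)


class TestBandFraction:
    def test_low_delta_uses_bins_1_and_2(self):
        freqs = np.arange(101.0)
        window = np.zeros(101)
        window[[1, 2]] = 0.25
        window[3] = 0.5
        assert ft.band_fraction(window, freqs, (0.5, 2.0)) == pytest.approx(0.5)

    def test_uniform_beta_is_point_three(self):
        freqs = np.arange(101.0)
        window = np.zeros(101)
        window[1:51] = 1 / 50
        assert ft.band_fraction(window, freqs, (15.0, 30.0)) == pytest.approx(15 / 50)

    def test_delta_theta_bins_disjoint(self):
        freqs = np.arange(101.0)
        scheme = ft.DEFAULT_SCHEME
        delta = set(np.flatnonzero(scheme.band_mask(freqs, "delta")))
        theta = set(np.flatnonzero(scheme.band_mask(freqs, "theta")))
        assert delta == {2, 3, 4}
        assert theta == {5, 6, 7, 8}

    def test_band_outside_analysis_range_rejected(self):
        with pytest.raises(ValueError):
            ft.band_fraction(np.zeros(101), np.arange(101.0), (40.0, 60.0))


class TestChannelFeatures:
    def test_constant_delta_makes_max_equal_rest(self):
        # pure 3 Hz sinusoid: every window has the same delta fraction
        t = np.arange(N) / FS
        f = ft.extract_channel_features(np.sin(2 * np.pi * 3 * t), FS)
        names = ft.FEATURE_NAMES_PER_CHANNEL
        k1, k2 = f[names.index("K_comp_1")], f[names.index("K_comp_2")]
        assert k1 == pytest.approx(k2, rel=1e-6)

    def test_k_comp_2_averages_58_values_excluding_argmax(self, rng):
        x = rng.standard_normal(N)
        frac = ft._epoch_band_fractions(x[None, :], FS, ft.DEFAULT_SCHEME)[0]
        delta = frac[:, 1]
        assert len(delta) == 59
        rest = np.delete(delta, delta.argmax())
        assert len(rest) == 58
        f = ft.extract_channel_features(x, FS)
        assert f[2] == pytest.approx(rest.mean(), rel=1e-12)
        assert f[1] == pytest.approx(delta.max(), rel=1e-12)

    def test_spindle_burst_raises_spindle_1(self, rng):
        base = simulate_epoch("N1", fs=FS, rng=rng, n_channels=1)[0]
        burst = base.copy()
        event = make_spindle(1.0, FS, 3.0 * base.std())
        burst[2000 : 2000 + len(event)] += event
        f_base = ft.extract_channel_features(base, FS)
        f_burst = ft.extract_channel_features(burst, FS)
        idx = ft.FEATURE_NAMES_PER_CHANNEL.index("spindle_1")
        assert f_burst[idx] > f_base[idx]

    def test_all_zero_epoch_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            ft.extract_channel_features(np.zeros(N), FS)


class TestEpochFeatures:
    def test_48_named_features(self, rng):
        block = rng.standard_normal((6, N))
        ef = ft.extract_epoch_features(block, FS)
        assert ef.values.shape == (48,)
        assert len(ef.names) == 48
        assert ef.names[0] == "F3.low_delta" and ef.names[-1] == "O2.beta"

    def test_duplicated_channel_gives_identical_blocks(self, rng):
        x = rng.standard_normal(N)
        ef = ft.extract_epoch_features(np.tile(x, (6, 1)), FS)
        blocks = ef.values.reshape(6, 8)
        assert np.allclose(blocks, blocks[0])

    def test_channel_permutation_permutes_blocks(self, rng):
        block = rng.standard_normal((6, N))
        perm = [3, 0, 5, 1, 4, 2]
        ef = ft.extract_epoch_features(block, FS)
        ef_perm = ft.extract_epoch_features(block[perm], FS)
        assert np.allclose(
            ef_perm.values.reshape(6, 8), ef.values.reshape(6, 8)[perm]
        )

    def test_wrong_channel_count_rejected(self, rng):
        with pytest.raises(ValueError, match="6"):
            ft.extract_epoch_features(rng.standard_normal((4, N)), FS)


class TestFeaturizeEpochs:
    def test_matrix_shape_and_labels(self, rng):
        epochs = [(rng.standard_normal((6, N)), s)
                  for s in ("W", "N1", "N2", "N3", "R") * 2]
        df = ft.featurize_epochs(epochs, FS, subject_id="s0")
        assert df.shape == (10, 3 + 48)
        assert list(df["stage"]) == [s for _, s in epochs]
        row = ft.extract_epoch_features(epochs[3][0], FS).values
        assert np.allclose(df.loc[3, list(ft.epoch_feature_names())], row)

    def test_empty_list_errors(self):
        with pytest.raises(ValueError, match="no epochs"):
            ft.featurize_epochs([], FS)


class TestFeatureInvariants:
    @given(st.integers(0, 2**31 - 1))
    def test_range_and_max_dominates_rest(self, seed):
        rng = np.random.default_rng(seed)
        stage = ["W", "N1", "N2", "N3", "R"][seed % 5]
        block = simulate_epoch(stage, fs=FS, rng=rng)
        ef = ft.extract_epoch_features(block, FS)
        assert np.all(ef.values >= 0.0) and np.all(ef.values <= 1.0)
        blocks = ef.values.reshape(6, 8)
        assert np.all(blocks[:, 1] >= blocks[:, 2] - 1e-12)  # K1 >= K2
        assert np.all(blocks[:, 5] >= blocks[:, 6] - 1e-12)  # spindle1 >= spindle2

    @given(st.floats(1e-3, 1e3), st.integers(0, 2**31 - 1))
    def test_amplitude_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        block = rng.standard_normal((6, N))
        a = ft.extract_epoch_features(block, FS).values
        b = ft.extract_epoch_features(scale * block, FS).values
        np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-12)

    def test_disjoint_band_means_bounded_by_one(self, rng):
        block = simulate_epoch("N2", fs=FS, rng=rng)
        frac = ft._epoch_band_fractions(block, FS, ft.DEFAULT_SCHEME)
        # delta, theta, alpha, sigma, beta occupy disjoint bins
        assert np.all(frac[..., 1:].sum(axis=-1) <= 1.0 + 1e-9)
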