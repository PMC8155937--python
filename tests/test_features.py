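"""Hjorth parameters, entropies, wavelet features and asymmetry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegaffect import (
    EEGAffectError,
    FeatureUndefinedError,
    asymmetry,
    dwt_detail_coefficients,
    hjorth_activity,
    hjorth_complexity,
    hjorth_mobility,
    spectral_entropy,
    spectral_entropy_from_psd,
    wavelet_energy,
    wavelet_entropy,
)

FS = 128.0


def sine(freq, seconds=4.0, fs=FS):
    t = np.arange(int(seconds * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


random_signal = st.integers(0, 2 ** 31 - 1).map(
    lambda s: np.random.default_rng(s).standard_normal(256)
)


class TestHjorth:
    def test_activity_examples(self):
        assert hjorth_activity([5.0, 5, 5, 5]) == 0.0
        assert hjorth_activity([1.0, -1, 1, -1]) == 1.0

    def test_mobility_of_alternating_signal_approaches_two(self):
        x = np.resize([1.0, -1.0], 1000)
        assert hjorth_mobility(x) == pytest.approx(2.0, abs=1e-4)

    @pytest.mark.parametrize("ratio", [32, 64, 128])
    def test_mobility_of_slow_sine_matches_continuous_limit(self, ratio):
        x = sine(FS / ratio, seconds=8.0)
        assert hjorth_mobility(x) == pytest.approx(2 * np.pi / ratio, rel=0.02)

    def test_complexity_of_pure_sine_is_one(self):
        assert hjorth_complexity(sine(4.0, seconds=8.0)) == pytest.approx(1.0, rel=0.05)

    def test_white_noise_more_complex_than_sine(self):
        sine_cx = hjorth_complexity(sine(4.0, seconds=8.0))
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(512)
            assert hjorth_complexity(x) > sine_cx

    @given(x=random_signal, c=st.floats(0.5, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_scaling_laws(self, x, c):
        assert hjorth_activity(c * x) == pytest.approx(
            c ** 2 * hjorth_activity(x), rel=1e-9
        )
        assert hjorth_mobility(c * x) == pytest.approx(hjorth_mobility(x), rel=1e-9)
        assert hjorth_complexity(c * x) == pytest.approx(
            hjorth_complexity(x), rel=1e-9
        )

    def test_degenerate_inputs_raise_typed_errors(self):
        with pytest.raises(FeatureUndefinedError):
            hjorth_mobility(np.full(16, 3.0))
        with pytest.raises(EEGAffectError):
            hjorth_activity([1.0])


class TestSpectralEntropy:
    def test_point_mass_spectrum_has_zero_entropy(self):
        psd = np.zeros(64)
        psd[10] = 5.0
        assert spectral_entropy_from_psd(psd) == 0.0

    def test_uniform_spectrum_has_log2_n_entropy(self):
        assert spectral_entropy_from_psd(np.ones(64)) == pytest.approx(6.0)

    def test_two_equal_tones_give_about_one_bit(self):
        x = sine(8.0) + sine(24.0)
        assert spectral_entropy(x) == pytest.approx(1.0, abs=0.2)

    def test_all_zero_signal_undefined(self):
        with pytest.raises(FeatureUndefinedError):
            spectral_entropy(np.zeros(64))

    @given(x=random_signal, c=st.floats(0.5, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_amplitude_scale_invariance(self, x, c):
        assert spectral_entropy(c * x) == pytest.approx(spectral_entropy(x), rel=1e-9)


class TestDwt:
    def test_zero_signal_gives_zero_coefficients(self):
        coeffs = dwt_detail_coefficients(np.zeros(512))
        for c in coeffs.values():
            np.testing.assert_allclose(c, 0.0)

    def test_parseval_identity(self, rng):
        x = rng.standard_normal(512)
        coeffs = dwt_detail_coefficients(x)
        total = sum(np.sum(c ** 2) for c in coeffs.values())
        assert total == pytest.approx(np.sum(x ** 2), rel=1e-6)

    def test_gamma_tone_concentrates_in_d1(self):
        coeffs = dwt_detail_coefficients(sine(40.0))
        assert wavelet_energy(coeffs["D1"]) > 10 * wavelet_energy(coeffs["D3"])

    @pytest.mark.parametrize(
        "freq,level", [(11.0, "D3"), (24.0, "D2"), (44.0, "D1")]
    )
    def test_subband_selectivity(self, freq, level):
        coeffs = dwt_detail_coefficients(sine(freq))
        detail_total = sum(
            wavelet_energy(c) for k, c in coeffs.items() if k.startswith("D")
        )
        assert wavelet_energy(coeffs[level]) >= 0.8 * detail_total

    def test_too_short_signal_names_minimum_length(self):
        with pytest.raises(EEGAffectError, match="64"):
            dwt_detail_coefficients(np.zeros(32))


class TestWaveletFeatures:
    def test_energy_examples(self):
        assert wavelet_energy(np.zeros(8)) == 0.0
        assert wavelet_energy(np.array([3.0, 4.0])) == 25.0

    def test_energy_scales_quadratically(self, rng):
        x = rng.standard_normal(512)
        e1 = wavelet_energy(dwt_detail_coefficients(x)["D2"])
        e3 = wavelet_energy(dwt_detail_coefficients(3 * x)["D2"])
        assert e3 == pytest.approx(9 * e1, rel=1e-9)

    def test_entropy_examples(self):
        assert wavelet_entropy(np.array([0.0, 2.5, 0.0])) == 0.0
        assert wavelet_entropy(np.ones(16)) == pytest.approx(4.0)
        coeffs = np.array([1.0, -2.0, 3.0, -4.0])
        assert wavelet_entropy(coeffs) == pytest.approx(
            wavelet_entropy(np.abs(coeffs))
        )

    def test_zero_energy_undefined(self):
        with pytest.raises(FeatureUndefinedError):
            wavelet_entropy(np.zeros(8))


class TestAsymmetry:
    def test_equal_hemispheres(self):
        np.testing.assert_allclose(asymmetry([2.0, 3.0], [2.0, 3.0], "differential"), 0.0)
        np.testing.assert_allclose(asymmetry([2.0, 3.0], [2.0, 3.0], "rational"), 1.0)

    def test_arithmetic(self):
        assert asymmetry([4.0], [2.0], "differential")[0] == 2.0
        assert asymmetry([4.0], [2.0], "rational")[0] == 2.0

    def test_both_concatenates_differential_then_rational(self):
        out = asymmetry([4.0], [2.0], "both")
        np.testing.assert_allclose(out, [2.0, 2.0])
        out = asymmetry([6.0], [2.0], "both")
        np.testing.assert_allclose(out, [4.0, 3.0])

    def test_rational_with_zero_right_undefined(self):
        with pytest.raises(FeatureUndefinedError):
            asymmetry([1.0], [0.0], "rational")

    def test_misaligned_pairs_rejected(self):
        with pytest.raises(EEGAffectError):
            asymmetry([1.0, 2.0], [1.0], "differential")
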