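"""Hann spectra, band aggregation and the exact five-band partition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from olfactomap.paradigm import ConditionLabel
from olfactomap.spectral import (
    DEFAULT_BANDS,
    DEFAULT_TOTAL_RANGE,
    BandDefinition,
    ConditionSpectrum,
    average_condition_spectrum,
    band_power,
    band_power_map,
    epoch_spectrum,
    hann_taper,
    relative_band_power,
    subtract_noise_psd,
    total_power,
)

RATE = 500.0


def dft_oracle(x: np.ndarray) -> np.ndarray:
    """O(N²) direct DFT power of the Hann-tapered signal, one-sided grid."""
    n = len(x)
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / n))
    xt = x * w
    k = np.arange(n // 2 + 1)
    e = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / n)
    spec = e @ xt
    return np.abs(spec) ** 2 / np.sum(w**2)


def spectrum_of(x, rate=RATE):
    return epoch_spectrum(np.atleast_2d(x), rate)


class TestEpochSpectrum:
    def test_zero_epoch_all_zero(self):
        s = spectrum_of(np.zeros(500))
        assert np.all(s.power == 0)

    def test_sinusoid_peak_at_its_frequency(self):
        t = np.arange(500) / RATE
        s = spectrum_of(np.sin(2 * np.pi * 10 * t))
        assert s.frequencies[np.argmax(s.power[0])] == pytest.approx(10.0)

    def test_matches_direct_dft_oracle_on_sinusoid(self):
        t = np.arange(500) / RATE
        x = np.sin(2 * np.pi * 10 * t)
        got = spectrum_of(x).power[0]
        want = dft_oracle(x)
        np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-16)

    def test_quadratic_homogeneity(self, rng):
        x = rng.normal(size=400)
        p1 = spectrum_of(x).power
        p3 = spectrum_of(3.0 * x).power
        np.testing.assert_allclose(p3, 9.0 * p1, rtol=1e-12)

    def test_white_noise_level_is_taper_invariant(self, rng):
        # normalization by sum(w^2) makes expected white-noise power per bin
        # equal to the sample variance, with or without the taper
        x = rng.normal(size=(1, 500 * 200)).reshape(200, 500)
        tapered = np.mean([epoch_spectrum(e[None], RATE).power for e in x], axis=0)
        boxcar = np.mean(
            [epoch_spectrum(e[None], RATE, taper="none").power for e in x], axis=0
        )
        interior = slice(1, -1)
        assert np.mean(tapered[0, interior]) == pytest.approx(
            np.mean(boxcar[0, interior]), rel=0.03
        )

    def test_non_finite_samples_rejected(self):
        bad = np.zeros(100)
        bad[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            spectrum_of(bad)

    def test_frequency_resolution_is_inverse_epoch_length(self):
        s = spectrum_of(np.zeros(1000))  # 2 s at 500 Hz
        assert s.frequencies[1] - s.frequencies[0] == pytest.approx(0.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_random_epochs_match_dft_oracle(self, seed):
        x = np.random.default_rng(seed).normal(size=256)
        got = epoch_spectrum(x[None], 256.0).power[0]
        want = dft_oracle(x)
        np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-18)

    def test_hann_taper_formula(self):
        w = hann_taper(8)
        k = np.arange(8)
        np.testing.assert_allclose(w, 0.5 * (1 - np.cos(2 * np.pi * k / 8)))


class TestAveraging:
    def test_single_spectrum_identity(self):
        s = spectrum_of(np.ones(100))
        avg = average_condition_spectrum([s], ConditionLabel.PEA)
        np.testing.assert_array_equal(avg.power, s.power)
        assert avg.n_epochs == 1

    def test_mean_of_zero_and_s_is_half_s(self):
        s = spectrum_of(np.sin(np.arange(100)))
        z = spectrum_of(np.zeros(100))
        avg = average_condition_spectrum([z, s])
        np.testing.assert_allclose(avg.power, s.power / 2)

    def test_permutation_invariance(self, rng):
        specs = [spectrum_of(rng.normal(size=100)) for _ in range(5)]
        a = average_condition_spectrum(specs)
        b = average_condition_spectrum(specs[::-1])
        np.testing.assert_allclose(a.power, b.power)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            average_condition_spectrum(
                [spectrum_of(np.zeros(100)), spectrum_of(np.zeros(128))]
            )


class TestBandPower:
    def test_five_band_partition_sums_to_total(self, rng):
        """The half-open band partition makes delta+...+gamma equal the
        1-80 Hz broadband total exactly."""
        spec = average_condition_spectrum(
            [spectrum_of(rng.normal(size=(3, 500))) for _ in range(4)]
        )
        per_band = sum(band_power(spec, b) for b in DEFAULT_BANDS)
        np.testing.assert_allclose(per_band, total_power(spec), rtol=1e-10)

    def test_sinusoid_alpha_dominates_broadband(self):
        t = np.arange(500) / RATE
        spec = average_condition_spectrum([spectrum_of(np.sin(2 * np.pi * 10 * t))])
        alpha = band_power(spec, DEFAULT_BANDS[2])
        assert alpha[0] / total_power(spec)[0] > 0.95

    def test_white_noise_alpha_share_is_five_eightieths(self, rng):
        reps = []
        for _ in range(8):
            spec = average_condition_spectrum(
                [spectrum_of(rng.normal(size=500)) for _ in range(40)]
            )
            reps.append(relative_band_power(spec, DEFAULT_BANDS[2])[0])
        se = np.std(reps, ddof=1) / np.sqrt(len(reps))
        assert abs(np.mean(reps) - 5 / 80) <= 3 * se + 0.003

    def test_empty_band_is_zero(self, rng):
        spec = average_condition_spectrum([spectrum_of(np.zeros(500))])
        assert band_power(spec, BandDefinition("gamma", 31, 81))[0] == 0.0

    def test_band_outside_range_rejected(self, rng):
        spec = average_condition_spectrum([spectrum_of(rng.normal(size=100), rate=100.0)])
        with pytest.raises(ValueError, match="outside"):
            band_power(spec, BandDefinition("hf", 200.0, 300.0))

    def test_relative_fractions_sum_to_one(self, rng):
        spec = average_condition_spectrum([spectrum_of(rng.normal(size=(2, 500)))])
        fractions = sum(relative_band_power(spec, b) for b in DEFAULT_BANDS)
        np.testing.assert_allclose(fractions, 1.0, rtol=1e-10)

    def test_relative_power_gain_invariant(self, rng):
        x = rng.normal(size=(2, 500))
        s1 = average_condition_spectrum([spectrum_of(x)])
        s2 = average_condition_spectrum([spectrum_of(5.0 * x)])
        np.testing.assert_allclose(
            relative_band_power(s1, DEFAULT_BANDS[2]),
            relative_band_power(s2, DEFAULT_BANDS[2]),
            rtol=1e-12,
        )

    def test_band_map_layout(self, rng):
        spec = average_condition_spectrum([spectrum_of(rng.normal(size=(3, 500)))])
        bp = band_power_map(spec, DEFAULT_BANDS, ["a", "b", "c"])
        assert bp.absolute.shape == (3, 5)
        np.testing.assert_allclose(bp.relative.sum(axis=1), 1.0, rtol=1e-10)


class TestNoiseSubtraction:
    def make(self, power):
        return ConditionSpectrum(
            ConditionLabel.REST, np.atleast_2d(power).astype(float),
            np.arange(np.atleast_2d(power).shape[1], dtype=float), 10,
        )

    def test_zero_empty_room_is_identity(self):
        cond = self.make([1.0, 2.0, 3.0])
        out = subtract_noise_psd(cond, self.make([0.0, 0.0, 0.0]))
        np.testing.assert_array_equal(out.power, cond.power)
        assert out.noise_subtracted

    def test_self_subtraction_is_zero(self):
        cond = self.make([1.0, 2.0, 3.0])
        assert np.all(subtract_noise_psd(cond, cond).power == 0)

    def test_never_negative(self):
        out = subtract_noise_psd(self.make([1.0, 0.5]), self.make([2.0, 0.1]))
        assert np.all(out.power >= 0)

    def test_grid_mismatch_rejected(self):
        a, b = self.make([1.0, 2.0]), self.make([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="mismatch"):
            subtract_noise_psd(a, b)
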