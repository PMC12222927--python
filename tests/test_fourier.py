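import numpy as np
import pytest

from lncspect import (
    SequenceRecord,
    key_fourier_features,
    map_sequence,
    power_spectrum,
    spectral_descriptors,
)
from lncspect.fourier import DESCRIPTOR_NAMES, PowerSpectrum, parseval_residual
from lncspect.mappings import MAPPING_NAMES, MappingProfile

from .conftest import random_record


def naive_dft_power(channels: np.ndarray) -> np.ndarray:
    """O(N^2) direct-sum DFT oracle, summed over channels."""
    n = channels.shape[1]
    k = np.arange(n)
    w = np.exp(-2j * np.pi * np.outer(k, k) / n)
    p = np.zeros(n)
    for ch in channels:
        p += np.abs(w @ ch.astype(complex)) ** 2
    return p


class TestPowerSpectrum:
    def test_impulse_has_flat_spectrum(self):
        prof = MappingProfile("real", np.array([[1.0, 0.0, 0.0, 0.0]]), 4)
        np.testing.assert_allclose(power_spectrum(prof).power, np.ones(4))

    def test_constant_signal_is_pure_dc(self):
        spec = power_spectrum(map_sequence(SequenceRecord("x", "AAAA"), "atomic"))
        assert spec.power[0] == pytest.approx((4 * 70) ** 2)
        np.testing.assert_allclose(spec.power[1:], 0, atol=1e-18)

    def test_matches_naive_dft_oracle(self):
        rng = np.random.default_rng(42)
        for i in range(100):
            rec = random_record(rng, int(rng.integers(50, 401)), f"d{i}")
            mapping = MAPPING_NAMES[i % len(MAPPING_NAMES)]
            prof = map_sequence(rec, mapping)
            got = power_spectrum(prof).power
            want = naive_dft_power(prof.channels)
            np.testing.assert_allclose(got, want, rtol=1e-8, atol=1e-6)

    def test_parseval_for_all_mappings(self):
        rng = np.random.default_rng(9)
        for i in range(50):
            rec = random_record(rng, int(rng.integers(30, 400)), f"p{i}")
            for mapping in MAPPING_NAMES:
                assert parseval_residual(map_sequence(rec, mapping)) < 1e-6

    def test_too_short_rejected(self):
        prof = MappingProfile("real", np.array([[1.0]]), 1)
        with pytest.raises(ValueError):
            power_spectrum(prof)


class TestSpectralDescriptors:
    def test_flat_nondc_spectrum_is_degenerate(self):
        spec = power_spectrum(map_sequence(SequenceRecord("x", "A" * 16), "atomic"))
        d = spectral_descriptors(spec)
        assert d["average"] == 0 and d["amplitude"] == 0 and d["variance"] == 0

    def test_worked_banded_example(self):
        spec = PowerSpectrum("real", np.array([0.0, 4.0, 2.0, 2.0]), 4)
        d = spectral_descriptors(spec, band="exclude_dc")
        assert d["average"] == pytest.approx(8 / 3)
        assert d["maximum"] == 4 and d["minimum"] == 2
        assert d["amplitude"] == 2

    def test_descriptor_identities(self, rng):
        for i in range(20):
            rec = random_record(rng, int(rng.integers(50, 300)), f"s{i}")
            spec = power_spectrum(map_sequence(rec, "eiip"))
            d = spectral_descriptors(spec)
            assert set(d) == set(DESCRIPTOR_NAMES)
            assert d["minimum"] <= d["percentile25"] <= d["median"] <= d["percentile75"] <= d["maximum"]
            assert d["amplitude"] == pytest.approx(d["maximum"] - d["minimum"])
            assert d["variance"] == pytest.approx(d["standard_deviation_population"] ** 2)
            assert d["interquartile_range"] == pytest.approx(d["percentile75"] - d["percentile25"])
            assert d["semi_interquartile_range"] == pytest.approx(d["interquartile_range"] / 2)
            assert d["median"] == d["percentile50"]

    def test_scale_property(self, rng):
        """Scaling a single-channel table by c scales power, hence average
        and amplitude, by c^2."""
        rec = random_record(rng, 120, "sc")
        prof = map_sequence(rec, "atomic")
        scaled = MappingProfile("atomic", prof.channels * 3.0, prof.n)
        d1 = spectral_descriptors(power_spectrum(prof))
        d2 = spectral_descriptors(power_spectrum(scaled))
        assert d2["average"] == pytest.approx(9 * d1["average"])
        assert d2["amplitude"] == pytest.approx(9 * d1["amplitude"])

    def test_degenerate_band_rejected(self):
        spec = PowerSpectrum("real", np.array([1.0, 1.0]), 2)
        with pytest.raises(ValueError):
            spectral_descriptors(spec, band="exclude_dc")


class TestKeyFourierFeatures:
    def test_homopolymer_average_is_zero(self):
        cavg, _ = key_fourier_features(SequenceRecord("x", "A" * 200))
        assert cavg == pytest.approx(0.0, abs=1e-9)

    def test_pure_codon_repeat_maximum_at_third_frequency(self):
        rec = SequenceRecord("x", "ATG" * 150)  # N = 450, exact period 3
        spec = power_spectrum(map_sequence(rec, "complex"))
        k_star = int(np.argmax(spec.power[1:])) + 1
        assert k_star in (rec.length // 3, 2 * rec.length // 3)  # conjugate pair

    def test_codon_structured_repeat_elevates_third_frequency_bin(self):
        # period-9 repeat: the codon-frequency bin N/3 is a harmonic and is
        # strongly elevated over the spectrum background
        rec = SequenceRecord("x", "ATGGCTGAA" * 50)  # N = 450
        spec = power_spectrum(map_sequence(rec, "complex"))
        d = spectral_descriptors(spec)
        assert d["peak"] == spec.power[round(rec.length / 3)]
        assert d["peak"] > 100 * d["median"]
        assert d["amplitude"] > 10 * d["median"]

    def test_reversal_preserves_power_spectrum(self, rng):
        rec = random_record(rng, 240, "fwd")
        rev = SequenceRecord("rev", rec.seq[::-1])
        for mapping in ("complex", "atomic"):
            pf = power_spectrum(map_sequence(rec, mapping)).power
            pr = power_spectrum(map_sequence(rev, mapping)).power
            np.testing.assert_allclose(np.sort(pf), np.sort(pr), rtol=1e-8)
        assert key_fourier_features(rec)[0] == pytest.approx(key_fourier_features(rev)[0])

    def test_separation_on_synthetic_benchmark(self, small_dataset):
        """Coding-like sequences show higher period-3 peak-to-average than
        noncoding-like ones (Mann-Whitney, complex mapping)."""
        from scipy.stats import mannwhitneyu

        ratios = {"mRNA": [], "lncRNA": []}
        for rec in small_dataset.records:
            spec = power_spectrum(map_sequence(rec, "complex"))
            d = spectral_descriptors(spec)
            ratios[small_dataset.labels[rec.id]].append(d["peak"] / d["average"])
        stat = mannwhitneyu(ratios["mRNA"], ratios["lncRNA"], alternative="greater")
        assert stat.pvalue < 0.01
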