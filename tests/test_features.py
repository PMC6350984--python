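import numpy as np
import pytest

from artexus.armodel import ARModel, ARSpectrum, ar_spectrum
from artexus.config import BANDS, CONVERSIONS
from artexus.features import (
    ER_REGISTRY,
    candidate_ratio_space,
    compute_features,
    main_peak_bounds,
    spectral_energy,
)

from conftest import random_stable_ar


def spectrum_from(density, band="TB", conversion_id=1):
    density = np.asarray(density, dtype=float)
    return ARSpectrum(np.linspace(0, 0.5, density.size), density, band, conversion_id)


def full_spectra_set(rng, order=6, n_freq=256):
    out = []
    for i in CONVERSIONS:
        for b in BANDS:
            a = random_stable_ar(rng, order)
            s = ar_spectrum(ARModel(a, 1.0), n_freq)
            out.append(ARSpectrum(s.freqs, s.density, b, i))
    return out


class TestRegistry:
    def test_thirty_features_two_kinds(self):
        assert len(ER_REGISTRY) == 30
        peak = [s for s in ER_REGISTRY if s.kind == "peak_over_total"]
        assert [s.id for s in peak] == [1, 2, 3, 4]
        assert all(s.num == s.den for s in peak)

    def test_known_rows(self):
        by_id = {s.id: s for s in ER_REGISTRY}
        assert (by_id[5].num, by_id[5].den) == ((1, "HF"), (1, "TB"))
        assert (by_id[12].num, by_id[12].den) == ((1, "LF"), (2, "HF"))
        assert (by_id[19].num, by_id[19].den) == ((3, "LF"), (2, "HF"))
        assert (by_id[30].num, by_id[30].den) == ((2, "MF"), (4, "HF"))

    def test_candidate_space_is_256(self):
        space = candidate_ratio_space()
        assert len(space) == 256
        assert len(set(space)) == 256
        assert all((s.num, s.den) in space for s in ER_REGISTRY)


class TestSpectralEnergy:
    def test_flat_unit_spectrum_full_band(self):
        assert spectral_energy(spectrum_from(np.ones(512))) == 512

    def test_partition_additivity(self, rng):
        s = spectrum_from(rng.random(257))
        lo = spectral_energy(s, 0.0, 0.25)
        hi = spectral_energy(s, 0.25, 0.5) - s.density[128]  # shared grid point
        assert lo + hi == pytest.approx(spectral_energy(s))

    def test_ar1_energy_concentrates_at_low_frequency(self):
        s = ar_spectrum(ARModel([-0.9], 1.0), 512)
        assert spectral_energy(s, 0.0, 0.1) > spectral_energy(s, 0.4, 0.5)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            spectral_energy(spectrum_from(np.ones(64)), 0.3, 0.1)


class TestMainPeakBounds:
    def test_unimodal_lobe_is_bracketed(self):
        f = np.linspace(0, 0.5, 501)
        d = np.exp(-((f - 0.2) ** 2) / (2 * 0.02 ** 2)) + 0.01
        f1, f2 = main_peak_bounds(spectrum_from(d))
        assert f1 < 0.2 < f2
        ipk = np.argmax(d)
        assert d[np.searchsorted(f, f1)] <= d[ipk]
        assert d[np.searchsorted(f, f2)] <= d[ipk]

    def test_taller_of_two_lobes_wins(self):
        """Sum of two AR(2)-like resonances: bounds bracket the taller one only."""
        f = np.linspace(0, 0.5, 1001)
        lobe = lambda f0, w, h: h / (1 + ((f - f0) / w) ** 2)
        d = lobe(0.1, 0.01, 5.0) + lobe(0.35, 0.01, 2.0)
        f1, f2 = main_peak_bounds(spectrum_from(d))
        assert f1 < 0.1 < f2 < 0.35

    def test_flat_spectrum_falls_back_to_boundaries(self):
        with pytest.warns(RuntimeWarning):
            f1, f2 = main_peak_bounds(spectrum_from(np.ones(128)))
        assert f1 == 0.0 or f2 == 0.5

    def test_monotone_spectrum_uses_half_power(self):
        s = ar_spectrum(ARModel([-0.9], 1.0), 512)  # monotone decreasing from f=0
        with pytest.warns(RuntimeWarning):
            f1, f2 = main_peak_bounds(s)
        assert f1 == 0.0
        assert 0.0 < f2 < 0.5  # half-power crossing, not the grid end


class TestComputeFeatures:
    def test_identical_spectra_give_unit_ratios(self, rng):
        base = ar_spectrum(ARModel(random_stable_ar(rng, 4), 1.0), 256)
        spectra = [
            ARSpectrum(base.freqs, base.density, b, i) for i in CONVERSIONS for b in BANDS
        ]
        fv = compute_features(spectra)
        np.testing.assert_allclose(fv.values[4:], 1.0)
        assert np.all(fv.values[:4] > 0) and np.all(fv.values[:4] <= 1)

    def test_peak_ratios_bounded_for_random_stable_models(self, rng):
        for _ in range(50):
            fv = compute_features(full_spectra_set(rng))
            assert np.all(fv.values > 0)
            assert np.all(fv.values[:4] <= 1.0)

    def test_whole_band_peak_gives_er4_of_one(self):
        # density rising to an interior max then falling, minima only at the ends
        f = np.linspace(0, 0.5, 256)
        d = 1.0 + np.sin(np.pi * f / 0.5)
        spectra = [
            spectrum_from(d, b, i) if (i, b) != (1, "TB") else spectrum_from(d, "TB", 1)
            for i in CONVERSIONS
            for b in BANDS
        ]
        fv = compute_features(spectra)
        assert fv.values[3] == pytest.approx(1.0)

    def test_missing_spectrum_is_reported(self, rng):
        spectra = full_spectra_set(rng)[:-1]
        with pytest.raises(ValueError, match=r"\(4, 'TB'\)"):
            compute_features(spectra)

    def test_duplicate_spectrum_rejected(self, rng):
        spectra = full_spectra_set(rng)
        with pytest.raises(ValueError, match="duplicate"):
            compute_features(spectra + [spectra[0]])

    def test_scale_invariance_of_features(self, small_cfg, rng):
        """Features are unchanged when the patch is scaled by c > 0."""
        from artexus.segment import patch_features

        patch = rng.random((12, 12))
        f1 = patch_features(patch, small_cfg).values
        f2 = patch_features(3.7 * patch, small_cfg).values
        np.testing.assert_allclose(f1, f2, rtol=1e-8)

    def test_deterministic_for_fixed_patch(self, small_cfg, rng):
        from artexus.segment import patch_features

        patch = rng.random((12, 12))
        np.testing.assert_array_equal(
            patch_features(patch, small_cfg).values,
            patch_features(patch, small_cfg).values,
        )
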