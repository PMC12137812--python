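import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xfct.spectra import (AugmentationConfig, EnergyCalibration, Spectrum,
                          SpectrumModelParams, apply_efficiency_correction,
                          augment_dataset, augment_spectrum, derive_seed,
                          simulate_dataset, simulate_spectrum,
                          spectra_to_table, table_to_spectra)


class TestEnergyCalibration:
    def test_defaults(self, calibration):
        assert calibration.n_channels == 800
        assert calibration.bin_width == pytest.approx(0.16)
        assert calibration.energy_range == (0.0, pytest.approx(128.0))

    def test_channel_of_half_open(self, calibration):
        # channel c spans [c*0.16, (c+1)*0.16)
        assert calibration.channel_of(0.0) == 0
        assert calibration.channel_of(68.8) == 430
        assert calibration.channel_of(0.16) == 1

    def test_invalid(self):
        with pytest.raises(ValueError):
            EnergyCalibration(n_channels=0)
        with pytest.raises(ValueError):
            EnergyCalibration(bin_width=-1)


class TestSimulateSpectrum:
    def test_zero_concentration_has_zero_doublet(self, noise_free_params):
        s = simulate_spectrum(0.0, 10.0, noise_free_params, seed=0)
        cont = noise_free_params.continuum(s.calibration) * 10.0
        assert s.ground_truth_net == 0.0
        np.testing.assert_allclose(s.counts, cont, rtol=1e-12)

    def test_doublet_mode_channel_430(self, noise_free_params, calibration):
        # 68.8 keV / 0.16 keV per bin = channel 430
        shape = noise_free_params.doublet_shape(calibration)
        assert int(np.argmax(shape)) == 430

    def test_linearity_in_concentration(self, noise_free_params):
        s1 = simulate_spectrum(0.2, 10.0, noise_free_params, seed=7)
        s2 = simulate_spectrum(0.4, 10.0, noise_free_params, seed=7)
        assert s2.ground_truth_net == pytest.approx(2.0 * s1.ground_truth_net)

    def test_linearity_in_time(self, noise_free_params):
        s1 = simulate_spectrum(0.3, 5.0, noise_free_params, seed=7)
        s2 = simulate_spectrum(0.3, 20.0, noise_free_params, seed=7)
        assert s2.ground_truth_net == pytest.approx(4.0 * s1.ground_truth_net)

    def test_deterministic_given_seed(self):
        a = simulate_spectrum(0.5, 10.0, seed=3)
        b = simulate_spectrum(0.5, 10.0, seed=3)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="concentration"):
            simulate_spectrum(-0.1, 10.0)

    def test_ka_outside_range_rejected(self):
        p = SpectrumModelParams(ka1_energy=200.0)
        with pytest.raises(ValueError, match="outside"):
            simulate_spectrum(0.1, 10.0, p)

    def test_counts_non_negative(self, noisy_spectra):
        for s in noisy_spectra:
            assert np.all(s.counts >= 0)


class TestAugmentation:
    def test_identity_config(self, clean_spectrum, identity_augmentation):
        out = augment_spectrum(clean_spectrum, identity_augmentation)
        np.testing.assert_array_equal(out.counts, clean_spectrum.counts)
        assert out.ground_truth_net == clean_spectrum.ground_truth_net

    def test_pure_shift_moves_argmax(self, clean_spectrum, identity_augmentation):
        cfg = AugmentationConfig(baseline_shift_range=0, slope_range=0,
                                 scale_range=(1.0, 1.0), peak_shift_channels=(1,),
                                 gaussian_noise_sd=0, seed=0)
        out = augment_spectrum(clean_spectrum, cfg)
        assert int(np.argmax(out.counts)) == int(np.argmax(clean_spectrum.counts)) + 1

    def test_scale_multiplies_label(self, clean_spectrum):
        cfg = AugmentationConfig(baseline_shift_range=0, slope_range=0,
                                 scale_range=(2.0, 2.0), peak_shift_channels=(0,),
                                 gaussian_noise_sd=0, seed=0)
        out = augment_spectrum(clean_spectrum, cfg)
        assert out.ground_truth_net == pytest.approx(2 * clean_spectrum.ground_truth_net)
        assert out.ground_truth_background == pytest.approx(
            2 * clean_spectrum.ground_truth_background)

    def test_baseline_raises_background_only(self, clean_spectrum):
        cfg = AugmentationConfig(baseline_shift_range=5.0, slope_range=0,
                                 scale_range=(1.0, 1.0), peak_shift_channels=(0,),
                                 gaussian_noise_sd=0, seed=1)
        out = augment_spectrum(clean_spectrum, cfg)
        assert out.ground_truth_net == clean_spectrum.ground_truth_net
        assert out.ground_truth_background != clean_spectrum.ground_truth_background

    def test_count_conservation(self, noisy_spectra):
        out = augment_dataset(noisy_spectra, 7, AugmentationConfig(seed=5))
        assert len(out) == len(noisy_spectra) * 7

    def test_deterministic(self, noisy_spectra):
        cfg = AugmentationConfig(seed=9)
        a = augment_dataset(noisy_spectra[:3], 4, cfg)
        b = augment_dataset(noisy_spectra[:3], 4, cfg)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.counts, y.counts)

    def test_piecewise_reproducible(self, noisy_spectra):
        # dataset draw (i, r) equals a single-spectrum call with the derived seed
        cfg = AugmentationConfig(seed=9)
        ds = augment_dataset(noisy_spectra[:3], 4, cfg)
        single = augment_spectrum(noisy_spectra[2], cfg, seed=derive_seed(9, 2, 3))
        np.testing.assert_array_equal(ds[2 * 4 + 3].counts, single.counts)

    def test_non_negative_after_augmentation(self, noisy_spectra):
        cfg = AugmentationConfig(baseline_shift_range=100.0, gaussian_noise_sd=50.0,
                                 seed=11)
        for s in augment_dataset(noisy_spectra, 3, cfg):
            assert np.all(s.counts >= 0)

    @given(scale=st.floats(0.5, 2.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_property(self, scale):
        s = simulate_spectrum(0.3, 10.0, SpectrumModelParams(noise_model="none"),
                              seed=0)
        cfg = AugmentationConfig(baseline_shift_range=0, slope_range=0,
                                 scale_range=(scale, scale),
                                 peak_shift_channels=(0,), gaussian_noise_sd=0,
                                 seed=0)
        out = augment_spectrum(s, cfg)
        np.testing.assert_allclose(out.counts, scale * s.counts, rtol=1e-12)

    def test_invalid_scale_range(self):
        with pytest.raises(ValueError):
            AugmentationConfig(scale_range=(0.0, 1.0))


class TestEfficiencyCorrection:
    def test_identity_default(self, clean_spectrum):
        out = apply_efficiency_correction(clean_spectrum)
        np.testing.assert_array_equal(out.counts, clean_spectrum.counts)

    def test_constant_half_doubles(self, clean_spectrum):
        eff = np.full(800, 0.5)
        out = apply_efficiency_correction(clean_spectrum, eff)
        np.testing.assert_allclose(out.counts, 2 * clean_spectrum.counts)

    def test_round_trip(self, clean_spectrum):
        rng = np.random.default_rng(0)
        eff = rng.uniform(0.5, 1.5, 800)
        out = apply_efficiency_correction(clean_spectrum, eff)
        np.testing.assert_allclose(out.counts * eff, clean_spectrum.counts,
                                   rtol=1e-12)

    def test_nonpositive_rejected(self, clean_spectrum):
        eff = np.ones(800)
        eff[3] = 0.0
        with pytest.raises(ValueError):
            apply_efficiency_correction(clean_spectrum, eff)


class TestTableIO:
    def test_round_trip(self, noisy_spectra, tmp_path):
        df = spectra_to_table(noisy_spectra)
        path = tmp_path / "spectra.csv"
        df.to_csv(path, index=False)
        import pandas as pd
        back = table_to_spectra(pd.read_csv(path))
        assert len(back) == len(noisy_spectra)
        for a, b in zip(noisy_spectra, back):
            np.testing.assert_allclose(a.counts, b.counts)
            assert a.ground_truth_net == pytest.approx(b.ground_truth_net)

    def test_empty(self):
        df = spectra_to_table([])
        assert len(df) == 0
        assert "c799" in df.columns

    def test_hdf5_round_trip(self, noisy_spectra, tmp_path):
        from xfct.spectra import hdf5_to_spectra, spectra_to_hdf5
        path = tmp_path / "spectra.h5"
        spectra_to_hdf5(noisy_spectra, path)
        back = hdf5_to_spectra(path)
        assert len(back) == len(noisy_spectra)
        for a, b in zip(noisy_spectra, back):
            np.testing.assert_allclose(a.counts, b.counts)
            assert a.ground_truth_background == pytest.approx(
                b.ground_truth_background)
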