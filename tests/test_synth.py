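"""Synthetic training-data generators: spectra, shapes, composition."""

import numpy as np
import pytest
from scipy import ndimage

from quasarfield.dipole import build_dipole_kernel, forward_dipole_field
from quasarfield.synth import (
    SynthesisConfig,
    add_magnitude_noise,
    cone_anisotropy_ratio,
    make_training_sample,
    organic_shapes,
    radial_psd_slope,
    spectral_noise_field,
    synthesize_chi,
    synthesize_f_rho,
    synthesize_magnitude,
    synthesize_mask,
)
from quasarfield.volumes import Volume3D


class TestSpectralNoise:
    @pytest.mark.parametrize("beta", [0.0, 1.0, 2.0, 3.0])
    def test_psd_slope_recovers_exponent(self, beta):
        field = spectral_noise_field((64, 64, 64), beta, seed=42)
        slope = radial_psd_slope(field.data)
        assert slope == pytest.approx(-beta, abs=0.3)

    def test_zero_mean_unit_variance(self):
        field = spectral_noise_field((48, 48, 48), 2.0, seed=7)
        assert field.data.mean() == pytest.approx(0.0, abs=1e-12)
        assert field.data.std() == pytest.approx(1.0, rel=1e-9)

    def test_deterministic(self):
        a = spectral_noise_field((32, 32, 32), 1.5, seed=9)
        b = spectral_noise_field((32, 32, 32), 1.5, seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            spectral_noise_field((16, 16, 16), -1.0, seed=0)


class TestOrganicShapes:
    def test_zero_shapes_is_zero_field(self):
        out = organic_shapes((32, 32, 32), 0, 3.0, seed=0)
        assert np.all(out.data == 0)

    @pytest.mark.parametrize("seed", [0, 3, 11])
    def test_single_shape_is_one_connected_component(self, seed):
        out = organic_shapes((48, 48, 48), 1, 3.0, seed=seed)
        lab, n = ndimage.label(out.data != 0, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_range_normalized(self):
        out = organic_shapes((32, 32, 32), 4, 2.5, seed=5)
        assert np.abs(out.data).max() == pytest.approx(1.0)

    def test_deterministic(self):
        a = organic_shapes((32, 32, 32), 3, 3.0, seed=2)
        b = organic_shapes((32, 32, 32), 3, 3.0, seed=2)
        np.testing.assert_array_equal(a.data, b.data)


class TestFieldSynthesis:
    def test_zero_amplitude_ranges(self):
        cfg = SynthesisConfig(chi_amplitude_range=(0.0, 0.0),
                              frho_amplitude_range=(0.0, 0.0), seed=3)
        assert np.all(synthesize_chi(cfg).data == 0)
        assert np.all(synthesize_f_rho(cfg).data == 0)

    def test_chi_peak_within_amplitude_range(self):
        cfg = SynthesisConfig(seed=4)
        peak = np.abs(synthesize_chi(cfg).data).max()
        lo, hi = cfg.chi_amplitude_range
        assert lo <= peak <= hi

    def test_distinct_seeds_give_distinct_fields(self):
        cfg = SynthesisConfig()
        a = synthesize_chi(cfg.with_seed(1)).data
        b = synthesize_chi(cfg.with_seed(2)).data
        assert np.mean(a != b) > 0.99

    def test_chi_frho_independent_draws(self):
        cfg = SynthesisConfig(seed=6)
        chi = synthesize_chi(cfg).data
        f_rho = synthesize_f_rho(cfg).data
        mask = synthesize_mask(cfg).data > 0
        r = np.corrcoef(chi[mask], f_rho[mask])[0, 1]
        assert abs(r) < 0.1

    def test_frho_isotropic_while_dipole_field_is_not(self):
        # statistical isotropy: ensemble-averaged spectra over several draws
        frho_draws, fchi_draws = [], []
        kernel = build_dipole_kernel((64, 64, 64))
        for seed in range(8):
            cfg = SynthesisConfig(seed=seed)
            frho_draws.append(synthesize_f_rho(cfg).data)
            fchi_draws.append(forward_dipole_field(synthesize_chi(cfg), kernel).data)
        ratio_frho = cone_anisotropy_ratio(frho_draws)
        ratio_fchi = cone_anisotropy_ratio(fchi_draws)
        assert 0.8 <= ratio_frho <= 1.2
        assert abs(ratio_fchi - 1.0) > 0.3


class TestMagnitudeAndNoise:
    def test_magnitude_range_and_dark_fraction(self):
        cfg = SynthesisConfig(seed=8)
        mag = synthesize_magnitude(cfg).data
        assert mag.min() > 0
        assert mag.max() <= 1.0
        assert np.quantile(mag, 0.1) < 0.2     # bottom decile is dark
        assert (mag < 0.2).mean() > 0

    def test_infinite_snr_leaves_input_unchanged(self, rng):
        f = Volume3D(rng.standard_normal((24, 24, 24)), unit="ppm")
        mag = f.with_data(np.full((24, 24, 24), 0.5), unit="arbitrary")
        out = add_magnitude_noise(f, mag, snr=1e12, seed=0)
        np.testing.assert_allclose(out.data, f.data, rtol=1e-6, atol=1e-9)

    def test_halving_magnitude_doubles_noise_std(self, rng):
        f = Volume3D(rng.standard_normal((32, 32, 32)), unit="ppm")
        mag1 = f.with_data(np.full((32, 32, 32), 0.8), unit="arbitrary")
        mag2 = f.with_data(np.full((32, 32, 32), 0.4), unit="arbitrary")
        n1 = add_magnitude_noise(f, mag1, 100.0, seed=5).data - f.data
        n2 = add_magnitude_noise(f, mag2, 100.0, seed=5).data - f.data
        assert n2.std() / n1.std() == pytest.approx(2.0, rel=0.1)

    def test_nonpositive_magnitude_rejected(self, rng):
        f = Volume3D(rng.standard_normal((8, 8, 8)), unit="ppm")
        mag = f.with_data(np.zeros((8, 8, 8)), unit="arbitrary")
        with pytest.raises(ValueError):
            add_magnitude_noise(f, mag, 100.0, seed=0)

    def test_same_seed_same_noise(self, rng):
        f = Volume3D(rng.standard_normal((16, 16, 16)), unit="ppm")
        mag = f.with_data(np.full((16, 16, 16), 0.5), unit="arbitrary")
        a = add_magnitude_noise(f, mag, 50.0, seed=3)
        b = add_magnitude_noise(f, mag, 50.0, seed=3)
        np.testing.assert_array_equal(a.data, b.data)


class TestTrainingSample:
    def test_compositional_identity(self):
        cfg = SynthesisConfig(seed=11)
        s = make_training_sample(cfg)
        kernel = build_dipole_kernel(cfg.grid_shape, cfg.voxel_size)
        f_chi = forward_dipole_field(s.chi, kernel)
        resid = s.f_total.data - s.f_rho.data - s.noise.data - f_chi.data
        assert np.abs(resid).max() < 1e-10

    def test_zero_frho_range_reduces_to_standard_model(self):
        cfg = SynthesisConfig(frho_amplitude_range=(0.0, 0.0), seed=12)
        s = make_training_sample(cfg)
        kernel = build_dipole_kernel(cfg.grid_shape, cfg.voxel_size)
        f_chi = forward_dipole_field(s.chi, kernel)
        np.testing.assert_allclose(s.f_total.data - s.noise.data, f_chi.data,
                                   atol=1e-12)

    def test_noise_zero_outside_mask(self):
        s = make_training_sample(SynthesisConfig(seed=13))
        assert np.all(s.noise.data[s.mask.data == 0] == 0)

    def test_reproducible_and_distinct_across_seeds(self):
        cfg = SynthesisConfig()
        a = make_training_sample(cfg.with_seed(20))
        b = make_training_sample(cfg.with_seed(20))
        np.testing.assert_array_equal(a.f_total.data, b.f_total.data)
        chis = [make_training_sample(cfg.with_seed(s)).chi.data for s in range(30, 40)]
        for i in range(len(chis)):
            for j in range(i + 1, len(chis)):
                assert not np.array_equal(chis[i], chis[j])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SynthesisConfig(psd_exponent_range=(3.0, 1.0))
        with pytest.raises(ValueError):
            SynthesisConfig(snr=0.0)
        with pytest.raises(ValueError):
            SynthesisConfig(mask_fill_fraction=0.0)
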