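"""Dipole kernel and forward-model physics.

The k-space dipole response and its FFT convolution are validated against
closed-form values and the analytic field of a uniformly magnetized
sphere (the standard free-space oracle for this kernel).
"""

import numpy as np
import pytest

from quasarfield.dipole import (
    analytic_sphere_field,
    build_dipole_kernel,
    forward_dipole_field,
    forward_dipole_field_padded,
    quasar_forward,
    rasterize_sphere,
)
from quasarfield.volumes import Volume3D

from conftest import sphere_setup


class TestKernel:
    def test_axis_and_orthogonal_values(self, kernel32):
        D = kernel32.values
        # bin along b0 (kz != 0, kx = ky = 0): 1/3 - 1 = -2/3
        assert D[0, 0, 1] == pytest.approx(-2.0 / 3.0, abs=1e-12)
        assert D[0, 0, 16] == pytest.approx(-2.0 / 3.0, abs=1e-12)
        # bin orthogonal to b0: 1/3
        assert D[1, 0, 0] == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert D[0, 5, 0] == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_zero_frequency_bin_is_exactly_zero(self, kernel32):
        assert kernel32.values[0, 0, 0] == 0.0

    def test_range_and_extremes(self, kernel32):
        D = kernel32.values
        assert D.min() == pytest.approx(-2.0 / 3.0, abs=1e-12)
        assert D.max() == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert np.all(D >= -2.0 / 3.0 - 1e-12)
        assert np.all(D <= 1.0 / 3.0 + 1e-12)

    def test_magic_angle_zero(self):
        # construct a frequency bin with (k.b0)^2/|k|^2 = 1/3 exactly:
        # kz = 1, kx = sqrt(2) -> achieved with anisotropic voxel size
        kern = build_dipole_kernel((8, 8, 8), voxel_size=(1.0 / np.sqrt(2.0), 1.0, 1.0))
        # bin (1, 0, 1): kx = sqrt(2)/8, kz = 1/8 -> cos^2 = (1/64)/(3/64)
        assert kern.values[1, 0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_hermitian_even_symmetry(self, kernel32):
        D = kernel32.values
        flipped = D[(-np.arange(32)) % 32][:, (-np.arange(32)) % 32][:, :, (-np.arange(32)) % 32]
        np.testing.assert_allclose(D, flipped, atol=1e-14)

    @pytest.mark.parametrize("bad", [
        {"shape": (1, 8, 8)},
        {"voxel_size": (0.0, 1.0, 1.0)},
        {"b0_dir": (0.0, 0.0, 0.0)},
    ])
    def test_invalid_arguments(self, bad):
        kwargs = {"shape": (8, 8, 8), "voxel_size": (1.0, 1.0, 1.0),
                  "b0_dir": (0.0, 0.0, 1.0), **bad}
        with pytest.raises(ValueError):
            build_dipole_kernel(**kwargs)


class TestForward:
    def test_zero_and_constant_chi_give_zero_field(self, kernel32):
        zero = Volume3D(np.zeros((32, 32, 32)), unit="ppm")
        assert np.all(forward_dipole_field(zero, kernel32).data == 0)
        const = zero.with_data(np.full((32, 32, 32), 0.7))
        np.testing.assert_allclose(forward_dipole_field(const, kernel32).data, 0.0,
                                   atol=1e-12)

    def test_linearity(self, kernel32, rng):
        a = Volume3D(rng.standard_normal((32, 32, 32)), unit="ppm")
        b = a.with_data(rng.standard_normal((32, 32, 32)))
        lhs = forward_dipole_field(a.with_data(2.0 * a.data - 3.0 * b.data), kernel32).data
        rhs = 2.0 * forward_dipole_field(a, kernel32).data \
            - 3.0 * forward_dipole_field(b, kernel32).data
        np.testing.assert_allclose(lhs, rhs, atol=1e-10 * np.abs(rhs).max())

    def test_parseval_energy_bound(self, kernel32, rng):
        chi = Volume3D(rng.standard_normal((32, 32, 32)), unit="ppm")
        f = forward_dipole_field(chi, kernel32)
        demeaned = chi.data - chi.data.mean()
        assert np.sum(f.data**2) <= (2.0 / 3.0) ** 2 * np.sum(demeaned**2) + 1e-9

    def test_shape_mismatch_raises(self, kernel32):
        with pytest.raises(ValueError):
            forward_dipole_field(Volume3D(np.zeros((16, 16, 16)), unit="ppm"), kernel32)

    def test_quasar_forward_degenerate_cases(self, kernel32, rng):
        zero = Volume3D(np.zeros((32, 32, 32)), unit="ppm")
        f_rho = zero.with_data(rng.standard_normal((32, 32, 32)))
        # chi = 0 -> f = f_rho (the trivial-solution degeneracy)
        np.testing.assert_allclose(quasar_forward(zero, f_rho, kernel32).data,
                                   f_rho.data, atol=1e-12)
        # f_rho = 0 -> f = f_chi
        chi = zero.with_data(rng.standard_normal((32, 32, 32)))
        np.testing.assert_allclose(
            quasar_forward(chi, zero, kernel32).data,
            forward_dipole_field(chi, kernel32).data, atol=1e-12)

    def test_quasar_forward_scaling_linearity(self, kernel32, rng):
        chi = Volume3D(rng.standard_normal((32, 32, 32)), unit="ppm")
        f_rho = chi.with_data(rng.standard_normal((32, 32, 32)))
        full = quasar_forward(chi, f_rho, kernel32).data
        scaled = quasar_forward(chi.with_data(2.5 * chi.data),
                                f_rho.with_data(2.5 * f_rho.data), kernel32).data
        np.testing.assert_allclose(scaled, 2.5 * full, atol=1e-10)


class TestAnalyticSphere:
    def test_closed_form_pole_and_equator(self):
        n = 64
        tpl = Volume3D(np.zeros((n, n, n)), unit="ppm")
        a, c = 8.0, (32.0, 32.0, 32.0)
        field = analytic_sphere_field(1.0, a, c, tpl)
        # pole: r = 2a on the b0 axis -> (1/3)(1/8)(2) = 1/12
        assert field.data[32, 32, 48] == pytest.approx(1.0 / 12.0, rel=1e-9)
        # equator: r = 2a, theta = 90 deg -> -(1/3)(1/8) = -1/24
        assert field.data[48, 32, 32] == pytest.approx(-1.0 / 24.0, rel=1e-9)

    def test_interior_is_zero(self):
        tpl = Volume3D(np.zeros((48, 48, 48)), unit="ppm")
        field = analytic_sphere_field(0.5, 6.0, (24.0, 24.0, 24.0), tpl)
        assert field.data[24, 24, 24] == 0.0
        assert field.data[24, 24, 28] == 0.0  # r = 4 < a

    def test_b0_rotation_equivariance(self):
        # rotating b0 into +x mirrors the pole/equator pattern
        tpl_x = Volume3D(np.zeros((64, 64, 64)), b0_dir=(1.0, 0.0, 0.0), unit="ppm")
        f = analytic_sphere_field(1.0, 8.0, (32.0, 32.0, 32.0), tpl_x)
        assert f.data[48, 32, 32] == pytest.approx(1.0 / 12.0, rel=1e-9)
        assert f.data[32, 32, 48] == pytest.approx(-1.0 / 24.0, rel=1e-9)

    def test_invalid_arguments(self):
        tpl = Volume3D(np.zeros((32, 32, 32)), unit="ppm")
        with pytest.raises(ValueError):
            analytic_sphere_field(1.0, -1.0, (16, 16, 16), tpl)
        with pytest.raises(ValueError):
            analytic_sphere_field(1.0, 20.0, (16, 16, 16), tpl)  # pokes out


class TestSphereOracle:
    """FFT forward field vs the analytic free-space solution."""

    def test_padded_forward_matches_analytic_exterior(self):
        tpl, chi, center, r = sphere_setup(n=96, a=8.0)
        f_fft = forward_dipole_field_padded(chi, pad=2)
        f_an = analytic_sphere_field(1.0, 8.0, center, tpl)
        shell = (r >= 12.0) & (r <= 24.0)
        err = f_fft.data[shell] - f_an.data[shell]
        rel_rms = np.sqrt(np.mean(err**2) / np.mean(f_an.data[shell] ** 2))
        assert rel_rms < 0.05

    def test_interior_shift_vanishes(self):
        tpl, chi, center, r = sphere_setup(n=96, a=8.0)
        f_fft = forward_dipole_field_padded(chi, pad=2)
        interior = r <= 8.0 - 1.0
        assert np.mean(np.abs(f_fft.data[interior])) < 0.01 * (1.0 / 3.0)

    def test_rasterize_sphere_volume(self):
        tpl = Volume3D(np.zeros((48, 48, 48)), unit="ppm")
        cov = rasterize_sphere(tpl, (24.0, 24.0, 24.0), 6.0)
        assert cov.sum() == pytest.approx(4.0 / 3.0 * np.pi * 6.0**3, rel=0.01)
        assert cov.max() == 1.0
        assert cov.min() == 0.0
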