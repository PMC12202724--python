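"""Dipole forward physics for susceptibility-induced Larmor frequency shifts.

The frequency shift caused by a susceptibility distribution chi is the 3D
convolution of chi with the unit magnetic dipole response.  In k-space the
(Lorentz-sphere-corrected) response is

    D(k) = 1/3 - (k . b0)^2 / ||k||^2,        D(0) = 0,

so D ranges over [-2/3, 1/3] and vanishes on the magic-angle cone
cos^2(theta_k) = 1/3.  The extended forward model adds a macroscopically
nondipolar shift f_rho on top of the dipolar field:

    f = d * chi + f_rho.

All convolutions here assume periodic boundaries; use ``pad`` to suppress
wrap-around in free-space simulations (the analytic-sphere oracle).
"""

from __future__ import annotations

import numpy as np

from .volumes import KSpaceKernel, Volume3D, _as_unit_vector

__all__ = [
    "build_dipole_kernel",
    "forward_dipole_field",
    "forward_dipole_field_padded",
    "quasar_forward",
    "analytic_sphere_field",
    "rasterize_sphere",
]


def build_dipole_kernel(shape, voxel_size=(1.0, 1.0, 1.0), b0_dir=(0.0, 0.0, 1.0)) -> KSpaceKernel:
    """Sample the k-space unit dipole response on an FFT grid.

    Parameters
    ----------
    shape:
        Grid dimensions (three ints, each >= 2).
    voxel_size:
        Voxel edge lengths in mm; frequencies are physical (1/mm), so
        anisotropic voxels are handled correctly.
    b0_dir:
        Main-field direction (normalized internally).

    Returns
    -------
    KSpaceKernel
        D(k) on the unshifted FFT grid, with the zero-frequency bin set to
        exactly 0.
    """
    shape = tuple(int(n) for n in shape)
    if len(shape) != 3 or any(n < 2 for n in shape):
        raise ValueError(f"grid shape must be three dims >= 2, got {shape!r}")
    vs = tuple(float(v) for v in voxel_size)
    if any(v <= 0 or not np.isfinite(v) for v in vs):
        raise ValueError(f"voxel_size must be positive, got {voxel_size!r}")
    b0 = _as_unit_vector(b0_dir)

    kx = np.fft.fftfreq(shape[0], d=vs[0])
    ky = np.fft.fftfreq(shape[1], d=vs[1])
    kz = np.fft.fftfreq(shape[2], d=vs[2])
    KX, KY, KZ = np.meshgrid(kx, ky, kz, indexing="ij", sparse=True)

    k2 = KX**2 + KY**2 + KZ**2
    kb = KX * b0[0] + KY * b0[1] + KZ * b0[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        values = 1.0 / 3.0 - kb**2 / k2
    values[0, 0, 0] = 0.0  # singular DC bin: the d(0)=0 convention
    return KSpaceKernel(values=values, voxel_size=vs, b0_dir=tuple(b0))


def _check_grid(vol: Volume3D, kernel: KSpaceKernel) -> None:
    if not kernel.matches(vol):
        raise ValueError(
            f"volume grid {vol.shape}/{vol.voxel_size}/{vol.b0_dir} does not match "
            f"kernel grid {kernel.shape}/{kernel.voxel_size}/{kernel.b0_dir}"
        )


def forward_dipole_field(chi: Volume3D, kernel: KSpaceKernel) -> Volume3D:
    """Dipolar frequency shift f_chi = IFFT(D . FFT(chi)).

    Output is real, in the same units as chi (ppm in, ppm out), and linear
    in chi.  Periodic boundaries.
    """
    _check_grid(chi, kernel)
    spec = np.fft.fftn(chi.data.astype(np.float64))
    f = np.fft.ifftn(spec * kernel.values).real
    return chi.with_data(f)


def forward_dipole_field_padded(chi: Volume3D, pad: int = 2) -> Volume3D:
    """Forward dipole field with zero-padding to emulate free space.

    The FFT convolution is circular; zero-padding each axis by the factor
    ``pad`` (default x2) and cropping back suppresses wrap-around from the
    periodic images, which matters when comparing against the analytic
    free-space sphere field.
    """
    if pad < 1:
        raise ValueError("pad factor must be >= 1")
    shape = chi.shape
    big = tuple(int(round(n * pad)) for n in shape)
    data = np.zeros(big, dtype=np.float64)
    data[: shape[0], : shape[1], : shape[2]] = chi.data
    kernel = build_dipole_kernel(big, chi.voxel_size, chi.b0_dir)
    f = np.fft.ifftn(np.fft.fftn(data) * kernel.values).real
    return chi.with_data(f[: shape[0], : shape[1], : shape[2]])


def quasar_forward(chi: Volume3D, f_rho: Volume3D, kernel: KSpaceKernel) -> Volume3D:
    """Extended forward model f = (d * chi) + f_rho."""
    _check_grid(chi, kernel)
    _check_grid(f_rho, kernel)
    if chi.unit != f_rho.unit:
        raise ValueError(f"unit mismatch: chi is {chi.unit}, f_rho is {f_rho.unit}")
    f_chi = forward_dipole_field(chi, kernel)
    return f_chi.with_data(f_chi.data + f_rho.data)


def _physical_coords(template: Volume3D):
    """Voxel-center coordinates in mm, one sparse axis array per dimension."""
    axes = [np.arange(n, dtype=float) * v
            for n, v in zip(template.shape, template.voxel_size)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def analytic_sphere_field(chi_contrast: float, radius: float, center, template: Volume3D) -> Volume3D:
    """Closed-form frequency shift of a uniformly magnetized sphere.

    Exterior: (chi_contrast/3) (a/r)^3 (3 cos^2 theta - 1), theta measured
    from b0.  Interior: 0 (the Lorentz-corrected shift inside a uniform
    sphere vanishes).  Serves as the free-space oracle for the FFT forward
    model.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    center = np.asarray(center, dtype=float).reshape(3)
    extent = np.array(template.shape) * np.array(template.voxel_size)
    if np.any(center - radius < 0) or np.any(center + radius > extent):
        raise ValueError("sphere must lie fully inside the grid")

    X, Y, Z = _physical_coords(template)
    dx, dy, dz = X - center[0], Y - center[1], Z - center[2]
    r2 = dx**2 + dy**2 + dz**2
    b0 = np.asarray(template.b0_dir)
    rb = dx * b0[0] + dy * b0[1] + dz * b0[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        cos2 = rb**2 / r2
        shell = (chi_contrast / 3.0) * (radius**2 / r2) ** 1.5 * (3.0 * cos2 - 1.0)
    field = np.where(r2 <= radius**2, 0.0, shell)
    field[r2 == 0] = 0.0
    return template.with_data(field, unit="ppm")


def rasterize_sphere(template: Volume3D, center, radius: float, value: float = 1.0,
                     supersample: int = 3) -> np.ndarray:
    """Anti-aliased sphere indicator: boundary voxels get fractional coverage.

    Coverage is estimated by ``supersample``^3 subvoxel sampling, which
    reduces the staircase error of the FFT forward field against the
    analytic oracle.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    center = np.asarray(center, dtype=float).reshape(3)
    vs = np.asarray(template.voxel_size)
    X, Y, Z = _physical_coords(template)
    r2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
    # voxels whose center is further than half the voxel diagonal from the
    # surface are entirely in or out; only the boundary shell is supersampled
    half_diag = float(np.linalg.norm(vs)) / 2.0
    inside = r2 <= (radius - half_diag) ** 2
    boundary = (~inside) & (r2 <= (radius + half_diag) ** 2)
    cov = inside.astype(float)

    if np.any(boundary):
        idx = np.argwhere(boundary)
        offs = (np.arange(supersample) + 0.5) / supersample - 0.5
        ox, oy, oz = np.meshgrid(offs * vs[0], offs * vs[1], offs * vs[2], indexing="ij")
        sub = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)  # (s^3, 3)
        centers = idx * vs  # physical voxel centers
        pts = centers[:, None, :] + sub[None, :, :] - center
        frac = np.mean(np.sum(pts**2, axis=2) <= radius**2, axis=1)
        cov[idx[:, 0], idx[:, 1], idx[:, 2]] = frac
    return value * cov
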