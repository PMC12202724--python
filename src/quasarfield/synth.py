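"""Pseudo-random synthetic training volumes for learned dipole inversion.

Training a network to invert the frequency-to-susceptibility map does not
require anatomical images: it requires fields with realistic second-order
statistics.  The generators here produce susceptibility (chi) and
nondipolar-shift (f_rho) volumes as sums of organic blob shapes and
power-law spectral textures (power spectral densities similar to natural
images), magnitude maps with dark regions, and total frequency maps
composed through the extended forward model with magnitude-dependent
Gaussian noise: dark magnitude regions get proportionally noisier
frequency values.

Everything is a pure function of (config, seed): the same seed always
yields bit-identical volumes, and each component (chi, f_rho, magnitude,
mask, noise) draws from an independent child stream, so zeroing one
component's amplitude never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .dipole import build_dipole_kernel, quasar_forward
from .volumes import Volume3D

__all__ = [
    "SynthesisConfig",
    "TrainingSample",
    "spectral_noise_field",
    "organic_shapes",
    "synthesize_chi",
    "synthesize_f_rho",
    "synthesize_magnitude",
    "synthesize_mask",
    "add_magnitude_noise",
    "make_training_sample",
    "radial_psd_slope",
    "cone_anisotropy_ratio",
    "magic_angle_enrichment",
]

# spawn keys of the independent child streams of a sample seed
_STREAM_CHI = 0
_STREAM_FRHO = 1
_STREAM_MAG = 2
_STREAM_MASK = 3
_STREAM_NOISE = 4


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(stream,)))


@dataclass(frozen=True)
class SynthesisConfig:
    """Knobs of the synthetic-sample generator.

    ``chi_amplitude_range`` / ``frho_amplitude_range`` bound the peak
    absolute value (ppm) of the signed fields: each draw picks a peak
    amplitude uniformly from the range.  ``psd_exponent_range`` is the
    power-law exponent beta of the texture spectra (P(k) ~ ||k||^-beta),
    drawn uniformly per field.  ``snr`` scales the magnitude-dependent
    frequency noise; the default matches the SNR used for the digital
    brain evaluation.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    psd_exponent_range: tuple[float, float] = (1.5, 3.0)
    n_shapes_range: tuple[int, int] = (3, 8)
    chi_amplitude_range: tuple[float, float] = (0.05, 0.2)
    frho_amplitude_range: tuple[float, float] = (0.01, 0.05)
    snr: float = 100.0
    mask_fill_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("psd_exponent_range", "n_shapes_range",
                     "chi_amplitude_range", "frho_amplitude_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered (low <= high), got {(lo, hi)!r}")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if not (0 < self.mask_fill_fraction <= 1):
            raise ValueError("mask_fill_fraction must lie in (0, 1]")

    def with_seed(self, seed: int) -> "SynthesisConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class TrainingSample:
    """One synthesis draw: (chi, f_rho, magnitude, f_total, mask) + noise.

    ``f_total = d*chi + f_rho + noise`` with the noise realization stored
    so the composition is exactly reconstructible; noise is zero outside
    the mask by convention.
    """

    chi: Volume3D
    f_rho: Volume3D
    magnitude: Volume3D
    f_total: Volume3D
    mask: Volume3D
    noise: Volume3D
    seed: int


def spectral_noise_field(shape: Sequence[int], beta: float, seed: int) -> Volume3D:
    """Zero-mean, unit-variance field with an isotropic power-law spectrum.

    The amplitude spectrum is shaped as ||k||^(-beta/2), so the radially
    averaged power spectrum follows ||k||^(-beta); beta = 0 is white noise.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    shape = tuple(int(n) for n in shape)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(shape)
    spec = np.fft.fftn(white)
    k = _knorm_grid(shape)
    with np.errstate(divide="ignore"):
        amp = np.where(k > 0, k ** (-beta / 2.0), 0.0)
    field = np.fft.ifftn(spec * amp).real
    field -= field.mean()
    sd = field.std()
    if sd > 0:
        field /= sd
    return Volume3D(field, unit="arbitrary")


def _knorm_grid(shape) -> np.ndarray:
    axes = [np.fft.fftfreq(n) for n in shape]
    KX, KY, KZ = np.meshgrid(*axes, indexing="ij", sparse=True)
    return np.sqrt(KX**2 + KY**2 + KZ**2)


def isotropic_lowpass(field: np.ndarray, sigma: float, pad: int = 0) -> np.ndarray:
    """Gaussian low-pass with an exactly isotropic transfer function.

    Applied in the Fourier domain as exp(-2 pi^2 sigma^2 ||k||^2) (sigma in
    voxels).  Unlike separable truncated spatial filtering, this leaves the
    field's spectral isotropy intact — which the f_rho generator contract
    depends on.  ``pad`` zero-pads each axis by that many voxels before the
    FFT (and crops after) to suppress periodic wrap-around, which matters
    when smoothing compact indicators rather than stationary noise.
    """
    if pad:
        field = np.pad(field, pad)
    k = _knorm_grid(field.shape)
    transfer = np.exp(-2.0 * np.pi**2 * sigma**2 * k**2)
    out = np.fft.ifftn(np.fft.fftn(field) * transfer).real
    if pad:
        out = out[pad:-pad, pad:-pad, pad:-pad]
    return out


def organic_shapes(shape: Sequence[int], n_shapes: int, smoothness: float, seed: int) -> Volume3D:
    """Piecewise-smooth blob field: n_shapes connected supports, random intensities.

    Each blob is the largest 26-connected component of a thresholded
    isotropically low-pass-filtered Gaussian random field.  Blob edges are
    softened (isotropic smoothing of the indicator, with the sub-2% tail
    clipped to keep the support compact): hard voxelized edges would leave
    an axis-aligned facet signature in the power spectrum, which the
    spectral-isotropy contract of f_rho forbids.  Blobs carry random signed
    intensities and the sum is normalized into [-1, 1].
    """
    if n_shapes < 0:
        raise ValueError("n_shapes must be >= 0")
    shape = tuple(int(n) for n in shape)
    rng = np.random.default_rng(seed)
    out = np.zeros(shape, dtype=float)
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    # keep blob supports away from the faces so the softened edges decay
    # inside the volume: otherwise the truncation at the boundary leaves
    # axis-aligned spectral energy (or wrap-around fragments)
    margin = min(7, min(shape) // 4)
    interior = np.zeros(shape, dtype=bool)
    interior[margin: shape[0] - margin,
             margin: shape[1] - margin,
             margin: shape[2] - margin] = True
    for _ in range(int(n_shapes)):
        smooth = isotropic_lowpass(rng.standard_normal(shape), smoothness)
        q = rng.uniform(0.90, 0.98)
        mask = (smooth > np.quantile(smooth, q)) & interior
        lab, n = ndimage.label(mask, structure=structure)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        blob = lab == (1 + int(np.argmax(sizes)))
        soft = isotropic_lowpass(blob.astype(float), 1.5, pad=8)
        # clip the far Gaussian tail so the support stays compact; the level
        # is below the value any voxel of the blob itself can take, so the
        # support remains one connected component per blob
        soft[soft < 0.001] = 0.0
        intensity = rng.uniform(0.2, 1.0) * rng.choice([-1.0, 1.0])
        out += intensity * soft
    peak = np.abs(out).max()
    if peak > 0:
        out /= peak
    return Volume3D(out, unit="arbitrary")


def _textured_field(config: SynthesisConfig, amplitude_range, stream: int) -> Volume3D:
    """Shared chi / f_rho generator: organic shapes plus spectral texture,
    scaled to a peak amplitude drawn from ``amplitude_range`` (ppm)."""
    rng = _child_rng(config.seed, stream)
    sub = rng.integers(0, 2**31 - 1, size=4)
    amp = rng.uniform(*amplitude_range)
    if amp == 0:
        return Volume3D(np.zeros(config.grid_shape), config.voxel_size, unit="ppm")
    n_shapes = int(rng.integers(config.n_shapes_range[0], config.n_shapes_range[1] + 1))
    beta = rng.uniform(*config.psd_exponent_range)
    smoothness = rng.uniform(2.0, 5.0)
    shapes = organic_shapes(config.grid_shape, n_shapes, smoothness, int(sub[0]))
    texture = spectral_noise_field(config.grid_shape, beta, int(sub[1]))
    texture_weight = rng.uniform(0.1, 0.4)
    field = shapes.data + texture_weight * texture.data / max(np.abs(texture.data).max(), 1e-12)
    peak = np.abs(field).max()
    if peak > 0:
        field *= amp / peak
    return Volume3D(field, config.voxel_size, unit="ppm")


def synthesize_chi(config: SynthesisConfig) -> Volume3D:
    """Draw a synthetic susceptibility volume (ppm)."""
    return _textured_field(config, config.chi_amplitude_range, _STREAM_CHI)


def synthesize_f_rho(config: SynthesisConfig) -> Volume3D:
    """Draw a nondipolar-shift volume (ppm): same generator family as chi,
    statistically independent, and spectrally isotropic — it carries none of
    the anisotropic dipole-cone imprint that d*chi has."""
    return _textured_field(config, config.frho_amplitude_range, _STREAM_FRHO)


def synthesize_magnitude(config: SynthesisConfig) -> Volume3D:
    """Smooth positive magnitude map in (0.05, 1] with dark regions.

    The field is rank-transformed to uniform and squared, which guarantees
    a substantial dark fraction (values < 0.2) so that magnitude-dependent
    noise scaling is exercised during training.
    """
    eps = 0.05
    rng = _child_rng(config.seed, _STREAM_MAG)
    smooth = ndimage.gaussian_filter(rng.standard_normal(config.grid_shape),
                                     sigma=rng.uniform(3.0, 6.0))
    flat = smooth.ravel()
    ranks = np.empty_like(flat)
    ranks[np.argsort(flat, kind="stable")] = np.arange(1, flat.size + 1)
    u = (ranks / flat.size).reshape(config.grid_shape)
    mag = eps + (1.0 - eps) * u**2
    return Volume3D(mag, config.voxel_size, unit="arbitrary")


def synthesize_mask(config: SynthesisConfig) -> Volume3D:
    """Random smooth blob covering ``mask_fill_fraction`` of the volume."""
    rng = _child_rng(config.seed, _STREAM_MASK)
    smooth = ndimage.gaussian_filter(rng.standard_normal(config.grid_shape),
                                     sigma=rng.uniform(4.0, 8.0))
    thr = np.quantile(smooth, 1.0 - config.mask_fill_fraction)
    return Volume3D((smooth >= thr).astype(float), config.voxel_size, unit="dimensionless")


def add_magnitude_noise(f: Volume3D, magnitude: Volume3D, snr: float, seed: int,
                        sigma0: float | None = None) -> Volume3D:
    """Add zero-mean Gaussian noise with per-voxel std sigma0 / (snr * magnitude).

    ``sigma0`` defaults to the std of ``f``; low (dark) magnitude regions
    therefore get proportionally higher frequency noise.
    """
    if not f.same_grid(magnitude):
        raise ValueError("f and magnitude grids do not match")
    if snr <= 0:
        raise ValueError("snr must be positive")
    if np.any(magnitude.data <= 0):
        raise ValueError("magnitude must be strictly positive everywhere")
    if sigma0 is None:
        sigma0 = float(f.data.std())
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(f.shape) * (sigma0 / (snr * magnitude.data))
    return f.with_data(f.data + noise)


def make_training_sample(config: SynthesisConfig) -> TrainingSample:
    """Compose one full sample through the extended forward model.

    f_total = d*chi + f_rho + noise, noise zeroed outside the mask.  Fully
    reproducible from ``config.seed``; chi / f_rho / magnitude / mask /
    noise use independent child streams.
    """
    chi = synthesize_chi(config)
    f_rho = synthesize_f_rho(config)
    magnitude = synthesize_magnitude(config)
    mask = synthesize_mask(config)
    kernel = build_dipole_kernel(config.grid_shape, config.voxel_size, chi.b0_dir)
    f_clean = quasar_forward(chi, f_rho, kernel)

    sigma0 = float(f_clean.data.std())
    noise_seed = _child_rng(config.seed, _STREAM_NOISE).integers(0, 2**31 - 1)
    noisy = add_magnitude_noise(f_clean, magnitude, config.snr, int(noise_seed), sigma0=sigma0)
    noise = (noisy.data - f_clean.data) * mask.data
    f_total = f_clean.with_data(f_clean.data + noise)
    return TrainingSample(chi=chi, f_rho=f_rho, magnitude=magnitude,
                          f_total=f_total, mask=mask,
                          noise=f_clean.with_data(noise), seed=config.seed)


# ---------------------------------------------------------------------------
# spectral diagnostics


def radial_psd_slope(field: np.ndarray, kmin: float = 0.03, kmax: float = 0.25) -> float:
    """Log-log slope of the radially averaged power spectrum.

    Frequencies in cycles/voxel; DC and near-Nyquist shells outside
    [kmin, kmax] are excluded from the fit.  A field generated with
    exponent beta fits a slope close to -beta.
    """
    field = np.asarray(field, dtype=float)
    power = np.abs(np.fft.fftn(field)) ** 2
    k = _knorm_grid(field.shape)
    nbins = 24
    edges = np.linspace(kmin, kmax, nbins + 1)
    centers, means = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (k >= lo) & (k < hi)
        if np.any(sel):
            centers.append(0.5 * (lo + hi))
            means.append(power[sel].mean())
    centers, means = np.asarray(centers), np.asarray(means)
    good = means > 0
    if good.sum() < 3:
        raise ValueError("too few nonzero spectral bins for a slope fit")
    slope = np.polyfit(np.log(centers[good]), np.log(means[good]), 1)[0]
    return float(slope)


def cone_anisotropy_ratio(fields, b0_dir=(0.0, 0.0, 1.0),
                          half_angle_deg: float = 10.0,
                          k_range: tuple[float, float] = (0.05, 0.4),
                          n_shells: int = 8) -> float:
    """PSD energy near the b0 axis relative to the orthogonal band.

    Within each radial k-shell the mean power per bin inside the polar caps
    (within ``half_angle_deg`` of the b0 axis) is divided by the mean power
    per bin in the equatorial belt; shell ratios are averaged.  Comparing
    per-bin means makes the statistic solid-angle normalized on the discrete
    grid without analytic-area bias.

    ``fields`` may be a single 3D array or an iterable of draws; power
    spectra of multiple draws are ensemble-averaged first, which is how the
    *statistical* isotropy of a generator should be measured (single draws
    of blob fields have large orientation variance).

    Spectrally isotropic fields give a ratio near 1; dipole-convolved
    fields are boosted along the axis (D^2 = 4/9 there vs 1/9 near the
    equator) and deviate strongly.
    """
    if isinstance(fields, np.ndarray) and fields.ndim == 3:
        fields = [fields]
    power = None
    for f in fields:
        p = np.abs(np.fft.fftn(np.asarray(f, dtype=float))) ** 2
        power = p if power is None else power + p
    if power is None:
        raise ValueError("no fields given")

    whitened, k, cos_t = _whitened_power(power, b0_dir)
    a = np.deg2rad(half_angle_deg)
    in_range = (k >= k_range[0]) & (k < k_range[1])
    axis_band = in_range & (cos_t >= np.cos(a))
    eq_band = in_range & (cos_t <= np.sin(a))
    if axis_band.sum() < 10 or eq_band.sum() < 10:
        raise ValueError("too few k-bins in the anisotropy bands")
    ratio = np.nanmean(whitened[axis_band]) / np.nanmean(whitened[eq_band])
    return float(ratio)


def _whitened_power(power: np.ndarray, b0_dir):
    """Power spectrum whitened by its finely-binned isotropic radial profile.

    Dividing each bin by the shell mean removes radial-spectrum leakage
    (red spectra otherwise dominate any angular-band comparison on a
    discrete grid).  Returns (whitened, ||k||, |cos angle to b0|).
    """
    axes = [np.fft.fftfreq(n) for n in power.shape]
    KX, KY, KZ = np.meshgrid(*axes, indexing="ij", sparse=True)
    k = np.sqrt(KX**2 + KY**2 + KZ**2)
    b0 = np.asarray(b0_dir, dtype=float)
    b0 = b0 / np.linalg.norm(b0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos_t = np.abs(KX * b0[0] + KY * b0[1] + KZ * b0[2]) / k
    fine = max(power.shape)
    bin_idx = np.minimum((k * fine * 2).astype(int), 2 * fine - 1)
    counts = np.bincount(bin_idx.ravel(), minlength=2 * fine)
    sums = np.bincount(bin_idx.ravel(), weights=power.ravel(), minlength=2 * fine)
    profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return power / profile[bin_idx], k, cos_t


#: angle (degrees) from b0 at which the dipole response vanishes
MAGIC_ANGLE_DEG = float(np.degrees(np.arccos(np.sqrt(1.0 / 3.0))))


def magic_angle_enrichment(field: np.ndarray, b0_dir=(0.0, 0.0, 1.0),
                           half_angle_deg: float = 10.0,
                           k_range: tuple[float, float] = (0.05, 0.45)) -> float:
    """Whitened spectral-energy enrichment of the magic-angle cone band.

    Mean whitened power of the bins whose angle to b0 lies within
    ``half_angle_deg`` of the magic angle (54.74 deg), relative to the mean
    over all bins in ``k_range`` — i.e. the factor by which the band
    exceeds its solid-angle-proportional share.  Spectrally isotropic
    fields give ~1; fields produced by deconvolving nondipolar content sit
    well above 1 because the inverse filter amplifies the cone.
    """
    field = np.asarray(field, dtype=float)
    power = np.abs(np.fft.fftn(field)) ** 2
    whitened, k, cos_t = _whitened_power(power, b0_dir)
    with np.errstate(invalid="ignore"):
        theta = np.degrees(np.arccos(np.clip(cos_t, 0.0, 1.0)))
    sel = (k >= k_range[0]) & (k < k_range[1])
    band = sel & (np.abs(theta - MAGIC_ANGLE_DEG) <= half_angle_deg)
    if band.sum() < 10:
        raise ValueError("too few k-bins in the magic-angle band")
    return float(np.nanmean(whitened[band]) / np.nanmean(whitened[sel]))
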