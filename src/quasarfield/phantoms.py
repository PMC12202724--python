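"""Digital evaluation phantoms with known ground truth.

Two families:

* a three-sphere scene separating the two contrast mechanisms — one sphere
  carries susceptibility only, one carries a nondipolar shift only, one
  carries both — used to illustrate how dipole deconvolution misattributes
  nondipolar shifts to susceptibility;
* a procedurally generated brain-like model (nested smooth surrogates for
  brain mask, ventricular CSF, bilateral white-matter lobes, a cortical
  ribbon and six deep-gray-matter nuclei with a ladder of paramagnetic
  susceptibilities), built in paired variants without and with
  "microstructure": a smooth nondipolar frequency field confined to the
  white matter.  The paired variants share identical susceptibility truth,
  labels and mask, so before/after comparisons isolate the effect of the
  nondipolar term.

The brain model is a stand-in for a realistic digital brain (no external
data is downloaded); its white-matter nondipolar field is a band-limited
random field under a smooth envelope, emulating fiber-architecture
contrast rather than deriving it from diffusion data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dipole import build_dipole_kernel, quasar_forward, rasterize_sphere
from .synth import isotropic_lowpass, spectral_noise_field
from .volumes import LabelVolume, PHANTOM_LEGEND, Volume3D

__all__ = [
    "PhantomBundle",
    "make_three_sphere_scene",
    "make_brain_phantom",
    "simulate_measurement",
    "DGM_CHI_LADDER",
]

#: construction susceptibilities (ppm) of the six DGM nuclei — a ladder of
#: pairwise-distinct paramagnetic values in the order caudate, globus
#: pallidus, putamen, red nucleus, dentate nucleus, thalamus, spanning the
#: published order of magnitude for iron-rich nuclei
DGM_CHI_LADDER = {
    "caudate": 0.048,
    "globus_pallidus": 0.160,
    "putamen": 0.076,
    "red_nucleus": 0.104,
    "dentate_nucleus": 0.132,
    "thalamus": 0.020,
}

_TISSUE_CHI = {"CSF": -0.045, "WM": -0.030, "cortex": 0.010}

_LABEL_OF = {name: code for code, name in PHANTOM_LEGEND.items()}


@dataclass(frozen=True)
class PhantomBundle:
    """Ground-truth volumes of one phantom realization."""

    chi_truth: Volume3D
    f_rho_truth: Volume3D
    labels: LabelVolume
    brain_mask: Volume3D
    with_microstructure: bool

    def __post_init__(self):
        if not self.with_microstructure and np.any(self.f_rho_truth.data != 0):
            raise ValueError("f_rho_truth must be identically zero without microstructure")


def make_three_sphere_scene(grid=(64, 64, 64), chi_amplitude: float = 0.1,
                            frho_amplitude: float = 0.1, radius_frac: float = 0.10) -> PhantomBundle:
    """Three spheres along x: chi only (left), chi + f_rho (middle), f_rho only (right)."""
    grid = tuple(int(n) for n in grid)
    if min(grid) < 64:
        raise ValueError("three-sphere scene needs a grid of at least 64^3")
    tpl = Volume3D(np.zeros(grid), unit="ppm")
    a = radius_frac * min(grid)
    cy, cz = grid[1] / 2.0, grid[2] / 2.0
    centers = [(grid[0] * x, cy, cz) for x in (0.25, 0.5, 0.75)]
    # 2-voxel clearance so anti-aliased boundary shells cannot touch
    if 2 * a + 2.0 >= grid[0] * 0.25:
        raise ValueError("spheres overlap; reduce radius_frac")

    left = rasterize_sphere(tpl, centers[0], a)
    middle = rasterize_sphere(tpl, centers[1], a)
    right = rasterize_sphere(tpl, centers[2], a)

    chi = chi_amplitude * (left + middle)
    f_rho = frho_amplitude * (middle + right)
    labels = np.zeros(grid, dtype=np.int32)
    for i, sph in enumerate((left, middle, right), start=1):
        labels[sph > 0] = i  # include partially covered boundary voxels
    legend = {0: "background", 1: "chi_sphere", 2: "both_sphere", 3: "frho_sphere"}
    mask = Volume3D(np.ones(grid), unit="dimensionless")
    return PhantomBundle(
        chi_truth=tpl.with_data(chi),
        f_rho_truth=tpl.with_data(f_rho),
        labels=LabelVolume(labels, legend),
        brain_mask=mask,
        with_microstructure=bool(frho_amplitude != 0),
    )


def _ellipsoid(shape, center, semi, orient_jitter: np.ndarray | None = None) -> np.ndarray:
    """Boolean ellipsoid; optional small random rotation via a jitter matrix."""
    idx = np.indices(shape, dtype=float)
    d = idx - np.asarray(center, dtype=float).reshape(3, 1, 1, 1)
    if orient_jitter is not None:
        d = np.einsum("ij,jxyz->ixyz", orient_jitter, d)
    semi = np.asarray(semi, dtype=float).reshape(3, 1, 1, 1)
    return np.sum((d / semi) ** 2, axis=0) <= 1.0


def make_brain_phantom(grid=(96, 96, 96), with_microstructure: bool = False,
                       seed: int = 0) -> PhantomBundle:
    """Brain-like labeled phantom, paired across the microstructure flag.

    The susceptibility truth, labels and brain mask depend only on
    ``(grid, seed)``; the flag switches the white-matter nondipolar field
    on or off.  DGM nuclei are bilateral ellipsoids with the construction
    susceptibilities of :data:`DGM_CHI_LADDER`.
    """
    grid = tuple(int(n) for n in grid)
    n0, n1, n2 = grid
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(10,)))
    c = np.array(grid) / 2.0

    labels = np.zeros(grid, dtype=np.int32)
    brain = _ellipsoid(grid, c, (0.42 * n0, 0.38 * n1, 0.36 * n2))

    # cortical ribbon: outer shell of the brain ellipsoid
    inner = _ellipsoid(grid, c, (0.36 * n0, 0.32 * n1, 0.30 * n2))
    labels[brain] = _LABEL_OF["cortex"]

    # bilateral WM lobes filling most of the interior
    wm = np.zeros(grid, dtype=bool)
    for side in (-1.0, 1.0):
        ctr = c + np.array([side * 0.13 * n0, 0.0, 0.0])
        wm |= _ellipsoid(grid, ctr, (0.20 * n0, 0.27 * n1, 0.25 * n2))
    wm &= inner
    labels[wm] = _LABEL_OF["WM"]

    # central CSF "ventricles": two elongated diamagnetic cavities
    csf = np.zeros(grid, dtype=bool)
    for side in (-1.0, 1.0):
        ctr = c + np.array([side * 0.06 * n0, -0.02 * n1, 0.02 * n2])
        csf |= _ellipsoid(grid, ctr, (0.035 * n0, 0.16 * n1, 0.05 * n2))
    labels[csf] = _LABEL_OF["CSF"]

    # six bilateral DGM nuclei at mid-depth positions around the ventricles
    nucleus_geom = {
        "caudate": ((0.11, -0.10, 0.06), (0.045, 0.075, 0.045)),
        "globus_pallidus": ((0.17, 0.02, 0.00), (0.045, 0.05, 0.04)),
        "putamen": ((0.22, -0.03, 0.05), (0.05, 0.08, 0.05)),
        "red_nucleus": ((0.045, 0.09, -0.05), (0.03, 0.03, 0.03)),
        "dentate_nucleus": ((0.13, 0.18, -0.14), (0.04, 0.04, 0.035)),
        "thalamus": ((0.09, 0.06, 0.08), (0.055, 0.075, 0.05)),
    }
    for name, (off, semi) in nucleus_geom.items():
        for side in (-1.0, 1.0):
            ctr = c + np.array([side * off[0] * n0, off[1] * n1, off[2] * n2])
            nuc = _ellipsoid(grid, ctr, (semi[0] * n0, semi[1] * n1, semi[2] * n2))
            labels[nuc & brain] = _LABEL_OF[name]

    chi = np.zeros(grid, dtype=float)
    chi[labels == _LABEL_OF["cortex"]] = _TISSUE_CHI["cortex"]
    chi[labels == _LABEL_OF["WM"]] = _TISSUE_CHI["WM"]
    chi[labels == _LABEL_OF["CSF"]] = _TISSUE_CHI["CSF"]
    for name, val in DGM_CHI_LADDER.items():
        chi[labels == _LABEL_OF[name]] = val
    # mild smooth texture inside the brain so regions are not perfectly flat
    texture = isotropic_lowpass(rng.standard_normal(grid), 2.0)
    texture /= max(np.abs(texture).max(), 1e-12)
    chi += 0.004 * texture * brain

    mask = brain.astype(float)

    # WM-confined nondipolar field: band-limited random texture under a
    # smooth "tract density" envelope, with a positive mean component —
    # microstructure raises the voxel-average WM frequency, which is what
    # makes dipole inversions read WM as more paramagnetic than it is.
    # Independent child stream so the chi truth is bit-identical across
    # the flag.
    f_rho = np.zeros(grid, dtype=float)
    if with_microstructure:
        rng_f = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(11,)))
        carrier = spectral_noise_field(grid, 1.5, int(rng_f.integers(2**31 - 1))).data
        carrier = isotropic_lowpass(carrier, 1.0)
        carrier /= max(np.abs(carrier).max(), 1e-12)
        envelope = isotropic_lowpass(rng_f.standard_normal(grid), 6.0)
        envelope = np.abs(envelope) / max(np.abs(envelope).max(), 1e-12)
        # myelinated tissue shifts frequency throughout the WM: a floor of
        # 0.5 keeps the field present everywhere while the envelope and
        # band-limited carrier modulate it spatially
        f_rho = (0.5 + 0.5 * envelope) * (0.8 + 0.2 * carrier)
        f_rho *= labels == _LABEL_OF["WM"]
        peak = np.abs(f_rho).max()
        if peak > 0:
            f_rho *= 0.02 / peak  # 0.02 ppm peak amplitude

    tpl = Volume3D(np.zeros(grid), unit="ppm")
    return PhantomBundle(
        chi_truth=tpl.with_data(chi),
        f_rho_truth=tpl.with_data(f_rho),
        labels=LabelVolume(labels),
        brain_mask=Volume3D(mask, unit="dimensionless"),
        with_microstructure=bool(with_microstructure),
    )


def simulate_measurement(bundle: PhantomBundle, snr: float = 100.0, seed: int = 0,
                         outside_magnitude: float = 0.05) -> Volume3D:
    """Noisy total frequency map of a phantom, masked to the brain.

    f_total = (d * chi_truth + f_rho_truth + noise) restricted to the brain
    mask.  Noise is zero-mean Gaussian with per-voxel std sigma0 / (snr *
    magnitude), magnitude = 1 inside the brain and ``outside_magnitude``
    outside; sigma0 is the within-mask std of the clean signal.  The
    default SNR of 100 matches the simulation setting used for evaluation.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    chi, f_rho = bundle.chi_truth, bundle.f_rho_truth
    kernel = build_dipole_kernel(chi.shape, chi.voxel_size, chi.b0_dir)
    f_clean = quasar_forward(chi, f_rho, kernel)
    mask = bundle.brain_mask.data > 0
    magnitude = np.where(mask, 1.0, outside_magnitude)
    sigma0 = float(f_clean.data[mask].std())
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(chi.shape) * (sigma0 / (snr * magnitude))
    return f_clean.with_data((f_clean.data + noise) * mask)
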