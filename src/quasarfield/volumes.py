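"""Core in-memory containers for 3D scalar fields and k-space kernels.

Susceptibility (chi), frequency shifts (f, f_chi, f_rho) and magnitude maps
are all carried as :class:`Volume3D`: a real 3D array plus the physical
metadata (voxel size in mm, main-field direction) that the dipole physics
depends on.  Frequency shifts are stored as dimensionless relative shifts in
ppm of the Larmor frequency, so a susceptibility in ppm maps to a frequency
shift in ppm without TE/gamma/B0 factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = ["Volume3D", "KSpaceKernel", "LabelVolume", "DEFAULT_B0"]

DEFAULT_B0 = (0.0, 0.0, 1.0)

_UNIT_NORM_TOL = 1e-9


def _as_unit_vector(b0_dir) -> np.ndarray:
    v = np.asarray(b0_dir, dtype=float).reshape(3)
    n = float(np.linalg.norm(v))
    if not np.isfinite(n) or n < 1e-12:
        raise ValueError(f"degenerate b0 direction {b0_dir!r}")
    return v / n


@dataclass(frozen=True)
class Volume3D:
    """A real scalar 3D field with voxel size (mm) and B0-direction metadata.

    Parameters
    ----------
    data:
        3D float array.  Must be finite unless ``allow_nonfinite`` is set
        (used for explicitly masked-out voxels).
    voxel_size:
        Edge lengths of a voxel in mm, one per axis, all positive.
    b0_dir:
        Unit vector of the main magnetic field in physical space.  Stored
        normalized; defaults to +z.
    unit:
        One of ``"ppm"``, ``"dimensionless"``, ``"arbitrary"``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    b0_dir: tuple[float, float, float] = DEFAULT_B0
    unit: str = "ppm"
    allow_nonfinite: bool = False

    def __post_init__(self):
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={arr.ndim}")
        if not self.allow_nonfinite and not np.all(np.isfinite(arr)):
            raise ValueError("volume contains non-finite values")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 or not np.isfinite(v) for v in vs):
            raise ValueError(f"voxel_size must be 3 positive reals, got {self.voxel_size!r}")
        b0 = _as_unit_vector(self.b0_dir)
        if abs(np.linalg.norm(b0) - 1.0) > _UNIT_NORM_TOL:
            raise ValueError("b0_dir could not be normalized")
        if self.unit not in ("ppm", "dimensionless", "arbitrary"):
            raise ValueError(f"unknown unit {self.unit!r}")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "voxel_size", vs)
        object.__setattr__(self, "b0_dir", tuple(b0))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, unit: str | None = None) -> "Volume3D":
        """Same grid metadata, new values."""
        return replace(self, data=np.asarray(data, dtype=float),
                       unit=self.unit if unit is None else unit)

    def same_grid(self, other: "Volume3D", atol: float = 1e-9) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.voxel_size, other.voxel_size, atol=atol)
                and np.allclose(self.b0_dir, other.b0_dir, atol=atol))


@dataclass(frozen=True)
class KSpaceKernel:
    """Unit dipole response D(k) sampled on the unshifted FFT grid.

    ``values`` lies in [-2/3, 1/3] with the singular zero-frequency bin set
    to 0 exactly (the d(0)=0 Lorentz-sphere convention).
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    b0_dir: tuple[float, float, float]

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 3:
            raise ValueError("kernel values must be a 3D array")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "b0_dir", tuple(_as_unit_vector(self.b0_dir)))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def matches(self, vol: Volume3D, atol: float = 1e-9) -> bool:
        return (self.shape == vol.shape
                and np.allclose(self.voxel_size, vol.voxel_size, atol=atol)
                and np.allclose(self.b0_dir, vol.b0_dir, atol=atol))


#: canonical label codes for the brain-like phantom
PHANTOM_LEGEND: Mapping[int, str] = {
    0: "background",
    1: "CSF",
    2: "WM",
    3: "cortex",
    4: "caudate",
    5: "globus_pallidus",
    6: "putamen",
    7: "red_nucleus",
    8: "dentate_nucleus",
    9: "thalamus",
}


@dataclass(frozen=True)
class LabelVolume:
    """Integer-coded anatomical regions with a label -> name legend."""

    labels: np.ndarray
    legend: Mapping[int, str] = field(default_factory=lambda: dict(PHANTOM_LEGEND))

    def __post_init__(self):
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise ValueError("labels must be integer-coded")
            arr = arr.astype(np.int32)
        if arr.min() < 0:
            raise ValueError("labels must be non-negative")
        object.__setattr__(self, "labels", arr)
        object.__setattr__(self, "legend", dict(self.legend))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask_of(self, name: str) -> np.ndarray:
        """Binary mask of the region with the given legend name."""
        for code, nm in self.legend.items():
            if nm == name:
                return self.labels == code
        raise KeyError(f"no label named {name!r}")

    def present_labels(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.labels) if v != 0)
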