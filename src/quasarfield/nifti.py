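"""NIfTI volume I/O.

Volumes are stored float32 on disk (float64 is used for FFT internals in
memory); voxel size comes from the header zooms and the affine is carried
through for round trips.  The B0 direction is not a NIfTI concept, so it is
supplied by the caller (CLI flag ``--b0``) and defaults to +z.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .volumes import Volume3D

__all__ = ["read_volume", "write_volume"]


def read_volume(path, b0_dir=(0.0, 0.0, 1.0), unit: str = "ppm") -> Volume3D:
    """Read a 3D NIfTI (.nii or .nii.gz) into a Volume3D.

    Raises FileNotFoundError for a missing path, and ValueError for
    volumes that are not 3D (time series must be split upstream).
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such volume: {p}")
    img = nib.load(str(p))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{p} has {data.ndim} dimensions; only 3D volumes are supported")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    vol = Volume3D(np.asarray(data, dtype=float), voxel_size, b0_dir, unit)
    object.__setattr__(vol, "_affine", img.affine)
    return vol


def write_volume(vol: Volume3D, path) -> None:
    """Write a Volume3D as float32 NIfTI, preserving a read affine if present."""
    affine = getattr(vol, "_affine", None)
    if affine is None:
        affine = np.diag(list(vol.voxel_size) + [1.0])
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine)
    img.header.set_zooms(vol.voxel_size)
    nib.save(img, str(path))
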