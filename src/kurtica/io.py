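"""NIfTI-1 reading and writing for volumes and masks.

Volumes round-trip with their affine, voxel sizes and TR (stored in
``pixdim[4]``); masks are written as uint8 0/1 images.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import KurticaError
from .preprocess import Mask3D, Volume4D

__all__ = ["read_volume", "write_volume", "read_mask", "write_mask"]


def write_volume(v: Volume4D, path: str | Path) -> None:
    img = nib.Nifti1Image(v.data.astype(np.float64), v.affine)
    img.header.set_zooms((*v.voxel_size_mm, v.tr_seconds))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_volume(path: str | Path) -> Volume4D:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise KurticaError(f"{path}: expected a 4-D NIfTI, got ndim={data.ndim}")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return Volume4D(
        data=data,
        voxel_size_mm=tuple(float(z) for z in zooms[:3]),
        tr_seconds=tr,
        affine=np.asarray(img.affine),
    )


def write_mask(m: Mask3D, path: str | Path) -> None:
    img = nib.Nifti1Image(m.data.astype(np.uint8), m.affine)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> Mask3D:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise KurticaError(f"{path}: expected a 3-D NIfTI mask, got ndim={data.ndim}")
    return Mask3D(data=data > 0, affine=np.asarray(img.affine))
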