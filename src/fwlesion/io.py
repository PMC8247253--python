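"""NIfTI-backed containers and I/O helpers."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .gradients import GradientTable, read_bvals_bvecs

__all__ = ["DWIVolume", "save_volume", "load_volume", "load_dwi"]


@dataclass
class DWIVolume:
    """A 4-D diffusion-weighted signal array with its gradient table.

    ``data`` is indexed (x, y, z, volume); ``voxel_size`` is mm per axis.
    """

    data: np.ndarray
    gtab: GradientTable
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4-D (x, y, z, volume)")
        if self.data.shape[3] != len(self.gtab):
            raise ValueError(
                f"number of volumes ({self.data.shape[3]}) does not match "
                f"gradient table length ({len(self.gtab)})"
            )

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_volume(data: np.ndarray, path: str | Path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    """Write a 3-D or 4-D array as NIfTI-1; masks should be passed as uint8."""
    img = nib.Nifti1Image(np.asarray(data), _affine(voxel_size))
    img.header.set_zooms(tuple(voxel_size) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), tuple(float(z) for z in img.header.get_zooms()[:3])


def load_dwi(dwi_path: str | Path, bval_path: str | Path, bvec_path: str | Path) -> DWIVolume:
    data, zooms = load_volume(dwi_path)
    gtab = read_bvals_bvecs(bval_path, bvec_path)
    return DWIVolume(data, gtab, zooms)
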