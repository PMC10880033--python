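"""NIfTI-1 reading/writing helpers shared by all pipeline stages."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np


def save_nifti(data: np.ndarray, voxel_size, path, dtype=None) -> None:
    """Write a 3D volume as NIfTI-1 with a diagonal affine in mm."""
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    affine = np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms(tuple(float(v) for v in voxel_size))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume; returns (array, voxel_size_mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


def save_complex_field(U: np.ndarray, voxel_size, stem: Path) -> list[Path]:
    """Write a complex vector field (3, nx, ny, nz) as paired re/im volumes."""
    stem = Path(stem)
    written = []
    for ci, comp in enumerate("xyz"):
        for part, arr in (("re", U[ci].real), ("im", U[ci].imag)):
            p = stem.parent / f"{stem.name}_{comp}_{part}.nii"
            save_nifti(arr, voxel_size, p, dtype=np.float32)
            written.append(p)
    return written


def load_complex_field(stem: Path, shape) -> np.ndarray:
    stem = Path(stem)
    U = np.zeros((3,) + tuple(shape), dtype=complex)
    for ci, comp in enumerate("xyz"):
        re, _ = load_nifti(stem.parent / f"{stem.name}_{comp}_re.nii")
        im, _ = load_nifti(stem.parent / f"{stem.name}_{comp}_im.nii")
        U[ci] = re + 1j * im
    return U
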