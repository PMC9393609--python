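"""NIfTI readers/writers for volumes, tensor fields and ROI labels.

All images use a scaled-identity affine (isotropic voxel size on the
diagonal), matching the RAS-like axis convention of the phantom: x =
left-right, y = anterior-posterior, z = superior-inferior.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .schemes import GradientScheme, read_fsl_gradients, write_fsl_gradients
from .synthcohort import DWIVolume
from .tensorfit import AxisDiffusivityMaps, DiffusionTensorField

__all__ = [
    "save_volume",
    "load_volume",
    "save_dwi",
    "load_dwi",
    "save_roi_labels",
    "load_roi_labels",
    "save_tensor_field",
    "save_axis_maps",
    "load_axis_maps",
]

AXIS_MAP_FILES = {"Dxx": "dxx.nii.gz", "Dyy": "dyy.nii.gz", "Dzz": "dzz.nii.gz"}
MASK_FILE = "mask.nii.gz"


def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm] * 3 + [1.0])


def save_volume(data: np.ndarray, path: str | Path, voxel_size_mm: float = 2.0) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), _affine(voxel_size_mm)), str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    voxel = float(img.header.get_zooms()[0])
    return np.asanyarray(img.dataobj), voxel


def save_dwi(dwi: DWIVolume, out_dir: str | Path, prefix: str = "dwi") -> Path:
    """Write a DWI volume as NIfTI plus FSL bvals/bvecs; returns the NIfTI path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nii = out_dir / f"{prefix}.nii.gz"
    save_volume(dwi.data, nii, dwi.voxel_size_mm)
    write_fsl_gradients(dwi.scheme, out_dir / f"{prefix}.bval",
                        out_dir / f"{prefix}.bvec")
    return nii


def load_dwi(
    nii_path: str | Path,
    bval_path: str | Path | None = None,
    bvec_path: str | Path | None = None,
) -> DWIVolume:
    """Read a DWI NIfTI with its gradient table (defaults to sibling files)."""
    nii_path = Path(nii_path)
    stem = nii_path.name.removesuffix(".gz").removesuffix(".nii")
    bval_path = bval_path or nii_path.parent / f"{stem}.bval"
    bvec_path = bvec_path or nii_path.parent / f"{stem}.bvec"
    data, voxel = load_volume(nii_path)
    scheme = read_fsl_gradients(bval_path, bvec_path)
    return DWIVolume(data=np.asarray(data, dtype=float), scheme=scheme,
                     voxel_size_mm=voxel)


def save_roi_labels(labels: np.ndarray, path: str | Path,
                    voxel_size_mm: float = 2.0) -> None:
    save_volume(np.asarray(labels, dtype=np.int16), path, voxel_size_mm)


def load_roi_labels(path: str | Path) -> np.ndarray:
    data, _ = load_volume(path)
    return np.asarray(data, dtype=np.int16)


def save_tensor_field(field: DiffusionTensorField, path: str | Path) -> None:
    """Write the six tensor components as one 4D NIfTI
    (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz)."""
    save_volume(field.components, path, field.voxel_size_mm)


def save_axis_maps(maps: AxisDiffusivityMaps, out_dir: str | Path,
                   voxel_size_mm: float = 2.0) -> None:
    """Write Dxx/Dyy/Dzz maps and the validity mask as separate NIfTIs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for axis, fname in AXIS_MAP_FILES.items():
        save_volume(maps.axis(axis), out_dir / fname, voxel_size_mm)
    save_volume(maps.mask.astype(np.uint8), out_dir / MASK_FILE, voxel_size_mm)


def load_axis_maps(map_dir: str | Path) -> AxisDiffusivityMaps:
    map_dir = Path(map_dir)
    arrays = {}
    for axis, fname in AXIS_MAP_FILES.items():
        arrays[axis], _ = load_volume(map_dir / fname)
    mask_path = map_dir / MASK_FILE
    if mask_path.exists():
        mask, _ = load_volume(mask_path)
        mask = np.asarray(mask, dtype=bool)
    else:
        mask = np.ones(arrays["Dxx"].shape, dtype=bool)
    return AxisDiffusivityMaps(
        dxx=np.asarray(arrays["Dxx"], dtype=float),
        dyy=np.asarray(arrays["Dyy"], dtype=float),
        dzz=np.asarray(arrays["Dzz"], dtype=float),
        mask=mask,
    )
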