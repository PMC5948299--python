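"""Voxel image container and file IO.

The whole pipeline works on isotropic 3-D scalar grids in mm units. A
:class:`VoxelImage` carries grayscale CT data, binary segmentations and
label maps alike; the ``values`` dtype distinguishes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["VoxelImage", "read_image", "write_image"]


@dataclass
class VoxelImage:
    """A 3-D scalar grid with isotropic voxel size and physical origin.

    Parameters
    ----------
    values
        Array of shape ``(nx, ny, nz)``. Axis order is (medio-lateral,
        anterior-posterior, vertical) once an image is in the anatomical
        frame; raw scanner images use scanner axes.
    voxel_size
        Isotropic edge length of one voxel in mm.
    origin
        Physical position (mm) of the centre of voxel ``(0, 0, 0)``.
    meta
        Free-form metadata (e.g. warning flags set by pipeline steps).
    """

    values: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("values must be a non-empty 3-D array")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_centres(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates (mm) of voxel centres along each axis."""
        return tuple(
            self.origin[a] + self.voxel_size * np.arange(self.shape[a])
            for a in range(3)
        )

    def copy_with(self, **kw) -> "VoxelImage":
        return replace(self, **kw)


def read_image(path: str | Path) -> VoxelImage:
    """Read a MetaImage (.mhd) or NIfTI (.nii/.nii.gz) volume.

    Only isotropic volumes are accepted; anisotropic spacing raises.
    """
    path = Path(path)
    if path.suffix in {".mhd", ".mha"}:
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        spacing = np.asarray(img.GetSpacing())
        origin = np.asarray(img.GetOrigin())
        # SimpleITK arrays come back (z, y, x); transpose to (x, y, z)
        values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    elif path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        spacing = np.asarray(img.header.get_zooms()[:3])
        origin = np.asarray(img.affine[:3, 3])
        values = np.asarray(img.dataobj)
    else:
        raise ValueError(f"unsupported image format: {path.name}")
    if not np.allclose(spacing, spacing[0]):
        raise ValueError(f"anisotropic voxels not supported: {spacing}")
    return VoxelImage(values, float(spacing[0]), origin)


def write_image(img: VoxelImage, path: str | Path) -> None:
    """Write a volume as MetaImage (.mhd + .raw) or NIfTI (.nii/.nii.gz)."""
    path = Path(path)
    if path.suffix in {".mhd", ".mha"}:
        import SimpleITK as sitk

        out = sitk.GetImageFromArray(np.ascontiguousarray(img.values.transpose(2, 1, 0)))
        out.SetSpacing((img.voxel_size,) * 3)
        out.SetOrigin(tuple(float(v) for v in img.origin))
        sitk.WriteImage(out, str(path))
    elif path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([img.voxel_size] * 3 + [1.0])
        affine[:3, 3] = img.origin
        nib.save(nib.Nifti1Image(np.asarray(img.values), affine), str(path))
    else:
        raise ValueError(f"unsupported image format: {path.name}")
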