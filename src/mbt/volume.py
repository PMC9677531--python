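"""Voxel lattice container and medical-image I/O.

A :class:`VoxelVolume` is a 3-D scalar lattice with physical spacing and
origin in millimetres.  Depending on its role it carries Hounsfield units,
activity (MBq per voxel), Ho concentration (mg/ml) or absorbed dose (Gy).

Conventions: right-handed world coordinates in mm; voxel indices are
0-based with array axis order (x, y, z); a voxel's world position is its
*center*, ``origin + index * spacing``.  File I/O goes through SimpleITK
(NIfTI ``.nii``/``.nii.gz`` and MetaImage ``.mha``), transposing between
the internal (x, y, z) order and SimpleITK's (z, y, x) array order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .errors import ConfigurationError, GeometryError

_SUPPORTED_EXT = (".nii", ".nii.gz", ".mha")
_GEOM_TOL_MM = 1e-6


@dataclass
class VoxelVolume:
    """3-D scalar lattice with physical geometry.

    Parameters
    ----------
    data
        Array of shape (nx, ny, nz).
    spacing
        Voxel spacing in mm per axis, all > 0.
    origin
        World position (mm) of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ConfigurationError("VoxelVolume data must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ConfigurationError(f"voxel spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "VoxelVolume", tol: float = _GEOM_TOL_MM) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )

    def require_same_geometry(self, other: "VoxelVolume") -> None:
        if not self.same_geometry(other):
            raise GeometryError(
                f"geometry mismatch: {self.shape}/{self.spacing}/{self.origin} vs "
                f"{other.shape}/{other.spacing}/{other.origin}"
            )

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel center(s) for integer index array (..., 3)."""
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)

    def world_to_index(self, point: np.ndarray) -> np.ndarray:
        """Containing-voxel index of world point(s), by rounding to nearest center."""
        idx = np.rint((np.asarray(point) - np.asarray(self.origin)) / np.asarray(self.spacing))
        return idx.astype(int)

    def contains_point(self, point: np.ndarray) -> bool:
        idx = self.world_to_index(point)
        return bool(np.all(idx >= 0) and np.all(idx < np.asarray(self.shape)))

    def voxel_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-center world coordinates."""
        grids = np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij")
        idx = np.stack(grids, axis=-1)
        return self.index_to_world(idx)

    def copy(self, data: np.ndarray | None = None) -> "VoxelVolume":
        return VoxelVolume(
            data=self.data.copy() if data is None else np.asarray(data),
            spacing=self.spacing,
            origin=self.origin,
        )


def _check_extension(path: str) -> None:
    p = str(path).lower()
    if not any(p.endswith(ext) for ext in _SUPPORTED_EXT):
        raise ConfigurationError(
            f"unsupported volume format for {path!r}; expected one of {_SUPPORTED_EXT}"
        )


def write_volume(vol: VoxelVolume, path: str) -> None:
    """Write a volume as NIfTI or MetaImage, preserving spacing and origin."""
    _check_extension(path)
    arr = np.ascontiguousarray(np.transpose(vol.data, (2, 1, 0)))
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    sitk.WriteImage(img, str(path))


def read_volume(path: str) -> VoxelVolume:
    """Read a NIfTI or MetaImage volume into a :class:`VoxelVolume`."""
    _check_extension(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ConfigurationError(f"{path!r} is not a 3-D volume")
    arr = sitk.GetArrayFromImage(img)
    return VoxelVolume(
        data=np.transpose(arr, (2, 1, 0)),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
    )
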