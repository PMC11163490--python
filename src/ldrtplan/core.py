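"""Volumetric grid primitives shared by every pipeline stage.

All volumes live on an axis-aligned grid in patient coordinates:
axis 0 = left-right (x), axis 1 = anterior-posterior (y),
axis 2 = inferior-superior (z), with superior = increasing z.
Physical positions are measured in millimetres at voxel centers,
``position = origin + index * spacing`` with 0-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = ["Grid", "ImageVolume", "StructureMask", "GridMismatchError"]

#: structure roles understood by the planning stages
ROLES = ("GTV", "PTV", "helper", "liver", "external", "normal")


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass(frozen=True)
class Grid:
    """Geometry of an axis-aligned voxel grid.

    Parameters
    ----------
    shape
        Number of voxels along (x, y, z).
    spacing
        Voxel size in mm along each axis; all entries > 0.
    origin
        Patient-coordinate position (mm) of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cubic centimetres."""
        return float(np.prod(self.spacing)) / 1000.0

    def coords(self, axis: int) -> np.ndarray:
        """Physical voxel-center coordinates (mm) along ``axis``."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (x, y, z) voxel-center coordinate arrays."""
        return np.meshgrid(*(self.coords(a) for a in range(3)), indexing="ij", sparse=True)

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def same_as(self, other: "Grid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


def _require_same_grid(a: Grid, b: Grid, what: str = "volumes") -> None:
    if not a.same_as(b):
        raise GridMismatchError(f"{what} are on different grids: {a} vs {b}")


@dataclass
class ImageVolume:
    """A scalar volume (SUV, density or Gy) on a :class:`Grid`."""

    values: np.ndarray
    grid: Grid
    unit: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"array shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.values.copy(), self.grid, self.unit)

    def to_nifti(self, path: str) -> None:
        save_nifti(path, self.values, self.grid)


@dataclass
class StructureMask:
    """A named binary region on a grid with a planning role.

    ``derivation`` records how the mask was produced (source structures,
    operation and margins) so derived structures can be replayed after the
    anatomy changes.
    """

    name: str
    mask: np.ndarray
    grid: Grid
    role: str = "normal"
    derivation: str | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != grid shape {self.grid.shape}"
            )
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")

    @property
    def volume_cc(self) -> float:
        return float(self.mask.sum()) * self.grid.voxel_volume_cc

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def is_empty(self) -> bool:
        return not self.mask.any()

    def centroid_mm(self) -> np.ndarray:
        """Centroid of the voxel set in patient mm; NaN for empty masks."""
        if self.is_empty():
            return np.full(3, np.nan)
        idx = np.argwhere(self.mask)
        return self.grid.index_to_mm(idx.mean(axis=0))

    def extent_mm(self, axis: int) -> tuple[float, float]:
        """(min, max) voxel-center coordinate of the mask along ``axis``."""
        if self.is_empty():
            raise ValueError(f"structure {self.name!r} is empty")
        idx = np.argwhere(self.mask)[:, axis]
        c = self.grid.coords(axis)
        return float(c[idx.min()]), float(c[idx.max()])

    def with_name(self, name: str, role: str | None = None,
                  derivation: str | None = None) -> "StructureMask":
        return StructureMask(name, self.mask, self.grid, role or self.role,
                             derivation if derivation is not None else self.derivation)

    def to_nifti(self, path: str) -> None:
        save_nifti(path, self.mask.astype(np.uint8), self.grid)


# ---------------------------------------------------------------------------
# NIfTI round-trip.  The in-memory axis order (x, y, z) maps directly onto
# NIfTI's RAS+ data axes via a diagonal affine.

def _affine(grid: Grid) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def save_nifti(path: str, values: np.ndarray, grid: Grid) -> None:
    img = nib.Nifti1Image(np.asarray(values), _affine(grid))
    nib.save(img, path)


def load_nifti(path: str) -> ImageVolume:
    img = nib.load(path)
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
        raise ValueError("only axis-aligned (diagonal-affine) NIfTI volumes are supported")
    spacing = tuple(float(d) for d in np.diag(aff[:3, :3]))
    if any(s <= 0 for s in spacing):
        raise ValueError("negative or zero spacing in NIfTI affine; reorient to RAS+ first")
    grid = Grid(tuple(img.shape[:3]), spacing, tuple(float(o) for o in aff[:3, 3]))
    return ImageVolume(np.asarray(img.dataobj).astype(np.float64), grid)


def load_mask(path: str, name: str, role: str = "normal") -> StructureMask:
    vol = load_nifti(path)
    return StructureMask(name, vol.values > 0.5, vol.grid, role)
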