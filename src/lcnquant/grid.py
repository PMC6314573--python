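"""Voxel-grid container and multi-page TIFF I/O.

Image stacks are indexed ``(z, y, x)`` with strictly positive, possibly
anisotropic voxel spacing in micrometres. Typical label-free bone stacks are
sampled at 200 nm in-plane and 300 nm axially, so physical lengths must be
computed with the spacing, never in voxel units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

Spacing = tuple[float, float, float]

#: default (dz, dy, dx) voxel spacing in micrometres
DEFAULT_SPACING: Spacing = (0.3, 0.2, 0.2)


@dataclass
class VoxelGrid:
    """A 3D scalar intensity field with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Intensity values. Binary masks are stored as ``bool``.
    spacing : (dz, dy, dx)
        Voxel spacing in micrometres; all entries strictly positive.
    """

    values: np.ndarray
    spacing: Spacing = field(default=DEFAULT_SPACING)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) array, got ndim={self.values.ndim}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(np.isfinite(self.values)):
            raise ValueError("grid contains non-finite values")
        self.spacing = spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    @property
    def volume_um3(self) -> float:
        """Total physical volume of the grid in µm³."""
        return self.voxel_volume_um3 * self.values.size

    @property
    def physical_size_um(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))  # type: ignore[return-value]

    def like(self, values: np.ndarray) -> "VoxelGrid":
        """New grid with the same geometry and different values."""
        values = np.asarray(values)
        if values.shape != self.values.shape:
            raise ValueError(f"shape mismatch: {values.shape} vs {self.values.shape}")
        return VoxelGrid(values, self.spacing)

    def same_geometry(self, other: "VoxelGrid") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


def read_stack(path, spacing: Spacing = DEFAULT_SPACING) -> VoxelGrid:
    """Read a multi-page TIFF stack as a :class:`VoxelGrid`.

    TIFF carries no reliable physical calibration for our stacks, so the
    spacing is supplied by the caller (defaults to 300 × 200 × 200 nm).
    """
    values = tifffile.imread(str(path))
    if values.ndim == 2:
        values = values[None]
    return VoxelGrid(values, spacing)


def write_stack(path, grid: VoxelGrid, dtype=None) -> None:
    """Write a grid as a multi-page TIFF (one page per z-slice)."""
    values = grid.values
    if dtype is not None:
        if np.issubdtype(np.dtype(dtype), np.integer):
            info = np.iinfo(dtype)
            values = np.clip(np.rint(values), info.min, info.max)
        values = values.astype(dtype)
    elif values.dtype == bool:
        values = values.astype(np.uint8) * 255
    tifffile.imwrite(str(path), values, photometric="minisblack")
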