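"""Shared spatial primitives: imaging slices, saturation slabs, target voxels
and the 2-D source-offset grid.

Conventions
-----------
Coordinates are RAS millimetres.  The imaging slice is axial with normal
along z (superior-inferior); source maps live on a 2-D grid over relative
offsets ``(dx, dz)`` and are projected along y (anterior-posterior).
Source offsets are defined as ``dr = r(tagging) - r(imaging)``, i.e. maps
localize where spins *came from*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SliceGeometry",
    "Slab",
    "VoxelGeometry",
    "SourceGrid",
    "GeometryError",
]


class GeometryError(ValueError):
    """Raised when geometric inputs are inconsistent."""


@dataclass(frozen=True)
class SliceGeometry:
    """Axial imaging slice: centre ``z`` and full thickness, both in mm."""

    z: float
    thickness: float

    def contains_z(self, zpos: np.ndarray) -> np.ndarray:
        return np.abs(np.asarray(zpos) - self.z) <= self.thickness / 2.0


@dataclass(frozen=True)
class Slab:
    """Axial saturation slab: centre ``z`` and full thickness in mm."""

    z: float
    thickness: float

    def contains_z(self, zpos: np.ndarray) -> np.ndarray:
        return np.abs(np.asarray(zpos) - self.z) <= self.thickness / 2.0


@dataclass(frozen=True)
class VoxelGeometry:
    """A target voxel inside an imaging slice.

    Parameters
    ----------
    center : tuple of float
        Voxel centre (x, y, z) in mm.
    size : tuple of float
        In-plane extent (sx, sy) in mm.
    thickness : float
        Through-plane extent (slice thickness) in mm.
    slice_index : int
        Index of the imaging slice this voxel belongs to.
    """

    center: tuple[float, float, float]
    size: tuple[float, float] = (4.0, 4.0)
    thickness: float = 5.0
    slice_index: int = 0

    def contains(self, positions: np.ndarray) -> np.ndarray:
        """Boolean mask of ``positions`` (n, 3) inside the voxel."""
        p = np.asarray(positions, dtype=float)
        c = np.asarray(self.center, dtype=float)
        d = np.abs(p - c)
        return (
            (d[:, 0] <= self.size[0] / 2.0)
            & (d[:, 1] <= self.size[1] / 2.0)
            & (d[:, 2] <= self.thickness / 2.0)
        )


@dataclass(frozen=True)
class SourceGrid:
    """Cartesian grid of relative source offsets ``(dx, dz)``.

    Bin centres are ``res * (index - n // 2)`` so the centre bin is exactly
    ``dr = 0``.  The grid is the image-domain dual of a rectangular
    displacement-encoding grid with step ``dk = 2*pi/fov`` reaching
    ``k_max = pi/res``.
    """

    fov: tuple[float, float]
    res: tuple[float, float]

    def __post_init__(self):
        for f, r in zip(self.fov, self.res):
            if not (f >= r > 0):
                raise GeometryError(f"require fov >= res > 0, got fov={f}, res={r}")

    @property
    def shape(self) -> tuple[int, int]:
        return (
            int(round(self.fov[0] / self.res[0])),
            int(round(self.fov[1] / self.res[1])),
        )

    def _axis(self, i: int) -> np.ndarray:
        n = self.shape[i]
        return self.res[i] * (np.arange(n) - n // 2)

    @property
    def offsets_x(self) -> np.ndarray:
        return self._axis(0)

    @property
    def offsets_z(self) -> np.ndarray:
        return self._axis(1)

    def bin_index(self, dx, dz, wrap: bool = False):
        """Nearest-centre bin indices for offsets; out-of-grid offsets map to
        -1 unless ``wrap`` (modular / aliased assignment) is requested."""
        nx, nz = self.shape
        ix = np.rint(np.asarray(dx, dtype=float) / self.res[0]).astype(int) + nx // 2
        iz = np.rint(np.asarray(dz, dtype=float) / self.res[1]).astype(int) + nz // 2
        if wrap:
            ix = np.mod(ix, nx)
            iz = np.mod(iz, nz)
        else:
            bad = (ix < 0) | (ix >= nx) | (iz < 0) | (iz >= nz)
            ix = np.where(bad, -1, ix)
            iz = np.where(bad, -1, iz)
        return ix, iz
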