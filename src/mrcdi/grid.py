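"""Regular voxel grids in world (RAS, millimetre) coordinates.

Every volume in the package lives on a :class:`GridGeometry`: an axis-aligned,
regularly spaced voxel grid whose world<->voxel mapping is an invertible
diagonal affine.  Voxel indices are 0-based and coordinates refer to voxel
centres.  Field quantities are SI (tesla, A/m^2, S/m); lengths at the grid
boundary are millimetres, matching neuroimaging conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridGeometry"]


@dataclass(frozen=True)
class GridGeometry:
    """Axis-aligned voxel grid.

    Parameters
    ----------
    shape
        Number of voxels along x, y, z.
    voxel_size
        Voxel edge length per axis, millimetres.
    origin
        World coordinate (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        if len(self.shape) != 3 or any(n <= 0 for n in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")

    # -- constructors ------------------------------------------------------
    @classmethod
    def centered(cls, shape, voxel_size) -> "GridGeometry":
        """Grid whose world origin is at the centre of the field of view."""
        shape = tuple(int(n) for n in np.atleast_1d(shape) * np.ones(3, dtype=int))
        voxel = tuple(float(v) for v in np.atleast_1d(voxel_size) * np.ones(3))
        origin = tuple(-(n - 1) * v / 2.0 for n, v in zip(shape, voxel))
        return cls(shape, voxel, origin)

    @classmethod
    def from_affine(cls, affine: np.ndarray, shape) -> "GridGeometry":
        """Build from a NIfTI-style affine; rejects oblique (non-diagonal) axes."""
        affine = np.asarray(affine, dtype=float)
        rot = affine[:3, :3]
        off_diag = rot - np.diag(np.diag(rot))
        if np.max(np.abs(off_diag)) > 1e-6 * max(1.0, np.max(np.abs(rot))):
            raise ValueError("non-orthogonal (oblique) affine: grid must be axis-aligned")
        voxel = np.diag(rot)
        if np.any(voxel <= 0):
            raise ValueError("affine must have positive diagonal voxel scales (RAS)")
        return cls(tuple(shape), tuple(voxel), tuple(affine[:3, 3]))

    # -- geometry ----------------------------------------------------------
    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (mm)."""
        a = np.eye(4)
        a[:3, :3] = np.diag(self.voxel_size)
        a[:3, 3] = self.origin
        return a

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1-D world coordinates (mm) of voxel centres along each axis."""
        return tuple(
            self.origin[k] + np.arange(self.shape[k]) * self.voxel_size[k]
            for k in range(3)
        )

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense meshgrid (ij indexing) of voxel-centre world coordinates, mm."""
        x, y, z = self.axes()
        return np.meshgrid(x, y, z, indexing="ij")

    def voxel_centres(self) -> np.ndarray:
        """(N, 3) array of all voxel-centre world coordinates, mm."""
        X, Y, Z = self.coordinate_grids()
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of world points (mm)."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.voxel_size)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk * np.asarray(self.voxel_size) + np.asarray(self.origin)

    def contains_world(self, xyz: np.ndarray) -> np.ndarray:
        """Whether world points fall inside the voxel-centre bounding box."""
        v = self.world_to_voxel(xyz)
        n = np.asarray(self.shape)
        return np.all((v >= 0) & (v <= n - 1), axis=-1)
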