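"""Core volumetric grid types and geometric utilities.

Conventions
-----------
Voxel indices are 0-based ``(i, j, k)`` mapping to world axes ``(x, y, z)``;
the world coordinate of a voxel center is ``origin + index * spacing``.
All distances and volumes are computed in mm / ccm, never in voxel units,
so anisotropic spacing is fully supported.  Oblique (rotated) orientations
are not represented; loaders reject them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

__all__ = [
    "VolumetricImage",
    "BinaryMask",
    "SeedPoint",
    "mask_volume_ccm",
    "max_diameter_mm",
    "start_cube",
]


@dataclass(frozen=True)
class VolumetricImage:
    """A 3D scalar grid of activity values with physical spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Activity concentration per voxel (arbitrary units, typically
        MBq/ccm for phantom data).
    spacing : tuple of float
        Voxel size ``(dx, dy, dz)`` in mm; all components > 0.
    origin : tuple of float
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3 or min(values.shape) < 1:
            raise ValueError("values must be a 3D array with each dimension >= 1")
        if not np.all(np.isfinite(values)):
            raise ValueError("image values must be finite")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError("spacing must be three positive values in mm")
        origin = tuple(float(o) for o in self.origin)
        if len(origin) != 3:
            raise ValueError("origin must be a world-mm triple")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ccm(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    def world_to_voxel(self, xyz: tuple[float, float, float]) -> tuple[int, int, int]:
        """Nearest-voxel-center index for a world-mm point (ties -> lower index)."""
        idx = []
        for w, o, s, n in zip(xyz, self.origin, self.spacing, self.shape):
            # ceil(t - 0.5) rounds to nearest with exact ties toward the lower index
            i = int(np.ceil((w - o) / s - 0.5))
            if not 0 <= i < n:
                raise ValueError(f"world point {xyz} falls outside the image grid")
            idx.append(i)
        return tuple(idx)


@dataclass(frozen=True)
class BinaryMask:
    """Voxel membership set on the grid of a :class:`VolumetricImage`."""

    membership: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.membership)
        if m.ndim != 3:
            raise ValueError("mask membership must be a 3D boolean array")
        object.__setattr__(self, "membership", m.astype(bool, copy=False))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.membership.shape

    @property
    def count(self) -> int:
        return int(self.membership.sum())

    def indices(self) -> np.ndarray:
        """Member voxel indices as an (n, 3) int array."""
        return np.argwhere(self.membership)

    def union(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.membership | other.membership)

    def __eq__(self, other: object) -> bool:  # mask identity = same voxel set
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return self.shape == other.shape and bool(
            np.array_equal(self.membership, other.membership)
        )

    def __hash__(self) -> None:  # pragma: no cover - masks are not hashable
        raise TypeError("BinaryMask is not hashable")


@dataclass(frozen=True)
class SeedPoint:
    """Integer voxel indices of the user-selected lesion center."""

    i: int
    j: int
    k: int

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.i, self.j, self.k)


def mask_volume_ccm(
    mask: BinaryMask, spacing: tuple[float, float, float]
) -> float:
    """Volume of a mask in ccm (member count x voxel volume).

    An empty mask has volume 0.0.
    """
    dx, dy, dz = spacing
    if dx <= 0 or dy <= 0 or dz <= 0:
        raise ValueError("spacing must be positive")
    return mask.count * dx * dy * dz / 1000.0


def max_diameter_mm(mask: BinaryMask, spacing: tuple[float, float, float]) -> float:
    """Maximal lesion diameter: largest center-to-center distance (mm).

    Measured in 3D between member-voxel centers.  For large masks the
    candidate set is reduced to the convex hull vertices of the centers
    before the pairwise scan; the maximum pairwise distance of a point set
    is attained on its hull, so this is exact.
    """
    pts = mask.indices().astype(float)
    if pts.shape[0] == 0:
        raise ValueError("empty mask")
    if pts.shape[0] == 1:
        return 0.0
    pts *= np.asarray(spacing, dtype=float)
    if pts.shape[0] > 2000:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear) sets: fall back to full scan
    return float(pdist(pts).max())


def start_cube(seed: SeedPoint, image: VolumetricImage) -> BinaryMask:
    """The 27-voxel (3x3x3) start volume centered on the seed.

    Raises if the cube does not fit inside the grid: region growing needs
    the full neighborhood of the clicked center.
    """
    shape = image.shape
    for idx, n in zip(seed.as_tuple(), shape):
        if idx - 1 < 0 or idx + 1 >= n:
            raise ValueError("seed too close to boundary")
    m = np.zeros(shape, dtype=bool)
    i, j, k = seed.as_tuple()
    m[i - 1 : i + 2, j - 1 : j + 2, k - 1 : k + 2] = True
    return BinaryMask(m)
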