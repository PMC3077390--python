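"""Shared spatial primitives: the image grid and world/voxel coordinate maps.

All volumes in the pipeline live on a common axis-aligned grid (the synthetic
stand-in for a shared atlas space). Axis convention follows the usual
radiological one for an axis-aligned RAS-like frame:

* axis 0 (x): left-right, fixed-x planes are *sagittal*
* axis 1 (y): posterior-anterior, fixed-y planes are *coronal*
* axis 2 (z): inferior-superior, fixed-z planes are *axial*

World coordinates are in mm; the centre of voxel ``(i, j, k)`` sits at
``origin + (index + 0.5) * voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

AXIS_NAMES = {"sagittal": 0, "coronal": 1, "axial": 2}


@dataclass(frozen=True)
class ImageGrid:
    """Geometry of a 3D voxel grid: shape, isotropy-agnostic spacing, origin."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {self.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel size must be 3 positive floats, got {self.voxel_size}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    @property
    def affine(self) -> np.ndarray:
        """Voxel-index -> world-mm affine (voxel centres at integer indices)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = np.asarray(self.origin) + 0.5 * np.asarray(self.voxel_size)
        return aff

    @property
    def extent(self) -> np.ndarray:
        """(3, 2) array of world-space [lo, hi] per axis."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + np.asarray(self.shape) * np.asarray(self.voxel_size)
        return np.stack([lo, hi], axis=1)

    def world_to_continuous_index(self, points: np.ndarray) -> np.ndarray:
        """Map world mm to continuous voxel indices (centre of voxel i -> i)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.voxel_size) - 0.5

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world mm to integer voxel indices (containment, floor rule)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.floor((pts - np.asarray(self.origin)) / np.asarray(self.voxel_size)).astype(int)

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates of voxel centres."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + (idx + 0.5) * np.asarray(self.voxel_size)

    def voxel_centers(self) -> np.ndarray:
        """(X, Y, Z, 3) array of all voxel centre coordinates."""
        axes = [
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.voxel_size[a]
            for a in range(3)
        ]
        grid = np.meshgrid(*axes, indexing="ij")
        return np.stack(grid, axis=-1)

    def in_bounds(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices))
        ok = np.ones(idx.shape[0], dtype=bool)
        for a in range(3):
            ok &= (idx[:, a] >= 0) & (idx[:, a] < self.shape[a])
        return ok


@dataclass
class ScalarMap:
    """A single 3D metric field (FA, RD or AD) on an :class:`ImageGrid`."""

    data: np.ndarray
    grid: ImageGrid
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"scalar map shape {self.data.shape} != grid shape {self.grid.shape}"
            )


@dataclass
class TensorVolume:
    """Per-voxel symmetric diffusion tensor, six unique coefficients.

    Coefficient order along the last axis is
    ``(Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)`` in mm^2/s.
    ``invalid`` flags voxels where the fit was degenerate (e.g. S0 <= 0).
    """

    coeffs: np.ndarray
    grid: ImageGrid
    invalid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (*self.grid.shape, 6):
            raise ValueError(
                f"tensor coeff shape {self.coeffs.shape} != {(*self.grid.shape, 6)}"
            )
        if self.invalid is None:
            self.invalid = np.zeros(self.grid.shape, dtype=bool)

    def as_matrices(self) -> np.ndarray:
        """(..., 3, 3) symmetric matrices."""
        return tensor_coeffs_to_matrices(self.coeffs)


def tensor_coeffs_to_matrices(coeffs: np.ndarray) -> np.ndarray:
    c = np.asarray(coeffs, dtype=float)
    m = np.zeros(c.shape[:-1] + (3, 3))
    m[..., 0, 0] = c[..., 0]
    m[..., 1, 1] = c[..., 1]
    m[..., 2, 2] = c[..., 2]
    m[..., 0, 1] = m[..., 1, 0] = c[..., 3]
    m[..., 0, 2] = m[..., 2, 0] = c[..., 4]
    m[..., 1, 2] = m[..., 2, 1] = c[..., 5]
    return m


def matrices_to_tensor_coeffs(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    return np.stack(
        [m[..., 0, 0], m[..., 1, 1], m[..., 2, 2], m[..., 0, 1], m[..., 0, 2], m[..., 1, 2]],
        axis=-1,
    )


def save_scalar_map(path, smap: ScalarMap) -> None:
    img = nib.Nifti1Image(smap.data.astype(np.float32), smap.grid.affine)
    nib.save(img, str(path))


def load_scalar_map(path, name: str = "") -> ScalarMap:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    grid = grid_from_affine(data.shape, img.affine)
    return ScalarMap(data=data, grid=grid, name=name)


def grid_from_affine(shape, affine: np.ndarray) -> ImageGrid:
    """Recover an :class:`ImageGrid` from a diagonal NIfTI affine."""
    aff = np.asarray(affine, dtype=float)
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
        raise ValueError("only axis-aligned (diagonal) affines are supported")
    vs = np.diag(aff[:3, :3])
    if np.any(vs <= 0):
        raise ValueError("voxel sizes in affine must be positive")
    origin = aff[:3, 3] - 0.5 * vs
    return ImageGrid(shape=tuple(shape[:3]), voxel_size=tuple(vs), origin=tuple(origin))
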