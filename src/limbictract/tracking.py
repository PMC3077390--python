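"""Deterministic FACT streamline tractography and multi-ROI bundle extraction.

FACT (fiber assignment by continuous tracking) propagates a polyline from
every seed voxel along the *nearest-voxel* principal eigenvector: the
direction is updated each time the track enters a new voxel, and polyline
vertices are laid down at voxel-boundary crossings.  Tracking is
bidirectional from the seed and stops when the track

* enters a voxel whose FA is below ``fa_thresh`` (default 0.15),
* would turn by more than ``angle_thresh`` (default 50 degrees), or
* leaves the grid.

Streamlines shorter than ``min_length`` (default 10 mm) are discarded.
Bundles are then selected with AND logic over planar or mask ROIs, the
cingulum-style bundle can be partitioned at two coronal planes, and binary
bundle masks support the volume-overlap reliability measure (Dice by
default, Jaccard by flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AXIS_NAMES, ImageGrid, ScalarMap

__all__ = [
    "Bundle",
    "RoiSpec",
    "track_all",
    "select_by_rois",
    "partition_cgc",
    "overlap_ratio",
    "bundle_mask",
    "streamline_length",
    "max_turning_angle",
]

_EPS = 1e-9


def streamline_length(points: np.ndarray) -> float:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def max_turning_angle(points: np.ndarray) -> float:
    """Largest angle (degrees) between successive segments of a polyline."""
    pts = np.asarray(points, dtype=float)
    seg = np.diff(pts, axis=0)
    norms = np.linalg.norm(seg, axis=1)
    keep = norms > _EPS
    seg = seg[keep] / norms[keep, None]
    if seg.shape[0] < 2:
        return 0.0
    cos = np.clip(np.einsum("ij,ij->i", seg[:-1], seg[1:]), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)).max())


@dataclass
class Bundle:
    """A named collection of streamlines (world-mm polylines)."""

    name: str
    streamlines: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.streamlines)


@dataclass
class RoiSpec:
    """A planar or mask region of interest used for bundle selection.

    For planar ROIs, ``kind`` is the plane orientation (``sagittal`` fixes
    x, ``coronal`` fixes y, ``axial`` fixes z), ``slice_index`` the voxel
    slice, and ``region`` an optional in-plane voxel-index rectangle
    ``((lo0, hi0), (lo1, hi1))`` (inclusive) over the two remaining axes in
    ascending axis order; ``None`` keeps the whole slice.  ``kind="mask"``
    takes an explicit boolean volume instead.
    """

    kind: str
    slice_index: int | None = None
    region: tuple | None = None
    mask: np.ndarray | None = None
    name: str = ""

    def voxel_mask(self, grid: ImageGrid) -> np.ndarray:
        if self.kind == "mask":
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != grid.shape:
                raise ValueError("ROI mask shape does not match grid")
            if not m.any():
                raise ValueError(f"ROI {self.name or self.kind} selects no voxels")
            return m
        if self.kind not in AXIS_NAMES:
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        axis = AXIS_NAMES[self.kind]
        if self.slice_index is None or not (0 <= self.slice_index < grid.shape[axis]):
            raise ValueError(
                f"slice index {self.slice_index} outside grid axis {axis} "
                f"(size {grid.shape[axis]})"
            )
        m = np.zeros(grid.shape, dtype=bool)
        sl = [slice(None)] * 3
        sl[axis] = self.slice_index
        if self.region is None:
            m[tuple(sl)] = True
        else:
            other = [a for a in range(3) if a != axis]
            (lo0, hi0), (lo1, hi1) = self.region
            sl[other[0]] = slice(int(lo0), int(hi0) + 1)
            sl[other[1]] = slice(int(lo1), int(hi1) + 1)
            m[tuple(sl)] = True
        if not m.any():
            raise ValueError(f"ROI {self.name or self.kind} selects no voxels")
        return m

    def centroid(self, grid: ImageGrid) -> np.ndarray:
        """World-mm centroid of the ROI's voxel centres."""
        idx = np.argwhere(self.voxel_mask(grid))
        return grid.voxel_to_world(idx).mean(axis=0)


# ---------------------------------------------------------------------------
# FACT propagation


def _trace_half(start_vox, start_pos, direction, fa, e1, grid,
                fa_thresh, cos_thresh, max_steps):
    """Trace one direction from the seed; returns the list of vertices after
    the seed point (exclusive)."""
    shape = fa.shape
    vs = np.asarray(grid.voxel_size)
    origin = np.asarray(grid.origin)
    vox = np.array(start_vox, dtype=int)
    pos = np.array(start_pos, dtype=float)
    d = np.array(direction, dtype=float)
    pts = []
    for _ in range(max_steps):
        # parametric distance to the exit face along each axis
        t_exit = np.full(3, np.inf)
        for a in range(3):
            if d[a] > _EPS:
                t_exit[a] = (origin[a] + (vox[a] + 1) * vs[a] - pos[a]) / d[a]
            elif d[a] < -_EPS:
                t_exit[a] = (origin[a] + vox[a] * vs[a] - pos[a]) / d[a]
        a_min = int(np.argmin(t_exit))
        t = t_exit[a_min]
        if not np.isfinite(t):
            break
        pos = pos + t * d
        pts.append(pos.copy())
        vox = vox.copy()
        vox[a_min] += 1 if d[a_min] > 0 else -1
        if not (0 <= vox[0] < shape[0] and 0 <= vox[1] < shape[1] and 0 <= vox[2] < shape[2]):
            break
        if fa[tuple(vox)] < fa_thresh:
            break
        nd = e1[tuple(vox)]
        dot = float(np.dot(nd, d))
        if dot < 0:
            nd = -nd
            dot = -dot
        if dot < cos_thresh:  # turning angle exceeds the threshold
            break
        d = nd
    return pts


def track_all(fa: ScalarMap, e1: np.ndarray, fa_thresh: float = 0.15,
              angle_thresh: float = 50.0, min_length: float = 10.0,
              seed_mask: np.ndarray | None = None, max_steps: int = 10000) -> list:
    """FACT tracking from every seed voxel with FA >= ``fa_thresh``.

    ``e1`` is the (x, y, z, 3) principal-eigenvector field on the same grid
    as ``fa``.  ``seed_mask`` restricts the seeds (e.g. a brain mask); by
    default all voxels are candidate seeds.  Returns one bidirectional
    streamline per qualifying seed (the two half-tracks merged at the seed),
    with streamlines shorter than ``min_length`` (mm) discarded.
    """
    if not (0 < fa_thresh < 1):
        raise ValueError("fa_thresh must be in (0, 1)")
    if not (0 < angle_thresh <= 90):
        raise ValueError("angle_thresh must be in (0, 90] degrees")
    e1 = np.asarray(e1, dtype=float)
    if e1.shape != (*fa.grid.shape, 3) or fa.data.shape != fa.grid.shape:
        raise ValueError("fa and e1 must share the same grid")
    grid = fa.grid
    cos_thresh = float(np.cos(np.radians(angle_thresh)))

    seeds = fa.data >= fa_thresh
    if seed_mask is not None:
        seeds &= np.asarray(seed_mask, dtype=bool)

    streamlines = []
    for vox in np.argwhere(seeds):
        center = grid.voxel_to_world(vox)[0]
        d0 = e1[tuple(vox)]
        n = np.linalg.norm(d0)
        if n < _EPS:
            continue
        d0 = d0 / n
        fwd = _trace_half(vox, center, d0, fa.data, e1, grid,
                          fa_thresh, cos_thresh, max_steps)
        bwd = _trace_half(vox, center, -d0, fa.data, e1, grid,
                          fa_thresh, cos_thresh, max_steps)
        pts = bwd[::-1] + [center] + fwd
        if len(pts) < 2:
            continue
        line = np.asarray(pts)
        # drop consecutive duplicates (zero-length steps at corner hits)
        keep = np.ones(len(line), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(line, axis=0), axis=1) > _EPS
        line = line[keep]
        if line.shape[0] >= 2 and streamline_length(line) >= min_length:
            streamlines.append(line)
    return streamlines


# ---------------------------------------------------------------------------
# ROI selection and bundle utilities


def _traversed_voxels(points: np.ndarray, grid: ImageGrid) -> np.ndarray:
    """Voxel indices visited by a polyline (dense sampling at < half-voxel
    steps along every segment)."""
    pts = np.asarray(points, dtype=float)
    step = 0.45 * min(grid.voxel_size)
    samples = [pts[0]]
    for p, q in zip(pts[:-1], pts[1:]):
        seg = np.linalg.norm(q - p)
        n = max(1, int(np.ceil(seg / step)))
        t = np.arange(1, n + 1) / n
        samples.append(p + t[:, None] * (q - p))
    samples = np.vstack([np.atleast_2d(s) for s in samples])
    idx = grid.world_to_voxel(samples)
    ok = grid.in_bounds(idx)
    idx = idx[ok]
    if idx.size == 0:
        return idx.reshape(0, 3)
    return np.unique(idx, axis=0)


def select_by_rois(streamlines, rois, grid: ImageGrid, name: str = "bundle") -> Bundle:
    """Keep exactly the streamlines that intersect *every* ROI (AND logic)."""
    if len(rois) < 1:
        raise ValueError("need at least one ROI")
    masks = [r.voxel_mask(grid) for r in rois]
    kept = []
    for line in streamlines:
        vox = _traversed_voxels(line, grid)
        if vox.shape[0] == 0:
            continue
        hit = tuple(vox.T)
        if all(m[hit].any() for m in masks):
            kept.append(line)
    return Bundle(name=name, streamlines=kept)


def _clip_polyline_y(points: np.ndarray, y_lo: float, y_hi: float) -> list:
    """Pieces of a polyline with y in [y_lo, y_hi], split at plane crossings
    with linear interpolation.  Returns a list of (k, 3) arrays (k >= 2)."""
    pts = np.asarray(points, dtype=float)
    pieces, current = [], []

    def inside(p):
        return y_lo <= p[1] <= y_hi

    def crossing(p, q, ybound):
        t = (ybound - p[1]) / (q[1] - p[1])
        return p + t * (q - p)

    if inside(pts[0]):
        current.append(pts[0])
    for p, q in zip(pts[:-1], pts[1:]):
        bounds = sorted([b for b in (y_lo, y_hi)
                         if min(p[1], q[1]) < b < max(p[1], q[1])],
                        key=lambda b: abs(b - p[1]))
        events = [crossing(p, q, b) for b in bounds] + [q]
        for ev in events:
            if inside(ev):
                if not current or np.linalg.norm(ev - current[-1]) > _EPS:
                    current.append(ev)
            else:
                if len(current) >= 2:
                    pieces.append(np.asarray(current))
                current = []
        # re-enter handling: if q is outside but a bound point was inside,
        # the loop above already closed the piece.
    if len(current) >= 2:
        pieces.append(np.asarray(current))
    return pieces


def partition_cgc(bundle: Bundle, coronal_planes: tuple) -> tuple:
    """Partition a cingulum-like bundle at two coronal (fixed-y) world planes.

    ``coronal_planes = (y_post, y_ant)`` with ``y_post < y_ant``.  Each
    streamline is clipped at the planes; the pieces anterior of ``y_ant``,
    between the planes, and posterior of ``y_post`` form the anterior,
    middle and posterior sub-bundles.  Empty clips are dropped.
    """
    y_post, y_ant = coronal_planes
    if not y_post < y_ant:
        raise ValueError("coronal_planes must satisfy y_post < y_ant")
    parts = {
        "anterior": Bundle(name=f"{bundle.name}_anterior"),
        "middle": Bundle(name=f"{bundle.name}_middle"),
        "posterior": Bundle(name=f"{bundle.name}_posterior"),
    }
    windows = {
        "anterior": (y_ant, np.inf),
        "middle": (y_post, y_ant),
        "posterior": (-np.inf, y_post),
    }
    ys = [p[:, 1] for p in bundle.streamlines]
    if ys and (min(y.min() for y in ys) > y_ant or max(y.max() for y in ys) < y_post):
        import warnings

        warnings.warn("partition planes lie outside the bundle extent; "
                      "some partitions will be empty", stacklevel=2)
    for line in bundle.streamlines:
        for key, (lo, hi) in windows.items():
            for piece in _clip_polyline_y(line, lo, hi):
                parts[key].streamlines.append(piece)
    return parts["anterior"], parts["middle"], parts["posterior"]


def bundle_mask(bundle: Bundle, grid: ImageGrid) -> np.ndarray:
    """Binary mask of all voxels traversed by any streamline of the bundle."""
    if len(bundle) == 0:
        raise ValueError("bundle is empty")
    mask = np.zeros(grid.shape, dtype=bool)
    for line in bundle.streamlines:
        vox = _traversed_voxels(line, grid)
        if vox.shape[0]:
            mask[tuple(vox.T)] = True
    return mask


def overlap_ratio(mask_a: np.ndarray, mask_b: np.ndarray, method: str = "dice") -> float:
    """Volume overlap between two binary masks: Dice (default) or Jaccard."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        raise ValueError("both masks are empty")
    inter = int((a & b).sum())
    if method == "dice":
        return 2.0 * inter / (na + nb)
    if method == "jaccard":
        union = int((a | b).sum())
        return inter / union
    raise ValueError(f"unknown overlap method {method!r}")
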