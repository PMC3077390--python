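"""Bundle geometry: 30-point mean curves, along-tract profiles, smoothing.

The geometric representation of a bundle is a single mean curve
parameterized at ``n = 30`` points of equal arc length.  It is computed by
(1) orienting every streamline consistently (first point nearer a chosen
origin ROI), (2) resampling each streamline to 30 equal-arc-length points,
(3) averaging coordinates pointwise across streamlines, and (4)
re-parameterizing the averaged polyline to exactly 30 uniform arc-length
points.  This deterministic orientation-align/resample/average construction
replaces diffeomorphic curve matching; on coherent bundles the two agree
(see docs/methods.md for the discussion).

Per-subject FA/RD/AD profiles are obtained by trilinear interpolation of the
subject's scalar maps at the shared mean-curve points, then smoothed by
averaging each point with its five nearest neighbours along the curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .core import ImageGrid, ScalarMap
from .tracking import Bundle, RoiSpec

__all__ = [
    "MeanCurve",
    "resample_arclength",
    "orient_bundle",
    "mean_curve",
    "extract_profile",
    "smooth_profile",
]

N_POINTS = 30


def _cumulative_arclength(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_arclength(points: np.ndarray, n: int = N_POINTS) -> np.ndarray:
    """Resample a polyline to ``n`` points at equal cumulative arc length.

    Endpoints are preserved exactly; interior points are linear
    interpolations along the original polyline.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValueError("polyline must be an (m >= 2, 3) array")
    arc = _cumulative_arclength(pts)
    total = arc[-1]
    if total <= 0:
        raise ValueError("polyline has zero length")
    targets = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for a in range(3):
        out[:, a] = np.interp(targets, arc, pts[:, a])
    out[0], out[-1] = pts[0], pts[-1]
    return out


def orient_bundle(bundle: Bundle, origin_roi: RoiSpec, grid: ImageGrid,
                  tol: float = 1e-9) -> Bundle:
    """Flip streamlines so every first point is nearer the origin ROI centroid.

    Streamlines whose endpoints are equidistant from the centroid (within
    ``tol``) keep their order; a warning is logged.
    """
    centroid = origin_roi.centroid(grid)
    oriented = []
    for line in bundle.streamlines:
        d0 = np.linalg.norm(line[0] - centroid)
        d1 = np.linalg.norm(line[-1] - centroid)
        if abs(d0 - d1) <= tol:
            import logging

            logging.getLogger(__name__).warning(
                "streamline endpoints equidistant from origin ROI; keeping order"
            )
            oriented.append(line)
        elif d1 < d0:
            oriented.append(line[::-1].copy())
        else:
            oriented.append(line)
    return Bundle(name=bundle.name, streamlines=oriented)


@dataclass
class MeanCurve:
    """30-point arc-length geometric representation of a bundle.

    ``arc_lengths`` is the cumulative arc-length parameterization along the
    source curve the points were sampled from (uniform by construction when
    produced by :func:`mean_curve`); if omitted it is recomputed from the
    stored points' chords, which coincides with the source parameterization
    for smooth curves.
    """

    points: np.ndarray
    bundle_name: str = ""
    orientation_tag: str = ""
    arc_lengths: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("mean curve points must be (n, 3)")
        if self.arc_lengths is None:
            self.arc_lengths = _cumulative_arclength(self.points)
        else:
            self.arc_lengths = np.asarray(self.arc_lengths, dtype=float)
            if self.arc_lengths.shape != (self.points.shape[0],):
                raise ValueError("arc_lengths must match the number of points")
        spacing = np.diff(self.arc_lengths)
        mean_sp = spacing.mean()
        if mean_sp <= 0 or np.any(np.abs(spacing - mean_sp) > 1e-6 * mean_sp):
            raise ValueError("mean curve arc-length spacing is not uniform")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "bundle": self.bundle_name,
                    "orientation": self.orientation_tag,
                    "points_mm": self.points.tolist(),
                    "arc_lengths_mm": self.arc_lengths.tolist(),
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "MeanCurve":
        with open(path) as fh:
            d = json.load(fh)
        return cls(points=np.asarray(d["points_mm"]), bundle_name=d["bundle"],
                   orientation_tag=d["orientation"],
                   arc_lengths=np.asarray(d["arc_lengths_mm"]))


def mean_curve(bundle: Bundle, n: int = N_POINTS, orientation_tag: str = "") -> MeanCurve:
    """Mean curve of an oriented bundle.

    Every streamline is resampled to ``n`` equal-arc-length points, the
    coordinates are averaged pointwise across streamlines, and the averaged
    polyline is re-resampled to exactly ``n`` uniform arc-length points.
    The bundle must already be consistently oriented (see
    :func:`orient_bundle`).
    """
    if len(bundle) == 0:
        raise ValueError("cannot compute the mean curve of an empty bundle")
    stack = np.stack([resample_arclength(s, n) for s in bundle.streamlines])
    avg = stack.mean(axis=0)
    pts = resample_arclength(avg, n)
    total = _cumulative_arclength(avg)[-1]
    return MeanCurve(points=pts, bundle_name=bundle.name,
                     orientation_tag=orientation_tag,
                     arc_lengths=np.linspace(0.0, total, n))


def extract_profile(smap: ScalarMap, curve: MeanCurve) -> np.ndarray:
    """Trilinear interpolation of a scalar map at the mean-curve points.

    All subjects share the same (atlas-frame) curve, so their profiles are
    directly comparable point by point.  A curve point outside the map's
    interpolation domain raises, naming the offending point index.
    """
    from scipy.ndimage import map_coordinates

    grid = smap.grid
    cont = grid.world_to_continuous_index(curve.points)
    shape = np.asarray(grid.shape)
    bad = np.where(np.any((cont < 0) | (cont > shape - 1), axis=1))[0]
    if bad.size:
        raise ValueError(
            f"curve point {int(bad[0])} at {curve.points[int(bad[0])]} lies outside "
            "the scalar map's interpolation domain"
        )
    return map_coordinates(smap.data, cont.T, order=1, mode="nearest")


def smooth_profile(values: np.ndarray, n: int = N_POINTS,
                   include_center: bool = True) -> np.ndarray:
    """Smooth an along-tract profile by nearest-neighbour averaging.

    Each point is replaced by the mean over itself and its five nearest
    neighbours along the index line; the tie between the two points at
    distance three is resolved toward the curve start, so the interior
    window is ``{i-3, ..., i+2}``.  At the boundaries the window truncates
    to the available indices.  ``include_center=False`` averages the five
    neighbours only (the alternative reading of "its closest five
    neighboring points").
    """
    v = np.asarray(values, dtype=float)
    if v.shape != (n,):
        raise ValueError(f"profile must have exactly {n} values, got shape {v.shape}")
    out = np.empty(n)
    for i in range(n):
        window = [j for j in range(i - 3, i + 3) if 0 <= j < n]
        if not include_center:
            window = [j for j in window if j != i]
        out[i] = v[window].mean()
    return out
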