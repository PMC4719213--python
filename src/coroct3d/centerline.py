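"""Stage 2 and 4 geometry: rough lumen segmentation and the luminal axis.

The lumen is grown from a user seed with 26-connectivity, per-slice
boundary contours are traced, their area centroids form an initial
polyline, which is moving-average smoothed and fitted with a cubic
(approximating) B-spline providing smooth first derivatives.  The spline
is finally resampled at equidistant arc-length stations (0.2 mm) that
drive the cross-sectional imaging.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import splev, splprep

from .volume_io import ImageVolume

log = logging.getLogger(__name__)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def region_grow(candidate, seed, low_hu: float | None = None,
                vol: ImageVolume | None = None) -> np.ndarray:
    """26-connected component of the inclusion predicate containing the seed.

    ``candidate`` may be a binary mask or an :class:`ImageVolume` (in
    which case ``low_hu`` thresholds it).  When both a mask and ``vol``
    with ``low_hu`` are given, the predicate is their conjunction.
    """
    if isinstance(candidate, ImageVolume):
        if low_hu is None:
            raise ValueError("low_hu required when growing directly on a volume")
        predicate = candidate.voxels >= low_hu
    else:
        predicate = np.asarray(candidate, dtype=bool).copy()
        if vol is not None and low_hu is not None:
            predicate &= vol.voxels >= low_hu
    seed = tuple(int(v) for v in seed)
    if any(s < 0 or s >= n for s, n in zip(seed, predicate.shape)):
        raise ValueError(f"seed {seed} outside grid {predicate.shape}")
    if not predicate[seed]:
        raise ValueError("seed not in vessel")
    labels, _ = ndimage.label(predicate, structure=_STRUCT26)
    return labels == labels[seed]


def slice_contours(lumen_mask: np.ndarray, vol: ImageVolume,
                   min_area_vox: float = 2.0) -> list[dict]:
    """Closed boundary polygon of the lumen on each axial (k) slice.

    Returns a list of dicts with keys ``k`` (slice index), ``polygon``
    (closed (n, 2) array of fractional (i, j) indices) and ``world``
    ((n, 3) points in mm).  Slices whose region is smaller than
    ``min_area_vox`` voxels are skipped; if a slice holds several
    components the largest is kept and the rest logged.
    """
    from skimage.measure import find_contours

    mask = np.asarray(lumen_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty lumen mask")
    out: list[dict] = []
    for k in range(mask.shape[2]):
        sl = mask[:, :, k]
        n_on = int(sl.sum())
        if n_on < min_area_vox:
            continue
        labels, n = ndimage.label(sl, structure=np.ones((3, 3), dtype=bool))
        if n > 1:
            sizes = ndimage.sum_labels(sl, labels, index=np.arange(1, n + 1))
            keep = int(np.argmax(sizes)) + 1
            log.debug("slice %d: keeping largest of %d components", k, n)
            sl = labels == keep
            if sl.sum() < min_area_vox:
                continue
        contours = find_contours(sl.astype(float), 0.5)
        if not contours:
            continue
        poly = max(contours, key=len)
        if _polygon_area(poly) < min_area_vox:
            continue
        world = vol.index_to_world(
            np.column_stack([poly, np.full(len(poly), float(k))]))
        out.append({"k": k, "polygon": poly, "world": world, "mask": sl})
    return out


def _polygon_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass
class CenterlinePolyline:
    points: np.ndarray                      # (n, 3) world mm

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)

    @property
    def station(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.station[-1])


def initial_centerline(contours: list[dict]) -> CenterlinePolyline:
    """One point per contour: the area centroid of the enclosed region.

    The centroid is computed on the filled polygon (not the vertex mean)
    in index space, then mapped to world mm through the contour's own
    in-plane affine, which is exact because each contour lies in one
    grid plane.
    """
    from shapely.geometry import Polygon

    if len(contours) < 3:
        raise ValueError(f"need at least 3 contours, got {len(contours)}")
    pts, order_key = [], []
    for c in contours:
        cen = Polygon(c["polygon"]).centroid
        pts.append(_inplane_to_world(np.array([cen.x, cen.y]), c))
        order_key.append(c["k"])
    pts = np.asarray(pts)[np.argsort(order_key)]
    return CenterlinePolyline(pts)


def _inplane_to_world(ij: np.ndarray, contour: dict) -> np.ndarray:
    """Map an in-slice (i, j) index point to world mm via the contour's
    boundary correspondence (world is affine in the in-plane indices)."""
    poly = contour["polygon"]
    world = contour["world"]
    X = np.column_stack([poly, np.ones(len(poly))])
    coef, *_ = np.linalg.lstsq(X, world, rcond=None)
    return np.concatenate([ij, [1.0]]) @ coef


def smooth_centerline(polyline: CenterlinePolyline, window: int = 11) -> CenterlinePolyline:
    """Centered moving average per coordinate; endpoint windows shrink."""
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    pts = polyline.points
    n = len(pts)
    if window >= 2 * n:
        raise ValueError(f"window {window} too large for {n} points")
    hw = window // 2
    out = np.empty_like(pts)
    for i in range(n):
        h = min(hw, i, n - 1 - i)
        out[i] = pts[i - h:i + h + 1].mean(axis=0)
    return CenterlinePolyline(out)


@dataclass
class CenterlineSpline:
    """Cubic B-spline lumen axis with arc-length parameterization."""

    tck: tuple
    u_grid: np.ndarray = field(repr=False)     # spline parameter samples
    s_grid: np.ndarray = field(repr=False)     # arc length at u_grid

    @property
    def length(self) -> float:
        return float(self.s_grid[-1])

    def _u_of_s(self, s) -> np.ndarray:
        return np.interp(np.asarray(s, dtype=float), self.s_grid, self.u_grid)

    def eval(self, s) -> np.ndarray:
        """Point at arc length s; linear continuation beyond the ends so
        sections can cover the full extent of the segmented lumen."""
        s_arr = np.atleast_1d(np.asarray(s, dtype=float))
        sc = np.clip(s_arr, 0.0, self.length)
        u = self._u_of_s(sc)
        pts = np.column_stack(splev(u, self.tck))
        over = s_arr - sc
        if np.any(over != 0):
            pts = pts + over[:, None] * self.deriv(sc)
        return pts[0] if np.isscalar(s) else pts

    def deriv(self, s) -> np.ndarray:
        """Unit tangent dP/ds; constant beyond the spline domain."""
        u = np.atleast_1d(self._u_of_s(np.clip(np.asarray(s, dtype=float),
                                               0.0, self.length)))
        dp = np.column_stack(splev(u, self.tck, der=1))
        norm = np.linalg.norm(dp, axis=1, keepdims=True)
        if np.any(norm <= 1e-12):
            raise ValueError("zero spline derivative")
        out = dp / norm
        return out[0] if np.isscalar(s) else out

    tangent = deriv


def fit_and_sample(polyline: CenterlinePolyline, step: float = 0.2,
                   smooth_per_point: float = 0.01,
                   ) -> tuple[CenterlineSpline, np.ndarray]:
    """Approximating cubic B-spline fit plus equidistant stations.

    ``smooth_per_point`` is the target mean squared residual (mm^2) per
    point handed to the smoothing spline; an interpolating fit would
    reintroduce the voxel jitter the moving average removed.  Returns
    the spline and stations spaced ``step`` mm apart, floor(L/step)+1
    of them.
    """
    pts = polyline.points
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9
    if not keep.all():
        warnings.warn("duplicate consecutive centerline points removed", stacklevel=2)
        pts = pts[keep]
    if len(pts) < 4:
        raise ValueError("need at least degree+1 = 4 distinct points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(seg)])
    u /= u[-1]
    s_factor = smooth_per_point * len(pts)
    tck, _ = splprep(list(pts.T), u=u, k=3, s=s_factor)

    n_dense = max(1000, 20 * len(pts))
    ug = np.linspace(0.0, 1.0, n_dense)
    dense = np.column_stack(splev(ug, tck))
    sg = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))])
    spline = CenterlineSpline(tck, ug, sg)
    n_st = int(np.floor(spline.length / step + 1e-9)) + 1
    stations = np.arange(n_st) * step
    return spline, stations
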