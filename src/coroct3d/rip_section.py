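"""Stages 4-5: radial cross-sections, wall borders and plaque regions.

At every 0.2 mm centerline station a cross-sectional image (the radial
intensity projection, RIP) is resampled in the plane perpendicular to
the B-spline tangent.  Because centerline smoothing can pull the station
off the lumen center, the section center is corrected iteratively (five
passes) by moving it onto the center of mass of the thresholded lumen
disk.  The corrected image is rebinned onto polar (ray angle, radius)
coordinates; per ray the artery region of interest ends just before the
first sample below -130 HU (the "zero cross"); the mixture model labels
each polar bin and the wall rules are

    lumen border  = first non-lumen bin outward from the center,
    outer border  = last non-background bin within the ROI.

Calcified-plaque regions are the 8-connected (wrap-aware) components of
bins whose calcium posterior exceeds 0.5 inside the wall annulus.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.ndimage import map_coordinates

from .hu_mixture import CLASS_INDEX, HuMixtureModel
from .volume_io import ImageVolume

log = logging.getLogger(__name__)

ZERO_CROSS_HU = -130.0


@dataclass
class SectionFrame:
    """Local orthonormal frame of one cross-section."""

    station: float                 # arc length, mm
    center: np.ndarray             # 3D mm, on the spline
    tangent: np.ndarray            # unit
    u_axis: np.ndarray             # unit, in-plane
    v_axis: np.ndarray             # unit, in-plane
    offset: np.ndarray = field(default_factory=lambda: np.zeros(2))  # (u, v) mm

    def plane_origin(self) -> np.ndarray:
        return (self.center + self.offset[0] * self.u_axis
                + self.offset[1] * self.v_axis)


def build_frames(spline, stations) -> list[SectionFrame]:
    """Frames with tangents from the spline derivative and in-plane axes
    propagated by rotation minimization (parallel transport)."""
    stations = np.asarray(stations, dtype=float)
    centers = spline.eval(stations)
    tangents = spline.deriv(stations)
    frames: list[SectionFrame] = []
    u_prev = None
    for s, c, t in zip(stations, centers, tangents):
        if np.linalg.norm(t) < 1e-12:
            raise ValueError(f"zero tangent at station {s}")
        t = t / np.linalg.norm(t)
        if u_prev is None:
            ref = np.eye(3)[np.argmin(np.abs(t))]
            u = np.cross(t, ref)
        else:
            u = u_prev - np.dot(u_prev, t) * t
        nrm = np.linalg.norm(u)
        if nrm < 1e-12:
            u = np.cross(t, np.eye(3)[np.argmin(np.abs(t))])
            nrm = np.linalg.norm(u)
        u = u / nrm
        v = np.cross(t, u)
        frames.append(SectionFrame(float(s), np.asarray(c, float), t, u, v))
        u_prev = u
    return frames


def sample_rip(vol: ImageVolume, frame: SectionFrame, half_width: float = 6.0,
               pixel: float = 0.1) -> np.ndarray:
    """Trilinear resampling of the section plane; outside voxels -> -1024.

    The returned image is indexed ``[a, b]`` with a along ``u_axis`` and
    b along ``v_axis``; the frame's plane origin maps to the image
    center.
    """
    nh = int(round(half_width / pixel))
    ax = (np.arange(2 * nh + 1) - nh) * pixel
    A, B = np.meshgrid(ax, ax, indexing="ij")
    pts = (frame.plane_origin()
           + A[..., None] * frame.u_axis + B[..., None] * frame.v_axis)
    idx = vol.world_to_index(pts.reshape(-1, 3))
    inside = np.all((idx > -0.5) & (idx < np.array(vol.shape) - 0.5), axis=1)
    if not inside.any():
        raise ValueError(f"section plane at station {frame.station} lies "
                         "entirely outside the volume")
    vals = map_coordinates(vol.voxels, idx.T, order=1, mode="constant",
                           cval=-1024.0)
    return vals.reshape(A.shape).astype(np.float32)


def correct_center(vol: ImageVolume, frame: SectionFrame, iterations: int = 5,
                   threshold_hu: float = 180.0, max_radius: float = 5.0,
                   half_width: float = 6.0, pixel: float = 0.1,
                   model: HuMixtureModel | None = None,
                   ) -> tuple[SectionFrame, list[np.ndarray]]:
    """Move the in-plane offset onto the lumen center of mass, iteratively.

    Each pass binarizes the section within ``max_radius`` of the current
    center and shifts the offset by the binary centroid.  Runs exactly
    ``iterations`` passes (the update is a contraction on disk-like
    images, so the residual shrinks each time).  Without a mixture model
    the binarization is the stage-1 threshold; with one, pixels
    classified as lumen are used instead, so bright calcium in the wall
    cannot drag the center off the lumen axis.  Returns the corrected
    frame and the per-iteration offset history.
    """
    history: list[np.ndarray] = [frame.offset.copy()]
    nh = int(round(half_width / pixel))
    ax = (np.arange(2 * nh + 1) - nh) * pixel
    A, B = np.meshgrid(ax, ax, indexing="ij")
    within = A * A + B * B <= max_radius * max_radius
    for _ in range(iterations):
        img = sample_rip(vol, frame, half_width, pixel)
        if model is None:
            binary = (img >= threshold_hu) & within
        else:
            binary = (model.classify(img) == CLASS_INDEX["lumen"]) & within
        if not binary.any():
            warnings.warn(f"station {frame.station}: empty binarization, "
                          "offset left unchanged", stacklevel=2)
            break
        # the lumen is one compact blob; partial-volume ghosts (lumen-like
        # HU on the outer face of a calcium arc) are thin rings attached by
        # thin bridges -> a small opening cuts them off, then keep the
        # component under the image center
        opened = ndimage.binary_opening(binary, structure=np.ones((3, 3)),
                                        iterations=2)
        if opened.any():
            binary = opened
        lab, n = ndimage.label(binary)
        if n > 1:
            center_lbl = lab[nh, nh]
            if center_lbl == 0:
                sizes = ndimage.sum_labels(binary, lab, np.arange(1, n + 1))
                center_lbl = int(np.argmax(sizes)) + 1
            binary = lab == center_lbl
        shift = np.array([A[binary].mean(), B[binary].mean()])
        frame = replace(frame, offset=frame.offset + shift)
        history.append(frame.offset.copy())
    return frame, history


def to_polar(image: np.ndarray, n_rays: int = 120, radial_step: float = 0.1,
             max_radius: float = 5.0, pixel: float = 0.1) -> np.ndarray:
    """Bilinear rebinning of a section image onto (ray, radius) bins.

    Bin (j, k) holds the HU at angle j*360/n_rays degrees (measured from
    the u axis toward the v axis) and radius k*radial_step mm from the
    image center.  Shape (n_rays, K+1) with K = floor(max_radius/step).
    """
    if n_rays < 8:
        raise ValueError("need at least 8 rays")
    nh = image.shape[0] // 2
    K = int(np.floor(max_radius / radial_step + 1e-9))
    r = np.arange(K + 1) * radial_step
    th = np.deg2rad(np.arange(n_rays) * 360.0 / n_rays)
    ia = nh + (r[None, :] * np.cos(th[:, None])) / pixel
    ib = nh + (r[None, :] * np.sin(th[:, None])) / pixel
    return map_coordinates(image, [ia, ib], order=1, mode="nearest")


def extract_roi(polar: np.ndarray, zero_cross_hu: float = ZERO_CROSS_HU) -> np.ndarray:
    """Per-ray index of the outermost bin before the first zero cross.

    A ray with no sub-threshold bin keeps its full length; a ray whose
    first bin is already below the threshold gets ROI index -1 (empty,
    flagged for the caller).
    """
    below = polar < zero_cross_hu
    n_rays, nk = polar.shape
    out = np.full(n_rays, nk - 1, dtype=int)
    any_below = below.any(axis=1)
    first = np.argmax(below, axis=1)
    out[any_below] = first[any_below] - 1
    return out


def _majority33(binary: np.ndarray) -> np.ndarray:
    """3x3 majority vote on a polar binary map, wrapping the ray axis."""
    pad = np.pad(binary.astype(np.int8), ((1, 1), (1, 1)),
                 mode="edge")
    pad[0, 1:-1] = binary[-1]
    pad[-1, 1:-1] = binary[0]
    summed = ndimage.uniform_filter(pad.astype(float), size=3, mode="nearest")
    return summed[1:-1, 1:-1] > 0.5


def _circular_interp(vals: np.ndarray) -> np.ndarray:
    n = len(vals)
    good = np.isfinite(vals)
    if good.all():
        return vals
    if not good.any():
        return vals
    idx = np.arange(n)
    return np.interp(idx, idx[good], vals[good], period=n)


def _circular_smooth(vals: np.ndarray, window: int) -> np.ndarray:
    h = window // 2
    ext = np.r_[vals[-h:], vals, vals[:h]]
    kernel = np.ones(window) / window
    return np.convolve(ext, kernel, mode="valid")


def refine_edge(profile: np.ndarray, k_edge: int, radial_step: float,
                lo: int, hi: int, inside_end: int, window: int = 4,
                min_contrast: float = 30.0, gap: int = 3) -> float:
    """Sub-bin edge localization by the half-height crossing.

    A hard-label border lands on the bin where the posterior flips,
    which under partial-volume blur sits wherever the HU profile crosses
    the *decision* level — a level that moves with the mixture weights.
    The physical tissue border is better estimated by the 50 % crossing
    between the two plateau levels flanking the transition, a standard
    subpixel edge rule.  ``k_edge`` is the label-rule bin, ``inside_end``
    the last bin counted as inside tissue; plateaus are medians over up
    to ``window`` bins per side, re-estimated in a second pass that skips
    ``gap`` bins around the first crossing so transition samples do not
    drag the plateau levels.  The crossing nearest the label edge wins;
    falls back to the bin radius when the plateau contrast is below
    ``min_contrast`` HU or no crossing exists.
    """
    k_fallback = k_edge * radial_step

    def crossing(center: float) -> float | None:
        ci = int(np.floor(center + 0.5))
        in_hi = min(ci - gap, inside_end)
        out_lo = max(ci + gap, inside_end + 1)
        inside = profile[max(lo, in_hi - window + 1):in_hi + 1]
        outside = profile[out_lo:min(hi, out_lo + window - 1) + 1]
        if len(inside) == 0 or len(outside) == 0:
            return None
        a, b = float(np.median(inside)), float(np.median(outside))
        if abs(a - b) < min_contrast:
            return None
        target = 0.5 * (a + b)
        i0, i1 = max(lo, ci - window), min(hi, ci + window)
        d = profile[i0:i1 + 1] - target
        cr = np.nonzero(d[:-1] * d[1:] <= 0)[0]
        if len(cr) == 0:
            return None
        j = cr[np.argmin(np.abs(cr + 0.5 - (center - i0)))]
        denom = d[j + 1] - d[j]
        frac = 0.5 if denom == 0 else -d[j] / denom
        return i0 + j + float(np.clip(frac, 0.0, 1.0))

    first = crossing(inside_end + 0.5)
    if first is None:
        return k_fallback
    second = crossing(first)
    return (second if second is not None else first) * radial_step


@dataclass
class WallContours:
    lumen_r: np.ndarray       # per-ray radius, mm
    outer_r: np.ndarray       # per-ray radius, mm
    valid: bool               # False when >25 % of rays were undefined
    undefined_fraction: float


def detect_walls(polar: np.ndarray, roi: np.ndarray, model: HuMixtureModel,
                 radial_step: float = 0.1, guard_mm: float = 0.3,
                 smooth_window: int = 7, clean_labels: bool = True,
                 refine: bool = True, refine_window: int = 8,
                 calcium_block_hu: float = 500.0) -> WallContours:
    """Lumen and outer-wall radii per ray from the classified profile.

    Bins are hard-labeled by the mixture; single-bin label islands are
    removed with a 3x3 majority vote (wrap-aware) before the border
    rules run, because one noisy sample should not move a wall.  The
    first ``guard_mm`` of every ray is skipped to avoid center-pixel
    misclassifications.  Undefined rays are circularly interpolated from
    their neighbors; both contours are circularly smoothed and
    lumen <= outer is enforced per ray.
    """
    n_rays, nk = polar.shape
    if (roi >= 0).sum() < 0.75 * n_rays:
        return WallContours(np.full(n_rays, np.nan), np.full(n_rays, np.nan),
                            False, 1.0)
    labels = model.classify(polar)
    is_lumen = labels == CLASS_INDEX["lumen"]
    is_bg = labels == CLASS_INDEX["background"]
    is_cp = labels == CLASS_INDEX["CP"]
    if clean_labels:
        is_lumen = _majority33(is_lumen)
        is_bg = _majority33(is_bg)
        is_cp = _majority33(is_cp)

    k_guard = int(np.ceil(guard_mm / radial_step))
    lumen_r = np.full(n_rays, np.nan)
    outer_r = np.full(n_rays, np.nan)
    cp_blocked = np.zeros(n_rays, dtype=bool)
    for j in range(n_rays):
        ro = roi[j]
        if ro < k_guard:
            continue
        ks = np.arange(k_guard, ro + 1)
        non_lumen = ks[~is_lumen[j, ks]]
        non_bg = ks[~is_bg[j, ks]]
        if len(non_lumen) == 0 or len(non_bg) == 0:
            continue
        k_l = int(non_lumen[0])
        k_o = int(non_bg[-1])
        # calcium blooms over the thin outer tissue band, so the outer
        # border behind calcium is not measurable; flag the ray and fill
        # it from clean neighbours afterwards (lumen stays measurable:
        # its border under calcium is the lumen/calcium interface).  The
        # flag uses a fixed conventional calcium level rather than the
        # fitted means so that refits cannot toggle the blocked set.
        cp_blocked[j] = bool(np.any(polar[j, ks] > calcium_block_hu))
        if refine:
            nk_last = polar.shape[1] - 1
            # bounds keep each refinement inside its own transition: the
            # lumen edge must not look beyond the outer border and the
            # outer edge must not look inward past the lumen border
            lumen_r[j] = refine_edge(polar[j], k_l, radial_step,
                                     lo=0, hi=min(k_o, nk_last),
                                     inside_end=k_l - 1, window=refine_window)
            outer_r[j] = refine_edge(polar[j], k_o, radial_step,
                                     lo=k_l, hi=nk_last,
                                     inside_end=k_o, window=refine_window)
        else:
            lumen_r[j] = k_l * radial_step
            outer_r[j] = k_o * radial_step

    undef = ~(np.isfinite(lumen_r) & np.isfinite(outer_r))
    frac = float(undef.mean())
    if frac > 0.25:
        log.info("section invalid: %.0f%% of rays undefined", 100 * frac)
        return WallContours(lumen_r, outer_r, False, frac)
    lumen_r[undef] = np.nan
    outer_r[undef] = np.nan
    if cp_blocked.any():
        # widen by two rays: partial volume smears calcium angularly
        pad = np.r_[cp_blocked[-2:], cp_blocked, cp_blocked[:2]]
        cp_blocked = ndimage.binary_dilation(pad, np.ones(5, bool))[2:-2]
        if not cp_blocked.all():
            outer_r[cp_blocked] = np.nan
    lumen_r = _circular_interp(lumen_r)
    outer_r = _circular_interp(outer_r)
    lumen_r = _circular_smooth(lumen_r, smooth_window)
    outer_r = _circular_smooth(outer_r, smooth_window)
    lumen_r = np.minimum(lumen_r, outer_r)
    return WallContours(lumen_r, outer_r, True, frac)


@dataclass
class PlaqueRegion:
    """One 2D plaque region on a section, in polar bins."""

    mask: np.ndarray              # (n_rays, K+1) bool
    area: float                   # mm^2, physical bin areas
    rays: np.ndarray              # sorted ray indices occupied
    radial_step: float
    n_rays: int
    station_index: int = -1
    station: float = 0.0
    polar: np.ndarray | None = None   # the section's HU profile, for
                                      # sub-bin boundary refinement


def extract_plaque_regions(polar: np.ndarray, walls: WallContours,
                           model: HuMixtureModel, plaque_class: str = "CP",
                           prob_threshold: float = 0.5,
                           radial_step: float = 0.1,
                           annulus_margin: float = 0.2) -> list[PlaqueRegion]:
    """Wrap-aware connected components of high-posterior plaque bins.

    Only bins inside the wall annulus count, with a small radial margin
    (mm) because the detected borders carry sub-voxel uncertainty — a
    calcium deposit flush with the lumen border must not be clipped.
    The area of bin (j, k) is radial_step * r_k * (2 pi / n_rays), the
    physical size of the polar cell it represents.
    """
    if not walls.valid:
        return []
    n_rays, nk = polar.shape
    r = np.arange(nk) * radial_step
    post = model.posterior(polar)[..., CLASS_INDEX[plaque_class]]
    annulus = ((r[None, :] >= walls.lumen_r[:, None] - annulus_margin)
               & (r[None, :] <= walls.outer_r[:, None] + annulus_margin))
    binary = (post > prob_threshold) & annulus
    if not binary.any():
        return []
    lab, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    # merge components touching across the 0/360 degree seam (8-connectivity)
    parent = list(range(n + 1))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    top, bot = lab[0], lab[-1]
    for k in range(nk):
        if top[k] == 0:
            continue
        for kk in (k - 1, k, k + 1):
            if 0 <= kk < nk and bot[kk] != 0:
                union(top[k], bot[kk])
    roots = np.array([find(a) for a in range(n + 1)])
    merged = roots[lab]

    regions: list[PlaqueRegion] = []
    dth = 2.0 * np.pi / n_rays
    for lbl in np.unique(merged):
        if lbl == 0:
            continue
        mask = merged == lbl
        area = float((radial_step * r[None, :] * dth * mask).sum())
        rays = np.unique(np.nonzero(mask)[0])
        regions.append(PlaqueRegion(mask, area, rays, radial_step, n_rays,
                                    polar=polar))
    regions.sort(key=lambda reg: int(reg.rays[0]))
    return regions


def contours_to_cartesian(frame: SectionFrame, radii: np.ndarray) -> np.ndarray:
    """Map a per-ray radius contour to a closed 3D curve (n_rays points).

    Point j sits at plane_origin + r_j (cos(theta_j) u + sin(theta_j) v)
    with theta_j = j * 360 / n_rays degrees, matching the polar sampling
    convention; ordering is consistent across frames.
    """
    radii = np.asarray(radii, dtype=float)
    n = len(radii)
    th = np.deg2rad(np.arange(n) * 360.0 / n)
    o = frame.plane_origin()
    return (o[None, :]
            + radii[:, None] * (np.cos(th)[:, None] * frame.u_axis
                                + np.sin(th)[:, None] * frame.v_axis))


@dataclass
class RIPSection:
    """All per-station products of stages 4-5."""

    frame: SectionFrame
    polar: np.ndarray
    roi: np.ndarray
    walls: WallContours | None = None
    regions: list[PlaqueRegion] = field(default_factory=list)
    station_index: int = -1

    @property
    def valid(self) -> bool:
        return self.walls is not None and self.walls.valid
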