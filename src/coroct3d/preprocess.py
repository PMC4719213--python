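"""Stage 1: contrast enhancement, thresholding and vesselness filtering.

Contrast enhancement saturates a small fraction (1 % by default) of the
lowest and highest intensities and linearly remaps the rest onto the
input HU range; it operates on the global volume histogram so HU remain
comparable along the vessel.  The tissue mixture model is always fit on
the ORIGINAL HU values — the enhanced volume and the Frangi vesselness
response are used only to localize the vessel.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volume_io import ImageVolume

DEFAULT_SCALES_MM = (0.5, 1.0, 1.5, 2.0)  # coronary lumen radii


@dataclass
class VesselnessMap:
    response: np.ndarray          # in [0, 1], same grid as the input
    scales_used: tuple[float, ...]


def enhance_contrast(vol: ImageVolume, saturation_fraction: float = 0.01) -> ImageVolume:
    """Percentile-clipped linear intensity remap onto the input HU range."""
    if not (0.0 <= saturation_fraction < 0.5):
        raise ValueError("saturation_fraction must lie in [0, 0.5)")
    x = vol.voxels
    vmin, vmax = float(x.min()), float(x.max())
    if vmin == vmax:
        warnings.warn("constant volume: contrast enhancement is a no-op", stacklevel=2)
        return ImageVolume(x.copy(), vol.spacing, vol.origin, vol.direction)
    lo = float(np.quantile(x, saturation_fraction))
    hi = float(np.quantile(x, 1.0 - saturation_fraction))
    if lo == hi:  # pathological histogram; fall back to identity
        return ImageVolume(x.copy(), vol.spacing, vol.origin, vol.direction)
    y = (np.clip(x, lo, hi) - lo) / (hi - lo) * (vmax - vmin) + vmin
    return ImageVolume(y.astype(np.float32), vol.spacing, vol.origin, vol.direction)


def threshold_volume(vol: ImageVolume, low_hu: float) -> np.ndarray:
    """Binary mask of voxels with HU >= low_hu."""
    return vol.voxels >= low_hu


def compute_vesselness(vol: ImageVolume, scales_mm=DEFAULT_SCALES_MM) -> VesselnessMap:
    """Multiscale Frangi tubularity response, normalized to [0, 1].

    Frangi's default parameters are used (alpha = beta = 0.5, gamma =
    half the maximum Hessian norm); the response is the maximum over
    scales.  Scales are given in mm and converted to voxels with the
    geometric-mean spacing; strongly anisotropic grids draw a warning.
    """
    from skimage.filters import frangi

    scales_mm = tuple(float(s) for s in scales_mm)
    if len(scales_mm) == 0 or any(s <= 0 for s in scales_mm):
        raise ValueError("need at least one positive scale")
    sp = vol.spacing
    if sp.max() / sp.min() > 1.1:
        warnings.warn("anisotropic spacing: vesselness scales use the mean spacing",
                      stacklevel=2)
    px = float(np.exp(np.mean(np.log(sp))))
    sigmas = []
    for s in scales_mm:
        sig = s / px
        if sig < 1.0:
            warnings.warn(f"scale {s} mm is below one voxel; clamped", stacklevel=2)
            sig = 1.0
        sigmas.append(sig)
    resp = frangi(vol.voxels.astype(np.float64), sigmas=sorted(set(sigmas)),
                  alpha=0.5, beta=0.5, gamma=None, black_ridges=False)
    m = float(resp.max())
    if m > 0:
        resp = resp / m
    return VesselnessMap(resp.astype(np.float32), scales_mm)


def candidate_region(vol: ImageVolume, threshold_hu: float = 180.0,
                     scales_mm=DEFAULT_SCALES_MM, vesselness_cut: float = 0.05,
                     saturation_fraction: float = 0.01) -> np.ndarray:
    """Stage-1 candidate vessel mask.

    The enhanced volume is thresholded at ``threshold_hu``; the Frangi
    response marks which bright structures are tubular.  Because the
    Hessian response decays at tube ends and near boundaries, the marker
    (threshold AND response > cut) is expanded back onto the full
    thresholded structure by morphological reconstruction, which keeps
    whole vessels while discarding bright non-tubular blobs.
    """
    from skimage.morphology import reconstruction

    enhanced = enhance_contrast(vol, saturation_fraction)
    thr = threshold_volume(enhanced, threshold_hu)
    ves = compute_vesselness(vol, scales_mm)
    marker = thr & (ves.response > vesselness_cut)
    if not marker.any():
        return marker
    rec = reconstruction(marker.astype(np.uint8), thr.astype(np.uint8),
                         method="dilation", footprint=np.ones((3, 3, 3)))
    return rec.astype(bool)
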