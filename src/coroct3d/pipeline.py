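"""End-to-end six-stage reconstruction pipeline.

Stages: (1) preprocessing (contrast stretch, threshold, vesselness) to a
candidate vessel mask; (2) seeded region growing, per-slice contours and
the initial centerline; (3) the four-class HU mixture fit from the class
seed points; (4) perpendicular section frames with iterative center
correction and polar rebinning; (5) wall-border and plaque-region
detection on every section; (6) contour lofting into lumen, outer-wall
and calcified-plaque meshes with metrics.

Stage 4 output (the polar section stack) depends only on geometry, so
re-running stages 3+5+6 under a different mixture initialization — as
the sensitivity experiment does — reuses the cached sections.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from . import centerline as cl
from . import compare as cmp
from . import hu_mixture as hm
from . import preprocess as pp
from . import rip_section as rs
from . import surface3d as s3
from .volume_io import ImageVolume

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # stage 1
    saturation_fraction: float = 0.01
    threshold_hu: float = 180.0
    scales_mm: tuple = pp.DEFAULT_SCALES_MM
    vesselness_cut: float = 0.05
    # stage 2 / 4 centerline
    smoothing_window: int = 11
    step_mm: float = 0.2
    spline_smooth_per_point: float = 0.01
    # stage 3 mixture
    gmm_rng_seed: int = 0
    # per-sample log-likelihood gain threshold: tight enough that the
    # fitted parameters (hence downstream labels) do not depend on the
    # initialization path once the optimum basin is reached
    gmm_tol: float = 1e-9
    gmm_max_iter: int = 500
    gmm_dilation_mm: float = 1.5   # expected wall thickness for the fit region
    # stage 4/5 sections
    n_rays: int = 120
    radial_step_mm: float = 0.1
    max_radius_mm: float = 5.0
    half_width_mm: float = 6.0
    pixel_mm: float = 0.1
    center_iterations: int = 5
    zero_cross_hu: float = rs.ZERO_CROSS_HU
    guard_mm: float = 0.3
    contour_smooth_window: int = 7
    refine_window_bins: int = 8    # plateau window for sub-bin border
                                   # refinement, ~2 voxel spacings of bins
    calcium_block_hu: float = 500.0  # HU level flagging calcium-obscured rays
    prob_threshold: float = 0.5
    # stage 6
    object_boundary_points: int = 64

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scales_mm"] = list(self.scales_mm)
        return d


@dataclass
class ReconstructionResult:
    config: PipelineConfig
    spline: cl.CenterlineSpline
    stations: np.ndarray
    sections: list[rs.RIPSection]
    model: hm.HuMixtureModel
    lumen_mesh: s3.SurfaceMesh
    outer_mesh: s3.SurfaceMesh
    objects: list[s3.PlaqueObject3D]
    lumen_mask: np.ndarray = field(repr=False, default=None)

    @property
    def lumen_volume(self) -> float:
        return s3.mesh_volume(self.lumen_mesh)

    @property
    def outer_volume(self) -> float:
        return s3.mesh_volume(self.outer_mesh)

    def report(self) -> dict:
        valid = [s for s in self.sections if s.valid]
        objs = []
        for o in self.objects:
            m = cmp.object_metrics(o)
            objs.append({
                "tissue": o.tissue,
                "volume": m.volume,
                "surface_area": m.surface_area,
                "max_length": m.max_length,
                "inner_angle": m.inner_angle,
                "station_span": list(o.station_span),
            })
        return {
            "schema_version": 1,
            "config": self.config.to_dict(),
            "gmm": self.model.to_json(),
            "centerline_length_mm": float(self.spline.length),
            "n_sections": len(self.sections),
            "n_valid_sections": len(valid),
            "lumen_volume_mm3": self.lumen_volume,
            "outer_volume_mm3": self.outer_volume,
            "per_station": [
                {"station": float(s.frame.station),
                 "mean_lumen_radius": float(np.mean(s.walls.lumen_r)),
                 "mean_outer_radius": float(np.mean(s.walls.outer_r))}
                for s in valid
            ],
            "objects": objs,
        }


# --------------------------------------------------------------- stages 1-2

def rough_lumen(vol: ImageVolume, seed_voxel, config: PipelineConfig) -> np.ndarray:
    candidate = pp.candidate_region(
        vol, config.threshold_hu, config.scales_mm, config.vesselness_cut,
        config.saturation_fraction)
    return cl.region_grow(candidate, seed_voxel, low_hu=config.threshold_hu, vol=vol)


def extract_centerline(vol: ImageVolume, lumen_mask: np.ndarray,
                       config: PipelineConfig):
    contours = cl.slice_contours(lumen_mask, vol)
    poly = cl.initial_centerline(contours)
    window = min(config.smoothing_window, 2 * (len(poly.points) // 2) - 1)
    if window >= 3:
        poly = cl.smooth_centerline(poly, window)
    spline, stations = cl.fit_and_sample(poly, config.step_mm,
                                         config.spline_smooth_per_point)
    # the polyline runs between the first and last slice *centroids*; the
    # segmented lumen extends half a slice spacing beyond each — cover it
    # with linearly continued stations so end volume is not truncated
    ext = int(round(0.5 * float(vol.spacing[2]) / config.step_mm))
    if ext > 0:
        step = config.step_mm
        before = stations[0] - step * np.arange(ext, 0, -1)
        after = stations[-1] + step * np.arange(1, ext + 1)
        stations = np.concatenate([before, stations, after])
    return spline, stations


# ----------------------------------------------------------------- stage 3

def auto_class_seeds(truth) -> dict:
    """Interior voxel of each ground-truth class mask.

    Headless stand-in for the interactive class-point picking: voxels
    well inside their class mask (at least two voxels from any class
    border, by the Euclidean distance transform) mimic what a careful
    user would click.  For the vessel classes the deepest voxel is
    taken; for background, the interior voxel closest to the vessel —
    a user clicks near the artery, not in a far corner of the scan.
    """
    seeds = {}
    bg_like = truth.class_masks["background"]
    d_vessel = ndimage.distance_transform_edt(bg_like)
    for c in hm.CLASSES:
        mask = truth.class_masks[c]
        if not mask.any():
            raise ValueError(f"phantom has no voxels of class {c}")
        dist = ndimage.distance_transform_edt(mask)
        interior = np.zeros_like(mask)
        interior[2:-2, 2:-2, 2:-2] = True
        if c == "background":
            cand = (dist >= 2.0) & interior
            if not cand.any():
                cand = mask
            score = np.where(cand, -d_vessel, -np.inf)
            idx = np.unravel_index(int(np.argmax(score)), mask.shape)
        else:
            idx = np.unravel_index(int(np.argmax(dist * interior)), mask.shape)
        seeds[c] = hm.ClassSeed(tuple(int(v) for v in idx))
    return seeds


def gmm_fit_region(vol: ImageVolume, lumen_mask: np.ndarray,
                   config: PipelineConfig) -> np.ndarray:
    """HU samples for the mixture fit: the rough lumen dilated by the
    expected wall thickness plus two voxels, covering the artery and its
    immediate surroundings."""
    sp = float(np.min(vol.spacing))
    iters = int(np.ceil(config.gmm_dilation_mm / sp)) + 2
    region = ndimage.binary_dilation(lumen_mask, structure=np.ones((3, 3, 3)),
                                     iterations=iters)
    return vol.voxels[region].astype(float)


def fit_tissue_model(vol: ImageVolume, lumen_mask: np.ndarray, seeds: dict,
                     config: PipelineConfig) -> hm.HuMixtureModel:
    labeled = hm.expand_seeds(vol, seeds, rng_seed=config.gmm_rng_seed)
    samples = gmm_fit_region(vol, lumen_mask, config)
    return hm.fit_em(samples, labeled, tol=config.gmm_tol,
                     max_iter=config.gmm_max_iter)


# ----------------------------------------------------------------- stage 4

def build_sections(vol: ImageVolume, spline: cl.CenterlineSpline,
                   stations: np.ndarray, config: PipelineConfig,
                   model: hm.HuMixtureModel | None = None,
                   ) -> list[rs.RIPSection]:
    frames = rs.build_frames(spline, stations)
    sections = []
    for i, frame in enumerate(frames):
        frame, _ = rs.correct_center(
            vol, frame, config.center_iterations, config.threshold_hu,
            config.max_radius_mm, config.half_width_mm, config.pixel_mm,
            model=model)
        img = rs.sample_rip(vol, frame, config.half_width_mm, config.pixel_mm)
        polar = rs.to_polar(img, config.n_rays, config.radial_step_mm,
                            config.max_radius_mm, config.pixel_mm)
        roi = rs.extract_roi(polar, config.zero_cross_hu)
        sections.append(rs.RIPSection(frame, polar, roi, station_index=i))
    return sections


# -------------------------------------------------------------- stages 5-6

def detect_and_mesh(sections: list[rs.RIPSection], model: hm.HuMixtureModel,
                    config: PipelineConfig, axial_support_mm: float = 0.0):
    """Stage 5-6 on a (possibly cached) section stack with a given model."""
    for sec in sections:
        sec.walls = rs.detect_walls(
            sec.polar, sec.roi, model, config.radial_step_mm, config.guard_mm,
            config.contour_smooth_window, refine_window=config.refine_window_bins,
            calcium_block_hu=config.calcium_block_hu)
        sec.regions = rs.extract_plaque_regions(
            sec.polar, sec.walls, model, "CP", config.prob_threshold,
            config.radial_step_mm) if sec.walls.valid else []
    valid = [s for s in sections if s.valid]
    if len(valid) < 2:
        raise RuntimeError("fewer than 2 valid sections; cannot mesh")
    lumen_contours = np.asarray([
        rs.contours_to_cartesian(s.frame, s.walls.lumen_r) for s in valid])
    outer_contours = np.asarray([
        rs.contours_to_cartesian(s.frame, s.walls.outer_r) for s in valid])
    lumen_mesh = s3.loft_mesh(lumen_contours, cap_ends=True)
    outer_mesh = s3.loft_mesh(outer_contours, cap_ends=True)

    per_section = [(s.station_index, float(s.frame.station), s.regions)
                   for s in valid]
    objects = s3.link_objects(per_section, "CP", station_step=config.step_mm)
    for obj in objects:
        obj.axial_support_mm = axial_support_mm
    frames_by_idx = {s.station_index: s.frame for s in sections}
    for obj in objects:
        s3.build_object_mesh(obj, frames_by_idx, config.object_boundary_points)
    return lumen_mesh, outer_mesh, objects


# ------------------------------------------------------------- entry points

def reconstruct(vol: ImageVolume, seed_voxel, class_seeds: dict,
                config: PipelineConfig | None = None) -> ReconstructionResult:
    """Run all six stages and return meshes, sections, model and report."""
    config = config or PipelineConfig()
    log.info("stage 1-2: candidate region and rough lumen")
    lumen_mask = rough_lumen(vol, seed_voxel, config)
    spline, stations = extract_centerline(vol, lumen_mask, config)
    log.info("centerline length %.1f mm, %d stations", spline.length, len(stations))
    log.info("stage 3: HU mixture fit")
    model = fit_tissue_model(vol, lumen_mask, class_seeds, config)
    log.info("stage 4: %d sections", len(stations))
    sections = build_sections(vol, spline, stations, config, model)
    log.info("stage 5-6: walls, plaque regions, meshes")
    lumen_mesh, outer_mesh, objects = detect_and_mesh(
        sections, model, config, axial_support_mm=float(np.max(vol.spacing)))
    return ReconstructionResult(config, spline, stations, sections, model,
                                lumen_mesh, outer_mesh, objects, lumen_mask)


@dataclass
class SensitivityResult:
    min_C: float
    records: list[dict]      # per artery/wall/delta_T retention values
    n_runs: int


def gmm_sensitivity(arteries: dict[str, tuple[ImageVolume, dict, np.ndarray]],
                    deltas=hm.DELTA_T_GRID, rng_seed: int = 0,
                    config: PipelineConfig | None = None) -> SensitivityResult:
    """Volume retention under random-sign perturbation of the class points.

    ``arteries`` maps a name to (volume, class_seeds, lumen_mask).  For
    each artery the geometric stages run once; for every delta-T each
    class seed HU is shifted by +/- delta-T (probability 0.5 each), the
    mixture is refit and the walls re-detected and re-meshed.  Records
    C = 100 (1 - |V - V0| / V0) for inner and outer wall volumes; the
    headline number is the minimum C over arteries, walls and delta-Ts.
    """
    config = config or PipelineConfig()
    records: list[dict] = []
    for name, (vol, seeds, lumen_mask) in arteries.items():
        spline, stations = extract_centerline(vol, lumen_mask, config)
        seeds0 = hm.resolve_seed_hu(vol, seeds)
        model0 = fit_tissue_model(vol, lumen_mask, seeds0, config)
        sections = build_sections(vol, spline, stations, config, model0)
        support = float(np.max(vol.spacing))
        lumen0, outer0, _ = detect_and_mesh(sections, model0, config, support)
        v0_in, v0_out = s3.mesh_volume(lumen0), s3.mesh_volume(outer0)
        for t_i, dT in enumerate(deltas):
            name_tag = sum(ord(ch) for ch in name)  # stable across runs
            sub_seed = (rng_seed * 1009 + t_i * 97 + name_tag) % (2 ** 31)
            perturbed = hm.perturb_seeds(seeds0, dT, rng_seed=sub_seed)
            model = fit_tissue_model(vol, lumen_mask, perturbed, config)
            lumen_m, outer_m, _ = detect_and_mesh(sections, model, config, support)
            c_in = hm.sensitivity_C(v0_in, s3.mesh_volume(lumen_m))
            c_out = hm.sensitivity_C(v0_out, s3.mesh_volume(outer_m))
            records.append({"artery": name, "delta_T": float(dT),
                            "C_inner": c_in, "C_outer": c_out})
            log.info("%s dT=%g: C_inner=%.3f C_outer=%.3f", name, dT, c_in, c_out)
    min_c = min(min(r["C_inner"], r["C_outer"]) for r in records)
    return SensitivityResult(min_c, records, 2 * len(records))
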