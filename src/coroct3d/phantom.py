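"""Synthetic CTA vessel phantoms with analytic ground truth.

A phantom is a contrast-filled tubular lumen following a straight or
helical centerline, wrapped in a soft (non-calcified) wall annulus, with
optional calcified arcs embedded in the wall, all floating in background
tissue.  Each voxel takes the tissue class of its center point and draws
its HU value from that class's Gaussian, so the geometric ground truth
(class masks, centerline, analytic volumes/angles/lengths) is exact.

Default HU distributions per class:

==========  ==========  ========
class       mean (HU)   std (HU)
==========  ==========  ========
lumen          350         40
CP             800         80
NCP             60         25
background     -50         60
==========  ==========  ========

The lumen mean sits far above the 180 HU contrast-arrival level used to
trigger clinical acquisitions, calcium sits above the lumen, soft plaque
near muscle/fibrous tissue, and the broad background straddles fat and
air so that a fraction of background voxels falls below the -130 HU
zero-cross level used for ROI extraction.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.integrate import quad
from scipy.spatial import cKDTree

CLASS_NAMES = ("lumen", "CP", "NCP", "background")
_CLASS_INDEX = {name: i for i, name in enumerate(CLASS_NAMES)}


def default_hu_params() -> dict[str, tuple[float, float]]:
    """Per-class (mean, std) HU of the default phantom tissue model."""
    return {
        "lumen": (350.0, 40.0),
        "CP": (800.0, 80.0),
        "NCP": (60.0, 25.0),
        "background": (-50.0, 60.0),
    }


@dataclass
class PlaqueArc:
    """An arc-shaped plaque deposit embedded in the wall annulus.

    The arc occupies stations [start_station, end_station] mm, the
    angular range [angular_start, angular_start + angular_extent) degrees
    and radii (lumen_radius, lumen_radius + radial_thickness] mm.
    """

    tissue: str = "CP"
    start_station: float = 5.0
    end_station: float = 15.0
    angular_start: float = 0.0
    angular_extent: float = 120.0
    radial_thickness: float = 0.6


@dataclass
class PhantomSpec:
    curve: str = "straight"            # "straight" | "helical"
    length: float = 20.0               # mm along the centerline
    helix_radius: float = 3.0          # mm (helical only)
    helix_pitch: float = 30.0          # mm rise per turn (helical only)
    lumen_radius: float | tuple[float, float] = 1.5   # mm; pair = linear taper
    wall_thickness: float = 1.0        # mm
    plaque_arcs: list[PlaqueArc] = field(default_factory=list)
    hu_params: dict[str, tuple[float, float]] = field(default_factory=default_hu_params)
    voxel_spacing: float = 0.4         # mm, isotropic
    margin: float = 2.0                # mm of background around the vessel
    air_border: bool = False           # -1000 HU one-voxel frame
    noise_seed: int = 0

    def lumen_radius_at(self, s) -> np.ndarray:
        """Lumen radius r(s) in mm; linear in s when a pair is given."""
        s = np.asarray(s, dtype=float)
        if np.isscalar(self.lumen_radius) or isinstance(self.lumen_radius, (int, float)):
            return np.full_like(s, float(self.lumen_radius))
        r0, r1 = (float(v) for v in self.lumen_radius)
        return r0 + (r1 - r0) * np.clip(s / self.length, 0.0, 1.0)

    def validate(self) -> None:
        if self.curve not in ("straight", "helical"):
            raise ValueError(f"unknown curve kind {self.curve!r}")
        if self.length <= 0 or self.wall_thickness <= 0 or self.voxel_spacing <= 0:
            raise ValueError("length, wall_thickness and voxel_spacing must be > 0")
        rmin = float(np.min(self.lumen_radius_at(np.linspace(0, self.length, 64))))
        if rmin < 2.0 * self.voxel_spacing:
            raise ValueError(
                f"lumen radius {rmin:.3f} mm < 2 voxels "
                f"({2 * self.voxel_spacing:.3f} mm): unresolvable geometry"
            )
        means = {c: self.hu_params[c][0] for c in CLASS_NAMES}
        if not (means["CP"] > means["lumen"] > means["NCP"] > means["background"]):
            raise ValueError("class HU means must be ordered CP > lumen > NCP > background")
        for arc in self.plaque_arcs:
            if arc.tissue not in ("CP", "NCP"):
                raise ValueError(f"plaque arc tissue must be CP or NCP, got {arc.tissue!r}")
            if not (0.0 < arc.angular_extent <= 360.0):
                raise ValueError("angular_extent must lie in (0, 360]")
            if not (0.0 <= arc.start_station < arc.end_station <= self.length):
                raise ValueError("plaque arc stations must lie within [0, length]")
            if not (0.0 < arc.radial_thickness <= self.wall_thickness):
                raise ValueError("plaque arcs must lie within the wall annulus")


@dataclass
class GroundTruth:
    class_masks: dict[str, np.ndarray]
    true_centerline: np.ndarray            # (n, 3) world mm, every 0.2 mm
    analytic: dict                          # exact volumes / angles / lengths

    def save_json(self, path) -> Path:
        path = Path(path)
        payload = {"analytic": self.analytic,
                   "true_centerline": self.true_centerline.tolist()}
        path.write_text(json.dumps(payload, indent=1))
        return path


def _curve(spec: PhantomSpec, ds: float = 0.05):
    """Sample the centerline by arc length; returns (s, points, tangents)."""
    s = np.arange(0.0, spec.length + ds * 0.5, ds)
    if spec.curve == "straight":
        pts = np.column_stack([np.zeros_like(s), np.zeros_like(s), s])
        tan = np.tile([0.0, 0.0, 1.0], (len(s), 1))
    else:
        R, P = spec.helix_radius, spec.helix_pitch
        l_turn = np.hypot(2 * np.pi * R, P)
        k, h = 2 * np.pi / l_turn, P / l_turn
        pts = np.column_stack([R * np.cos(k * s), R * np.sin(k * s), h * s])
        tan = np.column_stack([-R * k * np.sin(k * s), R * k * np.cos(k * s),
                               np.full_like(s, h)])
        tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    return s, pts, tan


def _transport_frames(tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation-minimizing in-plane axes (u, v) along a tangent sequence."""
    n = len(tangents)
    u = np.empty((n, 3))
    v = np.empty((n, 3))
    t0 = tangents[0]
    ref = np.eye(3)[np.argmin(np.abs(t0))]
    u[0] = np.cross(t0, ref)
    u[0] /= np.linalg.norm(u[0])
    v[0] = np.cross(t0, u[0])
    for i in range(1, n):
        t = tangents[i]
        ui = u[i - 1] - np.dot(u[i - 1], t) * t
        norm = np.linalg.norm(ui)
        if norm < 1e-12:  # degenerate: keep previous axis
            ui, norm = u[i - 1], 1.0
        u[i] = ui / norm
        v[i] = np.cross(t, u[i])
    return u, v


def _angle_in_arc(angle_deg: np.ndarray, start: float, extent: float) -> np.ndarray:
    rel = np.mod(angle_deg - start, 360.0)
    return rel < extent


def generate_phantom(spec: PhantomSpec) -> tuple["ImageVolume", GroundTruth]:
    """Voxelize the phantom and draw HU noise; deterministic per noise_seed."""
    from .volume_io import ImageVolume

    spec.validate()
    s_dense, pts, tan = _curve(spec)
    u_ax, v_ax = _transport_frames(tan)

    r_out = float(np.max(spec.lumen_radius_at(s_dense))) + spec.wall_thickness
    pad = r_out + spec.margin
    lo = pts.min(axis=0) - pad
    hi = pts.max(axis=0) + pad
    sp = spec.voxel_spacing
    shape = np.ceil((hi - lo) / sp).astype(int) + 1
    origin = lo

    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    centers = origin + np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * sp

    tree = cKDTree(pts)
    dist, idx = tree.query(centers, workers=-1)
    delta = centers - pts[idx]
    t_near = tan[idx]
    axial = np.einsum("ij,ij->i", delta, t_near)
    s_vox = s_dense[idx] + axial
    radial_vec = delta - axial[:, None] * t_near
    d = np.linalg.norm(radial_vec, axis=1)
    ang = np.degrees(np.arctan2(np.einsum("ij,ij->i", radial_vec, v_ax[idx]),
                                np.einsum("ij,ij->i", radial_vec, u_ax[idx]))) % 360.0

    in_span = (s_vox >= 0.0) & (s_vox <= spec.length)
    r_s = spec.lumen_radius_at(np.clip(s_vox, 0.0, spec.length))
    labels = np.full(centers.shape[0], _CLASS_INDEX["background"], dtype=np.uint8)
    lumen = in_span & (d <= r_s)
    wall = in_span & ~lumen & (d <= r_s + spec.wall_thickness)
    labels[lumen] = _CLASS_INDEX["lumen"]
    labels[wall] = _CLASS_INDEX["NCP"]
    for arc in spec.plaque_arcs:
        sel = (in_span & (s_vox >= arc.start_station) & (s_vox <= arc.end_station)
               & (d > r_s) & (d <= r_s + arc.radial_thickness)
               & _angle_in_arc(ang, arc.angular_start, arc.angular_extent))
        labels[sel] = _CLASS_INDEX[arc.tissue]

    rng = np.random.default_rng(spec.noise_seed)
    hu = np.empty(centers.shape[0], dtype=np.float32)
    for name in CLASS_NAMES:
        m = labels == _CLASS_INDEX[name]
        mean, std = spec.hu_params[name]
        hu[m] = rng.normal(mean, std, int(m.sum()))

    labels = labels.reshape(shape)
    hu = hu.reshape(shape)
    if spec.air_border:
        border = np.zeros(shape, dtype=bool)
        border[[0, -1], :, :] = True
        border[:, [0, -1], :] = True
        border[:, :, [0, -1]] = True
        hu[border] = -1000.0

    vol = ImageVolume(hu, np.full(3, sp), origin).clamp_hu()
    masks = {name: labels == _CLASS_INDEX[name] for name in CLASS_NAMES}
    truth = GroundTruth(
        class_masks=masks,
        true_centerline=pts[:: max(1, int(round(0.2 / 0.05)))],
        analytic=_analytic_quantities(spec),
    )
    return vol, truth


def _analytic_quantities(spec: PhantomSpec) -> dict:
    r = lambda s: float(spec.lumen_radius_at(s))
    w = spec.wall_thickness
    lumen_volume = quad(lambda s: np.pi * r(s) ** 2, 0, spec.length, limit=200)[0]
    outer_volume = quad(lambda s: np.pi * (r(s) + w) ** 2, 0, spec.length, limit=200)[0]
    plaques = []
    for arc in spec.plaque_arcs:
        ext = np.radians(arc.angular_extent)
        vol = quad(
            lambda s: 0.5 * ext * ((r(s) + arc.radial_thickness) ** 2 - r(s) ** 2),
            arc.start_station, arc.end_station, limit=200,
        )[0]
        plaques.append({
            "tissue": arc.tissue,
            "volume": vol,
            "inner_angle": arc.angular_extent,
            "length": arc.end_station - arc.start_station,
        })
    return {
        "lumen_volume": lumen_volume,
        "outer_volume": outer_volume,
        "wall_volume": outer_volume - lumen_volume,
        "plaques": plaques,
    }


def study_arteries(base_seed: int = 0) -> dict[str, PhantomSpec]:
    """The three phantom arteries used in the sensitivity experiment.

    One straight, one helical (gentle curvature: 3 mm helix radius,
    30 mm pitch) and one stenosed (lumen tapering 1.8 -> 1.2 mm), each
    20 mm long with a 1 mm soft wall and one calcified arc.
    """
    return {
        "straight": PhantomSpec(
            curve="straight", noise_seed=base_seed * 3 + 11,
            plaque_arcs=[PlaqueArc("CP", 5.0, 15.0, 0.0, 120.0, 0.6)],
        ),
        "helical": PhantomSpec(
            curve="helical", noise_seed=base_seed * 3 + 12,
            plaque_arcs=[PlaqueArc("CP", 6.0, 14.0, 40.0, 90.0, 0.6)],
        ),
        "stenosed": PhantomSpec(
            curve="straight", lumen_radius=(1.8, 1.2), noise_seed=base_seed * 3 + 13,
            plaque_arcs=[PlaqueArc("CP", 8.0, 16.0, 200.0, 100.0, 0.6)],
        ),
    }


# ---------------------------------------------------------------- YAML I/O

def spec_to_yaml(spec: PhantomSpec, path) -> Path:
    import yaml

    path = Path(path)
    d = asdict(spec)
    path.write_text(yaml.safe_dump(d, sort_keys=False))
    return path


def spec_from_yaml(path) -> PhantomSpec:
    import yaml

    d = yaml.safe_load(Path(path).read_text())
    arcs = [PlaqueArc(**a) for a in d.pop("plaque_arcs", [])]
    hu = {k: tuple(v) for k, v in d.pop("hu_params", default_hu_params()).items()}
    lr = d.get("lumen_radius")
    if isinstance(lr, (list, tuple)):
        d["lumen_radius"] = tuple(float(v) for v in lr)
    spec = PhantomSpec(plaque_arcs=arcs, hu_params=hu, **d)
    spec.validate()
    return spec
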