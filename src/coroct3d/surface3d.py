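"""Stage 6: contour lofting into triangle meshes and 3D plaque objects.

Border points of two sequential sections are connected into a triangle
strip: each pair of N-point contours yields exactly 2N triangles (each
quad split along a diagonal); end caps are fan triangulations so capped
meshes are watertight.  Plaque regions on consecutive stations whose
angular footprints overlap are linked into 3D objects, whose boundary
curves are lofted the same way.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .rip_section import PlaqueRegion, SectionFrame

log = logging.getLogger(__name__)


@dataclass
class SurfaceMesh:
    vertices: np.ndarray           # (V, 3) mm
    faces: np.ndarray              # (F, 3) vertex index triples
    closed: bool = False

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)


def loft_mesh(contours: np.ndarray, cap_ends: bool = False) -> SurfaceMesh:
    """Triangle mesh connecting sequential closed contours.

    ``contours`` has shape (F, N, 3): F frames of N consistently ordered
    points.  Side walls contribute 2*N*(F-1) triangles; with
    ``cap_ends`` a centroid-fan cap (N triangles each) closes both ends.
    """
    contours = np.asarray(contours, dtype=float)
    if contours.ndim != 3 or contours.shape[2] != 3:
        raise ValueError("contours must have shape (frames, N, 3)")
    F, N, _ = contours.shape
    if F < 2:
        raise ValueError("need at least two contours to loft")
    verts = contours.reshape(F * N, 3)
    faces = []
    for i in range(F - 1):
        a = i * N
        b = (i + 1) * N
        for j in range(N):
            jn = (j + 1) % N
            faces.append([a + j, b + j, b + jn])
            faces.append([a + j, b + jn, a + jn])
    closed = False
    if cap_ends:
        c0 = contours[0].mean(axis=0)
        c1 = contours[-1].mean(axis=0)
        verts = np.vstack([verts, c0, c1])
        i0, i1 = F * N, F * N + 1
        for j in range(N):
            jn = (j + 1) % N
            # winding chosen to match the side strips so the closed mesh
            # is consistently oriented (divergence-theorem volume needs it)
            faces.append([i0, j, jn])                     # first ring
            faces.append([i1, (F - 1) * N + jn, (F - 1) * N + j])  # last ring
        closed = True
    mesh = SurfaceMesh(verts, np.asarray(faces), closed=closed)
    if _has_self_intersecting_contour(contours):
        warnings.warn("self-intersecting contour; mesh built anyway", stacklevel=2)
    return mesh


def _has_self_intersecting_contour(contours: np.ndarray) -> bool:
    # cheap proxy: a simple closed contour has strictly positive
    # circumference and no repeated consecutive points
    seg = np.linalg.norm(np.diff(contours, axis=1), axis=2)
    return bool(np.any(seg.sum(axis=1) <= 0))


def mesh_area(mesh: SurfaceMesh) -> float:
    """Total triangle area in mm^2."""
    v = mesh.vertices
    f = mesh.faces
    if len(f) == 0:
        raise ValueError("empty mesh")
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def mesh_volume(mesh: SurfaceMesh) -> float:
    """|signed volume| by the divergence theorem; requires a closed mesh."""
    if not mesh.closed:
        raise ValueError("volume requires closed mesh")
    v = mesh.vertices
    f = mesh.faces
    signed = np.einsum("ij,ij->i", v[f[:, 0]],
                       np.cross(v[f[:, 1]], v[f[:, 2]])).sum() / 6.0
    return float(abs(signed))


@dataclass
class PlaqueObject3D:
    """A linked 3D plaque object: one region per consecutive station."""

    tissue: str
    sections: list[tuple[float, PlaqueRegion]]     # (station mm, region)
    mesh: SurfaceMesh | None = None
    station_step: float = 0.2
    axial_support_mm: float = 0.0   # voxel support width for sub-station
                                    # end-face localization (0 = off)

    @property
    def station_span(self) -> tuple[float, float]:
        return (self.sections[0][0], self.sections[-1][0])

    @property
    def n_sections(self) -> int:
        return len(self.sections)


def link_objects(per_section_regions: list[tuple[int, float, list[PlaqueRegion]]],
                 tissue: str = "CP", max_gap: int = 0,
                 station_step: float = 0.2) -> list[PlaqueObject3D]:
    """Join regions on consecutive stations with overlapping ray footprints.

    ``per_section_regions`` lists (station_index, station_mm, regions).
    Regions whose angular footprints (sets of occupied rays) intersect
    on stations at most ``max_gap + 1`` indices apart become one object;
    objects covering fewer than 2 stations are discarded.
    """
    nodes: list[tuple[int, float, PlaqueRegion]] = []
    for si, s_mm, regions in per_section_regions:
        for reg in regions:
            reg.station_index = si
            reg.station = s_mm
            nodes.append((si, s_mm, reg))
    n = len(nodes)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    by_station: dict[int, list[int]] = {}
    for i, (si, _, _) in enumerate(nodes):
        by_station.setdefault(si, []).append(i)
    for si, idxs in by_station.items():
        for gap in range(1, max_gap + 2):
            for j in by_station.get(si + gap, []):
                for i in idxs:
                    ra = nodes[i][2].rays
                    rb = nodes[j][2].rays
                    if np.intersect1d(ra, rb, assume_unique=True).size:
                        union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    objects = []
    for idxs in groups.values():
        stations = sorted({nodes[i][0] for i in idxs})
        if len(stations) < 2:
            continue
        # one region per station: fragments of the same object on the same
        # slice are re-joined so per-slice angles and lofted curves see the
        # whole footprint
        secs = []
        for si in stations:
            regs = [nodes[i][2] for i in idxs if nodes[i][0] == si]
            secs.append((regs[0].station, _merge_regions(regs)))
        objects.append(PlaqueObject3D(tissue, secs, station_step=station_step))
    objects.sort(key=lambda o: o.station_span[0])
    return objects


def _merge_regions(regions: list[PlaqueRegion]) -> PlaqueRegion:
    if len(regions) == 1:
        return regions[0]
    first = regions[0]
    mask = np.logical_or.reduce([r.mask for r in regions])
    rays = np.unique(np.concatenate([r.rays for r in regions]))
    return PlaqueRegion(mask, sum(r.area for r in regions), rays,
                        first.radial_step, first.n_rays, first.station_index,
                        first.station, first.polar)


def _arc_order(rays: np.ndarray, n_rays: int) -> np.ndarray:
    """Occupied rays reordered to run along the covering arc."""
    rs = np.sort(rays)
    if len(rs) == 1:
        return rs
    gaps = np.diff(np.r_[rs, rs[0] + n_rays])
    start = (int(np.argmax(gaps)) + 1) % len(rs)
    return np.r_[rs[start:], rs[:start]]


def region_boundary_3d(region: PlaqueRegion, frame: SectionFrame,
                       n_points: int = 64) -> np.ndarray:
    """Closed 3D boundary curve of a polar plaque region, resampled.

    The outline follows the outer radial extent of each occupied ray
    along the arc, then the inner extent backwards, with half-bin
    margins so the curve encloses the physical bins.  Resampled to a
    fixed number of points by arc length for frame-to-frame lofting.
    """
    from .rip_section import refine_edge

    h = region.radial_step
    order = _arc_order(region.rays, region.n_rays)
    th = np.deg2rad(order * 360.0 / region.n_rays)
    r_in = np.empty(len(order))
    r_out = np.empty(len(order))
    nk = region.mask.shape[1]
    for i, j in enumerate(order):
        ks = np.nonzero(region.mask[j])[0]
        k_in, k_out = int(ks.min()), int(ks.max())
        if region.polar is not None:
            # sub-bin localization of the plaque's radial faces (the
            # posterior-threshold bins inherit the mixture-weight bias);
            # the inside plateau window cannot exceed the region thickness
            w = int(np.clip(k_out - k_in + 1, 3, 8))
            r_out[i] = refine_edge(region.polar[j], k_out, h,
                                   lo=k_in, hi=nk - 1, inside_end=k_out,
                                   window=w, gap=2)
            prof_rev = region.polar[j][::-1]
            k_rev = nk - 1 - k_in
            rin_rev = refine_edge(prof_rev, k_rev, h, lo=nk - 1 - k_out,
                                  hi=nk - 1, inside_end=k_rev,
                                  window=w, gap=2)
            r_in[i] = max((nk - 1) * h - rin_rev, 0.0)
            if r_in[i] >= r_out[i]:       # fall back to bin extents
                r_in[i] = max(k_in * h - 0.5 * h, 0.0)
                r_out[i] = k_out * h + 0.5 * h
        else:
            r_in[i] = max(k_in * h - 0.5 * h, 0.0)
            r_out[i] = k_out * h + 0.5 * h
    # closed polygon in the section plane: outer arc forward, inner back
    ang = np.r_[th, th[::-1]]
    rad = np.r_[r_out, r_in[::-1]]
    o = frame.plane_origin()
    poly = (o[None, :] + rad[:, None] * (np.cos(ang)[:, None] * frame.u_axis
                                         + np.sin(ang)[:, None] * frame.v_axis))
    return _resample_closed(poly, n_points)


def _resample_closed(poly: np.ndarray, n_points: int) -> np.ndarray:
    closed = np.vstack([poly, poly[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.r_[0.0, np.cumsum(seg)]
    total = s[-1]
    if total <= 0:
        return np.tile(poly[0], (n_points, 1))
    targets = np.linspace(0.0, total, n_points, endpoint=False)
    out = np.empty((n_points, 3))
    for d in range(3):
        out[:, d] = np.interp(targets, s, closed[:, d])
    return out


def build_object_mesh(obj: PlaqueObject3D,
                      frames_by_station_index: dict[int, SectionFrame],
                      n_points: int = 64) -> SurfaceMesh:
    """Loft a plaque object's per-station boundary curves; capped ends."""
    curves = []
    for _, region in obj.sections:
        frame = frames_by_station_index[region.station_index]
        curves.append(region_boundary_3d(region, frame, n_points))
    mesh = loft_mesh(np.asarray(curves), cap_ends=True)
    obj.mesh = mesh
    return mesh
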