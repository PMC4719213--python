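"""Reading and writing of CT volumes and surface meshes.

Volumes are held as :class:`ImageVolume`: a 3D array of Hounsfield units
(HU) on a regular grid with physical spacing, origin and an orthonormal
direction matrix.  The convention used everywhere in this package is

    world = origin + direction @ (index * spacing)

with 0-based voxel indices.  DICOM series and NIfTI-1 files are read
through :mod:`pydicom` and :mod:`nibabel`; meshes are exported through
:mod:`trimesh` (binary STL or Wavefront OBJ).
"""
from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

HU_MIN = -1024.0
HU_MAX = 3071.0


@dataclass
class ImageVolume:
    """A 3D HU image with physical geometry.

    voxels are indexed ``[i, j, k]``; ``spacing`` is the per-axis voxel
    size in mm and ``direction`` the orthonormal axis matrix whose
    columns are the world directions of the i, j and k axes.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3D array")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("all spacing components must be > 0")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix must be orthonormal (tol 1e-6)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices (may be fractional) to world mm."""
        idx = np.asarray(idx, dtype=float)
        return self.origin + (idx * self.spacing) @ self.direction.T

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map (..., 3) world points in mm to fractional voxel indices."""
        pts = np.asarray(pts, dtype=float)
        return ((pts - self.origin) @ self.direction) / self.spacing

    def clamp_hu(self) -> "ImageVolume":
        np.clip(self.voxels, HU_MIN, HU_MAX, out=self.voxels)
        return self


def _detect_format(path: Path) -> str:
    if path.is_dir():
        return "dicom_series"
    name = path.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    raise ValueError(f"cannot infer volume format from {path}")


def read_volume(path, fmt: str | None = None) -> ImageVolume:
    """Read a DICOM series directory or NIfTI file into an :class:`ImageVolume`.

    HU values are clamped to the 12-bit CT range [-1024, 3071] on read so
    that sentinel padding values cannot corrupt downstream statistics.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = fmt or _detect_format(path)
    if fmt == "nifti":
        vol = _read_nifti(path)
    elif fmt == "dicom_series":
        vol = _read_dicom_series(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return vol.clamp_hu()


def _read_nifti(path: Path) -> ImageVolume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got shape {data.shape}")
    affine = img.affine
    mat = affine[:3, :3]
    spacing = np.linalg.norm(mat, axis=0)
    if np.any(spacing <= 0):
        raise ValueError("NIfTI affine has a zero-length axis (missing spacing)")
    direction = mat / spacing
    return ImageVolume(data, spacing, affine[:3, 3], direction)


def _read_dicom_series(path: Path) -> ImageVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file() and not p.name.startswith("."))
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no DICOM image slices found in {path}")
    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in slices}
    if len(uids) > 1:
        raise ValueError(f"directory {path} mixes {len(uids)} DICOM series")
    first = slices[0]
    if not hasattr(first, "PixelSpacing"):
        raise KeyError("missing DICOM tag PixelSpacing (0028,0030)")
    row_spacing, col_spacing = (float(v) for v in first.PixelSpacing)

    orient = getattr(first, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0])
    row_dir = np.asarray(orient[:3], dtype=float)   # direction across columns
    col_dir = np.asarray(orient[3:], dtype=float)   # direction across rows
    normal = np.cross(row_dir, col_dir)

    def slice_pos(ds) -> float:
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is None:
            return float(getattr(ds, "InstanceNumber", 0))
        return float(np.dot(np.asarray(ipp, dtype=float), normal))

    slices.sort(key=slice_pos)
    if len(slices) >= 2:
        positions = np.array([slice_pos(ds) for ds in slices])
        dz = float(np.median(np.diff(positions)))
        if dz <= 0:
            raise ValueError("non-increasing DICOM slice positions")
    elif hasattr(first, "SliceThickness"):
        dz = float(first.SliceThickness)
    else:
        raise KeyError("missing DICOM tag SliceThickness (0018,0050)")

    planes = []
    for ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(ds.pixel_array.astype(np.float32) * slope + intercept)
    stack = np.stack(planes, axis=-1)        # (rows, cols, k)
    voxels = np.transpose(stack, (1, 0, 2))  # (i=col, j=row, k)

    origin = np.asarray(
        getattr(slices[0], "ImagePositionPatient", [0.0, 0.0, 0.0]), dtype=float
    )
    direction = np.column_stack([row_dir, col_dir, normal])
    spacing = np.array([col_spacing, row_spacing, dz])
    return ImageVolume(voxels, spacing, origin, direction)


def write_volume(vol: ImageVolume, path) -> Path:
    """Write an :class:`ImageVolume` as NIfTI-1; round-trips losslessly."""
    import nibabel as nib

    path = Path(path)
    affine = np.eye(4)
    affine[:3, :3] = vol.direction @ np.diag(vol.spacing)
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(vol.voxels.astype(np.float32), affine)
    os.makedirs(path.parent, exist_ok=True)
    nib.save(img, str(path))
    return path


def write_mesh(mesh, path) -> Path:
    """Export a surface mesh (anything with .vertices/.faces) as STL or OBJ.

    The format is taken from the file suffix. A mesh whose faces all have
    zero area is written with a warning; an empty mesh is an error.
    """
    import trimesh

    path = Path(path)
    verts = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    if faces.size == 0:
        raise ValueError("cannot write a mesh with no triangles")
    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if float(tm.area) == 0.0:
        warnings.warn("mesh has zero total area; writing anyway", stacklevel=2)
    suffix = path.suffix.lower().lstrip(".")
    if suffix not in {"stl", "obj"}:
        raise ValueError(f"unsupported mesh format {suffix!r} (use stl or obj)")
    os.makedirs(path.parent, exist_ok=True)
    tm.export(str(path))
    return path


def read_mesh(path):
    """Load a mesh file back as a trimesh.Trimesh (testing convenience)."""
    import trimesh

    return trimesh.load(str(path), force="mesh", process=False)
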