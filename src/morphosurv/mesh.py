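"""Tumor morphometrics from segmented surfaces and masks.

Computes the two shape descriptors used for prognosis stratification in oral
cancer cohorts: tumor volume ``Vt`` and tumor (Wadell) sphericity ``St``.
Inputs are closed triangle meshes (STL, the usual export format of clinical
segmentation software) or binary voxel masks with anisotropic spacing in mm.

All geometry is computed in millimetres; reported volumes are converted to
cm³ to match the clinical convention. Sphericity compares the surface area of
the volume-equivalent sphere with the actual surface area,

    S = pi^(1/3) * (6 * V_p)^(2/3) / A_p,

so a perfect sphere scores 1 and increasingly irregular surfaces score lower.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

logger = logging.getLogger("morphosurv")

MM3_PER_CM3 = 1000.0
MM2_PER_CM2 = 100.0

#: vertices closer than this (mm) are merged when cleaning a mesh
MERGE_TOLERANCE_MM = 1e-6


class MeshValidationError(ValueError):
    """Raised when a mesh violates a geometric precondition (e.g. open edges)."""


class MaskValidationError(ValueError):
    """Raised when a voxel mask is unusable (empty foreground, bad spacing)."""


@dataclass(frozen=True)
class VoxelMask:
    """Binary segmentation on an axial grid.

    Parameters
    ----------
    grid : ndarray of bool, shape (nx, ny, nz)
        Foreground = tumor. Axis order (x, y, z), 0-based indices.
    spacing : tuple of float
        Voxel edge lengths (dx, dy, dz) in mm; all strictly positive.
    origin : tuple of float
        World coordinate (mm) of voxel (0, 0, 0).
    """

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid).astype(bool)
        object.__setattr__(self, "grid", grid)
        if grid.ndim != 3:
            raise MaskValidationError(f"mask grid must be 3D, got ndim={grid.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise MaskValidationError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def foreground_count(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class Morphometrics:
    """Per-tumor shape descriptors: ``Vt`` (cm³), surface area (cm²), ``St``."""

    volume_cm3: float
    area_cm2: float
    sphericity: float

    # clinical-shorthand aliases
    @property
    def Vt(self) -> float:
        return self.volume_cm3

    @property
    def St(self) -> float:
        return self.sphericity


# ---------------------------------------------------------------------------
# mesh ingestion
# ---------------------------------------------------------------------------

def read_mesh(path: Union[str, Path]) -> trimesh.Trimesh:
    """Read an STL file (binary or ASCII) and return a cleaned triangle mesh.

    Cleaning merges duplicate vertices (tolerance ~1e-6 mm) and drops
    degenerate (zero-area) faces so downstream invariants are checkable.
    Whether the mesh is watertight is logged; it is *not* enforced here
    because surface-area-only uses tolerate open meshes.

    Raises
    ------
    IOError
        If the file does not exist or cannot be parsed as STL.
    MeshValidationError
        If the cleaned mesh has no faces.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"mesh file not found: {path}")
    try:
        raw = trimesh.load_mesh(str(path), file_type="stl", process=False)
    except Exception as exc:  # trimesh raises a zoo of types for bad input
        raise IOError(f"could not parse {path} as STL: {exc}") from exc
    return clean_mesh(raw, name=str(path))


def clean_mesh(mesh: trimesh.Trimesh, name: str = "<mesh>") -> trimesh.Trimesh:
    """Merge duplicate vertices and drop degenerate faces."""
    n_faces_raw = len(mesh.faces)
    cleaned = trimesh.Trimesh(
        vertices=mesh.vertices.copy(),
        faces=mesh.faces.copy(),
        process=True,  # merges duplicate vertices
        validate=True,  # removes degenerate/duplicate faces
    )
    if len(cleaned.faces) == 0:
        raise MeshValidationError(f"{name}: mesh has no valid faces after cleaning")
    dropped = n_faces_raw - len(cleaned.faces)
    if dropped > 0:
        logger.warning("%s: dropped %d degenerate/duplicate face(s)", name, dropped)
    logger.info(
        "%s: %d vertices, %d faces, watertight=%s",
        name, len(cleaned.vertices), len(cleaned.faces), cleaned.is_watertight,
    )
    return cleaned


def _require_watertight(mesh: trimesh.Trimesh) -> None:
    if not mesh.is_watertight:
        # edges on the boundary of exactly one face are the holes
        edges = mesh.edges_sorted
        unique, counts = np.unique(edges, axis=0, return_counts=True)
        open_edges = unique[counts != 2]
        raise MeshValidationError(
            f"mesh is not watertight: {len(open_edges)} edge(s) not shared by "
            f"exactly two faces (first few: {open_edges[:5].tolist()})"
        )


# ---------------------------------------------------------------------------
# core geometry
# ---------------------------------------------------------------------------

def mesh_volume(mesh: trimesh.Trimesh) -> float:
    """Enclosed volume in mm³ by the divergence theorem.

    Sums signed tetrahedron volumes det(v0, v1, v2)/6 over faces and returns
    the absolute value, so a globally flipped orientation cannot yield a
    negative volume (a warning is logged when the signed sum is negative).
    """
    _require_watertight(mesh)
    tri = mesh.vertices[mesh.faces]  # (n, 3, 3)
    signed = float(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0)
    if signed < 0:
        logger.warning("mesh orientation is inward-facing (signed volume %.3g); using |V|", signed)
    return abs(signed)


def mesh_surface_area(mesh: trimesh.Trimesh) -> float:
    """Total surface area in mm² (sum of triangle areas)."""
    if len(mesh.faces) == 0:
        raise MeshValidationError("mesh has no faces")
    tri = mesh.vertices[mesh.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return float(np.linalg.norm(cross, axis=1).sum() / 2.0)


def sphericity(volume: float, area: float) -> float:
    """Wadell sphericity S = pi^(1/3) (6 V)^(2/3) / A.

    Ratio of the surface area of the sphere with volume ``volume`` to the
    actual surface ``area``; 1 for a sphere, < 1 for anything else (by the
    isoperimetric inequality). Units must be consistent (e.g. mm³ and mm²,
    or cm³ and cm²): the ratio is scale-free.
    """
    if volume <= 0 or area <= 0:
        raise ValueError(f"sphericity requires positive volume and area, got V={volume}, A={area}")
    return float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area)


def morphometrics_of(mesh: trimesh.Trimesh) -> Morphometrics:
    """Compute (Vt [cm³], surface area [cm²], St) for a watertight mesh in mm."""
    v_mm3 = mesh_volume(mesh)
    a_mm2 = mesh_surface_area(mesh)
    return Morphometrics(
        volume_cm3=v_mm3 / MM3_PER_CM3,
        area_cm2=a_mm2 / MM2_PER_CM2,
        sphericity=sphericity(v_mm3, a_mm2),
    )


# ---------------------------------------------------------------------------
# voxel masks
# ---------------------------------------------------------------------------

def mesh_from_mask(mask: VoxelMask, level: float = 0.5,
                   smoothing_sigma: float = 0.8) -> trimesh.Trimesh:
    """Extract a watertight surface mesh from a binary mask.

    The binary grid is zero-padded by one voxel on every side (so surfaces
    touching the grid boundary still close), lightly Gaussian-smoothed
    (``smoothing_sigma`` in voxel units) and the ``level`` iso-surface of the
    result is extracted with marching cubes; vertex coordinates are scaled by
    the voxel spacing into mm and shifted to the mask origin. The smoothing
    removes the staircase bevels a binary field produces, which would
    otherwise overstate the surface area by ~8% on sphere-like masks and
    bias sphericity low; at sigma 0.8 both volume and area of a digitized
    radius-20-voxel sphere are within ~1% of the analytic values.

    For very small foregrounds the smoothed field never reaches ``level``;
    extraction then falls back to the raw binary field, where a single
    foreground voxel yields the closed octahedron spanned by its face
    midpoints (volume = voxel_volume/6) — this convention is pinned by a
    regression test.
    """
    if mask.foreground_count == 0:
        raise MaskValidationError("mask has no foreground voxels")
    padded = np.pad(mask.grid.astype(np.float32), 1)
    if smoothing_sigma > 0:
        field = ndimage.gaussian_filter(padded, smoothing_sigma)
        if field.max() <= level:
            logger.info("mask too small for smoothed iso-surface; "
                        "falling back to the binary field")
            field = padded
    else:
        field = padded
    verts, faces, _, _ = measure.marching_cubes(field, level=level, spacing=mask.spacing)
    # undo the one-voxel pad, move to world origin
    verts = verts - np.asarray(mask.spacing) + np.asarray(mask.origin)
    mesh = clean_mesh(trimesh.Trimesh(vertices=verts, faces=faces, process=False),
                      name="<marching-cubes surface>")
    if not mesh.is_watertight:  # should not happen on a padded binary field
        raise MeshValidationError("iso-surface extraction produced a non-watertight mesh")
    return mesh


def voxel_volume_mm3(mask: VoxelMask) -> float:
    """Voxel-counting volume oracle: foreground voxels × voxel volume (mm³)."""
    return mask.foreground_count * mask.voxel_volume_mm3


def read_mask(path: Union[str, Path]) -> VoxelMask:
    """Read a binary mask from a NIfTI file; spacing comes from the header."""
    import nibabel as nib

    path = Path(path)
    if not path.is_file():
        raise IOError(f"mask file not found: {path}")
    img = nib.load(str(path))
    grid = np.asanyarray(img.dataobj) > 0
    zooms = img.header.get_zooms()[:3]
    return VoxelMask(grid=grid, spacing=tuple(float(z) for z in zooms))
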