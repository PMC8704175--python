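"""Masks, contours and the conversions between them.

The distance and overlap metrics operate on binary voxel grids with
anisotropic physical spacing; planar contours are the exchange format for
slice-wise delineations. Conventions used throughout the package:

* voxel indices are 0-based and ordered (z, y, x);
* the physical coordinate of voxel ``(i, j, k)`` is its *center*,
  ``origin + (i*dz, j*dy, k*dx)``, in millimetres;
* a mask stores only {0, 1}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage


class EmptyMaskError(ValueError):
    """An operation that needs foreground voxels received none."""


class GridMismatchError(ValueError):
    """Two masks do not share shape and spacing."""


class InvalidContourError(ValueError):
    """A polygon has fewer than 3 vertices or lies outside the grid."""


@dataclass(frozen=True)
class Mask3D:
    """Binary voxel grid with physical spacing.

    Parameters
    ----------
    voxels
        uint8 array of shape (nz, ny, nx) containing only {0, 1}.
    spacing
        (dz, dy, dx) voxel pitch in mm, all strictly positive.
    origin
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"voxels must be 3D, got shape {vox.shape}")
        uniq = np.unique(vox)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("voxels must contain only {0, 1}")
        object.__setattr__(self, "voxels", vox.astype(np.uint8, copy=False))
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def volume_voxels(self) -> int:
        return int(self.voxels.sum())

    def is_empty(self) -> bool:
        return not self.voxels.any()

    def same_grid(self, other: "Mask3D") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def foreground_points_mm(self) -> np.ndarray:
        """Physical (z, y, x) coordinates of all foreground voxel centers."""
        idx = np.argwhere(self.voxels > 0)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Mask3D):
            return NotImplemented
        return self.same_grid(other) and np.array_equal(self.voxels, other.voxels)


@dataclass(frozen=True)
class ContourPolygon:
    """Closed planar polygon on one axial slice.

    ``vertices`` are ordered (y, x) pairs in mm; the ring is implicitly
    closed (last vertex connects back to the first).
    """

    z_mm: float
    vertices: np.ndarray  # (n, 2) float, ordered (y, x) in mm

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise InvalidContourError(
                f"polygon needs >= 3 (y, x) vertices, got shape {v.shape}"
            )
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "z_mm", float(self.z_mm))


@dataclass
class StructureSet:
    """Named collections of contour polygons for one patient."""

    patient_id: str
    structures: dict[str, list[ContourPolygon]] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "structures": {
                name: [
                    {"z_mm": p.z_mm, "vertices": p.vertices.tolist()}
                    for p in polys
                ]
                for name, polys in self.structures.items()
            },
        }

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "StructureSet":
        return cls(
            patient_id=str(d["patient_id"]),
            structures={
                name: [
                    ContourPolygon(z_mm=p["z_mm"], vertices=np.asarray(p["vertices"]))
                    for p in polys
                ]
                for name, polys in d["structures"].items()
            },
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "StructureSet":
        return cls.from_json_dict(json.loads(Path(path).read_text()))


def _points_in_polygon(points_yx: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even-odd rule point-in-polygon test, vectorized over points.

    A point exactly on a vertex or an edge crossing counts as inside
    (ties resolved as inside, for determinism).
    """
    py = points_yx[:, 0][:, None]
    px = points_yx[:, 1][:, None]
    vy = vertices[:, 0]
    vx = vertices[:, 1]
    wy = np.roll(vy, -1)
    wx = np.roll(vx, -1)

    # edge straddles the horizontal ray through the point
    straddle = (vy <= py) != (wy <= py)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_cross = vx + (py - vy) / np.where(wy != vy, wy - vy, np.inf) * (wx - vx)
    crossings = np.sum(straddle & (px <= x_cross), axis=1)
    inside = (crossings % 2) == 1
    # vertex-on-center tie -> inside
    on_vertex = np.any((py == vy) & (px == vx), axis=1)
    return inside | on_vertex


def rasterize(
    structure: Sequence[ContourPolygon],
    grid_shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> Mask3D:
    """Rasterize planar polygons onto a voxel grid.

    A voxel is set iff its center lies inside any polygon on its slice
    (even-odd rule). Polygons are assigned to the nearest slice by z.

    Raises
    ------
    InvalidContourError
        If a polygon has < 3 vertices or a vertex falls outside the grid.
    """
    nz, ny, nx = grid_shape
    dz, dy, dx = spacing
    z0, y0, x0 = origin
    vox = np.zeros(grid_shape, dtype=np.uint8)

    yy, xx = np.meshgrid(
        y0 + np.arange(ny) * dy, x0 + np.arange(nx) * dx, indexing="ij"
    )
    centers = np.column_stack([yy.ravel(), xx.ravel()])

    for poly in structure:
        if not isinstance(poly, ContourPolygon):
            poly = ContourPolygon(*poly)
        k = int(round((poly.z_mm - z0) / dz))
        if not 0 <= k < nz:
            raise InvalidContourError(
                f"polygon at z={poly.z_mm} mm maps to slice {k}, outside grid"
            )
        v = poly.vertices
        if (
            v[:, 0].min() < y0 - 0.5 * dy
            or v[:, 0].max() > y0 + (ny - 0.5) * dy
            or v[:, 1].min() < x0 - 0.5 * dx
            or v[:, 1].max() > x0 + (nx - 0.5) * dx
        ):
            raise InvalidContourError("polygon vertex outside the voxel grid")
        inside = _points_in_polygon(centers, v).reshape(ny, nx)
        vox[k] |= inside.astype(np.uint8)

    return Mask3D(vox, spacing, origin)


_SURFACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def surface_mask(mask: Mask3D) -> np.ndarray:
    """Boolean array marking foreground voxels with a 6-connected background
    or out-of-grid neighbor."""
    if mask.is_empty():
        raise EmptyMaskError("cannot extract the surface of an empty mask")
    fg = mask.voxels.astype(bool)
    interior = ndimage.binary_erosion(fg, structure=_SURFACE_STRUCT, border_value=0)
    return fg & ~interior


def extract_surface_points(mask: Mask3D) -> np.ndarray:
    """Physical (z, y, x) mm coordinates of border voxel centers.

    A border voxel is a foreground voxel with at least one 6-connected
    neighbor that is background or outside the grid.
    """
    idx = np.argwhere(surface_mask(mask))
    return np.asarray(mask.origin) + idx * np.asarray(mask.spacing)


# ---------------------------------------------------------------------------
# File I/O: NIfTI and PNG stacks
# ---------------------------------------------------------------------------

_SIDECAR_NAME = "spacing.json"


def save_mask(mask: Mask3D, path: str | Path) -> None:
    """Write a mask as NIfTI (.nii/.nii.gz) or as a PNG stack directory.

    The PNG stack stores one 8-bit image per slice (0/255) plus a JSON
    sidecar with ``spacing_mm`` and ``origin_mm``.
    """
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        import nibabel as nib

        dz, dy, dx = mask.spacing
        # NIfTI stores (x, y, z); keep mm spacing on the diagonal affine
        affine = np.diag([dx, dy, dz, 1.0])
        affine[:3, 3] = mask.origin[::-1]
        img = nib.Nifti1Image(
            np.ascontiguousarray(mask.voxels.transpose(2, 1, 0)), affine
        )
        nib.save(img, str(path))
    else:
        from PIL import Image

        path.mkdir(parents=True, exist_ok=True)
        for i, sl in enumerate(mask.voxels):
            Image.fromarray((sl * 255).astype(np.uint8)).save(
                path / f"slice_{i:04d}.png"
            )
        sidecar = {
            "spacing_mm": list(mask.spacing),
            "origin_mm": list(mask.origin),
        }
        (path / _SIDECAR_NAME).write_text(json.dumps(sidecar))


def load_mask(path: str | Path) -> Mask3D:
    """Read a mask saved by :func:`save_mask`.

    Non-binary data is thresholded at 0.5 with a warning; a PNG stack
    without its spacing sidecar is an error, because all metrics are in mm.
    """
    import warnings

    path = Path(path)
    if path.is_dir():
        from PIL import Image

        sidecar_path = path / _SIDECAR_NAME
        if not sidecar_path.exists():
            raise FileNotFoundError(
                f"PNG stack {path} lacks the {_SIDECAR_NAME} spacing sidecar; "
                "distance metrics require physical spacing in mm"
            )
        sidecar = json.loads(sidecar_path.read_text())
        slices = sorted(path.glob("*.png"))
        data = np.stack([np.asarray(Image.open(p).convert("L")) for p in slices])
        data = data.astype(float) / 255.0
        origin = tuple(sidecar.get("origin_mm", (0.0, 0.0, 0.0)))
        spacing = tuple(sidecar["spacing_mm"])
    else:
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj).transpose(2, 1, 0).astype(float)
        zooms = img.header.get_zooms()[:3]  # (dx, dy, dz)
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        origin = tuple(float(v) for v in img.affine[:3, 3][::-1])

    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        warnings.warn("mask data is not binary; thresholding at 0.5", stacklevel=2)
    return Mask3D((data > 0.5).astype(np.uint8), spacing, origin)


def masks_equal(a: Mask3D, b: Mask3D) -> bool:
    return a == b
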