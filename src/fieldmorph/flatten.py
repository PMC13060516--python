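"""Aspect partitioning, flattening, rasterization and overlap scores.

After a 3D mesh has been morphed onto a 2D reference illustration, its
faces are split into *palmar* and *dorsal* aspects by the angle between
each face normal and the depth (viewing) vector: palmar for angles in
[0°, 90°), dorsal for [90°, 180°].  Faces whose normals sit between 60°
and 120° of the depth vector are additionally flagged *oblique* — they
are nearly edge-on to the viewer and poorly represented in any flat
projection — without being removed from their aspect.

Each aspect is flattened onto the plane orthogonal to the depth vector
and its annotated faces rasterized into a binary pixel mask, directly
comparable with a 2D illustration annotation via the Jaccard index
(intersection over union).  Occlusion is deliberately not resolved:
overlapping faces of the same aspect all rasterize, so the mask records
the union silhouette, exactly as a flattened 3D annotation map does.

Conventions: the depth vector points from the illustration toward the
viewer (+z when the illustration lives in the z = 0 plane); a pixel is
annotated when its center falls inside or on the boundary of an annotated
projected triangle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

from .annotation import ProjectedField
from .mesh import TriMesh, face_areas, face_normals

__all__ = [
    "FacePartition",
    "PixelMask",
    "partition_faces",
    "split_aspect_meshes",
    "flatten_mesh",
    "rasterize",
    "jaccard",
    "obliqueness",
]

OBLIQUE_LO = 60.0
OBLIQUE_HI = 120.0


class CompareError(ValueError):
    """Raised for mismatched grids or undefined scores."""


@dataclass(frozen=True)
class FacePartition:
    """Per-face palmar/dorsal labels, oblique flags and normal angles.

    ``angles`` are degrees from the depth vector, in [0, 180]; ``palmar``
    is True for angles strictly below 90° (the 90° tie goes to dorsal);
    ``oblique`` is True strictly between 60° and 120°.
    """

    angles: np.ndarray
    palmar: np.ndarray
    oblique: np.ndarray

    @property
    def dorsal(self) -> np.ndarray:
        return ~self.palmar


def _unit(v: np.ndarray, what: str = "depth vector") -> np.ndarray:
    v = np.asarray(v, float).reshape(3)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise CompareError(f"{what} must be nonzero")
    return v / n


def partition_faces(mesh: TriMesh, depth_vector: Sequence[float] = (0, 0, 1)) -> FacePartition:
    """Classify every face by the angle of its normal to the depth vector."""
    d = _unit(depth_vector)
    cos = np.clip(face_normals(mesh) @ d, -1.0, 1.0)
    angles = np.degrees(np.arccos(cos))
    return FacePartition(
        angles=angles,
        palmar=angles < 90.0,
        oblique=(angles > OBLIQUE_LO) & (angles < OBLIQUE_HI),
    )


def split_aspect_meshes(
    mesh: TriMesh, partition: FacePartition
) -> tuple[tuple[TriMesh, np.ndarray], tuple[TriMesh, np.ndarray]]:
    """Split into palmar and dorsal submeshes.

    Returns ``((palmar_mesh, palmar_face_map), (dorsal_mesh,
    dorsal_face_map))`` where each face map sends submesh face indices
    back to faces of the source mesh.  Submeshes keep the full vertex
    array so vertex indices stay comparable across aspects.
    """
    if len(partition.palmar) != mesh.n_faces:
        raise CompareError("partition does not match the mesh")
    out = []
    for mask in (partition.palmar, ~partition.palmar):
        fmap = np.flatnonzero(mask)
        out.append((TriMesh(vertices=mesh.vertices, faces=mesh.faces[fmap]), fmap))
    return out[0], out[1]


def flatten_mesh(mesh: TriMesh, depth_vector: Sequence[float] = (0, 0, 1)) -> TriMesh:
    """Zero each vertex's component along the depth vector.

    In-plane coordinates are untouched, so fronto-parallel geometry is
    preserved exactly; the operation is idempotent.
    """
    d = _unit(depth_vector)
    v = mesh.vertices - np.outer(mesh.vertices @ d, d)
    return mesh.with_vertices(v)


# ---------------------------------------------------------------------------
# pixel masks


@dataclass(frozen=True)
class PixelMask:
    """A binary raster with an invertible pixel↔model-plane mapping.

    Pixel (row, col) covers the square with corners ``origin + pixel_size
    * (col, row)`` and ``origin + pixel_size * (col+1, row+1)``; its center
    is at half-integer multiples.  Rows increase with the model y
    coordinate (mathematical orientation; PNG I/O flips as needed).
    """

    grid: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        g = np.asarray(self.grid).astype(bool)
        if g.ndim != 2:
            raise CompareError("mask grid must be 2D")
        if self.pixel_size <= 0:
            raise CompareError("pixel size must be positive")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "origin", (float(self.origin[0]), float(self.origin[1])))

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    @property
    def count(self) -> int:
        return int(self.grid.sum())

    def same_grid(self, other: "PixelMask") -> bool:
        return (
            self.grid.shape == other.grid.shape
            and self.origin == other.origin
            and self.pixel_size == other.pixel_size
        )

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Model-plane x and y coordinates of every pixel center."""
        ox, oy = self.origin
        xs = ox + (np.arange(self.width) + 0.5) * self.pixel_size
        ys = oy + (np.arange(self.height) + 0.5) * self.pixel_size
        return xs, ys

    @classmethod
    def empty(
        cls, width: int, height: int, origin=(0.0, 0.0), pixel_size: float = 1.0
    ) -> "PixelMask":
        return cls(np.zeros((height, width), bool), origin=tuple(origin), pixel_size=pixel_size)


def rasterize(
    mesh2d: TriMesh,
    faces: Iterable[int],
    grid: PixelMask,
    axes: tuple[int, int] = (0, 1),
) -> PixelMask:
    """Rasterize annotated faces of a flattened mesh into a pixel mask.

    A pixel is set when its center lies inside or on the boundary of at
    least one annotated triangle (projected onto the plane spanned by
    ``axes``).  Sampling is pure pixel-center — no partial coverage —
    matching the binarized-pixel 2D annotation maps being compared to.
    """
    face_idx = np.fromiter((int(f) for f in faces), dtype=np.int64)
    out = np.zeros((grid.height, grid.width), bool)
    if face_idx.size:
        if face_idx.min() < 0 or face_idx.max() >= mesh2d.n_faces:
            raise CompareError("annotated face index out of range")
        xs, ys = grid.pixel_centers()
        tri2 = mesh2d.vertices[mesh2d.faces[face_idx]][:, :, list(axes)]
        for (a, b, c) in tri2:
            # candidate pixels from the triangle's bounding box
            lo = np.minimum(np.minimum(a, b), c)
            hi = np.maximum(np.maximum(a, b), c)
            j0 = np.searchsorted(xs, lo[0] - 1e-12)
            j1 = np.searchsorted(xs, hi[0] + 1e-12)
            i0 = np.searchsorted(ys, lo[1] - 1e-12)
            i1 = np.searchsorted(ys, hi[1] + 1e-12)
            if j0 >= j1 or i0 >= i1:
                continue
            px, py = np.meshgrid(xs[j0:j1], ys[i0:i1])
            # signed edge functions, orientation-normalized
            area2 = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if area2 == 0.0:
                continue
            sgn = np.sign(area2)
            e0 = ((b[0] - a[0]) * (py - a[1]) - (b[1] - a[1]) * (px - a[0])) * sgn
            e1 = ((c[0] - b[0]) * (py - b[1]) - (c[1] - b[1]) * (px - b[0])) * sgn
            e2 = ((a[0] - c[0]) * (py - c[1]) - (a[1] - c[1]) * (px - c[0])) * sgn
            inside = (e0 >= 0) & (e1 >= 0) & (e2 >= 0)
            out[i0:i1, j0:j1] |= inside
    return PixelMask(out, origin=grid.origin, pixel_size=grid.pixel_size)


def jaccard(a: PixelMask, b: PixelMask) -> float:
    """Intersection over union of two binary masks on the same grid.

    Both masks empty → 0.0 by convention (no agreement claimable).
    """
    if not a.same_grid(b):
        raise CompareError("masks are on different grids")
    union = int((a.grid | b.grid).sum())
    if union == 0:
        return 0.0
    inter = int((a.grid & b.grid).sum())
    return inter / union


def obliqueness(
    field: ProjectedField, partition: FacePartition, areas: np.ndarray
) -> float:
    """Fraction of an annotation's surface area lying on oblique faces.

    Oblique faces are nearly edge-on to the viewer (normals 60°–120° from
    the depth vector) and are the part of a 3D annotation that any flat
    projection distorts or hides.
    """
    if not field.faces:
        raise CompareError("obliqueness is undefined for an empty annotation")
    idx = field.face_array()
    areas = np.asarray(areas, float)
    if idx.max() >= len(areas) or len(areas) != len(partition.oblique):
        raise CompareError("partition/areas do not match the annotated mesh")
    total = areas[idx].sum()
    return float(areas[idx[partition.oblique[idx]]].sum() / total)


def field_obliqueness(
    field: ProjectedField, mesh: TriMesh, depth_vector: Sequence[float] = (0, 0, 1)
) -> float:
    """Convenience wrapper: partition + areas + :func:`obliqueness`."""
    return obliqueness(field, partition_faces(mesh, depth_vector), face_areas(mesh))


# ---------------------------------------------------------------------------
# mask I/O (PNG + JSON sidecar with the grid geometry)


def save_mask(mask: PixelMask, path: str | Path) -> None:
    """Write a mask as an 8-bit PNG (255 = annotated, row 0 at the top)
    plus a ``.json`` sidecar recording origin and pixel size."""
    path = Path(path)
    img = (np.flipud(mask.grid).astype(np.uint8)) * 255
    Image.fromarray(img, mode="L").save(path, format="PNG")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"origin": list(mask.origin), "pixel_size": mask.pixel_size}) + "\n"
    )


def load_mask(path: str | Path) -> PixelMask:
    """Read a PNG mask (any nonzero pixel = annotated) and its sidecar;
    a missing sidecar yields the identity grid (origin 0, pixel size 1)."""
    path = Path(path)
    img = np.asarray(Image.open(path).convert("L"))
    grid = np.flipud(img != 0)
    sidecar = path.with_suffix(path.suffix + ".json")
    origin, pixel_size = (0.0, 0.0), 1.0
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        origin = tuple(meta.get("origin", origin))
        pixel_size = float(meta.get("pixel_size", pixel_size))
    return PixelMask(grid, origin=origin, pixel_size=pixel_size)
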