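"""Projected-field annotations.

A projected field is the body-surface region where a stimulation-evoked
sensation is felt.  On a 3D mesh it is recorded as a set of annotated
faces plus optional hotspots (points of most intense sensation), visual
analog scale ratings, and quality descriptors.

Canonical storage is face-level — the face is the paint/erase unit — and
the per-vertex binary array consumed by cross-mesh transfer is a derived
view: an annotated face sets all three of its vertices, and a face is
recovered from a vertex array when all three of its vertices are set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .mesh import TriMesh

#: Maximum point-to-surface distance for a hotspot to count as on-mesh.
HOTSPOT_TOL = 1e-6


class FieldError(ValueError):
    """Raised for annotations inconsistent with their mesh or schema."""


class Depth(str, Enum):
    """Perceived depth of a sensation quality relative to the skin."""

    ABOVE_SKIN = "above_skin"
    AT_SKIN = "at_skin"
    BELOW_SKIN = "below_skin"


def _check_unit(value: float, what: str) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0):
        raise FieldError(f"{what} must lie in [0, 1], got {value}")
    return value


@dataclass(frozen=True)
class Quality:
    """One sensation descriptor (e.g. "tingle", "pressure") with its own
    intensity and perceived depth."""

    name: str
    intensity: float
    depth: Depth

    def __post_init__(self) -> None:
        object.__setattr__(self, "intensity", _check_unit(self.intensity, "intensity"))
        object.__setattr__(self, "depth", Depth(self.depth))


@dataclass(frozen=True)
class ProjectedField:
    """One annotation of a sensation on a named mesh.

    Scale ratings (naturalness, pain, overall intensity) are stored
    normalized to [0, 1] regardless of the slider range they came from.
    Hotspots are 3D points on the mesh surface, not face indices.
    """

    mesh_id: str
    faces: frozenset[int]
    hotspots: tuple[np.ndarray, ...] = ()
    naturalness: float = 0.0
    pain: float = 0.0
    overall_intensity: float = 0.0
    qualities: tuple[Quality, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "faces", frozenset(int(f) for f in self.faces))
        object.__setattr__(
            self,
            "hotspots",
            tuple(np.asarray(h, dtype=np.float64).reshape(3) for h in self.hotspots),
        )
        object.__setattr__(self, "qualities", tuple(self.qualities))
        for what in ("naturalness", "pain", "overall_intensity"):
            object.__setattr__(self, what, _check_unit(getattr(self, what), what))

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_array(self) -> np.ndarray:
        return np.fromiter(sorted(self.faces), dtype=np.int64, count=len(self.faces))


def _point_triangle_distances(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Distance from each point to each triangle, (n_points, n_tris).

    Closest-point projection onto the triangle's plane clamped to the
    triangle via barycentric regions.  Vectorized over triangles per point.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a
    out = np.empty((len(points), len(tri)))
    for i, p in enumerate(points):
        ap = p - a
        d1 = np.einsum("ij,ij->i", ab, ap)
        d2 = np.einsum("ij,ij->i", ac, ap)
        bp = p - b
        d3 = np.einsum("ij,ij->i", ab, bp)
        d4 = np.einsum("ij,ij->i", ac, bp)
        cp = p - c
        d5 = np.einsum("ij,ij->i", ab, cp)
        d6 = np.einsum("ij,ij->i", ac, cp)
        va = d3 * d6 - d5 * d4
        vb = d5 * d2 - d1 * d6
        vc = d1 * d4 - d3 * d2
        denom = va + vb + vc
        closest = np.empty_like(tri[:, 0])
        # vertex regions
        m = (d1 <= 0) & (d2 <= 0)
        closest[m] = a[m]
        m2 = (d3 >= 0) & (d4 <= d3)
        closest[m2] = b[m2]
        m3 = (d6 >= 0) & (d5 <= d6)
        closest[m3] = c[m3]
        done = m | m2 | m3
        # edge AB
        e = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
        t = np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 != 0, d1 - d3, 1.0), 0.0)
        closest[e] = a[e] + t[e, None] * ab[e]
        done |= e
        # edge AC
        e = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
        t = np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 != 0, d2 - d6, 1.0), 0.0)
        closest[e] = a[e] + t[e, None] * ac[e]
        done |= e
        # edge BC
        e = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
        denom_bc = (d4 - d3) + (d5 - d6)
        t = np.where(denom_bc != 0, (d4 - d3) / np.where(denom_bc != 0, denom_bc, 1.0), 0.0)
        closest[e] = b[e] + t[e, None] * (c[e] - b[e])
        done |= e
        # interior
        inside = ~done
        safe = np.where(denom != 0, denom, 1.0)
        v = vb / safe
        w = vc / safe
        closest[inside] = a[inside] + v[inside, None] * ab[inside] + w[inside, None] * ac[inside]
        out[i] = np.linalg.norm(p - closest, axis=1)
    return out


def surface_distance(points: Sequence, mesh: TriMesh) -> np.ndarray:
    """Minimum distance from each point to the mesh surface."""
    pts = np.asarray(points, float).reshape(-1, 3)
    tri = mesh.vertices[mesh.faces]
    return _point_triangle_distances(pts, tri).min(axis=1)


def validate_field(field_: ProjectedField, mesh: TriMesh, mesh_id: str | None = None) -> None:
    """Check a field against its mesh: face indices in range, hotspots on
    the surface (within ``HOTSPOT_TOL``).  Raises :class:`FieldError`."""
    if mesh_id is not None and field_.mesh_id != mesh_id:
        raise FieldError(f"field targets mesh {field_.mesh_id!r}, expected {mesh_id!r}")
    if field_.faces and (min(field_.faces) < 0 or max(field_.faces) >= mesh.n_faces):
        raise FieldError("annotated face index out of range for mesh")
    if field_.hotspots:
        d = surface_distance(np.array(field_.hotspots), mesh)
        off = d > HOTSPOT_TOL
        if off.any():
            raise FieldError(
                f"{int(off.sum())} hotspot(s) off the mesh surface "
                f"(max distance {d.max():.3g})"
            )


def field_to_vertex_array(field_: ProjectedField, mesh: TriMesh,
                          mesh_id: str | None = None) -> np.ndarray:
    """Per-vertex binary array: 1 where the vertex belongs to at least one
    annotated face.  This is the array the transfer matrix multiplies."""
    if mesh_id is not None and field_.mesh_id != mesh_id:
        raise FieldError(f"field targets mesh {field_.mesh_id!r}, expected {mesh_id!r}")
    if field_.faces and max(field_.faces) >= mesh.n_faces:
        raise FieldError("annotated face index out of range for mesh")
    arr = np.zeros(mesh.n_vertices, dtype=np.int8)
    if field_.faces:
        arr[mesh.faces[field_.face_array()].ravel()] = 1
    return arr


def vertex_array_to_faces(arr: np.ndarray, mesh: TriMesh) -> frozenset[int]:
    """Faces all three of whose vertices are set in the binary array."""
    arr = np.asarray(arr)
    if arr.shape != (mesh.n_vertices,):
        raise FieldError(
            f"vertex array length {arr.shape} does not match vertex count "
            f"{mesh.n_vertices}"
        )
    on = arr.astype(bool)[mesh.faces].all(axis=1)
    return frozenset(np.flatnonzero(on).tolist())


# ---------------------------------------------------------------------------
# JSON serialization


def field_to_dict(field_: ProjectedField) -> dict:
    return {
        "mesh_id": field_.mesh_id,
        "faces": sorted(field_.faces),
        "hotspots": [[float(x) for x in h] for h in field_.hotspots],
        "naturalness": field_.naturalness,
        "pain": field_.pain,
        "overall_intensity": field_.overall_intensity,
        "qualities": [
            {"name": q.name, "intensity": q.intensity, "depth": q.depth.value}
            for q in field_.qualities
        ],
    }


def field_from_dict(data: Mapping) -> ProjectedField:
    try:
        qualities = tuple(
            Quality(name=str(q["name"]), intensity=q["intensity"], depth=Depth(q["depth"]))
            for q in data.get("qualities", ())
        )
        return ProjectedField(
            mesh_id=str(data["mesh_id"]),
            faces=frozenset(int(f) for f in data["faces"]),
            hotspots=tuple(np.asarray(h, float) for h in data.get("hotspots", ())),
            naturalness=data.get("naturalness", 0.0),
            pain=data.get("pain", 0.0),
            overall_intensity=data.get("overall_intensity", 0.0),
            qualities=qualities,
        )
    except FieldError:
        raise
    except (KeyError, ValueError, TypeError) as exc:
        raise FieldError(f"malformed projected-field record: {exc}") from exc


def save_field(field_: ProjectedField, path: str | Path) -> None:
    Path(path).write_text(json.dumps(field_to_dict(field_), indent=1) + "\n")


def load_field(path: str | Path, mesh: TriMesh | None = None) -> ProjectedField:
    """Read a projected-field JSON file; if ``mesh`` is given, validate
    face indices and hotspot placement against it."""
    data = json.loads(Path(path).read_text())
    f = field_from_dict(data)
    if mesh is not None:
        validate_field(f, mesh)
    return f
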