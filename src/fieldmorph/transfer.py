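"""Cross-mesh annotation transfer via a sparse proportional-coverage matrix.

To port a projected-field annotation from one mesh (e.g. a patient's
scanned hand) onto another (a generic reference hand), a sparse matrix T
of shape (target vertices × source vertices) is built once per mesh pair,
after both meshes have been brought into a common frame by the landmark
morph:

For each target face, the k nearest source faces (by centroid distance,
via a k-d tree) are gathered; all vertices are re-zeroed about the target
face centroid and rotated so the target face normal points along +z; the
source vertices are flattened (z zeroed), producing a perspective view of
the source faces along the target normal.  Each source face's overlap
area with the projected target face, divided by the target face's area,
is its *proportional coverage*; that coverage is accumulated into T at
every (target-vertex, source-vertex) combination of the two faces.

An annotation then transfers as ``s = T @ a`` with ``a`` the source
per-vertex binary array.  A target vertex whose summed coverage reaches
1.5 — three vertices per face × 50% coverage — is annotated; target faces
are recovered from the vertex array.  The threshold is inclusive (≥ 1.5).
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from scipy.spatial import cKDTree

from .annotation import ProjectedField, field_to_vertex_array, vertex_array_to_faces
from .mesh import TriMesh, face_areas, face_centroids, face_normals

__all__ = [
    "TransferMatrix",
    "choose_k",
    "rotation_to_z",
    "triangle_overlap_area",
    "build_transfer_matrix",
    "project_field",
]

logger = logging.getLogger(__name__)

#: Per-vertex coverage sum required to annotate a target vertex:
#: 3 vertices per face × 50% coverage.
DEFAULT_THRESHOLD = 1.5

#: Baseline neighbor count for a 1:1 source:target face ratio.
BASE_K = 30


class TransferError(ValueError):
    """Raised for mismatched meshes or malformed matrices."""


@dataclass(frozen=True)
class TransferMatrix:
    """Sparse (target vertices × source vertices) coverage weights."""

    matrix: sp.csr_matrix
    source_mesh_id: str = ""
    target_mesh_id: str = ""
    k: int = BASE_K

    def __post_init__(self) -> None:
        m = sp.csr_matrix(self.matrix)
        if m.nnz and m.data.min() < 0:
            raise TransferError("coverage entries must be nonnegative")
        object.__setattr__(self, "matrix", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def choose_k(source_face_count: int, target_face_count: int) -> int:
    """Neighbor count scaled with the source:target face-count ratio.

    30 neighbors suit a 1:1 ratio; a denser source mesh needs
    proportionally more neighbors to see the same surface area, so
    k = max(30, ceil(30 · source/target)).
    """
    if source_face_count <= 0 or target_face_count <= 0:
        raise TransferError("face counts must be positive")
    return max(BASE_K, math.ceil(BASE_K * source_face_count / target_face_count))


def rotation_to_z(normal: np.ndarray) -> np.ndarray:
    """Rotation matrix sending a unit vector onto (0, 0, 1).

    Rodrigues rotation about ``normal × z``; the antiparallel case
    (normal = −z) falls back to a 180° rotation about the x axis.
    """
    n = np.asarray(normal, float).reshape(3)
    if abs(np.linalg.norm(n) - 1.0) > 1e-6:
        raise TransferError("normal must be a unit vector")
    z = np.array([0.0, 0.0, 1.0])
    c = float(n @ z)
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(n, z)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def _clip_polygon(subject: list[np.ndarray], a: np.ndarray, b: np.ndarray) -> list[np.ndarray]:
    """Sutherland–Hodgman: clip a polygon against the half-plane left of a→b."""
    out: list[np.ndarray] = []
    n = len(subject)
    for i in range(n):
        p, q = subject[i], subject[(i + 1) % n]
        side_p = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
        side_q = (b[0] - a[0]) * (q[1] - a[1]) - (b[1] - a[1]) * (q[0] - a[0])
        if side_p >= 0:
            out.append(p)
        if (side_p > 0 and side_q < 0) or (side_p < 0 and side_q > 0):
            t = side_p / (side_p - side_q)
            out.append(p + t * (q - p))
    return out


def _polygon_area(poly: list[np.ndarray]) -> float:
    if len(poly) < 3:
        return 0.0
    p = np.array(poly)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def triangle_overlap_area(triA: np.ndarray, triB: np.ndarray) -> float:
    """Area of the intersection of two planar triangles.

    Convex clipping of A against B's edges (Sutherland–Hodgman) followed
    by the shoelace formula.  Degenerate input triangles give 0.
    """
    A = [np.asarray(p, float).reshape(2) for p in triA]
    B = [np.asarray(p, float).reshape(2) for p in triB]
    areaB2 = (B[1][0] - B[0][0]) * (B[2][1] - B[0][1]) - (B[1][1] - B[0][1]) * (
        B[2][0] - B[0][0]
    )
    if abs(areaB2) < 2e-12 or _polygon_area(A) < 1e-12:
        return 0.0
    if areaB2 < 0:  # ensure CCW clip window
        B = [B[0], B[2], B[1]]
    poly = A
    for i in range(3):
        poly = _clip_polygon(poly, B[i], B[(i + 1) % 3])
        if not poly:
            return 0.0
    return _polygon_area(poly)


def build_transfer_matrix(
    source: TriMesh,
    target: TriMesh,
    k: int | None = None,
    source_mesh_id: str = "",
    target_mesh_id: str = "",
    require_facing: bool = False,
) -> TransferMatrix:
    """Build the sparse coverage matrix from a source to a target mesh.

    Both meshes must already live in a common frame (typically after the
    landmark morph).  ``k`` defaults to :func:`choose_k` on the two face
    counts and is clamped (with a warning) to the source face count.
    ``require_facing`` drops source faces whose normals oppose the target
    face normal — useful for folded meshes where back faces project onto
    the front; by default proximity alone selects contributors.
    """
    if source.n_faces == 0 or target.n_faces == 0:
        raise TransferError("source and target meshes must both have faces")
    if k is None:
        k = choose_k(source.n_faces, target.n_faces)
    if k < 1:
        raise TransferError("k must be at least 1")
    if k > source.n_faces:
        warnings.warn(
            f"k={k} exceeds source face count {source.n_faces}; clamping", stacklevel=2
        )
        k = source.n_faces

    src_centroids = face_centroids(source)
    tgt_centroids = face_centroids(target)
    tgt_normals = face_normals(target)
    src_normals = face_normals(source) if require_facing else None
    tgt_areas = face_areas(target)
    tree = cKDTree(src_centroids)
    _, neighbor_idx = tree.query(tgt_centroids, k=k)
    neighbor_idx = np.atleast_2d(neighbor_idx.reshape(target.n_faces, k))

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for tf in range(target.n_faces):
        center = tgt_centroids[tf]
        R = rotation_to_z(tgt_normals[tf])
        tgt_tri = (target.vertices[target.faces[tf]] - center) @ R.T
        tgt_tri2 = tgt_tri[:, :2]
        for sf in neighbor_idx[tf]:
            if require_facing and float(src_normals[sf] @ tgt_normals[tf]) <= 0.0:
                continue
            src_tri = (source.vertices[source.faces[sf]] - center) @ R.T
            src_tri2 = src_tri[:, :2]  # z zeroed: perspective along the normal
            overlap = triangle_overlap_area(src_tri2, tgt_tri2)
            if overlap <= 0.0:
                continue
            coverage = overlap / tgt_areas[tf]
            for tv in target.faces[tf]:
                for sv in source.faces[sf]:
                    rows.append(int(tv))
                    cols.append(int(sv))
                    vals.append(float(coverage))
    m = sp.coo_matrix(
        (vals, (rows, cols)), shape=(target.n_vertices, source.n_vertices)
    ).tocsr()
    return TransferMatrix(
        matrix=m, source_mesh_id=source_mesh_id, target_mesh_id=target_mesh_id, k=k
    )


def project_field(
    field_src: ProjectedField,
    T: TransferMatrix,
    source: TriMesh,
    target: TriMesh,
    threshold: float = DEFAULT_THRESHOLD,
    target_mesh_id: str | None = None,
) -> ProjectedField:
    """Project an annotation through the transfer matrix.

    ``s = T @ a`` sums, at each target vertex, the coverage contributed by
    annotated source vertices; vertices with ``s >= threshold`` are set
    and target faces recovered (a face is annotated when all three of its
    vertices are).  Scale ratings and qualities are copied verbatim;
    hotspots are not transferred.
    """
    if T.source_mesh_id and field_src.mesh_id and T.source_mesh_id != field_src.mesh_id:
        raise TransferError(
            f"matrix was built from mesh {T.source_mesh_id!r}, "
            f"field annotates {field_src.mesh_id!r}"
        )
    if T.shape != (target.n_vertices, source.n_vertices):
        raise TransferError("matrix shape does not match the mesh pair")
    a = field_to_vertex_array(field_src, source).astype(float)
    s = np.asarray(T.matrix @ a).ravel()
    b = (s >= threshold).astype(np.int8)
    faces = vertex_array_to_faces(b, target)
    return ProjectedField(
        mesh_id=target_mesh_id if target_mesh_id is not None else T.target_mesh_id,
        faces=faces,
        hotspots=(),
        naturalness=field_src.naturalness,
        pain=field_src.pain,
        overall_intensity=field_src.overall_intensity,
        qualities=field_src.qualities,
    )


# ---------------------------------------------------------------------------
# persistence: Matrix Market + JSON metadata sidecar


def save_transfer_matrix(T: TransferMatrix, path: str | Path) -> None:
    path = Path(path)
    mmwrite(str(path), T.matrix)
    meta = {"source_mesh": T.source_mesh_id, "target_mesh": T.target_mesh_id, "k": T.k}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta) + "\n")


def load_transfer_matrix(path: str | Path) -> TransferMatrix:
    path = Path(path)
    m = sp.csr_matrix(mmread(str(path)))
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return TransferMatrix(
        matrix=m,
        source_mesh_id=meta.get("source_mesh", ""),
        target_mesh_id=meta.get("target_mesh", ""),
        k=int(meta.get("k", BASE_K)),
    )
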