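"""Deterministic synthetic fixtures: articulated hand meshes, 2D reference
landmark sets and patch annotations.

The generated hand is a toy stand-in for a generic right-hand model: a
closed, genus-0 slab built on a rectilinear grid — a palm block with four
finger strips (index–pinky along +y) and a thumb strip leaving the radial
side (−x), palmar surface toward +z.  It carries the full canonical
54-landmark complement and a tree-valid dependency list, so every stage
of the alignment/flattening/transfer pipeline can be exercised without
any external asset.  The slab construction (top and bottom sheets joined
by a boundary band) guarantees a manifold mesh by construction, which a
boolean union of capsule primitives would not.

All generators are pure functions of their spec and seed: the same
inputs yield bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from . import hand
from .alignment import DependencyList
from .annotation import ProjectedField
from .mesh import Landmark, LandmarkRole, LandmarkSet, TriMesh


class SyntheticError(ValueError):
    """Raised for invalid generator specifications."""


@dataclass(frozen=True)
class SyntheticHandSpec:
    """Geometry of the toy hand, in model units.

    ``resolution`` is the grid subdivision level; level 1 already gives
    every digit segment at least 8 faces (the minimum needed to carry its
    width markers on distinct geometry).
    """

    finger_segment_length: float = 1.0
    thumb_segment_length: float = 1.2
    finger_radius: float = 0.35
    thumb_radius: float = 0.45
    palm_width: float = 4.2
    palm_height: float = 4.0
    thickness: float = 0.9
    resolution: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "finger_segment_length",
            "thumb_segment_length",
            "finger_radius",
            "thumb_radius",
            "palm_width",
            "palm_height",
            "thickness",
        ):
            if getattr(self, name) <= 0:
                raise SyntheticError(f"{name} must be positive")
        if self.resolution < 1:
            raise SyntheticError("resolution must be at least 1")
        if 4 * 2 * self.finger_radius >= self.palm_width:
            raise SyntheticError("palm too narrow for four fingers")


def _subdivide(lines: np.ndarray, r: int) -> np.ndarray:
    """Insert r−1 evenly spaced lines into every interval."""
    if r == 1:
        return lines
    out = [lines[:1]]
    for a, b in zip(lines[:-1], lines[1:]):
        out.append(np.linspace(a, b, r + 1)[1:])
    return np.concatenate(out)


def _slab_mesh(
    xs: np.ndarray, ys: np.ndarray, occupied: np.ndarray, thickness: float
) -> TriMesh:
    """Closed slab over the occupied cells of a rectilinear grid.

    Top sheet at +thickness/2 (CCW from +z), mirrored bottom sheet, and a
    quad band along the silhouette boundary.  The occupied region must be
    edge-connected and simply connected for a genus-0 result.
    """
    n_x, n_y = len(xs), len(ys)
    h = thickness / 2.0

    # lattice corners used by at least one occupied cell
    corner_used = np.zeros((n_x, n_y), bool)
    cj, ci = np.nonzero(occupied)
    for dj, di in ((0, 0), (1, 0), (0, 1), (1, 1)):
        corner_used[cj + dj, ci + di] = True

    top_id = -np.ones((n_x, n_y), np.int64)
    order = np.argwhere(corner_used)
    top_id[tuple(order.T)] = np.arange(len(order))
    n_sheet = len(order)  # bottom copy ids are top ids + n_sheet

    verts = np.empty((2 * n_sheet, 3))
    verts[:n_sheet, 0] = xs[order[:, 0]]
    verts[:n_sheet, 1] = ys[order[:, 1]]
    verts[:n_sheet, 2] = h
    verts[n_sheet:] = verts[:n_sheet]
    verts[n_sheet:, 2] = -h

    faces: list[tuple[int, int, int]] = []
    for j, i in zip(cj, ci):
        a, b = top_id[j, i], top_id[j + 1, i]
        c, d = top_id[j + 1, i + 1], top_id[j, i + 1]
        faces += [(a, b, c), (a, c, d)]  # CCW seen from +z
        a2, b2, c2, d2 = (v + n_sheet for v in (a, b, c, d))
        faces += [(a2, c2, b2), (a2, d2, c2)]  # reversed for the bottom

    # boundary edges of the 2D sheet: edges used by exactly one cell
    edge_count: dict[tuple[int, int], int] = {}
    edge_dir: dict[tuple[int, int], tuple[int, int]] = {}
    for j, i in zip(cj, ci):
        a, b = top_id[j, i], top_id[j + 1, i]
        c, d = top_id[j + 1, i + 1], top_id[j, i + 1]
        for u, v in ((a, b), (b, c), (c, d), (d, a)):  # CCW cell boundary
            key = (min(u, v), max(u, v))
            edge_count[key] = edge_count.get(key, 0) + 1
            edge_dir[key] = (u, v)
    for key, count in edge_count.items():
        if count == 1:
            u, v = edge_dir[key]
            # side band wound so normals face outward (away from the sheet)
            faces += [(u, u + n_sheet, v + n_sheet), (u, v + n_sheet, v)]
    return TriMesh(vertices=verts, faces=np.array(faces, np.int64))


def make_hand(
    spec: SyntheticHandSpec = SyntheticHandSpec(),
) -> tuple[TriMesh, LandmarkSet, DependencyList]:
    """Generate the toy hand mesh, its 54 landmarks and dependency list.

    Returns a closed genus-0 :class:`TriMesh`, the canonical
    :class:`LandmarkSet` (22 primary + 32 accessory, anchored at the
    wrist) and the wrist→MCP→…→tip :class:`DependencyList`.
    """
    fw = 2 * spec.finger_radius
    tw = 2 * spec.thumb_radius
    W, H = spec.palm_width, spec.palm_height
    Lf, Lt = spec.finger_segment_length, spec.thumb_segment_length

    gap = (W - 4 * fw) / 5.0  # even margins and inter-finger gaps
    finger_x0 = [gap + i * (fw + gap) for i in range(4)]
    finger_top = H + 3 * Lf
    thumb_y0 = 0.25 * H
    thumb_x0 = -2 * Lt

    # rectilinear grid lines: region boundaries + digit midlines
    xs = {0.0, W, thumb_x0, thumb_x0 + Lt, thumb_x0 + 1.5 * Lt, thumb_x0 + 0.5 * Lt}
    for x0 in finger_x0:
        xs |= {x0, x0 + fw / 2, x0 + fw}
    ys = {0.0, H, thumb_y0, thumb_y0 + tw / 2, thumb_y0 + tw, H / 2}
    for s in range(1, 7):  # finger segment boundaries and midpoints
        ys.add(H + s * Lf / 2)
    xs_arr = _subdivide(np.array(sorted(xs)), spec.resolution)
    ys_arr = _subdivide(np.array(sorted(ys)), spec.resolution)

    # occupancy by cell-center point-in-rectangle tests
    cx = (xs_arr[:-1] + xs_arr[1:]) / 2
    cy = (ys_arr[:-1] + ys_arr[1:]) / 2
    occ = np.zeros((len(cx), len(cy)), bool)
    rects = [(0.0, W, 0.0, H)]  # palm
    rects += [(x0, x0 + fw, H, finger_top) for x0 in finger_x0]  # fingers
    rects.append((thumb_x0, 0.0, thumb_y0, thumb_y0 + tw))  # thumb
    for x0, x1, y0, y1 in rects:
        jmask = (cx > x0) & (cx < x1)
        imask = (cy > y0) & (cy < y1)
        occ[np.ix_(jmask, imask)] = True
    mesh = _slab_mesh(xs_arr, ys_arr, occ, spec.thickness)

    # ---- landmarks ----------------------------------------------------
    lms: list[Landmark] = []

    def prim(name: str, x: float, y: float, z: float = 0.0) -> None:
        lms.append(Landmark(name, LandmarkRole.PRIMARY, (x, y, z)))

    def acc(name: str, x: float, y: float, z: float = 0.0) -> None:
        lms.append(Landmark(name, LandmarkRole.ACCESSORY, (x, y, z)))

    prim("wrist", W / 2, 0.0)
    prim("palmarCenter", W / 2, H / 2, spec.thickness / 2)
    prim("dorsalCenter", W / 2, H / 2, -spec.thickness / 2)
    acc("wrist_t", 0.0, 0.0)
    acc("wrist_p", W, 0.0)
    acc("palmarCenter_t", 0.0, H / 2)
    acc("palmarCenter_p", W, H / 2)

    # thumb along −x; "_t" markers on the wrist-facing side (lower y)
    yc = thumb_y0 + tw / 2
    joints = {"Tmcp": 0.0, "Tipj": -Lt, "Ttip": -2 * Lt}
    for name, x in joints.items():
        prim(name, x, yc)
    for distal, x_mid in (("Tipj", -Lt / 2), ("Ttip", -1.5 * Lt)):
        acc(f"{distal}_t", x_mid, thumb_y0)
        acc(f"{distal}_p", x_mid, thumb_y0 + tw)

    for d, x0 in zip(hand.FINGERS, finger_x0):
        xc = x0 + fw / 2
        chain = hand.finger_chain(d)
        for s, joint in enumerate(chain):
            prim(joint, xc, H + s * Lf)
        for s, distal in enumerate(chain[1:]):
            y_mid = H + (s + 0.5) * Lf
            acc(f"{distal}_t", x0, y_mid)
            acc(f"{distal}_p", x0 + fw, y_mid)

    lm_set = LandmarkSet(landmarks=tuple(lms), anchor_name="wrist")
    assert len(lm_set) == 54, "canonical hand must carry 54 landmarks"
    return mesh, lm_set, hand.canonical_dependencies()


# ---------------------------------------------------------------------------
# 2D reference generation


@dataclass(frozen=True)
class SegmentSimilarity:
    """In-plane deformation of one segment: rotation (degrees, about the
    parent joint) and scale (about the same pivot)."""

    angle_deg: float = 0.0
    scale: float = 1.0


def random_deformation(
    deps: DependencyList,
    seed: int,
    max_angle_deg: float = 12.0,
    scale_range: tuple[float, float] = (0.9, 1.1),
) -> dict[str, SegmentSimilarity]:
    """Seeded per-segment articulation: small ad-/abduction rotations and
    mild length scaling, the magnitudes typical of matching a hand model
    to a drawn illustration."""
    rng = np.random.default_rng(seed)
    out = {}
    for _, child in deps.pairs:
        out[child] = SegmentSimilarity(
            angle_deg=float(rng.uniform(-max_angle_deg, max_angle_deg)),
            scale=float(rng.uniform(*scale_range)),
        )
    return out


def _rot2(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def apply_deformation(
    lms: LandmarkSet,
    deps: DependencyList,
    deformation: Mapping[str, SegmentSimilarity],
) -> LandmarkSet:
    """Articulated deformation of a landmark set.

    Each dependency segment is rotated/scaled (in the xy plane) about its
    parent joint's already-deformed position, the transform propagating
    to the segment's accessory landmarks and to all descendant segments —
    chains stay attached, as in real joint articulation.
    """
    deps.validate_against(lms)
    orig = {lm.name: lm.position for lm in lms}
    # accumulated affine (A, b): x -> A x + b per primary landmark
    acc: dict[str, tuple[np.ndarray, np.ndarray]] = {
        deps.root: (np.eye(3), np.zeros(3))
    }
    new_pos = dict(orig)
    for parent, child in deps.pairs:
        Ap, bp = acc[parent]
        sim = deformation.get(child, SegmentSimilarity())
        pivot = Ap @ orig[parent] + bp  # parent's deformed position
        R = sim.scale * _rot2(sim.angle_deg)
        A = R @ Ap
        b = R @ (bp - pivot) + pivot
        acc[child] = (A, b)
        new_pos[child] = A @ orig[child] + b
    for lm in lms.accessories():
        A, b = acc.get(lm.base_name, (np.eye(3), np.zeros(3)))
        new_pos[lm.name] = A @ orig[lm.name] + b
    return LandmarkSet(
        landmarks=tuple(Landmark(lm.name, lm.role, new_pos[lm.name]) for lm in lms.landmarks),
        anchor_name=lms.anchor_name,
    )


def make_2d_reference(
    lms: LandmarkSet,
    deps: DependencyList,
    deformation: Mapping[str, SegmentSimilarity] | None = None,
    seed: int = 0,
) -> tuple[LandmarkSet, dict[str, SegmentSimilarity]]:
    """Build a deformed planar landmark set standing in for a 2D
    illustration's landmarks.

    All landmarks are flattened to z = 0, then deformed by
    :func:`apply_deformation` (in-plane articulation, so the result stays
    planar).  With no explicit ``deformation``,
    :func:`random_deformation` with the given seed is used.  Returns the
    planar landmark set and the deformation record.
    """
    if deformation is None:
        deformation = random_deformation(deps, seed)
    flat = LandmarkSet(
        landmarks=tuple(
            Landmark(lm.name, lm.role, (lm.position[0], lm.position[1], 0.0))
            for lm in lms.landmarks
        ),
        anchor_name=lms.anchor_name,
    )
    return apply_deformation(flat, deps, deformation), dict(deformation)


# ---------------------------------------------------------------------------
# patch annotations


def make_patch_field(
    mesh: TriMesh,
    center_face: int,
    radius: float,
    seed: int = 0,
    mesh_id: str = "synthetic-hand",
) -> ProjectedField:
    """A connected patch annotation around a center face.

    Faces are included when their breadth-first distance from the center
    face — summed centroid-to-centroid hops across shared edges, a cheap
    geodesic surrogate — is at most ``radius``.  Radius 0 gives exactly
    the center face; a radius beyond the mesh diameter gives every face.
    """
    if not (0 <= center_face < mesh.n_faces):
        raise SyntheticError(f"center face {center_face} out of range")
    if radius < 0:
        raise SyntheticError("radius must be nonnegative")
    centroids = mesh.vertices[mesh.faces].mean(axis=1)

    edges: dict[tuple[int, int], list[int]] = {}
    for fi, (a, b, c) in enumerate(mesh.faces):
        for u, v in ((a, b), (b, c), (c, a)):
            edges.setdefault((min(u, v), max(u, v)), []).append(fi)
    rows, cols, vals = [], [], []
    for flist in edges.values():
        for i in range(len(flist)):
            for j in range(i + 1, len(flist)):
                f1, f2 = flist[i], flist[j]
                w = float(np.linalg.norm(centroids[f1] - centroids[f2]))
                rows += [f1, f2]
                cols += [f2, f1]
                vals += [w, w]
    graph = coo_matrix((vals, (rows, cols)), shape=(mesh.n_faces, mesh.n_faces))
    dist = dijkstra(graph.tocsr(), indices=center_face)
    faces = frozenset(np.flatnonzero(dist <= radius).tolist())
    return ProjectedField(mesh_id=mesh_id, faces=faces)
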