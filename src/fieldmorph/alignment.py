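"""Landmark-driven Procrustes alignment and segmented mesh morphing.

The morph warps a 3D body mesh so that its landmark configuration matches
a reference configuration (the landmarks of a 2D illustration, or of
another 3D mesh).  It proceeds in two stages:

1. **Initial alignment** — one unrestricted similarity Procrustes fit over
   the full matched landmark complement (translation, rotation, optional
   reflection, scale), followed by a rigid translation that puts the two
   anchor landmarks (base of the wrist) exactly on top of each other.

2. **Segmented Procrustes** — the body part is treated as a hierarchy of
   segments (a dependency tree over the primary landmarks, rooted at the
   anchor).  Iterating over the dependency list in topological order, each
   parent→child pair gets its own no-reflection similarity fit over the
   pair's primary landmarks plus the accessory (width-marker) landmarks
   sharing their base names, and the fit is applied to those landmarks and
   — weighted by a per-vertex segment assignment — to the mesh vertices
   the segment controls.  Transforms compose sequentially down the tree,
   so each finger segment rotates and scales independently while staying
   attached to its parent.

Vertex→segment assignment densifies the primary landmarks into temporary
landmarks interpolated along each dependency segment, assigns each vertex
to the segment of its nearest temporary landmark, and gives partial
influence to dependency-linked segments with an exponential falloff in
distance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
from scipy.spatial import cKDTree

from .mesh import LandmarkSet, TriMesh

__all__ = [
    "ProcrustesTransform",
    "DependencyList",
    "SegmentAssignment",
    "procrustes",
    "initial_align",
    "expand_landmarks",
    "assign_vertices",
    "segmented_procrustes",
    "load_dependencies",
    "save_dependencies",
]


class AlignmentError(ValueError):
    """Raised for degenerate configurations or mismatched landmark sets."""


@dataclass(frozen=True)
class ProcrustesTransform:
    """A similarity transform ``x -> scale * R @ x + translation``."""

    scale: float
    rotation: np.ndarray
    translation: np.ndarray
    reflection_allowed: bool = False

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float).reshape(3, 3)
        t = np.asarray(self.translation, float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise AlignmentError("rotation matrix is not orthogonal")
        det = np.linalg.det(R)
        if not self.reflection_allowed and det < 0:
            raise AlignmentError("reflection present but not allowed")
        if self.scale <= 0:
            raise AlignmentError("scale must be positive")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        return self.scale * pts @ self.rotation.T + self.translation

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.apply(points)


def procrustes(
    source_pts: np.ndarray,
    target_pts: np.ndarray,
    allow_reflection: bool = False,
    allow_scale: bool = True,
) -> ProcrustesTransform:
    """Least-squares similarity fit of matched point sets.

    Minimizes sum ||s R x_i + t - y_i||^2 over rotation R, scale s and
    translation t.  With ``allow_reflection`` false, det(R) = +1 is
    enforced by flipping the sign of the smallest-singular-value axis;
    with it true the unconstrained orthogonal optimum (possibly a
    reflection) is returned.
    """
    X = np.asarray(source_pts, float).reshape(-1, 3)
    Y = np.asarray(target_pts, float).reshape(-1, 3)
    if X.shape != Y.shape:
        raise AlignmentError("point sets must be matched 1:1")
    n = len(X)
    if n < 3:
        raise AlignmentError(f"need at least 3 matched points, got {n}")
    mx, my = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - mx, Y - my
    cov = Yc.T @ Xc / n
    U, S, Vt = np.linalg.svd(cov)
    if np.linalg.matrix_rank(Xc, tol=1e-12) < 2:
        raise AlignmentError("degenerate (collinear or coincident) configuration")
    d = np.ones(3)
    if not allow_reflection and np.linalg.det(U) * np.linalg.det(Vt) < 0:
        d[-1] = -1.0
    R = U @ np.diag(d) @ Vt
    var_x = (Xc**2).sum() / n
    scale = float((S * d).sum() / var_x) if allow_scale else 1.0
    if scale <= 0:
        raise AlignmentError("degenerate configuration: non-positive fitted scale")
    t = my - scale * R @ mx
    return ProcrustesTransform(
        scale=scale, rotation=R, translation=t, reflection_allowed=allow_reflection
    )


def residual(transform: ProcrustesTransform, source_pts, target_pts) -> float:
    """Root-mean-square misfit of the transformed source to the target."""
    diff = transform.apply(source_pts) - np.asarray(target_pts, float)
    return float(np.sqrt((diff**2).sum(axis=1).mean()))


# ---------------------------------------------------------------------------
# whole-model initial alignment


def initial_align(
    mesh: TriMesh, lms3d: LandmarkSet, lms2d: LandmarkSet
) -> tuple[TriMesh, LandmarkSet]:
    """Whole-model unrestricted Procrustes fit, then anchor re-translation.

    Fits one similarity (reflection permitted) over every matched landmark,
    applies it to the mesh and its landmarks, then rigidly translates so
    that the two anchor landmarks coincide exactly.
    """
    names = lms3d.names
    if set(names) != set(lms2d.names):
        missing = set(names) ^ set(lms2d.names)
        raise AlignmentError(f"landmark name mismatch between sets: {sorted(missing)}")
    if lms3d.anchor_name != lms2d.anchor_name:
        raise AlignmentError("landmark sets disagree on the anchor name")
    T = procrustes(
        lms3d.positions(names), lms2d.positions(names),
        allow_reflection=True, allow_scale=True,
    )
    new_lms = lms3d.transformed(T.apply)
    shift = lms2d.anchor.position - new_lms.anchor.position
    new_lms = new_lms.transformed(lambda p: p + shift)
    new_mesh = mesh.with_vertices(T.apply(mesh.vertices) + shift)
    return new_mesh, new_lms


# ---------------------------------------------------------------------------
# dependency tree


@dataclass(frozen=True)
class DependencyList:
    """Ordered parent→child pairs forming a tree over primary landmarks.

    The list order is topological: each pair's parent is the root or has
    already appeared as a child.  The child name doubles as the segment
    id — "segment Ipip" is the piece of anatomy between ``Imcp`` and
    ``Ipip`` (a proximal index phalanx, say).
    """

    root: str
    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "pairs", tuple((str(p), str(c)) for p, c in self.pairs)
        )
        seen = {self.root}
        children = set()
        for parent, child in self.pairs:
            if parent not in seen:
                raise AlignmentError(
                    f"dependency list not topological: parent {parent!r} of "
                    f"{child!r} has not yet appeared"
                )
            if child in children or child == self.root:
                raise AlignmentError(f"landmark {child!r} appears as child twice")
            children.add(child)
            seen.add(child)

    @property
    def segments(self) -> list[str]:
        """Segment ids in dependency order; the root is its own segment."""
        return [self.root] + [c for _, c in self.pairs]

    def neighbors(self, segment: str) -> set[str]:
        """Segments sharing a dependency edge with ``segment``."""
        out: set[str] = set()
        for parent, child in self.pairs:
            if parent == segment:
                out.add(child)
            if child == segment:
                out.add(parent)
        return out

    def validate_against(self, lms: LandmarkSet) -> None:
        primary = {lm.name for lm in lms.primaries()}
        names = {self.root} | {n for pair in self.pairs for n in pair}
        unknown = names - primary
        if unknown:
            raise AlignmentError(f"dependency names not primary landmarks: {sorted(unknown)}")
        uncovered = primary - names
        if uncovered:
            raise AlignmentError(f"primary landmarks missing from tree: {sorted(uncovered)}")


def load_dependencies(path: str | Path) -> DependencyList:
    """Read ``{"root": "...", "pairs": [[parent, child], ...]}``."""
    data = json.loads(Path(path).read_text())
    return DependencyList(root=str(data["root"]), pairs=tuple(map(tuple, data["pairs"])))


def save_dependencies(deps: DependencyList, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"root": deps.root, "pairs": [list(p) for p in deps.pairs]}, indent=1)
        + "\n"
    )


# ---------------------------------------------------------------------------
# temporary landmarks and vertex assignment


@dataclass(frozen=True)
class TemporaryLandmarks:
    """Densified landmark cloud: positions plus per-point segment ids."""

    positions: np.ndarray
    segment_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "positions", np.asarray(self.positions, float).reshape(-1, 3)
        )
        object.__setattr__(self, "segment_ids", tuple(self.segment_ids))
        if len(self.positions) != len(self.segment_ids):
            raise AlignmentError("positions and segment ids differ in length")


def expand_landmarks(
    lms: LandmarkSet, deps: DependencyList, spacing: float
) -> TemporaryLandmarks:
    """Interpolate temporary landmarks along each dependency segment.

    For each parent→child pair, evenly spaced points at most ``spacing``
    apart are inserted along the straight segment between the two primary
    landmarks, each tagged with the child's segment id.  The original
    primary landmarks are retained: each child keeps its own segment id
    and the root is its own segment.
    """
    if spacing <= 0:
        raise AlignmentError("spacing must be positive")
    positions: list[np.ndarray] = [lms[deps.root].position]
    segs: list[str] = [deps.root]
    for parent, child in deps.pairs:
        p0 = lms[parent].position
        p1 = lms[child].position
        length = float(np.linalg.norm(p1 - p0))
        n_interior = max(0, math.ceil(length / spacing) - 1)
        for i in range(1, n_interior + 1):
            positions.append(p0 + (p1 - p0) * (i / (n_interior + 1)))
            segs.append(child)
        positions.append(p1)
        segs.append(child)
    return TemporaryLandmarks(positions=np.array(positions), segment_ids=tuple(segs))


@dataclass(frozen=True)
class SegmentAssignment:
    """Per-vertex segment ownership with partial influence.

    ``primary`` holds each vertex's owning segment (nearest temporary
    landmark); ``weights`` is an (n_vertices, n_segments) array of
    convex weights, nonzero only on the owning segment and segments
    sharing a dependency edge with it.
    """

    segments: tuple[str, ...]
    primary: np.ndarray
    weights: np.ndarray

    def column(self, segment: str) -> np.ndarray:
        return self.weights[:, self.segments.index(segment)]


def _segment_lengths(lms: LandmarkSet, deps: DependencyList) -> dict[str, float]:
    """Per-segment parent↔child landmark distance; the root gets the mean."""
    out = {
        child: float(np.linalg.norm(lms[child].position - lms[parent].position))
        for parent, child in deps.pairs
    }
    out[deps.root] = float(np.mean(list(out.values()))) if out else 1.0
    return out


def assign_vertices(
    mesh: TriMesh,
    temp_lms: TemporaryLandmarks,
    deps: DependencyList,
    falloff_scale: float | Mapping[str, float] | None = None,
    lms: LandmarkSet | None = None,
) -> SegmentAssignment:
    """Assign each vertex a segment and exponential-falloff influence weights.

    Each vertex's owning segment is that of its nearest temporary landmark
    (ties broken toward the earlier segment in dependency order).  The
    weight of segment ``s`` — over the owning segment and the segments
    dependency-linked to it — is ``exp(-d_s / falloff)`` with ``d_s`` the
    distance to the nearest temporary landmark of ``s``, normalized to sum
    to one.

    ``falloff_scale`` may be a single length, a per-segment mapping, or
    None, in which case it defaults to 0.25 × the local segment length
    (requires ``lms``).  The falloff used for a vertex is its owning
    segment's.
    """
    if len(temp_lms.positions) == 0:
        raise AlignmentError("temporary landmark set is empty")
    segments = tuple(deps.segments)
    seg_index = {s: i for i, s in enumerate(segments)}

    if falloff_scale is None:
        if lms is None:
            raise AlignmentError("falloff_scale=None requires the landmark set")
        lengths = _segment_lengths(lms, deps)
        falloff = {s: 0.25 * lengths[s] for s in segments}
    elif isinstance(falloff_scale, Mapping):
        falloff = {s: float(falloff_scale[s]) for s in segments}
    else:
        falloff = {s: float(falloff_scale) for s in segments}
    if any(v <= 0 for v in falloff.values()):
        raise AlignmentError("falloff_scale must be positive")

    # nearest temporary landmark per segment
    per_seg_dist = np.full((mesh.n_vertices, len(segments)), np.inf)
    for s in segments:
        mask = np.array([sid == s for sid in temp_lms.segment_ids])
        if not mask.any():
            continue
        tree = cKDTree(temp_lms.positions[mask])
        per_seg_dist[:, seg_index[s]], _ = tree.query(mesh.vertices)

    # owning segment: global nearest, ties to lowest segment index
    primary_idx = np.argmin(per_seg_dist, axis=1)  # argmin takes first minimum
    weights = np.zeros_like(per_seg_dist)
    for i, s in enumerate(segments):
        vmask = primary_idx == i
        if not vmask.any():
            continue
        involved = [i] + sorted(seg_index[n] for n in deps.neighbors(s))
        d = per_seg_dist[np.ix_(vmask, involved)]
        w = np.exp(-d / falloff[s])
        w[~np.isfinite(d)] = 0.0
        w /= w.sum(axis=1, keepdims=True)
        weights[np.ix_(vmask, involved)] = w
    primary = np.array([segments[i] for i in primary_idx])
    return SegmentAssignment(segments=segments, primary=primary, weights=weights)


# ---------------------------------------------------------------------------
# iterative segmented Procrustes


def _pair_superset(lms: LandmarkSet, parent: str, child: str) -> list[str]:
    """The pair's primary landmarks plus accessory landmarks sharing their
    base names (``Rdip`` pulls in ``Rdip_t`` and ``Rdip_p``)."""
    bases = {parent, child}
    names = [parent, child]
    names += [lm.name for lm in lms.accessories() if lm.base_name in bases]
    return names


def segmented_procrustes(
    mesh: TriMesh,
    lms_src: LandmarkSet,
    lms_tgt: LandmarkSet,
    deps: DependencyList,
    assignment: SegmentAssignment,
    blend: Literal["weighted", "hard"] = "weighted",
    n_passes: int | Literal["auto"] = 1,
) -> tuple[TriMesh, LandmarkSet]:
    """Morph a mesh segment by segment onto target landmark positions.

    For each dependency pair in list order: gather the pair's primary
    landmarks and the accessory landmarks sharing their base names; fit a
    no-reflection similarity Procrustes from the superset's *current*
    positions to their targets; move the superset landmarks by the fit;
    and move every vertex with positive weight ``w`` on the pair's child
    segment to the convex combination ``w·T(x) + (1−w)·x`` of its current
    position (``blend="hard"`` instead applies ``T`` fully to vertices
    whose owning segment is the child).  Transforms compose sequentially
    down the tree.

    ``n_passes`` repeats the whole dependency sweep.  One pass is the
    minimal procedure; because a pair's fit also holds on to the parent
    segment's width markers, a single sweep leaves a residual that grows
    with deformation size.  ``"auto"`` sweeps to a fixed point (stops
    when the landmark RMS residual improves by less than one part in 1e6
    of the landmark cloud's extent, capped at 64 sweeps), as iterative
    Procrustes alignments conventionally are.
    """
    if set(lms_src.names) != set(lms_tgt.names):
        missing = set(lms_src.names) ^ set(lms_tgt.names)
        raise AlignmentError(f"landmark name mismatch: {sorted(missing)}")
    deps.validate_against(lms_src)
    if assignment.weights.shape[0] != mesh.n_vertices:
        raise AlignmentError("segment assignment does not match the mesh")

    auto = n_passes == "auto"
    max_passes = 64 if auto else int(n_passes)
    tgt_all = lms_tgt.positions(lms_src.names)
    scale = float(np.ptp(tgt_all, axis=0).max())
    last_rms = np.inf

    current = lms_src
    V = mesh.vertices.copy()
    for _ in range(max_passes):
        for parent, child in deps.pairs:
            names = _pair_superset(current, parent, child)
            src = current.positions(names)
            tgt = lms_tgt.positions(names)
            T = procrustes(src, tgt, allow_reflection=False, allow_scale=True)
            current = current.with_positions(names, T.apply(src))
            if blend == "hard":
                move = assignment.primary == child
                if move.any():
                    V[move] = T.apply(V[move])
            else:
                w = assignment.column(child)
                move = w > 0
                if move.any():
                    V[move] = (
                        w[move, None] * T.apply(V[move]) + (1.0 - w[move, None]) * V[move]
                    )
        if auto:
            diff = current.positions(lms_src.names) - tgt_all
            rms = float(np.sqrt((diff**2).sum(axis=1).mean()))
            if last_rms - rms < 1e-6 * scale:
                break
            last_rms = rms
    return mesh.with_vertices(V), current


def morph_to_reference(
    mesh: TriMesh,
    lms3d: LandmarkSet,
    lms_ref: LandmarkSet,
    deps: DependencyList,
    spacing: float | None = None,
    falloff_scale: float | None = None,
    blend: Literal["weighted", "hard"] = "weighted",
    n_passes: int | Literal["auto"] = 1,
) -> tuple[TriMesh, LandmarkSet]:
    """Full pipeline: initial alignment then segmented Procrustes morph.

    ``spacing`` defaults to 0.05 × the anchor→farthest-primary-landmark
    distance, making temporary-landmark density scale-free.
    """
    aligned_mesh, aligned_lms = initial_align(mesh, lms3d, lms_ref)
    if spacing is None:
        anchor = aligned_lms.anchor.position
        prim = np.array([lm.position for lm in aligned_lms.primaries()])
        reach = float(np.linalg.norm(prim - anchor, axis=1).max())
        spacing = 0.05 * reach
    temp = expand_landmarks(aligned_lms, deps, spacing)
    assign = assign_vertices(
        aligned_mesh, temp, deps, falloff_scale=falloff_scale, lms=aligned_lms
    )
    return segmented_procrustes(
        aligned_mesh, aligned_lms, lms_ref, deps, assign, blend=blend, n_passes=n_passes
    )
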