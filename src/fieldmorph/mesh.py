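"""Triangle-mesh and landmark primitives.

The meshes handled here are body-part surfaces (hands, residual limbs,
generic body models) on which stimulation-evoked sensations are annotated.
Everything downstream — alignment, flattening, annotation transfer — works
on the plain vertex/face representation defined in this module.

Coordinates are dimensionless model units.  Vertex indexing is 0-based
internally; OBJ's 1-based indices are converted at the file boundary.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import trimesh as _trimesh

logger = logging.getLogger(__name__)

#: Faces with area below this (model units squared) are dropped at load.
DEGENERATE_AREA = 1e-12


class MeshError(ValueError):
    """Raised for structurally invalid meshes (bad indices, no faces)."""


@dataclass(frozen=True)
class TriMesh:
    """An indexed triangle mesh.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex positions in model units.
    faces : (m, 3) int array
        Vertex index triples, counter-clockwise when viewed from outside
        so that right-hand-rule normals point outward.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        f = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise MeshError("face index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def with_vertices(self, vertices: np.ndarray) -> "TriMesh":
        """Same connectivity, new vertex positions."""
        return TriMesh(vertices=np.asarray(vertices, float), faces=self.faces)

    def edges_consistent(self) -> bool:
        """True when every interior edge appears once in each direction."""
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        # consistent winding <=> no directed edge is traversed twice
        return len(np.unique(e, axis=0)) == len(e)

    def is_closed(self) -> bool:
        """True when every edge is shared by exactly two faces."""
        e = np.sort(
            np.concatenate(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            ),
            axis=1,
        )
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def euler_characteristic(self) -> int:
        e = np.sort(
            np.concatenate(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            ),
            axis=1,
        )
        n_edges = len(np.unique(e, axis=0))
        used = np.unique(self.faces)
        return int(len(used) - n_edges + self.n_faces)


class LandmarkRole(str, Enum):
    PRIMARY = "primary"
    ACCESSORY = "accessory"


@dataclass(frozen=True)
class Landmark:
    """A named anatomical point used to drive alignment.

    Primary landmarks sit on joints and tips and define the segment
    hierarchy; accessory landmarks pin widths.  An accessory name is its
    base (primary) name plus a suffix: ``_t`` marks the thumb-side width
    marker and ``_p`` the pinky-side one, e.g. ``Rdip_t`` / ``Rdip_p``
    belong to the primary landmark ``Rdip``.  Landmarks on 2D reference
    illustrations carry depth coordinate 0.
    """

    name: str
    role: LandmarkRole
    position: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=np.float64).reshape(3)
        )

    @property
    def base_name(self) -> str:
        """Name with any ``_``-suffix stripped (``Rdip_t`` → ``Rdip``)."""
        return self.name.split("_", 1)[0]


class LandmarkError(ValueError):
    """Raised for landmark sets violating naming or anchoring rules."""


@dataclass(frozen=True)
class LandmarkSet:
    """A named collection of landmarks with a designated anchor.

    The anchor is the landmark at the end of the wrist (or the equivalent
    proximal point on other body parts); alignment re-translates models so
    anchors coincide.
    """

    landmarks: tuple[Landmark, ...]
    anchor_name: str = "wrist"

    def __post_init__(self) -> None:
        object.__setattr__(self, "landmarks", tuple(self.landmarks))
        names = [lm.name for lm in self.landmarks]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise LandmarkError(f"duplicate landmark names: {dupes}")
        primaries = {lm.name for lm in self.landmarks if lm.role is LandmarkRole.PRIMARY}
        for lm in self.landmarks:
            if lm.role is LandmarkRole.ACCESSORY and lm.base_name not in primaries:
                raise LandmarkError(
                    f"accessory landmark {lm.name!r} has no primary base "
                    f"landmark {lm.base_name!r}"
                )
        anchor = self._by_name().get(self.anchor_name)
        if anchor is None or anchor.role is not LandmarkRole.PRIMARY:
            raise LandmarkError(
                f"anchor {self.anchor_name!r} does not resolve to a primary landmark"
            )

    def _by_name(self) -> dict[str, Landmark]:
        return {lm.name: lm for lm in self.landmarks}

    def __len__(self) -> int:
        return len(self.landmarks)

    def __iter__(self):
        return iter(self.landmarks)

    def __getitem__(self, name: str) -> Landmark:
        try:
            return self._by_name()[name]
        except KeyError:
            raise LandmarkError(f"no landmark named {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name()

    @property
    def names(self) -> list[str]:
        return [lm.name for lm in self.landmarks]

    @property
    def anchor(self) -> Landmark:
        return self[self.anchor_name]

    def primaries(self) -> list[Landmark]:
        return [lm for lm in self.landmarks if lm.role is LandmarkRole.PRIMARY]

    def accessories(self) -> list[Landmark]:
        return [lm for lm in self.landmarks if lm.role is LandmarkRole.ACCESSORY]

    def positions(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Stacked (k, 3) positions, in ``names`` order (all, if omitted)."""
        if names is None:
            names = self.names
        by = self._by_name()
        return np.array([by[n].position for n in names], dtype=np.float64)

    def with_positions(self, names: Sequence[str], positions: np.ndarray) -> "LandmarkSet":
        """Copy with the named landmarks moved to the given positions."""
        positions = np.asarray(positions, float).reshape(len(names), 3)
        moved = dict(zip(names, positions))
        new = tuple(
            replace(lm, position=moved[lm.name]) if lm.name in moved else lm
            for lm in self.landmarks
        )
        return LandmarkSet(landmarks=new, anchor_name=self.anchor_name)

    def transformed(self, fn) -> "LandmarkSet":
        """Copy with every position mapped through ``fn((k,3)) -> (k,3)``."""
        pos = fn(self.positions())
        return self.with_positions(self.names, pos)


# ---------------------------------------------------------------------------
# geometry


def face_normals(mesh: TriMesh) -> np.ndarray:
    """Per-face outward unit normals (right-hand rule on the winding)."""
    v = mesh.vertices
    f = mesh.faces
    n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    return n / norm


def face_areas(mesh: TriMesh) -> np.ndarray:
    """Per-face triangle areas."""
    v = mesh.vertices
    f = mesh.faces
    n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    return 0.5 * np.linalg.norm(n, axis=1)


def face_centroids(mesh: TriMesh) -> np.ndarray:
    """Per-face vertex-mean centroids — the mesh's "face locations"."""
    return mesh.vertices[mesh.faces].mean(axis=1)


_MIRROR_AXIS = {"x": 0, "y": 1, "z": 2}


def mirror_mesh(mesh: TriMesh, plane: str = "x") -> TriMesh:
    """Reflect across a coordinate plane (``"x"`` means the plane x = 0).

    Used to represent a contralateral limb from a scan of the intact one.
    Face winding is reversed so normals remain outward; the operation is
    an involution and preserves all face areas exactly.
    """
    try:
        axis = _MIRROR_AXIS[plane]
    except KeyError:
        raise ValueError(f"plane must be one of {sorted(_MIRROR_AXIS)}, got {plane!r}")
    v = mesh.vertices.copy()
    v[:, axis] = -v[:, axis]
    f = mesh.faces[:, [0, 2, 1]]
    return TriMesh(vertices=v, faces=f)


def signed_volume(mesh: TriMesh) -> float:
    """Divergence-theorem volume of a closed mesh (sign follows winding)."""
    v = mesh.vertices[mesh.faces]
    return float(np.einsum("ij,ij->i", v[:, 0], np.cross(v[:, 1], v[:, 2])).sum() / 6.0)


# ---------------------------------------------------------------------------
# mesh I/O


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
    else:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("obj", "glb"):
        raise ValueError(f"unsupported mesh format {fmt!r} (use 'obj' or 'glb')")
    return fmt


def _clean_faces(vertices: np.ndarray, faces: np.ndarray, origin: str) -> np.ndarray:
    """Drop degenerate (near-zero-area) faces; vertices stay untouched so
    that annotation indices remain valid."""
    if len(faces) == 0:
        return faces
    tri = vertices[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    keep = areas >= DEGENERATE_AREA
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("%s: dropped %d degenerate face(s)", origin, dropped)
        warnings.warn(f"{origin}: dropped {dropped} degenerate face(s)", stacklevel=3)
    return faces[keep]


def load_mesh(path: str | Path, format: str | None = None) -> TriMesh:
    """Load an OBJ or GLB triangle mesh.

    Non-triangular polygons are fan-triangulated; duplicate-position
    vertices are *not* merged, so vertex indexing in annotation files
    stays valid.  Degenerate faces are dropped with a logged warning.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise FileNotFoundError(path)
    loaded = _trimesh.load(
        str(path), file_type=fmt, process=False, maintain_order=True, force=None
    )
    if isinstance(loaded, _trimesh.Scene):
        geoms = list(loaded.geometry.values())
        if len(geoms) != 1:
            raise MeshError(
                f"{path}: expected a single mesh primitive, found {len(geoms)}"
            )
        loaded = geoms[0]
    if not isinstance(loaded, _trimesh.Trimesh):
        raise MeshError(f"{path}: no triangle mesh found")
    vertices = np.asarray(loaded.vertices, dtype=np.float64)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    faces = _clean_faces(vertices, faces, str(path))
    if len(faces) == 0:
        raise MeshError(f"{path}: no non-degenerate faces")
    return TriMesh(vertices=vertices, faces=faces)


def save_mesh(mesh: TriMesh, path: str | Path, format: str | None = None) -> None:
    """Write a mesh as OBJ (text, 9 significant digits) or GLB.

    The OBJ writer is deliberately plain so that ``load_mesh(save_mesh(m))``
    reproduces coordinates to the printed precision and face indices
    exactly.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if mesh.n_faces == 0:
        raise MeshError("refusing to save a mesh with no faces")
    if fmt == "obj":
        lines = ["# fieldmorph OBJ export"]
        lines += [f"v {x:.9g} {y:.9g} {z:.9g}" for x, y, z in mesh.vertices]
        lines += [f"f {a + 1} {b + 1} {c + 1}" for a, b, c in mesh.faces]
        path.write_text("\n".join(lines) + "\n")
    else:
        tm = _trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
        path.write_bytes(tm.export(file_type="glb"))


# ---------------------------------------------------------------------------
# landmark I/O


def load_landmarks(path: str | Path) -> LandmarkSet:
    """Read a landmark JSON file.

    Schema::

        {"anchor": "wrist",
         "landmarks": [{"name": "...", "role": "primary|accessory",
                        "position": [x, y, z]}, ...]}
    """
    path = Path(path)
    data = json.loads(path.read_text())
    return landmarks_from_dict(data)


def landmarks_from_dict(data: Mapping) -> LandmarkSet:
    try:
        lms = tuple(
            Landmark(
                name=str(item["name"]),
                role=LandmarkRole(item["role"]),
                position=item["position"],
            )
            for item in data["landmarks"]
        )
        anchor = str(data["anchor"])
    except (KeyError, ValueError, TypeError) as exc:
        raise LandmarkError(f"malformed landmark record: {exc}") from exc
    return LandmarkSet(landmarks=lms, anchor_name=anchor)


def landmarks_to_dict(lms: LandmarkSet) -> dict:
    return {
        "anchor": lms.anchor_name,
        "landmarks": [
            {
                "name": lm.name,
                "role": lm.role.value,
                "position": [float(x) for x in lm.position],
            }
            for lm in lms.landmarks
        ],
    }


def save_landmarks(lms: LandmarkSet, path: str | Path) -> None:
    Path(path).write_text(json.dumps(landmarks_to_dict(lms), indent=1) + "\n")
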