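import numpy as np
import pytest
import trimesh

from fieldmorph.annotation import ProjectedField
from fieldmorph.flatten import (
    CompareError,
    PixelMask,
    flatten_mesh,
    jaccard,
    load_mask,
    obliqueness,
    partition_faces,
    rasterize,
    save_mask,
    split_aspect_meshes,
)
from fieldmorph.mesh import TriMesh, face_areas


def tilted_triangle(angle_deg: float) -> TriMesh:
    """One triangle whose normal makes the given angle with +z."""
    a = np.radians(angle_deg)
    normal = np.array([np.sin(a), 0.0, np.cos(a)])
    u = np.array([0.0, 1.0, 0.0])
    v = np.cross(normal, u)
    verts = np.array([np.zeros(3), u, v])
    return TriMesh(verts, [[0, 1, 2]])


class TestPartition:
    @pytest.mark.parametrize(
        "angle,palmar,oblique",
        [
            (0.0, True, False),
            (45.0, True, False),
            (75.0, True, True),      # inside the 60-120 oblique band, still palmar
            (105.0, False, True),
            (135.0, False, False),
            (180.0, False, False),
        ],
    )
    def test_angle_classification(self, angle, palmar, oblique):
        part = partition_faces(tilted_triangle(angle), (0, 0, 1))
        assert part.angles[0] == pytest.approx(angle, abs=1e-9)
        assert bool(part.palmar[0]) is palmar
        assert bool(part.oblique[0]) is oblique

    def test_exactly_90_degrees_is_dorsal_not_oblique_boundary(self):
        part = partition_faces(tilted_triangle(90.0), (0, 0, 1))
        assert not part.palmar[0]
        assert part.oblique[0]  # strictly inside (60, 120)

    def test_oblique_band_is_open_interval(self):
        # strictly inside just past the edges, outside just before them
        for angle in (60.001, 119.999):
            assert partition_faces(tilted_triangle(angle), (0, 0, 1)).oblique[0]
        for angle in (59.999, 120.001):
            assert not partition_faces(tilted_triangle(angle), (0, 0, 1)).oblique[0]

    def test_invariant_to_rotation_about_depth_vector(self, sphere):
        part = partition_faces(sphere, (0, 0, 1))
        th = 0.83
        Rz = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        rotated = sphere.with_vertices(sphere.vertices @ Rz.T)
        part2 = partition_faces(rotated, (0, 0, 1))
        np.testing.assert_array_equal(part.palmar, part2.palmar)
        np.testing.assert_array_equal(part.oblique, part2.oblique)

    def test_zero_depth_vector_rejected(self, sphere):
        with pytest.raises(CompareError):
            partition_faces(sphere, (0, 0, 0))


class TestSplit:
    def test_face_counts_conserved_and_maps_invert(self, sphere):
        part = partition_faces(sphere)
        (pm, pmap), (dm, dmap) = split_aspect_meshes(sphere, part)
        assert pm.n_faces + dm.n_faces == sphere.n_faces
        np.testing.assert_array_equal(sphere.faces[pmap], pm.faces)
        np.testing.assert_array_equal(sphere.faces[dmap], dm.faces)

    def test_sphere_hemispheres_have_equal_area(self):
        ico = trimesh.creation.icosphere(subdivisions=4)  # 5120 faces
        c, s = np.cos(0.1), np.sin(0.1)
        R = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
        m = TriMesh(np.asarray(ico.vertices) @ R.T, np.asarray(ico.faces))
        (pm, _), (dm, _) = split_aspect_meshes(m, partition_faces(m))
        ratio = face_areas(pm).sum() / face_areas(dm).sum()
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_all_palmar_mesh_gives_empty_dorsal(self, sheet):
        part = partition_faces(sheet)
        (_, pmap), (dm, _) = split_aspect_meshes(sheet, part)
        assert dm.n_faces == 0
        assert len(pmap) == sheet.n_faces


class TestFlatten:
    def test_depth_component_zeroed_in_plane_preserved(self, hand_mesh):
        flat = flatten_mesh(hand_mesh, (0, 0, 1))
        assert np.abs(flat.vertices[:, 2]).max() == 0
        np.testing.assert_array_equal(flat.vertices[:, :2], hand_mesh.vertices[:, :2])

    def test_idempotent(self, hand_mesh):
        once = flatten_mesh(hand_mesh, (0, 1, 0))
        twice = flatten_mesh(once, (0, 1, 0))
        np.testing.assert_array_equal(once.vertices, twice.vertices)


def oracle_pixel_count(tri, grid):
    """Exhaustive pixel-center point-in-triangle count (inclusive edges)."""
    xs, ys = grid.pixel_centers()
    count = 0
    a, b, c = [np.asarray(p, float) for p in tri]

    def cross2(u, v):
        return u[0] * v[1] - u[1] * v[0]

    sgn = np.sign(cross2(b - a, c - a))
    for y in ys:
        for x in xs:
            p = np.array([x, y])
            s0 = cross2(b - a, p - a) * sgn
            s1 = cross2(c - b, p - b) * sgn
            s2 = cross2(a - c, p - c) * sgn
            if s0 >= 0 and s1 >= 0 and s2 >= 0:
                count += 1
    return count


class TestRasterize:
    def test_no_faces_gives_empty_mask(self, sheet):
        grid = PixelMask.empty(12, 12)
        assert rasterize(sheet, [], grid).count == 0

    def test_covering_triangle_fills_grid(self):
        m = TriMesh([[-5, -5, 0], [30, -5, 0], [-5, 30, 0]], [[0, 1, 2]])
        grid = PixelMask.empty(10, 10)
        assert rasterize(m, [0], grid).count == 100

    @pytest.mark.parametrize(
        "tri",
        [
            [[0, 0], [10, 0], [0, 10]],
            [[0.3, 0.2], [9.1, 1.4], [4.0, 8.7]],
            [[2, 2], [2.9, 2.1], [2.2, 2.8]],  # sub-pixel sliver
        ],
    )
    def test_pixel_count_matches_exhaustive_oracle(self, tri):
        verts = [[x, y, 0.0] for x, y in tri]
        m = TriMesh(verts, [[0, 1, 2]])
        grid = PixelMask.empty(10, 10)
        mask = rasterize(m, [0], grid)
        assert mask.count == oracle_pixel_count(tri, grid)

    def test_rasterized_area_converges_to_projected_area(self):
        tri = [[0.05, 0.1], [0.92, 0.23], [0.41, 0.88]]
        m = TriMesh([[x, y, 0.0] for x, y in tri], [[0, 1, 2]])
        true_area = 0.5 * abs(
            (tri[1][0] - tri[0][0]) * (tri[2][1] - tri[0][1])
            - (tri[1][1] - tri[0][1]) * (tri[2][0] - tri[0][0])
        )
        px = 1.0 / 500  # hand-length/500 resolution on a unit-extent patch
        grid = PixelMask.empty(500, 500, pixel_size=px)
        mask = rasterize(m, [0], grid)
        assert mask.count * px**2 == pytest.approx(true_area, rel=0.02)


class TestJaccard:
    @staticmethod
    def mask_from(indices, shape=(10, 10)):
        g = np.zeros(shape, bool)
        for i, j in indices:
            g[i, j] = True
        return PixelMask(g)

    def test_identical_nonempty_masks_give_one(self):
        a = self.mask_from([(1, 1), (2, 3)])
        assert jaccard(a, a) == 1.0

    def test_disjoint_masks_give_zero(self):
        a = self.mask_from([(0, 0)])
        b = self.mask_from([(5, 5)])
        assert jaccard(a, b) == 0.0

    def test_worked_pixel_count_case(self):
        # |a| = 60, |b| = 60, overlap 30, union 90 -> 1/3
        a = self.mask_from([(i, j) for i in range(6) for j in range(10)])
        b = self.mask_from([(i, j) for i in range(3, 9) for j in range(10)])
        assert a.count == b.count == 60
        assert jaccard(a, b) == pytest.approx(1 / 3)

    def test_symmetry_and_size_ratio_bound(self):
        rng = np.random.default_rng(12)
        a = PixelMask(rng.random((10, 10)) < 0.4)
        b = PixelMask(rng.random((10, 10)) < 0.4)
        assert jaccard(a, b) == jaccard(b, a)
        if a.count and b.count:
            assert jaccard(a, b) <= min(a.count, b.count) / max(a.count, b.count)

    def test_both_empty_gives_zero(self):
        assert jaccard(PixelMask.empty(4, 4), PixelMask.empty(4, 4)) == 0.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(CompareError):
            jaccard(PixelMask.empty(4, 4), PixelMask.empty(5, 4))


class TestObliqueness:
    def test_frontoparallel_annotation_scores_zero(self, sheet):
        part = partition_faces(sheet)
        f = ProjectedField(mesh_id="sheet", faces=frozenset(range(10)))
        assert obliqueness(f, part, face_areas(sheet)) == 0.0

    def test_steeply_tilted_annotation_scores_one(self):
        m = tilted_triangle(80.0)
        part = partition_faces(m)
        f = ProjectedField(mesh_id="tilt", faces=frozenset({0}))
        assert obliqueness(f, part, face_areas(m)) == 1.0

    def test_cylinder_lateral_band_approaches_one_third(self):
        # depth vector perpendicular to the axis: the 60-120 plus 240-300
        # azimuthal bands cover 120 of 360 degrees of the lateral surface
        cyl = trimesh.creation.cylinder(radius=1.0, height=2.0, sections=2500)
        m = TriMesh(np.asarray(cyl.vertices), np.asarray(cyl.faces))
        part = partition_faces(m, (1, 0, 0))
        areas = face_areas(m)
        normals_z = np.cross(
            m.vertices[m.faces[:, 1]] - m.vertices[m.faces[:, 0]],
            m.vertices[m.faces[:, 2]] - m.vertices[m.faces[:, 0]],
        )[:, 2]
        lateral = frozenset(np.flatnonzero(np.abs(normals_z) < 1e-9).tolist())
        f = ProjectedField(mesh_id="cyl", faces=lateral)
        assert obliqueness(f, part, areas) == pytest.approx(1 / 3, rel=0.01)

    def test_invariant_under_midpoint_subdivision(self):
        m = tilted_triangle(70.0)
        f = ProjectedField(mesh_id="t", faces=frozenset({0}))
        score = obliqueness(f, partition_faces(m), face_areas(m))
        v = m.vertices
        mids = np.array([(v[0] + v[1]) / 2, (v[1] + v[2]) / 2, (v[2] + v[0]) / 2])
        m2 = TriMesh(
            np.vstack([v, mids]),
            [[0, 3, 5], [3, 1, 4], [5, 4, 2], [3, 4, 5]],
        )
        f2 = ProjectedField(mesh_id="t", faces=frozenset(range(4)))
        score2 = obliqueness(f2, partition_faces(m2), face_areas(m2))
        assert score2 == pytest.approx(score, abs=1e-9)

    def test_empty_annotation_rejected(self, sheet):
        part = partition_faces(sheet)
        with pytest.raises(CompareError):
            obliqueness(
                ProjectedField(mesh_id="s", faces=frozenset()), part, face_areas(sheet)
            )


class TestMaskIO:
    def test_png_roundtrip_preserves_grid_and_geometry(self, tmp_path):
        rng = np.random.default_rng(3)
        mask = PixelMask(rng.random((7, 11)) < 0.5, origin=(-1.5, 2.0), pixel_size=0.25)
        p = tmp_path / "mask.png"
        save_mask(mask, p)
        back = load_mask(p)
        np.testing.assert_array_equal(back.grid, mask.grid)
        assert back.origin == mask.origin
        assert back.pixel_size == mask.pixel_size
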