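import numpy as np
import pytest

from fieldmorph.alignment import (
    AlignmentError,
    DependencyList,
    assign_vertices,
    expand_landmarks,
    initial_align,
    morph_to_reference,
    procrustes,
    residual,
    segmented_procrustes,
)
from fieldmorph.mesh import Landmark, LandmarkRole, LandmarkSet, TriMesh
from fieldmorph.synthetic import (
    SegmentSimilarity,
    apply_deformation,
    make_2d_reference,
    random_deformation,
)


def random_rotation(rng):
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def landmark_rms(lms_a, lms_b):
    d = lms_a.positions() - lms_b.positions(lms_a.names)
    return float(np.sqrt((d**2).sum(axis=1).mean()))


def hand_length(lms):
    prim = np.array([lm.position for lm in lms.primaries()])
    return float(np.linalg.norm(prim - lms.anchor.position, axis=1).max())


class TestProcrustes:
    def test_identity_fit(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        T = procrustes(X, X)
        assert T.scale == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(T.translation, 0, atol=1e-12)

    def test_recovers_constructed_similarity(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 3))
        Rz = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], float)  # 90 deg about z
        Y = 2.0 * X @ Rz.T + np.array([1.0, 0.0, 0.0])
        T = procrustes(X, Y)
        assert T.scale == pytest.approx(2.0, rel=1e-12)
        np.testing.assert_allclose(T.rotation, Rz, atol=1e-12)
        assert residual(T, X, Y) < 1e-9

    def test_reflection_excluded_gives_proper_rotation_and_misfit(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 3))
        Y = X.copy()
        Y[:, 0] = -Y[:, 0]  # mirrored configuration
        T = procrustes(X, Y, allow_reflection=False)
        assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)
        assert residual(T, X, Y) > 1e-3
        T2 = procrustes(X, Y, allow_reflection=True)
        assert residual(T2, X, Y) < 1e-9

    def test_left_invariance_of_residual(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(9, 3))
        Y = rng.normal(size=(9, 3))
        r0 = residual(procrustes(X, Y), X, Y)
        Q = random_rotation(rng)
        r1 = residual(procrustes(X @ Q.T, Y @ Q.T), X @ Q.T, Y @ Q.T)
        assert r1 == pytest.approx(r0, abs=1e-9)

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(AlignmentError):
            procrustes(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(AlignmentError):
            procrustes(line, line)

    def test_no_scale_fit_keeps_unit_scale(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 3))
        T = procrustes(X, 3.0 * X, allow_scale=False)
        assert T.scale == 1.0


class TestInitialAlign:
    def test_identity_reference_leaves_mesh_fixed(self, hand_mesh, hand_landmarks):
        out, out_lms = initial_align(hand_mesh, hand_landmarks, hand_landmarks)
        np.testing.assert_allclose(out.vertices, hand_mesh.vertices, atol=1e-9)
        np.testing.assert_allclose(
            out_lms.positions(), hand_landmarks.positions(), atol=1e-9
        )

    def test_anchors_coincide_exactly(self, hand_mesh, hand_landmarks, hand_deps):
        ref, _ = make_2d_reference(hand_landmarks, hand_deps, seed=11)
        _, out_lms = initial_align(hand_mesh, hand_landmarks, ref)
        assert np.linalg.norm(out_lms.anchor.position - ref.anchor.position) < 1e-12

    def test_alignment_reduces_landmark_rms(self, hand_mesh, hand_landmarks, hand_deps):
        # a flattened, scaled, shifted copy of the hand landmarks
        flat = hand_landmarks.transformed(
            lambda p: 1.7 * np.c_[p[:, 0], p[:, 1], np.zeros(len(p))] + [5.0, -2.0, 0.0]
        )
        before = landmark_rms(hand_landmarks, flat)
        _, out_lms = initial_align(hand_mesh, hand_landmarks, flat)
        assert landmark_rms(out_lms, flat) < before

    def test_name_mismatch_rejected(self, hand_mesh, hand_landmarks):
        dropped = LandmarkSet(hand_landmarks.landmarks[:-1], "wrist")
        with pytest.raises(AlignmentError):
            initial_align(hand_mesh, hand_landmarks, dropped)


class TestDependencyList:
    def test_non_topological_order_rejected(self):
        with pytest.raises(AlignmentError, match="topological"):
            DependencyList(root="wrist", pairs=(("Imcp", "Ipip"), ("wrist", "Imcp")))

    def test_duplicate_child_rejected(self):
        with pytest.raises(AlignmentError):
            DependencyList(root="w", pairs=(("w", "a"), ("w", "a")))

    def test_canonical_tree_covers_all_primaries(self, hand_landmarks, hand_deps):
        hand_deps.validate_against(hand_landmarks)
        assert len(hand_deps.pairs) == len(hand_landmarks.primaries()) - 1


class TestExpandLandmarks:
    @staticmethod
    def toy(length=2.0):
        lms = LandmarkSet(
            landmarks=(
                Landmark("wrist", LandmarkRole.PRIMARY, (0, 0, 0)),
                Landmark("tip", LandmarkRole.PRIMARY, (length, 0, 0)),
            ),
        )
        return lms, DependencyList(root="wrist", pairs=(("wrist", "tip"),))

    def test_midpoint_inserted_at_spacing_one(self):
        lms, deps = self.toy(2.0)
        temp = expand_landmarks(lms, deps, spacing=1.0)
        assert any(np.allclose(p, [1, 0, 0]) for p in temp.positions)

    def test_wide_spacing_adds_no_interior_points(self):
        lms, deps = self.toy(2.0)
        temp = expand_landmarks(lms, deps, spacing=2.5)
        assert len(temp.positions) == 2  # just the two originals

    def test_interior_count_matches_ceil_rule(self, hand_landmarks, hand_deps):
        import math

        spacing = 0.3
        temp = expand_landmarks(hand_landmarks, hand_deps, spacing)
        expected_interior = 0
        for parent, child in hand_deps.pairs:
            length = np.linalg.norm(
                hand_landmarks[child].position - hand_landmarks[parent].position
            )
            expected_interior += max(0, math.ceil(length / spacing) - 1)
        # root + one retained endpoint per pair + interior points
        assert len(temp.positions) == 1 + len(hand_deps.pairs) + expected_interior


class TestAssignVertices:
    @staticmethod
    def chain():
        lms = LandmarkSet(
            landmarks=(
                Landmark("wrist", LandmarkRole.PRIMARY, (0, 0, 0)),
                Landmark("a", LandmarkRole.PRIMARY, (2, 0, 0)),
                Landmark("b", LandmarkRole.PRIMARY, (4, 0, 0)),
            ),
        )
        deps = DependencyList(root="wrist", pairs=(("wrist", "a"), ("a", "b")))
        return lms, deps

    def test_far_vertex_weight_saturates(self):
        lms, deps = self.chain()
        temp = expand_landmarks(lms, deps, spacing=1.0)
        mesh = TriMesh([[4, 0, 0], [4, 0.1, 0], [4.1, 0, 0]], [[0, 1, 2]])
        assign = assign_vertices(mesh, temp, deps, falloff_scale=0.01)
        assert assign.primary[0] == "b"
        assert assign.column("b")[0] > 0.99

    def test_equidistant_vertex_splits_weight_evenly(self):
        lms = LandmarkSet(
            landmarks=(
                Landmark("wrist", LandmarkRole.PRIMARY, (0, 0, 0)),
                Landmark("a", LandmarkRole.PRIMARY, (2, 0, 0)),
            ),
        )
        deps = DependencyList(root="wrist", pairs=(("wrist", "a"),))
        temp = expand_landmarks(lms, deps, spacing=5.0)  # endpoints only
        mesh = TriMesh([[1, 0, 0], [0, 5, 0], [2, 5, 0]], [[0, 1, 2]])
        assign = assign_vertices(mesh, temp, deps, falloff_scale=1.0)
        # vertex 0 sits exactly 1 unit from both segments' only landmarks
        assert assign.column("wrist")[0] == pytest.approx(0.5)
        assert assign.column("a")[0] == pytest.approx(0.5)

    def test_weights_sum_to_one(self, hand_mesh, hand_landmarks, hand_deps):
        temp = expand_landmarks(hand_landmarks, hand_deps, spacing=0.4)
        assign = assign_vertices(
            hand_mesh, temp, hand_deps, falloff_scale=None, lms=hand_landmarks
        )
        np.testing.assert_allclose(assign.weights.sum(axis=1), 1.0, atol=1e-12)
        assert (assign.weights >= 0).all()


class TestSegmentedProcrustes:
    def test_identical_targets_leave_mesh_fixed(self, hand_mesh, hand_landmarks, hand_deps):
        out, out_lms = morph_to_reference(
            hand_mesh, hand_landmarks, hand_landmarks, hand_deps
        )
        np.testing.assert_allclose(out.vertices, hand_mesh.vertices, atol=1e-9)

    def test_single_segment_toy_recovers_similarity_exactly(self):
        lms = LandmarkSet(
            landmarks=(
                Landmark("wrist", LandmarkRole.PRIMARY, (0, 0, 0)),
                Landmark("tip", LandmarkRole.PRIMARY, (2, 0, 0)),
                Landmark("tip_t", LandmarkRole.ACCESSORY, (1, 0.4, 0)),
                Landmark("tip_p", LandmarkRole.ACCESSORY, (1, -0.4, 0)),
            ),
        )
        deps = DependencyList(root="wrist", pairs=(("wrist", "tip"),))
        rng = np.random.default_rng(5)
        R = random_rotation(rng)
        s, t = 1.6, np.array([0.3, -0.2, 0.5])
        target = lms.transformed(lambda p: s * p @ R.T + t)
        mesh = TriMesh([[0.5, 0.2, 0.1], [1.5, -0.3, 0.0], [1.0, 0.1, 0.3]], [[0, 1, 2]])
        temp = expand_landmarks(lms, deps, spacing=0.5)
        assign = assign_vertices(mesh, temp, deps, falloff_scale=0.5)
        out, out_lms = segmented_procrustes(
            mesh, lms, target, deps, assign, blend="hard"
        )
        np.testing.assert_allclose(
            out_lms.positions(), target.positions(out_lms.names), atol=1e-9
        )
        np.testing.assert_allclose(
            out.vertices, s * mesh.vertices @ R.T + t, atol=1e-9
        )

    def test_morph_improves_on_initial_alignment(self, hand):
        mesh, lms, deps = hand
        ref, _ = make_2d_reference(lms, deps, seed=7)
        _, aligned_lms = initial_align(mesh, lms, ref)
        _, morphed_lms = morph_to_reference(mesh, lms, ref, deps)
        assert landmark_rms(morphed_lms, ref) < landmark_rms(aligned_lms, ref)

    def test_converged_morph_recovers_articulated_targets(self, hand):
        mesh, lms, deps = hand
        deform = random_deformation(deps, seed=9)
        target = apply_deformation(lms, deps, deform)
        _, morphed_lms = morph_to_reference(mesh, lms, target, deps, n_passes="auto")
        assert landmark_rms(morphed_lms, target) < 0.01 * hand_length(lms)

    def test_untouched_segment_vertices_do_not_move(self, hand):
        mesh, lms, deps = hand
        # deform only the index finger; all other pair fits are identity
        deform = {
            "Ipip": SegmentSimilarity(angle_deg=15.0, scale=1.1),
            "Idip": SegmentSimilarity(angle_deg=-10.0, scale=1.0),
        }
        target = apply_deformation(lms, deps, deform)
        temp = expand_landmarks(lms, deps, spacing=0.3)
        assign = assign_vertices(mesh, temp, deps, falloff_scale=None, lms=lms)
        out, _ = segmented_procrustes(mesh, lms, target, deps, assign)
        index_cols = [assign.segments.index(s) for s in ("Imcp", "Ipip", "Idip", "Itip")]
        untouched = assign.weights[:, index_cols].sum(axis=1) == 0
        assert untouched.any()
        np.testing.assert_allclose(
            out.vertices[untouched], mesh.vertices[untouched], atol=1e-9
        )
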