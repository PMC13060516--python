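"""Project an annotation from one hand mesh onto another via the sparse
transfer matrix.

A patch annotation on a fine "patient-specific" hand is ported onto a
coarser "generic" hand: both meshes share the 54-landmark scheme, the
source is morphed onto the target's landmarks, and the sparse
(target-vertex x source-vertex) coverage matrix carries the annotation
across.  Target vertices whose summed coverage reaches 1.5 (3 vertices
per face x 50% coverage) become annotated.
"""

import numpy as np

from fieldmorph import SyntheticHandSpec, make_hand, make_patch_field
from fieldmorph.alignment import morph_to_reference
from fieldmorph.mesh import face_areas
from fieldmorph.transfer import build_transfer_matrix, choose_k, project_field

# patient-specific hand: finer mesh, slightly different proportions
patient_spec = SyntheticHandSpec(resolution=2, finger_segment_length=1.08,
                                 palm_width=4.4, thumb_segment_length=1.15)
src_mesh, src_lms, deps = make_hand(patient_spec)
tgt_mesh, tgt_lms, _ = make_hand(SyntheticHandSpec())  # generic hand

# a palmar patch centered on the palm
from fieldmorph.mesh import face_centroids, face_normals

cent = face_centroids(src_mesh)
palm_center = src_lms["palmarCenter"].position
on_palm = np.flatnonzero(
    (face_normals(src_mesh)[:, 2] > 0.9)
    & (np.linalg.norm(cent - palm_center, axis=1) < 0.5)
)
field = make_patch_field(src_mesh, center_face=int(on_palm[0]), radius=1.8,
                         mesh_id="patient")

# bring the patient mesh into the generic frame, then build the matrix.
# require_facing drops back-facing source faces — on a thin slab the
# opposite surface sits within k-NN range and would bleed through.
morphed_src, _ = morph_to_reference(src_mesh, src_lms, tgt_lms, deps)
k = choose_k(morphed_src.n_faces, tgt_mesh.n_faces)
T = build_transfer_matrix(morphed_src, tgt_mesh, k=k, require_facing=True,
                          source_mesh_id="patient", target_mesh_id="generic")
projected = project_field(field, T, morphed_src, tgt_mesh)

src_area = face_areas(morphed_src)[field.face_array()].sum()
tgt_area = face_areas(tgt_mesh)[projected.face_array()].sum()
print(f"source mesh {src_mesh.n_faces} faces, target mesh {tgt_mesh.n_faces} faces, k = {k}")
print(f"annotated: {field.n_faces} source faces ({src_area:.2f} units^2 after morph)")
print(f"projected: {projected.n_faces} target faces ({tgt_area:.2f} units^2)")
print(f"transfer matrix: {T.shape[0]} x {T.shape[1]}, {T.matrix.nnz} nonzeros")
print()
print("The annotation lands at the same anatomical location on the generic")
print("hand.  Its area is dilated at the boundary: any target face at least")
print("half-covered is annotated (the >= 1.5 vertex-sum rule), which adds")
print("about one face ring — a visible cost on a coarse target mesh, and")
print("the reason annotated-area comparisons belong on equal-resolution")
print("meshes while location comparisons transfer freely.")
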