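"""Flatten a 3D annotation into a pixel mask and score it against a 2D one.

A patch annotation is painted on the side of the index finger (where many
faces are oblique — nearly edge-on to the viewer), the mesh is split into
palmar/dorsal aspects and flattened, and the annotation is rasterized.
The Jaccard index against a reference 2D mask and the obliqueness score
quantify how much a flat projection distorts the annotation.
"""

import numpy as np

from fieldmorph import make_hand, make_patch_field
from fieldmorph.flatten import (
    PixelMask,
    flatten_mesh,
    jaccard,
    partition_faces,
    rasterize,
    split_aspect_meshes,
)
from fieldmorph.mesh import face_areas, face_centroids, face_normals
from fieldmorph.flatten import obliqueness

mesh, landmarks, deps = make_hand()

# pick a center face on the radial side of the index finger (normal ~ -x)
normals = face_normals(mesh)
cent = face_centroids(mesh)
index_x = landmarks["Ipip"].position[0] - 0.35
side = np.flatnonzero((normals[:, 0] < -0.9) & (np.abs(cent[:, 0] - index_x) < 0.1)
                      & (cent[:, 1] > landmarks["Imcp"].position[1]))
field = make_patch_field(mesh, center_face=int(side[0]), radius=1.0)

part = partition_faces(mesh)          # depth vector +z (palm toward viewer)
areas = face_areas(mesh)
obl = obliqueness(field, part, areas)

flat = flatten_mesh(mesh)
(palmar, pmap), (dorsal, dmap) = split_aspect_meshes(flat, part)
grid = PixelMask.empty(240, 320, origin=(-4.0, -1.0), pixel_size=0.05)
ann = np.zeros(mesh.n_faces, bool)
ann[field.face_array()] = True
mask3d = rasterize(palmar, np.flatnonzero(ann[pmap]), grid)

# stand-in 2D annotation: the same patch grown by one face ring (as a
# participant might paint a slightly larger region on the flat diagram)
grown = make_patch_field(mesh, center_face=int(side[0]), radius=1.35)
ann2 = np.zeros(mesh.n_faces, bool)
ann2[grown.face_array()] = True
mask2d = rasterize(palmar, np.flatnonzero(ann2[pmap]), grid)

print(f"annotated faces: {field.n_faces}; obliqueness = {obl:.2f}")
print(f"palmar-aspect mask pixels, 3D annotation: {mask3d.count}")
print(f"palmar-aspect mask pixels, 2D stand-in:   {mask2d.count}")
print(f"Jaccard index between the two masks:      {jaccard(mask3d, mask2d):.2f}")
print()
print("A high obliqueness score means most of this annotation sits on faces")
print("60-120 degrees from the viewing axis, so its flattened silhouette is a")
print("thin sliver — exactly the situation where 2D and 3D reports diverge.")
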