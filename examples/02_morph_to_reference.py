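"""Morph the 3D hand onto a deformed 2D reference with segmented Procrustes.

A planar reference landmark set is generated by articulating each digit
segment (random small rotations and length scalings, as between a 3D
model and a drawn illustration).  The morph first runs one unrestricted
whole-hand Procrustes fit plus anchor re-translation, then per-segment
no-reflection similarity fits down the dependency tree.
"""

import numpy as np

from fieldmorph import make_2d_reference, make_hand
from fieldmorph.alignment import initial_align, morph_to_reference


def rms(lms_a, lms_b):
    d = lms_a.positions() - lms_b.positions(lms_a.names)
    return float(np.sqrt((d**2).sum(axis=1).mean()))


mesh, landmarks, deps = make_hand()
reference, deformation = make_2d_reference(landmarks, deps, seed=3)

_, aligned = initial_align(mesh, landmarks, reference)
morphed_mesh, morphed = morph_to_reference(mesh, landmarks, reference, deps)
_, converged = morph_to_reference(mesh, landmarks, reference, deps, n_passes="auto")

print(f"landmark RMS to reference after whole-hand alignment: {rms(aligned, reference):.4f}")
print(f"landmark RMS after one segmented sweep:               {rms(morphed, reference):.4f}")
print(f"landmark RMS after sweeping to convergence:           {rms(converged, reference):.4f}")
print(f"max |z| of morphed mesh vertices: {np.abs(morphed_mesh.vertices[:, 2]).max():.3f}")
print()
print("Each segmented sweep fits one similarity per digit segment; the RMS")
print("drop shows the segments rotating/scaling onto the articulated 2D pose")
print("that a single whole-hand similarity cannot reach.")
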