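# fieldmorph

Geometry for comparing and pooling **projected fields** — body-surface
annotations of sensations evoked by neural-interface stimulation
(intracortical microstimulation, peripheral nerve stimulation) — across
body representations.

When participants report where an electrically evoked sensation is felt,
some report on flat 2D body diagrams and some on 3D meshes, and
patient-specific meshes differ from generic ones.  Putting these reports
in one frame requires geometry:

- **Segmented Procrustes morphing** — warp a 3D mesh and its annotations
  onto a 2D reference illustration (or another 3D mesh) using a
  54-landmark hand scheme and a wrist-rooted segment hierarchy, so each
  digit segment rotates and scales independently while staying attached.
- **Flattening & rasterization** — split faces into palmar/dorsal
  aspects by normal angle to the viewing axis, flatten, and rasterize
  annotations into binary pixel masks comparable with 2D annotation
  maps.
- **Overlap & obliqueness scores** — Jaccard index J = |A∩B| / |A∪B|
  between masks, and the fraction of annotated surface area on *oblique*
  faces (normals 60–120° from the viewing axis — the part any flat
  projection distorts or hides).
- **Cross-mesh transfer** — a sparse (target-vertex × source-vertex)
  proportional-coverage matrix, built per mesh pair via k-nearest-face
  search and planar projection along target normals, ports annotations
  between meshes; target vertices with summed coverage ≥ 1.5 (3 vertices
  per face × 50% coverage) become annotated.
- **Synthetic fixtures** — a deterministic articulated hand mesh with
  the full landmark scheme, deformed 2D references, and patch
  annotations, so the whole pipeline runs without any external asset.

Everything is importable from Python (`import fieldmorph`); a thin
`fieldmorph` command-line tool wraps the pipeline stages
(`generate` / `align` / `flatten-compare` / `transfer`), and the
`examples/` directory holds one short narrative script per capability.

## Worked example

`examples/02_morph_to_reference.py` builds the synthetic hand, generates
an articulated planar reference (per-segment rotations up to ±12°,
length scalings 0.9–1.1), and morphs the hand onto it:

```
landmark RMS to reference after whole-hand alignment: 0.3863
landmark RMS after one segmented sweep:               0.1337
landmark RMS after sweeping to convergence:           0.0478
max |z| of morphed mesh vertices: 0.535
```

The whole-hand similarity fit cannot match an articulated pose (RMS 0.39
model units, about 5% of hand length); one segmented sweep cuts the
landmark misfit to a third, and sweeping to convergence reaches ~0.7% of
hand length.  The residual z extent is the hand's physical thickness,
which no landmark morph should remove — flattening is a separate,
explicit step.

`examples/04_transfer_between_meshes.py` then ports a palm annotation
from a fine patient-specific hand onto a coarse generic hand through the
sparse transfer matrix, and `examples/03_flatten_and_compare.py` shows
an oblique finger-side annotation losing most of its flattened
silhouette — the situation the obliqueness score quantifies.

## Layout

```
src/fieldmorph/      mesh.py        meshes, landmarks, I/O, mirroring
                     annotation.py  projected-field data model
                     alignment.py   Procrustes, hierarchy, segmented morph
                     flatten.py     aspects, rasterization, Jaccard, obliqueness
                     transfer.py    sparse cross-mesh annotation transfer
                     synthetic.py   deterministic test-scale generators
                     hand.py        canonical 54-landmark scheme
                     cli.py         command-line interface
docs/methods.md      models, parameters, conventions, limitations
examples/            one narrative script per capability
tests/               pytest suite
```
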