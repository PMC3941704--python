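# connexel

Batch-computable building blocks for visualizing dense brain-connectivity
data as **connexels** — connections between two 3D positions plus a
strength, i.e. single points in the 6D pair-of-positions space. The package
is aimed at researchers who want to turn surface-based functional
connectivity matrices into renderable geometry (bundled edge curves, glyph
primitives) from scripts and pipelines rather than a GUI.

It provides:

* **Data model** (`connexel.model`) — connexel sets, multi-representation
  cortical surface sets (pial / inflated / sphere over shared node
  indexing), square symmetric connectivity matrices, thresholding by
  minimum value and minimum endpoint distance, seed-based connectivity
  maps, Pearson matrices from node timeseries, nearest-neighbour 4D-volume
  sampling to surface nodes, Fisher r-to-z group averaging
  (`r̄ = tanh(mean(atanh r))`), and per-connexel covariate correlation
  across subjects.
* **File formats** (`connexel.io`) — seven-column `.cxls` connexel text
  files, FreeSurfer ASCII surfaces (`.asc`), legacy VTK POLYDATA line sets
  (`.vtk` / tractography-style `.fib`, ASCII and big-endian binary), raw
  float32 connectivity matrices, and `.glyphset`/`.set` descriptor bundles.
* **Mean-shift edge bundling** (`connexel.bundling`) — pairwise edge
  compatibilities after Holten & van Wijk
  (`Ce = Ca·Cs·Cp·Cv`, each in [0, 1]: angle, scale, position, visibility),
  and a subdivision schedule in which cycle *c* of 10 resamples each edge to
  `ceil(1.3^c)` segments and runs `10 − c` Gaussian mean-shift iterations
  (bandwidth r = 5 mm, compatibility threshold c_thr = 0.8) that move each
  interior point to the kernel-weighted mean of all interior points of
  compatible edges. Endpoints stay fixed; because the kernel mean
  normalizes by local density, sparse and dense bundles contract evenly.
* **Connectivity glyphs** (`connexel.glyphs`) — point glyphs
  `g = p_g + s·(q_d − p_d)`, vector glyphs, hue- or value-sorted pie-chart
  glyphs with radius `r = i·r_n + (1 − i)·r_a`, and difference glyphs (one
  per unique mesh edge, showing `|atanh(r_ak) − atanh(r_bk)|` profiles),
  with orientation coloring (|unit connection vector| → RGB) or colormap
  value coloring plus linear alpha ramps.
* **Synthetic fixtures** (`connexel.synthetic`) — icosphere surface sets,
  modular connectivity matrices, parallel bundle fixtures and subject
  groups with known covariate effects; everything the test-suite and the
  examples need is generated, no dataset downloads.
* **CLI** (`connexel`) — `threshold`, `bundle`, `glyphs`, `matrix`,
  `convert`, `simulate` subcommands over the same library calls.

## Worked example

Simulate a glyphset, threshold its matrix into connexels, and bundle them:

```sh
$ connexel simulate --seed 5 --level 1 --out-dir demo
wrote glyphset (42 nodes) and 110 bundle connexels to demo

$ connexel threshold -i demo/synthetic.glyphset -o demo/strong.cxls --min-value 0.5
INFO threshold parameters: input=demo/synthetic.glyphset min_length=0.0 min_value=0.5 output=demo/strong.cxls two_sided=False
210 connexels survive

$ connexel bundle -i demo/bundles.cxls -o demo/bundled.vtk
INFO bundle parameters: c_thr=0.8 input=demo/bundles.cxls kernel_radius_mm=5.0 min_length=0.0 min_value=-inf mode=ascii n_cycles=10 output=demo/bundled.vtk
bundled 110 connexels
```

`demo/strong.cxls` holds one `px py pz qx qy qz c` line per connexel whose
correlation exceeds 0.5 (210 of the 861 node pairs on the 42-node demo
surface). `demo/bundled.vtk` contains 110 polylines whose interior points
have been drawn together into two bundles (the input holds a sparse
10-edge and a dense 100-edge bundle); endpoints are untouched, so the
curves still connect the original termination points. The same three steps
as library calls:

```python
from connexel import (read_glyphset, matrix_to_connexels, ThresholdSpec,
                      bundle, BundlingParams)

surfaces, matrix, load_thr = read_glyphset("demo/synthetic.glyphset")
cset = matrix_to_connexels(matrix, surfaces.surfaces[0],
                           ThresholdSpec(min_value=0.5))
lines = bundle(cset, BundlingParams())   # c_thr=0.8, r=5 mm, 10 cycles
```

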