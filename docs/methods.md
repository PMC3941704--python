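# Methods

## The data model

A connexel is a pair of termination points *P*, *Q* in a common anatomical
millimetre space together with a connectivity value *c* — one point in the
6D space of position pairs. Dense surface connectivity is carried either as
an N×N symmetric matrix over the nodes of a cortical surface, or as an
explicit connexel list. A surface comes in multiple corresponding
representations (pial, inflated, spherical) over identical node and face
indexing, each with an additive translation offset (used, e.g., to separate
two hemispheres whose inflated representations would overlap). Surfaces and
connexels are assumed pre-aligned; affine transforms are honoured only when
sampling a 4D volume to surface nodes, never for display alignment.

Thresholding follows a two-stage strategy: a low load-time minimum keeps
the data volume manageable, and subsequent filtering by minimum value and
minimum endpoint distance carves out structure. Which surface
representation supplies coordinates for the distance test is genuinely
ambiguous (folded and inflated geometries give different lengths), so it is
an explicit parameter defaulting to the display surface (the first of the
set). Thresholds compare the signed value by default; a two-sided mode
compares |value| for matrices mixing positive and negative correlations.

Group statistics: correlation matrices are averaged through Fisher's
transform, `tanh(mean(atanh r))`, with |r| clamped at 1 − 1e−7 so the
transform stays finite; per-connexel covariate correlations (e.g. against
age) are plain Pearson correlations across subjects of each matrix entry.
Degenerate correlations (zero variance) are stored as 0 and reported in a
flag list rather than NaN, so downstream thresholding is total.

## File formats

The `.cxls` format is seven whitespace-separated numbers per line
(`px py pz qx qy qz c`); any other field count is a hard error naming the
line. FreeSurfer ASCII surfaces use the `N M` header plus `x y z v` /
`i j k v` body, with header/body count mismatches rejected. Legacy VTK
POLYDATA carries both two-point lines (connexels; a scalar array named
`connectivity`/`value(s)`/`scalars` supplies weights, else 1 for binarized
graphs) and longer polylines (bundling output); binary VTK is big-endian
float32/int32 per the legacy standard, and writing defaults to ASCII for
diffability.

Two dialects are this package's own declared conventions, documented
because third-party files may differ:

* binary matrices are headerless float32, little-endian, row-major; a file
  whose asymmetry exceeds 1e−4 is symmetrized with a warning;
* a `.glyphset` is three meaningful lines (set-file path, matrix path,
  load-time threshold, `#` comments ignored), and a set file lists one
  surface path per line optionally followed by a three-number offset.

## Mean-shift edge bundling

Compatibility between two straight edges is the product of four measures
in [0, 1] (angle, scale, position, visibility — the Holten–van-Wijk
criteria). The scale term is implemented as
`Cs = 2 / (lavg/lmin + lmax/lavg)` with `lavg = (|P|+|Q|)/2`, the only
form of the published criterion that reaches 1 exactly for equal lengths
and stays in (0, 1]. Visibility projects the other edge's endpoints onto
this edge's supporting line (I₀, I₁) and measures how far their midpoint
sits from the edge midpoint relative to the projected span, taking the
minimum over both directions. Zero-length edges are incompatible with
everything (Ce = 0) and pass through unbundled.

The schedule runs cycles c = 1…10. Each cycle resamples every polyline to
`ceil(1.3^c)` equal arc-length segments (floored at 2 so the first cycle
already has an interior point to move) and then performs `10 − c`
mean-shift iterations; the last cycle only refines the sampling. An
iteration moves every interior point x of edge e to the Gaussian-weighted
mean `Σ wᵢxᵢ / Σ wᵢ`, `wᵢ = exp(−‖x − xᵢ‖²/(2r²))`, over all interior
points of all edges f with `Ce(e, f) ≥ c_thr` (including e's own points);
endpoints never move, and all shifts in an iteration are computed from the
same snapshot, which makes the procedure deterministic and
order-independent. Defaults are `c_thr = 0.8`, `r = 5 mm`, 10 cycles.

Numerical choices worth knowing:

* Compatibilities are computed once from the original straight edges and
  reused in every cycle; memory is O(E²) (hence a warning above 40,000
  edges, the reference desktop limit for this family of algorithms).
* The Gaussian kernel uses bandwidth σ = r with a hard support cutoff at
  3r by default for efficiency; `neighborhood_cutoff=None` gives exact
  infinite support. With the cutoff at or beyond the domain diameter the
  result matches a loop-based all-pairs reference to well below 1e−6
  (verified in the tests).
* Because the kernel is isotropic and compatibilities are
  rigid-motion-invariant, bundling commutes with rigid motions of the
  input to floating-point accuracy.
* A single straight edge is a fixed point as a curve: its interior points
  can only slide along the segment (the weighted mean of collinear points
  is collinear), and the arc-length resampling of the next cycle restores
  even spacing.

## Glyph geometry

Per-node glyphs summarize one node's above-threshold connections. The
point glyph places, for each connection, `g = p_g + s·(q_d − p_d)`: the
node's position in the placement representation plus the scaled offset
toward the connected node measured in the geometry representation. The
offset convention is deliberately "toward the connected node" — the
natural reading of a glyph that miniaturizes the connectivity pattern
around its node. Placement, geometry and color representations are
independent, so a pial-shaped glyph can sit on the inflated surface and be
colored by spherical orientation. Offsets can be rotated by three Euler
angles (intrinsic x-then-y-then-z) about the glyph center to reveal
connections on the far side. Vector glyphs connect the node position to
each point-glyph position.

Pie glyphs allocate one 2π/n sector per connection in the plane orthogonal
to a caller-supplied view direction (the geometric stand-in for
screen-facing billboards in a renderer), sorted by the hue of the
orientation color or by value, ties broken by target node index. The
radius interpolates, `r = i·r_n + (1 − i)·r_a`, between a constant `r_n`
and `r_a = r_max·sqrt(n/n_ref)`; the square root makes every connection
cover an equal area, which is the stated motivation for a count-dependent
radius (a strictly linear radius would grow the area quadratically).
`n_ref` is the largest connection count in the dataset at hand — a dialect
choice, since no canonical normalizer exists. Each pie primitive carries a
z-order hint equal to its radius so renderers can draw small pies on top.

Difference glyphs exploit mesh neighbourhood structure: one glyph per
unique undirected triangle edge (shared sides deduplicated), at the edge
midpoint, showing `d_k = |atanh(r_ak) − atanh(r_bk)|` over target nodes k
after value/length thresholding — a Fisher-space profile difference that
is symmetric in (a, b), non-negative and zero for identical rows.

Orientation color is the DTI convention: absolute components of the
normalized connection vector as RGB, symmetric under edge reversal. Value
color is a piecewise-linear colormap lookup with clamping; the default map
is an isoluminant green-to-red opponent scale. Transparency can encode
value via a clamped linear ramp between two reference values.

## Synthetic study conditions

The generators emulate the shape of a surface-based resting-state
connectivity study at desk scale:

* **Surfaces** — a level-2 icosphere (162 nodes, 320 faces; level k has
  10·4^k + 2 vertices) at radius 50 mm plays the role of a decimated
  hemisphere. The pial-like representation modulates the radius by ±~10%
  with fixed low-order spherical-harmonic-style terms; the inflated-like
  one uses the same pattern at one-third amplitude. Real cortical meshes
  have ~10k nodes per hemisphere and far richer folding; node count here
  is chosen so full matrices and all-pairs compatibilities stay trivial.
* **Connectivity** — four spatially contiguous longitude-sector modules;
  node timeseries are module latents (sharing a common component sized to
  give between-module r ≈ 0.05) mixed at √0.7 against node noise, plus
  measurement noise of SD 0.1, over 300 timepoints. This produces the
  within ≫ between modular structure the glyph and thresholding tests
  need, but none of fMRI's autocorrelation, motion or physiological
  structure — passing tests says the computations are right, not that the
  noise model is realistic.
* **Bundles** — a sparse (10-edge) and a dense (100-edge) bundle of 40 mm
  parallel edges, endpoints jittered within 0.8 mm discs, axes 60 mm
  apart. The jitter keeps within-bundle compatibility above 0.9 while the
  separation keeps cross-bundle compatibility below 0.4, so the default
  threshold 0.8 separates them cleanly; both bundles' midpoint spreads
  contract by >95% under the default schedule, demonstrating
  density-independent contraction.
* **Group data** — 65 subjects with an age-like covariate spanning 11–83
  years; one tenth of the connexels of a 30-node matrix increase linearly
  with the covariate (swing 0.4 over the span), another tenth decrease,
  the rest are constant, all plus per-subject noise (SD 0.1). At zero
  noise the covariate correlation recovers ±1 exactly; at noise 0.1 the
  labeled connexels separate essentially completely from the unlabeled
  background (≥90% above its 95th percentile).

A single integer seed governs all randomness; identical seed and
parameters give bit-identical outputs everywhere, including the CLI.

## Known limitations

* Bundling stores the full E×E compatibility matrix; beyond a few tens of
  thousands of edges this dominates memory.
* The binary matrix and glyphset dialects are declared conventions, not a
  reverse-engineered wire format; interoperability with files produced by
  other tools may need conversion.
* Weighted-graph bundling (using connexel values as masses) is out of
  scope; bundling operates on the binarized geometry and carries values
  through unchanged.
* Statistical inference on thresholds (random-field, network-based or
  cluster statistics) is intentionally absent; thresholds here are
  exploratory display parameters.
* Volume-to-surface sampling is nearest-neighbour only.
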