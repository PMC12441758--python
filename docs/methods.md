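# Methods

## Overview

`clusterscape` turns gene-level differential-expression tables (or any
pre-computed 2-D/3-D embedding) into two kinds of 3-D visualization:

1. **HTML pathway** — a single self-contained HTML file rendering the final
   embedding as an orbitable sphere cloud with cluster colors, hover
   metadata and per-point hyperlinks.
2. **Blender pathway** — a bundle of plain-text scripts for Blender's
   scripting window that generate one sphere object per point, keyframe
   each captured optimization snapshot, and set up an HDRI-lit scene, so
   the embedding's convergence can be rendered as an animation.

Both pathways share one analytic core: significance filtering, a
snapshot-capturing 3-D t-SNE, and deterministic DBSCAN.

## Significance filtering

An entry of the gene × condition log2 fold-change matrix is retained iff
|log2FC| > 1 **strictly** and p < 0.05 **strictly** (both cut-offs
configurable); every other entry is set to zero, and genes with all-zero
rows are dropped. Boundary values (log2FC exactly ±1, p exactly 0.05) are
excluded. A measured fold-change with a missing p-value is an error rather
than silently significant or ignored; a missing fold-change is simply not
significant. Filtering is idempotent: re-filtering a filtered matrix
returns it unchanged.

## t-SNE with trajectory capture

The embedder is an exact-gradient t-SNE (full n² affinity and repulsion
matrices). Defaults mirror the Rtsne R package: perplexity 30, 1000
iterations, early exaggeration 12 ending at iteration 250, momentum 0.5
switching to 0.8 at iteration 250, adaptive per-coordinate gains. The
learning rate (eta) defaults to 2000. The input-size precondition is
n ≥ 3·perplexity + 2.

Snapshots of the layout are recorded at iteration 0, every
`snapshot_every` iterations (default 50), and at the final iteration
(deduplicated when the cadence lands on it), so for a cadence that does
not divide `n_iter` the count is ⌊n_iter / snapshot_every⌋ + 2. The exact
gradient — rather than a Barnes-Hut approximation — was chosen because it
keeps trajectories bit-reproducible under a fixed seed and is entirely
adequate at the few-hundred-to-few-thousand-gene scale of filtered
differential-expression matrices; cost grows quadratically, so clouds
beyond ~5,000 points are better embedded externally and loaded as
coordinate files.

### Embedding scale normalization

t-SNE coordinates have no units, and their span grows with the learning
rate and the separability of the data: at eta = 2000 a strongly modular
synthetic matrix embeds into a range of several hundred units (sklearn's
exact t-SNE shows the same behavior, to several thousand). The clustering
and display defaults, however, assume the conventional working range of
roughly [-20, 20]. The pipeline therefore rescales embeddings **it
computes** so the final snapshot spans `tsne.target_span` (default 20),
applying one factor to every snapshot so relative motion in the animation
is preserved. Scaling is an exact similarity transform — cluster structure
is untouched provided eps is interpreted in the normalized units.
User-supplied coordinate files are never rescaled (set
`tsne.target_span = 0` to disable the step entirely).

## DBSCAN

Classical semantics: a core point has ≥ `min_pts` neighbors within `eps`
(itself included, closed ball); clusters are connected components of core
points plus reachable border points; the rest is noise (label −1).
Defaults eps = 2, min_pts = 10, meaningful in the normalized ±20
embedding range.

DBSCAN's two classical order ambiguities are fixed deterministically:

* a border point reachable from several clusters joins the cluster whose
  formation starts earliest under an ascending-id scan (equivalently, the
  cluster whose lexicographically smallest core id is smallest);
* final labels 0..k−1 are assigned by decreasing cluster size, ties broken
  by the lexicographically smallest member id.

The result is invariant under permutation of the input rows, which
off-the-shelf implementations do not guarantee for border points.
Neighborhoods come from scikit-learn's `NearestNeighbors`; the expansion
and tie-breaking are implemented here. The test suite checks the
implementation against an independent brute-force O(n²) oracle and
cross-checks core-point partitions against scikit-learn's DBSCAN.

## Geometry utilities

* `lift_to_3d` adds z = 0 to 2-D coordinates (3-D input is an error, never
  silently overwritten).
* `scale_coordinates` multiplies by a positive factor (the conventional
  "spread by 3" to open space between rendered spheres). The operation is
  one rounding per coordinate; when *measuring* the effect through a
  distance matrix the comparison tolerance must be absolute in the cloud
  radius (≈16 eps · factor · radius), because for near-coincident points
  the rounding of the scaled coordinates dominates the tiny distance.
* `convert_coordinates` centralizes the axis conventions: the Blender
  backend keeps (x, y, z) with z up; the HTML backend gets (x, z, −y) so
  the viewer's vertical (y-up) matches the embedding's z axis. Both maps
  are invertible isometries.

## HTML backend

The scene is one JSON record per point (id, position, cluster, color,
radius, hover fields, hyperlink) embedded in a single `<script
type="application/json">` block, so the document is a self-contained,
shareable file. Exactly two external scripts are referenced, pinned on
jsDelivr (`three@0.110.0` and the matching standalone
`three-orbitcontrols@2.110.3`); an offline mode rewrites those references
to local filenames beside the document for archival use. Cluster colors
come from a 17-color palette (cluster i → palette[i mod 17]); noise points
get a fixed grey.

Level of detail is the sphere segment pair — the last two arguments of the
`sphereGeometry` constructor. The default (32, 32) can be halved to
(16, 16) for large clouds with near-invisible quality loss; rendering is a
pure function, and switching segments changes exactly those two numerals
in the output. Optional view-frustum culling (off by default) toggles only
a rendering code path, never the embedded data. Occlusion is addressed via
a global opacity option and the factor-3 coordinate spread, not automatic
jittering.

`validate_html` re-checks a rendered document structurally: well-formed
markup, embedded record count vs the declared point count, each dependency
referenced exactly once, no unresolved template placeholders.

## Blender backend

Scripts target Blender 4.1-era `bpy` interfaces and are emitted as plain
text; nothing in this package (or its tests) ever executes Blender.
Object generation is batched (default 5,000 spheres per batch, the point
where single script runs become slow) and clouds above 50,000 points are
joined into one object per batch to reduce scene strain — at the
documented cost of per-point animation, which the script warns about.
Object names derive deterministically from point ids (`pt_` + sanitized
id); sanitization collisions are a hard error.

Snapshot s lands on frame s × `frames_per_iteration` (default 10 — the
source never dictates animation timing; Blender's default linear
interpolation fills the gaps). Every keyframe script carries its data as
one literal Python list, which makes the bundle statically verifiable: the
portable keyframe table (id, frame, x, y, z) can be reproduced exactly by
parsing the scripts with the `ast` module, without execution. Keyframe
deletion scripts refuse an empty id list (a silent scene-wide wipe would
be too easy) and embed a warning that deletion is slower than creation and
can stall Blender on large selections.

Scene setup references a single HDRI image path for the world background
(a small synthetic gridded placeholder can be generated for tests and
previews — it is a PNG stand-in, not a real radiance file), positions a
camera tracking the origin, optionally keyframes a quarter-turn camera
orbit, and sets the frame range to cover the last keyframe.

## Synthetic data

All inputs are generated, seeded and in memory:

* `make_blobs3d` — k Gaussian blobs at uniform centers (spread 15, sd 0.5
  by default, coordinates roughly in [−20, 20] so the clustering defaults
  are meaningful) plus optional uniform noise, with truth labels.
* `make_gene_table` — a background of small or non-significant entries
  (including ~5 % large-but-insignificant fold-changes to keep the filter
  honest) with an exact planted number of significant genes. With
  `n_modules > 0` the significant genes share per-module sign patterns
  with lognormal magnitude spread, emulating co-regulated transcriptional
  modules — the structure that makes an embedding condense into clusters.
  Independently random significant genes (the default) carry no such
  structure.
* `make_trajectory` — a simulated convergence path: seeded random start,
  linear interpolation toward the exact final cloud with decaying Gaussian
  jitter. This stands in for captured t-SNE iterations so animation code
  is testable in milliseconds; it shares the trajectory type with real
  captured runs but does not reproduce t-SNE's actual dynamics (early
  exaggeration expansion, cluster merging), so tests passing on it say
  nothing about embedding quality — those properties are tested on the
  real embedder.

What the generators do **not** emulate: real datasets' biological
correlation structure, heavy-tailed p-value distributions, batch effects,
or the size of published single-cell compendia. Passing tests demonstrate
the mechanics of filtering, embedding, clustering and rendering, not
biological validity on any particular dataset.

## Numerical and design choices

* CSV is RFC 4180, UTF-8, header mandatory; empty cells and `NA` read as
  missing; writers emit empty cells and `%.17g` floats. Numeric parsing
  goes through correctly-rounded `float()` so write→read round-trips are
  bit-exact (pandas' fast parser is not correctly rounded).
* Duplicate ids are a hard error everywhere — gene identity is the join
  key for metadata and labels.
* Same seed ⇒ byte-identical artifacts end-to-end (the run manifest lists
  a SHA-256 per artifact, which doubles as the determinism check).
* Degenerate inputs: an empty gene table filters to an empty matrix; an
  empty point cloud writes a header-only CSV; an all-noise labeling
  renders with every point in the noise color.

## Problem sizes used in tests

The suite exercises the embedder at 120–240 points in 50 or fewer input
dimensions and 500–1000 iterations, DBSCAN/oracle comparisons at up to
~2,000 points, and the renderers at 1,000–12,198 points — sizes chosen so
the full suite runs in seconds while still crossing every batching and
cadence boundary the code distinguishes.

## Known limitations

* The exact-gradient embedder is O(n²) per iteration; tens of thousands of
  points should be embedded externally (e.g. a UMAP/t-SNE run elsewhere)
  and loaded as coordinates.
* The HTML viewer draws one mesh per point; far beyond ~50,000 points
  browsers will lag even at (16, 16) segments (instancing is not used, to
  keep the template close to the original sphere-per-point design).
* Blender scripts are validated statically (syntax and keyframe replay),
  not by running Blender.
* The emitted camera path and material defaults are this package's own
  choices, not canonical reproductions of any reference scene file.
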