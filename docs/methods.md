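# Methods

## Scope and model

`wingasym` quantifies bilateral asymmetry between two wing images of one
individual without landmarks. The unit of comparison is the membrane cell:
a connected light region enclosed by dark veins. The analysis assumes the
two images share dimensions and resolution, that veins binarize dark and
membranes light, and that size differences between the wings are signal —
hence superimposition is rigid (translation + rotation) and never scales.

## Binarization and orientation

Intensities are normalized to [0, 1] (RGB collapsed to luminance with the
BT.601 weights 0.299/0.587/0.114). A pixel is membrane iff its intensity is
*strictly greater* than the threshold (default 0.54). The strict comparison
makes a pixel exactly at the threshold a vein pixel, erring toward a
connected vein network — the safer failure mode, since a broken vein merges
two cells while an overgrown vein only thins them. The left wing is
mirrored (column reversal) so both wings share chirality; mirroring is an
involution and conserves pixel counts.

## Segmentation

Foreground (membrane) uses 8-connectivity; the vein/background phase is
implicitly 4-connected — the standard dual pairing that avoids topological
paradoxes. Components touching the image border are background; remaining
components of at least `min_cell_area` pixels (default 8, to suppress
noise speckle) become cells, numbered in row-major discovery order so ids
are deterministic. Region growing records, while flooding, every dark pixel
8-adjacent to the region as its boundary.

Per-cell metrics:

* **area** — interior pixel count (× scale²);
* **length** — maximum pairwise distance between boundary pixels, computed
  via convex hull + pairwise scan over hull vertices; degenerate
  (single-pixel or collinear) regions use max(1 px, diameter) so width
  stays finite;
* **width** — area / length (exact by construction);
* **perimeter** — length of the Moore-traced closed contour of the cell
  interior, counting 1 per axial and √2 per diagonal step;
* **circularity** — 4π·area / perimeter². On coarse digital shapes this
  may exceed 1 (e.g. a 3×3 block); values are recorded as computed.

The perimeter estimator matters: circularity is calibrated to it. On a
digital disk of radius 30 the traced perimeter overestimates 2πr by ~5 %,
giving C ≈ 0.91 (area within 0.3 % of πr²); a 50-px square gives C ≈ 0.82
against the continuous π/4 ≈ 0.785 because the trace runs through pixel
centers, shortening each side by one pixel. These discretization bands are
asserted in the tests.

The wing silhouette is the complement of the border-touching background —
cells and veins filled solid; an interior light region is a cell, not a
hole. Its external boundary, Moore-traced, is the outline; silhouette pixel
count, outline diameter, their ratio, and trace length give wing area,
length, width and perimeter. If several disjoint silhouettes exist the
largest is kept with a warning; an image that is all background yields an
empty geometry with a warning.

## Skeleton and junctions

The vein phase is thinned to a 1-px skeleton (two-subiteration
morphological thinning, topology-preserving). A skeleton pixel is a raw
junction pixel when it has ≥ 3 skeleton neighbors *and* crossing number ≥ 3
(0→1 transitions around the 8-neighborhood cycle) — i.e. at least three
distinct branches leave it. The rule is checked exhaustively against a
branch-run-counting oracle over all 256 neighborhood patterns. Raw junction
pixels are merged by 8-connected clustering (thinning an X-crossing often
yields two nearby 3-way pixels) and reported at cluster centroids, sorted
by (row, col).

Free-ended skeleton branches shorter than 5 px are pruned first: each pass
deletes pixels whose on-neighbors form at most one contiguous run
(crossing number ≤ 1). This endpoint definition also removes the final spur
pixel resting diagonally against a line, which has three neighbors but only
one incident branch and would otherwise leave a false junction.

## Superimposition

The moving wing is rotated about its outline centroid and translated; the
centroid pivot decouples θ from (x, y). Outlines are resampled to N = 200
points at equal arc length; the alignment objective is the mean distance
from each moving point to its nearest reference point (one-directional
inside the optimizer for speed; the symmetric average of both directions is
the reported outline-distance metric). The optimizer is global-best PSO
over (x, y, θ) with 30 particles, 40 iterations, inertia w = 1.0 multiplied
by 0.95 per iteration, cognitive and social coefficients 1.2, velocities
initialized to zero, positions uniform within bounds centered on the
centroid-aligning translation (± W/4 px in x and y, ± 30° in θ, W = image
width), positions clamped to bounds. With a fixed seed the run is
bit-reproducible, and the best-objective history is non-increasing by
construction. On synthetic wings, rigid offsets up to 15 px / 10° are
recovered to ≪ 1° and sub-pixel outline residual in 20 of 20 seeds.

Because the recovered (x, y) is coupled to θ through the pivot, recovery
accuracy is measured as the mean outline residual after applying the
recovered transform, plus the direct θ comparison.

## Matching and asymmetry metrics

Each reference cell is matched to the target cell with the nearest centroid;
the match is run twice, once per reference direction, so extra cells on
either side (segmentation differences, wing damage) are still covered. A
target cell may be the nearest match of several reference cells; no
injective assignment is forced. Junctions are matched the same way.

Per metric (area, length, width, circularity) and direction: OLS regression
of target on reference (slope, intercept, r²) and NRMSE — RMSE of
(target − reference) normalized by the reference range (max − min), which
is scale-free and comparable across the four metrics. The headline
"regression" value is r²; slope and intercept are always emitted alongside
so either reading is available. Distance statistics pool both matching
directions and report arithmetic mean and *population* SD (a descriptive
summary, not an inferential estimate) for centroid, junction and symmetric
outline distances, in scaled units. Count/size deltas are signed
wing1 − wing2 differences; they use the untransformed geometries since
rigid motion leaves them unchanged. No significance testing is provided by
design; the tables are meant for downstream statistical software.

Cell sets (≤ 5 per wing, ≥ 3 cells each, disjoint, possibly not covering
all cells) are defined per wing by explicit ids or by polygons capturing
centroids, and correspond across wings by index. Per-set evaluation reuses
the whole-pair machinery restricted to the set's cells, so the set
containing all cells reproduces the whole-wing numbers exactly.

## Synthetic wings

The generator emulates the measurement contract, not wing biology: a
Voronoi tessellation (seed points inside an elliptical, tapered blade,
3 Lloyd relaxation iterations) gives convex polygonal cells with exact
areas, centroids and vein-graph vertices; cell edges and the blade outline
are rasterized as dark strokes. Defaults: 480×720 px, 20 cells, 3-px
veins — a desk-scale stand-in for a scanned wing (real scans have 10–500
cells and veins a few pixels wide). Output is bit-identical per seed.

Left-wing perturbations: global area scaling by √factor about the blade
centroid (per-cell independent scaling cannot preserve a shared-edge
tessellation); vertex jitter applied once per shared vertex so neighboring
cells deform together; a rigid offset applied before mirroring, so the
recorded transform is what the pipeline should undo; pixelwise
salt-and-pepper (half salt, half pepper) before binarization; Gaussian blur
of given sigma. Because mirroring maps column j to (w−1)−j exactly, a
mirror-only pair re-binarizes pixel-identically and evaluates as perfectly
symmetric — the rasterization band only appears once rotation resamples the
strokes.

**Recoverable noise envelope.** Salt pixels can bridge a vein and merge two
cells when the vein is thin relative to the noise: at 3-px veins, 0.5 %
salt-and-pepper occasionally forms 2-px salt bridges (expected ≈ 17
adjacent salt pairs on a 480×720 image), and one merged cell collapses the
area regression. At 4-px veins and 0.5 % noise the read-out is stable (all
regression shifts < 0.05 across seeds). The artifact-robustness experiment
therefore uses 4-px veins, emulating a 300-DPI scan where veins span
several pixels; the min-area filter handles isolated pepper speckle at all
widths.

What passing tests on these wings do *not* show: robustness to uneven
illumination, transparent or low-contrast veins, anti-aliased vein edges,
pigmentation, or torn margins — real-scan failure modes the generator does
not model.

## Numerical choices

* Coordinates are (row, col), 0-based, origin top-left; centroids are
  arithmetic means.
* θ is in radians, counterclockwise in the (x = col, y = row) frame.
* Matching ties (equidistant targets) resolve to the KD-tree's first hit;
  tests compare distances, not tie identities.
* Report floats are serialized with 12 significant digits so the written
  CSVs parse back to the in-memory result within 1e-9 relative error;
  two runs with identical inputs and seed produce byte-identical reports.
* Problem sizes in the tests and acceptance script (20-cell wings, 100
  oracle masks, 20 PSO seeds) are chosen as the smallest sizes at which the
  checked properties are non-trivial while the whole suite stays fast.

## Known limitations

* Cell length is the boundary-pixel diameter, measured on the vein-side
  boundary as defined — about 1 px larger than the interior diameter, and
  the diagonal for rectangular cells, making width = area/length a crude
  axis estimate (ellipse fitting would refine both).
* Circularity carries no orientation/anisotropy information.
* No vein-gap repair or interactive cleanup: broken veins merge cells and
  the pipeline reports the merged geometry.
* Junction detection degrades gracefully but not perfectly near the wing
  margin, where outline strokes meet vein strokes at shallow angles.
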