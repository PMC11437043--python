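"""Region-growing segmentation of wing cells and outline morphometrics.

A binarized wing partitions its pixels into three classes: light background
(the foreground component touching the image border), dark veins, and the
membrane cells — interior foreground components enclosed by veins.  Each cell
is measured by

* area — number of interior pixels (times scale squared),
* length — maximum pairwise Euclidean distance between its boundary (vein)
  pixels,
* width — area / length,
* circularity — 4*pi*area / perimeter**2, where the perimeter is the length of
  the traced 8-connected contour of the cell interior (axial steps count 1,
  diagonal steps sqrt(2)).

Foreground regions are 8-connected; the dual 4-connectivity is implicit in the
vein phase.  Coordinates are (row, col), 0-based, origin at the top-left.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .errors import ValidationError
from .io import BinaryWingImage

#: Cells smaller than this many pixels are treated as speckle and dropped.
DEFAULT_MIN_CELL_AREA = 8

_EIGHT = np.ones((3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def max_pairwise_distance(points: np.ndarray) -> float:
    """Diameter of a point set: the largest pairwise Euclidean distance.

    Uses the convex hull to reduce the candidate set (the diameter is attained
    between hull vertices) and checks all hull-vertex pairs.  Degenerate
    (collinear or tiny) inputs fall back to a direct pairwise scan.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) == 0:
        return 0.0
    if len(pts) < 2:
        return 0.0
    cand = pts
    if len(pts) > 8:
        try:
            cand = pts[ConvexHull(pts).vertices]
        except QhullError:
            # collinear input: extremes along the principal direction suffice,
            # but a pairwise scan over the (small) unique set is simplest
            cand = np.unique(pts, axis=0)
    d2 = np.sum((cand[:, None, :] - cand[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


#: Moore neighborhood in clockwise order starting from the west neighbor.
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Trace the external boundary of a connected region as an ordered closed
    polyline of pixel coordinates (Moore-neighbor tracing).

    Returns an (n, 2) int array of (row, col) boundary pixels in traversal
    order; the polyline is implicitly closed (last connects back to first).
    A single-pixel region yields one point.
    """
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)
    if len(coords) == 0:
        raise ValidationError("cannot trace an empty region")
    # uppermost-leftmost pixel; its west neighbor is guaranteed background
    start = tuple(coords[np.lexsort((coords[:, 1], coords[:, 0]))][0])
    if len(coords) == 1:
        return np.array([start])

    h, w = mask.shape

    def is_on(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    # The trace is a deterministic walk on (pixel, backtrack-direction)
    # states; the external boundary is the cycle through the start state, so
    # we walk until a state repeats.  A pixel may legitimately appear twice
    # (both sides of a one-pixel-wide protrusion).
    path: list[tuple[int, int]] = []
    seen: set[tuple[tuple[int, int], int]] = set()
    cur, back = start, 0  # backtrack initially points west
    while (cur, back) not in seen:
        seen.add((cur, back))
        path.append(cur)
        for k in range(1, 9):
            idx = (back + k) % 8
            nr, nc = cur[0] + _MOORE[idx][0], cur[1] + _MOORE[idx][1]
            if is_on(nr, nc):
                # next backtrack: the off-pixel examined just before this one
                pr = cur[0] + _MOORE[(idx - 1) % 8][0]
                pc = cur[1] + _MOORE[(idx - 1) % 8][1]
                back = _MOORE.index((pr - nr, pc - nc))
                cur = (nr, nc)
                break
        else:  # isolated pixel (no neighbors) — handled above, safety only
            break
    return np.array(path)


def polyline_length(path: np.ndarray, closed: bool = True) -> float:
    """Sum of step lengths along a pixel polyline (1 axial, sqrt(2) diagonal)."""
    path = np.asarray(path, dtype=float)
    if len(path) < 2:
        return 0.0
    pts = np.vstack([path, path[:1]]) if closed else path
    steps = np.diff(pts, axis=0)
    return float(np.sqrt((steps ** 2).sum(axis=1)).sum())


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CellRegion:
    """One membrane cell: its pixels and morphometrics.

    ``interior_pixels`` are the 8-connected foreground pixels of the cell;
    ``boundary_pixels`` are the vein (dark) pixels 8-adjacent to the interior.
    Metrics are in scaled units when a scale is attached, else pixels.
    """

    cell_id: int
    interior_pixels: np.ndarray  # (n, 2) int
    boundary_pixels: np.ndarray  # (m, 2) int
    centroid: tuple[float, float]
    area: float
    length: float
    width: float
    circularity: float
    perimeter: float


@dataclass
class WingGeometry:
    """Segmented wing: cells, outline, junctions and whole-wing metrics."""

    cells: list[CellRegion]
    outline: np.ndarray  # (n, 2) float, ordered, implicitly closed
    junctions: list = field(default_factory=list)
    wing_area: float = 0.0
    wing_length: float = 0.0
    wing_width: float = 0.0
    wing_perimeter: float = 0.0
    scale: float | None = None
    image_shape: tuple[int, int] | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)

    def cell_centroids(self) -> np.ndarray:
        if not self.cells:
            return np.zeros((0, 2))
        return np.array([c.centroid for c in self.cells], dtype=float)

    def junction_points(self) -> np.ndarray:
        if not self.junctions:
            return np.zeros((0, 2))
        return np.array([j.position for j in self.junctions], dtype=float)


# ---------------------------------------------------------------------------
# region growing
# ---------------------------------------------------------------------------

def grow_region(
    image: BinaryWingImage,
    seed: tuple[int, int],
    cell_id: int = 1,
    claimed: np.ndarray | None = None,
) -> CellRegion:
    """Flood-fill the 8-connected foreground component containing ``seed``.

    Starting from the seed, the fill repeatedly examines the 8 neighbors of
    each front pixel: foreground neighbors join the region, dark neighbors are
    recorded (once) as boundary pixels.  Visited pixels are marked so no pixel
    is examined twice.  ``claimed``, when given, is updated in place and lets
    a caller run successive fills over one image.
    """
    mask = image.mask
    h, w = mask.shape
    r0, c0 = seed
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValidationError(f"seed {seed} outside image of shape {(h, w)}")
    if not mask[r0, c0]:
        raise ValidationError(f"seed {seed} lies on a vein/background pixel")
    if claimed is None:
        claimed = np.zeros_like(mask)
    if claimed[r0, c0]:
        raise ValidationError(f"seed {seed} already claimed by another region")

    interior: list[tuple[int, int]] = []
    boundary: list[tuple[int, int]] = []
    seen_boundary = np.zeros_like(mask)
    stack = [(r0, c0)]
    claimed[r0, c0] = True
    while stack:
        r, c = stack.pop()
        interior.append((r, c))
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                nr, nc = r + dr, c + dc
                if not (0 <= nr < h and 0 <= nc < w):
                    continue
                if mask[nr, nc]:
                    if not claimed[nr, nc]:
                        claimed[nr, nc] = True
                        stack.append((nr, nc))
                elif not seen_boundary[nr, nc]:
                    seen_boundary[nr, nc] = True
                    boundary.append((nr, nc))

    interior_arr = np.array(interior)
    boundary_arr = np.array(boundary) if boundary else np.zeros((0, 2), dtype=int)
    return _make_cell(cell_id, interior_arr, boundary_arr, image.scale)


def _make_cell(
    cell_id: int,
    interior: np.ndarray,
    boundary: np.ndarray,
    scale: float | None,
) -> CellRegion:
    s = 1.0 if scale is None else float(scale)
    area = float(len(interior)) * s * s
    centroid = tuple(interior.mean(axis=0))
    length_px = max_pairwise_distance(boundary) if len(boundary) else 0.0
    length_px = max(length_px, 1.0)  # degenerate regions: keep width finite
    length = length_px * s
    width = area / length
    region_mask = _coords_to_mask(interior)
    contour = trace_boundary(region_mask)
    perim_px = max(polyline_length(contour, closed=True), 1.0)
    perimeter = perim_px * s
    circularity = 4.0 * np.pi * float(len(interior)) / perim_px ** 2
    return CellRegion(
        cell_id=cell_id,
        interior_pixels=interior,
        boundary_pixels=boundary,
        centroid=centroid,
        area=area,
        length=length,
        width=width,
        circularity=circularity,
        perimeter=perimeter,
    )


def _coords_to_mask(coords: np.ndarray) -> np.ndarray:
    rmin, cmin = coords.min(axis=0)
    rmax, cmax = coords.max(axis=0)
    m = np.zeros((rmax - rmin + 1, cmax - cmin + 1), dtype=bool)
    m[coords[:, 0] - rmin, coords[:, 1] - cmin] = True
    # trace_boundary works on the local mask; shift coords back afterwards
    return m


def cell_metrics(region: CellRegion) -> tuple[float, float, float, float]:
    """Return (area, length, width, circularity) of a cell."""
    return region.area, region.length, region.width, region.circularity


# ---------------------------------------------------------------------------
# whole-image segmentation
# ---------------------------------------------------------------------------

def segment_all(
    image: BinaryWingImage,
    min_cell_area: int = DEFAULT_MIN_CELL_AREA,
) -> WingGeometry:
    """Segment every cell of a binarized wing and measure the whole wing.

    Foreground components are found in row-major discovery order.  The
    component(s) touching the image border are the light background; the
    remaining components at least ``min_cell_area`` pixels large become cells,
    numbered in discovery order.  The wing silhouette (everything that is not
    background) provides the outline and whole-wing metrics.
    """
    mask = image.mask
    if not mask.any():
        raise ValidationError("empty image: no foreground pixels")
    labels, n_labels = ndimage.label(mask, structure=_EIGHT)
    border = np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
    )
    background_labels = set(np.unique(border[border > 0]).tolist())
    silhouette = (
        ~np.isin(labels, list(background_labels))
        if background_labels
        else np.ones_like(mask)
    )
    # only the main silhouette component matters for the ambiguity warning;
    # stray dark speckles at the border are not the wing
    sil_labels, n_sil = ndimage.label(silhouette, structure=_EIGHT)
    if n_sil > 1:
        sizes = np.bincount(sil_labels.ravel())[1:]
        silhouette = sil_labels == (int(np.argmax(sizes)) + 1)
    if (
        silhouette[0, :].any()
        and silhouette[-1, :].any()
        and silhouette[:, 0].any()
        and silhouette[:, -1].any()
    ):
        warnings.warn(
            "wing silhouette touches the image border on all four sides; "
            "background/wing separation may be ambiguous",
            stacklevel=2,
        )

    scale = image.scale
    cells: list[CellRegion] = []
    vein = ~mask
    objects = ndimage.find_objects(labels)
    counts = np.bincount(labels.ravel(), minlength=n_labels + 1)
    next_id = 1
    for lab in range(1, n_labels + 1):
        if lab in background_labels or counts[lab] < min_cell_area:
            continue
        sl = objects[lab - 1]
        rsl = slice(max(sl[0].start - 1, 0), min(sl[0].stop + 1, mask.shape[0]))
        csl = slice(max(sl[1].start - 1, 0), min(sl[1].stop + 1, mask.shape[1]))
        local = labels[rsl, csl] == lab
        interior = np.argwhere(local)
        interior[:, 0] += rsl.start
        interior[:, 1] += csl.start
        dil = ndimage.binary_dilation(local, structure=_EIGHT)
        bnd_local = dil & ~local & vein[rsl, csl]
        boundary = np.argwhere(bnd_local)
        boundary[:, 0] += rsl.start
        boundary[:, 1] += csl.start
        cells.append(_make_cell(next_id, interior, boundary, scale))
        next_id += 1

    if not silhouette.any():
        # the whole image is border-touching background (e.g. all white):
        # no wing, no cells, degenerate outline
        warnings.warn("no wing silhouette found; image is all background",
                      stacklevel=2)
        return WingGeometry(
            cells=cells,
            outline=np.zeros((0, 2)),
            scale=image.scale,
            image_shape=mask.shape,
        )
    geom = extract_outline(image)
    geom.cells = cells
    return geom


def extract_outline(image: BinaryWingImage) -> WingGeometry:
    """Extract the wing silhouette outline and whole-wing metrics.

    The silhouette is the complement of the border-touching light background
    component: cells and veins filled solid.  Its external boundary is traced
    as an ordered closed polyline; interior holes are ignored.  When several
    disjoint silhouettes exist the largest is kept (with a warning).
    """
    mask = image.mask
    labels, _ = ndimage.label(mask, structure=_EIGHT)
    border = np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
    )
    background_labels = np.unique(border[border > 0])
    background = np.isin(labels, background_labels)
    silhouette = ~background
    if not silhouette.any():
        raise ValidationError("no wing silhouette: image is all background")
    sil_labels, n_sil = ndimage.label(silhouette, structure=_EIGHT)
    if n_sil > 1:
        sizes = np.bincount(sil_labels.ravel())[1:]
        keep = int(np.argmax(sizes)) + 1
        if np.sum(sizes >= DEFAULT_MIN_CELL_AREA) > 1:
            warnings.warn(
                f"{n_sil} disjoint silhouettes found; keeping the largest",
                stacklevel=2,
            )
        silhouette = sil_labels == keep

    s = 1.0 if image.scale is None else float(image.scale)
    outline = trace_boundary(silhouette).astype(float)
    wing_area = float(silhouette.sum()) * s * s
    wing_perimeter = polyline_length(outline, closed=True) * s
    wing_length = max(max_pairwise_distance(outline), 1.0) * s
    wing_width = wing_area / wing_length
    return WingGeometry(
        cells=[],
        outline=outline,
        junctions=[],
        wing_area=wing_area,
        wing_length=wing_length,
        wing_width=wing_width,
        wing_perimeter=wing_perimeter,
        scale=image.scale,
        image_shape=mask.shape,
    )
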