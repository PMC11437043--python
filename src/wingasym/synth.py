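"""Synthetic wing-pair generator with exact ground truth.

Real inputs are scans of wing pairs: a closed venation network of dark veins
partitioning a blade-shaped silhouette into polygonal membrane cells on a
light background.  This module emulates them with a Voronoi tessellation:
seed points are scattered in an elliptical, tapered blade, relaxed by a few
Lloyd iterations so cells are convex and fat, and the resulting cell edges
plus the blade outline are rasterized as dark strokes of configurable width.
The construction gives exact polygonal ground truth — cell polygons, areas,
centroids, vein-graph vertices, the outline — against which every pipeline
stage can be validated.

A pair is a base render (the right wing) plus a perturbed copy (the left
wing): optional global area scaling, shared-vertex jitter, a rigid offset,
mirroring, salt-and-pepper noise and Gaussian blur, with every applied
perturbation recorded.  Output is bit-identical for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw
from scipy import ndimage
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import voronoi_diagram

from .errors import ValidationError
from .io import RawImage
from .superimpose import RigidTransform, transform_points

#: Minimum blade area per requested cell (px^2) below which generation fails.
_MIN_AREA_PER_CELL = 64.0


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    The defaults render a 480x720 wing with 20 cells bounded by 3-px veins —
    a desk-scale stand-in for a scanned wing.  Perturbations default to off;
    ``area_scale`` scales every cell area of the left wing by that factor
    (implemented as a global coordinate scaling by its square root),
    ``jitter_sd`` jitters each shared vein-graph vertex once (both incident
    cells move together), the offset fields are a rigid displacement applied
    before mirroring, ``noise_fraction`` is the total salt-and-pepper pixel
    fraction (half salt, half pepper) and ``blur_radius`` the Gaussian sigma
    in pixels.
    """

    seed: int = 0
    n_cells_target: int = 20
    height: int = 480
    width: int = 720
    vein_width: int = 3
    lloyd_iterations: int = 3
    area_scale: float = 1.0
    jitter_sd: float = 0.0
    offset_x: float = 0.0
    offset_y: float = 0.0
    offset_theta: float = 0.0  # radians
    noise_fraction: float = 0.0
    blur_radius: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cells_target < 10:
            raise ValidationError("n_cells_target must be at least 10")
        if self.vein_width < 2:
            raise ValidationError("vein_width must be at least 2 px")
        if not 0.0 <= self.noise_fraction < 1.0:
            raise ValidationError("noise_fraction must be in [0, 1)")
        if self.area_scale <= 0:
            raise ValidationError("area_scale must be positive")


@dataclass
class GroundTruth:
    """Exact geometry behind a rendered wing, in (row, col) coordinates."""

    cell_polygons: list[np.ndarray]
    cell_areas: np.ndarray
    cell_centroids: np.ndarray
    junctions_interior: np.ndarray  # vein-graph vertices of degree >= 3
    junctions_outline: np.ndarray  # points where an internal vein meets the outline
    outline: np.ndarray
    applied_transform: RigidTransform | None = None
    area_scale: float = 1.0
    mirrored: bool = False
    config: SynthConfig | None = None


@dataclass
class PairGroundTruth:
    """Ground truth for a generated wing pair."""

    right: GroundTruth
    left: GroundTruth
    true_transform: RigidTransform = field(default_factory=RigidTransform)
    area_scale: float = 1.0


# ---------------------------------------------------------------------------
# blade and tessellation (internal coordinates are (x=col, y=row))
# ---------------------------------------------------------------------------

def _blade_polygon(height: int, width: int, n: int = 256) -> Polygon:
    """Elliptical blade, gently tapered toward the (right) wing tip."""
    cx, cy = width / 2.0, height / 2.0
    a, b = 0.42 * width, 0.32 * height
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    x = cx + a * np.cos(t)
    y = cy + b * np.sin(t) * (0.82 + 0.18 * np.cos(t))
    return Polygon(np.column_stack([x, y]))


def _sample_in_polygon(poly: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    minx, miny, maxx, maxy = poly.bounds
    pts: list[tuple[float, float]] = []
    while len(pts) < n:
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if poly.contains(Point(x, y)):
            pts.append((x, y))
    return np.array(pts)


def _clipped_voronoi(points: np.ndarray, blade: Polygon) -> list[Polygon]:
    """Voronoi cells of ``points`` clipped to the blade, in point order."""
    envelope = blade.buffer(max(blade.bounds[2], blade.bounds[3]))
    diagram = voronoi_diagram(MultiPoint(points.tolist()), envelope=envelope)
    regions = list(diagram.geoms)
    cells: list[Polygon] = []
    for px, py in points:
        p = Point(px, py)
        hit = None
        for reg in regions:
            if reg.covers(p):
                hit = reg
                break
        if hit is None:  # numerically on an edge: take the nearest region
            hit = min(regions, key=lambda r: r.distance(p))
        clipped = hit.intersection(blade)
        if clipped.geom_type == "MultiPolygon":
            clipped = max(clipped.geoms, key=lambda g: g.area)
        cells.append(clipped)
    return cells


def _tessellate(
    config: SynthConfig, rng: np.random.Generator
) -> tuple[list[np.ndarray], np.ndarray, Polygon]:
    """Lloyd-relaxed clipped Voronoi tessellation of the blade.

    Returns (cell rings as (k, 2) xy arrays, seed points, blade polygon).
    """
    blade = _blade_polygon(config.height, config.width)
    if blade.area < _MIN_AREA_PER_CELL * config.n_cells_target:
        raise ValidationError(
            "silhouette too small for the requested number of cells"
        )
    points = _sample_in_polygon(blade, config.n_cells_target, rng)
    for _ in range(config.lloyd_iterations):
        cells = _clipped_voronoi(points, blade)
        points = np.array([[c.centroid.x, c.centroid.y] for c in cells])
    cells = _clipped_voronoi(points, blade)
    rings = [np.asarray(c.exterior.coords)[:-1] for c in cells]
    return rings, points, blade


def _vein_graph_vertices(
    rings: list[np.ndarray], blade: Polygon
) -> tuple[np.ndarray, np.ndarray]:
    """Split cell-polygon vertices into interior junctions (>= 3 incident
    cells) and outline junctions (>= 2 incident cells on the blade boundary).
    """
    incident: dict[tuple[float, float], set[int]] = {}
    for i, ring in enumerate(rings):
        for x, y in ring:
            key = (round(float(x), 6), round(float(y), 6))
            incident.setdefault(key, set()).add(i)
    boundary = blade.exterior
    interior, outline = [], []
    for (x, y), cells in incident.items():
        on_edge = boundary.distance(Point(x, y)) < 1e-6
        if on_edge:
            if len(cells) >= 2:
                outline.append((x, y))
        elif len(cells) >= 3:
            interior.append((x, y))
    interior_arr = np.array(interior) if interior else np.zeros((0, 2))
    outline_arr = np.array(outline) if outline else np.zeros((0, 2))
    return interior_arr, outline_arr


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _render(
    rings: list[np.ndarray],
    outline_ring: np.ndarray,
    height: int,
    width: int,
    vein_width: int,
) -> np.ndarray:
    """Rasterize vein strokes (cell edges + blade outline) as dark lines on a
    light background; returns a float image in [0, 1]."""
    img = Image.new("L", (width, height), 255)
    draw = ImageDraw.Draw(img)
    for ring in rings + [outline_ring]:
        xy = [(float(x), float(y)) for x, y in ring]
        xy.append(xy[0])
        draw.line(xy, fill=0, width=vein_width, joint="curve")
    return np.asarray(img, dtype=float) / 255.0


def _xy_to_rowcol(arr: np.ndarray) -> np.ndarray:
    if arr.size == 0:
        return arr.reshape(0, 2)
    return np.column_stack([arr[:, 1], arr[:, 0]])


def _truth_from_geometry(
    rings: list[np.ndarray],
    blade_ring: np.ndarray,
    blade: Polygon,
    config: SynthConfig,
) -> GroundTruth:
    polys = [Polygon(r) for r in rings]
    interior, outline_j = _vein_graph_vertices(rings, blade)
    return GroundTruth(
        cell_polygons=[_xy_to_rowcol(r) for r in rings],
        cell_areas=np.array([p.area for p in polys]),
        cell_centroids=_xy_to_rowcol(
            np.array([[p.centroid.x, p.centroid.y] for p in polys])
        ),
        junctions_interior=_xy_to_rowcol(interior),
        junctions_outline=_xy_to_rowcol(outline_j),
        outline=_xy_to_rowcol(blade_ring),
        config=config,
    )


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def generate_wing(config: SynthConfig | None = None) -> tuple[RawImage, GroundTruth]:
    """Render one synthetic wing and its ground truth."""
    if config is None:
        config = SynthConfig()
    rng = np.random.default_rng(config.seed)
    rings, _, blade = _tessellate(config, rng)
    blade_ring = np.asarray(blade.exterior.coords)[:-1]
    image = _render(rings, blade_ring, config.height, config.width,
                    config.vein_width)
    truth = _truth_from_geometry(rings, blade_ring, blade, config)
    return RawImage(pixels=image), truth


def _apply_rigid_xy(
    rings: list[np.ndarray], t: RigidTransform, center_xy: np.ndarray
) -> list[np.ndarray]:
    center_rc = np.array([center_xy[1], center_xy[0]])
    out = []
    for ring in rings:
        rc = transform_points(_xy_to_rowcol(ring), t, center_rc)
        out.append(np.column_stack([rc[:, 1], rc[:, 0]]))
    return out


def generate_pair(
    config: SynthConfig | None = None,
) -> tuple[RawImage, RawImage, PairGroundTruth]:
    """Render a synthetic left/right wing pair.

    The right wing is the base tessellation.  The left wing applies, in
    order: global area scaling, shared-vertex jitter, the configured rigid
    offset (all in the right wing's frame), then mirroring, and finally
    salt-and-pepper noise and Gaussian blur on the rendered image.  The
    recorded ``true_transform`` is the rigid offset in the unmirrored frame,
    i.e. what segmentation + un-mirroring + superimposition should recover
    (up to inversion).
    """
    if config is None:
        config = SynthConfig()
    rng = np.random.default_rng(config.seed)
    rings, _, blade = _tessellate(config, rng)
    blade_ring = np.asarray(blade.exterior.coords)[:-1]
    h, w = config.height, config.width

    right_img = _render(rings, blade_ring, h, w, config.vein_width)
    right_truth = _truth_from_geometry(rings, blade_ring, blade, config)

    center = np.array([blade.centroid.x, blade.centroid.y])
    left_rings = [r.copy() for r in rings]
    left_blade_ring = blade_ring.copy()

    if config.area_scale != 1.0:
        s = float(np.sqrt(config.area_scale))
        left_rings = [center + s * (r - center) for r in left_rings]
        left_blade_ring = center + s * (left_blade_ring - center)

    if config.jitter_sd > 0:
        jitter: dict[tuple[float, float], np.ndarray] = {}

        def jitter_of(x: float, y: float) -> np.ndarray:
            key = (round(float(x), 6), round(float(y), 6))
            if key not in jitter:
                jitter[key] = rng.normal(0.0, config.jitter_sd, size=2)
            return jitter[key]

        left_rings = [
            np.array([[x, y] + jitter_of(x, y) for x, y in ring])
            for ring in left_rings
        ]

    t_true = RigidTransform(
        x=config.offset_x, y=config.offset_y, theta=config.offset_theta
    )
    if (config.offset_x, config.offset_y, config.offset_theta) != (0.0, 0.0, 0.0):
        left_rings = _apply_rigid_xy(left_rings, t_true, center)
        left_blade_ring = _apply_rigid_xy([left_blade_ring], t_true, center)[0]

    left_blade = Polygon(left_blade_ring)
    left_truth = _truth_from_geometry(
        left_rings, left_blade_ring, left_blade, config
    )
    left_truth.applied_transform = t_true
    left_truth.area_scale = config.area_scale

    # mirror for rendering: column j maps to (w - 1) - j, matching a
    # left-right flip of the pixel grid
    def mirror(ring: np.ndarray) -> np.ndarray:
        out = ring.copy()
        out[:, 0] = (w - 1) - out[:, 0]
        return out

    mirrored_rings = [mirror(r) for r in left_rings]
    mirrored_blade = mirror(left_blade_ring)
    left_img = _render(mirrored_rings, mirrored_blade, h, w, config.vein_width)
    left_truth.mirrored = True

    if config.noise_fraction > 0:
        k = int(round(config.noise_fraction * h * w))
        idx = rng.choice(h * w, size=k, replace=False)
        flat = left_img.ravel()
        flat[idx[: k // 2]] = 0.0  # pepper
        flat[idx[k // 2:]] = 1.0  # salt
    if config.blur_radius > 0:
        left_img = np.clip(
            ndimage.gaussian_filter(left_img, sigma=config.blur_radius), 0.0, 1.0
        )

    pair_truth = PairGroundTruth(
        right=right_truth,
        left=left_truth,
        true_transform=t_true,
        area_scale=config.area_scale,
    )
    return RawImage(pixels=left_img), RawImage(pixels=right_img), pair_truth
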