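"""Rigid superimposition of two wings and correspondence matching.

Two segmented wings are aligned with a rigid transform — translation plus
rotation, deliberately *no* scaling, so that genuine size differences between
left and right wings survive as asymmetry signal.  The transform is either
supplied manually or found by global-best Particle Swarm Optimization (PSO)
minimizing the mean distance between the two wing outlines, after an initial
centroid alignment.

After alignment, cells (and junctions) are put in correspondence by
nearest-centroid matching, run once in each reference direction by the
pipeline; a target cell may be the nearest match of several reference cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .segment import WingGeometry

#: Number of equal-arc-length points each outline is resampled to.
DEFAULT_OUTLINE_POINTS = 200


@dataclass(frozen=True)
class RigidTransform:
    """Translation (x = columns, y = rows) plus rotation.

    ``theta`` is in radians, applied about the moving wing's outline centroid
    before the translation; there is no scale or shear component.
    """

    x: float = 0.0
    y: float = 0.0
    theta: float = 0.0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.theta)


@dataclass(frozen=True)
class PSOConfig:
    """Particle-swarm settings for automated superimposition.

    Defaults: 3 variables (x, y, theta), 40 iterations, 30 particles,
    inertia w = 1.0 damped by 0.95 per iteration, cognitive and social
    coefficients both 1.2.
    """

    n_variables: int = 3
    max_iterations: int = 40
    n_particles: int = 30
    inertia: float = 1.0
    damping: float = 0.95
    cognitive: float = 1.2
    social: float = 1.2
    seed: int | None = 0
    bounds: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        for name in ("max_iterations", "n_particles", "inertia", "damping",
                     "cognitive", "social"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"PSO parameter {name} must be positive")


@dataclass
class Correspondence:
    """Nearest-centroid pairing of cells (or junctions) between two wings."""

    cell_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    junction_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    reference: int = 1

    @property
    def cell_distances(self) -> np.ndarray:
        return np.array([d for _, _, d in self.cell_pairs], dtype=float)

    @property
    def junction_distances(self) -> np.ndarray:
        return np.array([d for _, _, d in self.junction_pairs], dtype=float)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def outline_centroid(geometry: WingGeometry) -> np.ndarray:
    """Arithmetic mean of the outline points, (row, col)."""
    return np.asarray(geometry.outline, dtype=float).mean(axis=0)


def transform_points(
    points: np.ndarray, t: RigidTransform, center: np.ndarray
) -> np.ndarray:
    """Rotate ``points`` by ``t.theta`` about ``center`` then translate.

    Points and center are (row, col); the translation adds ``t.y`` to rows
    and ``t.x`` to columns.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return pts.copy()
    if t.x == 0.0 and t.y == 0.0 and t.theta == 0.0:
        return pts.copy()  # exact fixed point for the identity
    c, s = np.cos(t.theta), np.sin(t.theta)
    d = pts - center
    rows = center[0] + c * d[:, 0] - s * d[:, 1] + t.y
    cols = center[1] + s * d[:, 0] + c * d[:, 1] + t.x
    return np.column_stack([rows, cols])


def apply_transform(geometry: WingGeometry, t: RigidTransform) -> WingGeometry:
    """Apply a rigid transform to a wing's coordinates.

    The outline, cell centroids and junction positions move; all metrics
    (areas, lengths, circularities, counts) are rigid-invariant and are kept.
    Pixel sets of the cells are kept in their original frame.
    """
    center = outline_centroid(geometry)
    new_outline = transform_points(geometry.outline, t, center)
    new_cells = []
    if geometry.cells:
        cents = transform_points(geometry.cell_centroids(), t, center)
        for cell, cent in zip(geometry.cells, cents):
            new_cells.append(replace_centroid(cell, tuple(cent)))
    new_junctions = []
    if geometry.junctions:
        pos = transform_points(geometry.junction_points(), t, center)
        for j, p in zip(geometry.junctions, pos):
            new_junctions.append(
                type(j)(position=tuple(p), support_pixels=j.support_pixels)
            )
    return WingGeometry(
        cells=new_cells,
        outline=new_outline,
        junctions=new_junctions,
        wing_area=geometry.wing_area,
        wing_length=geometry.wing_length,
        wing_width=geometry.wing_width,
        wing_perimeter=geometry.wing_perimeter,
        scale=geometry.scale,
        image_shape=geometry.image_shape,
    )


def replace_centroid(cell, centroid):
    return replace(cell, centroid=centroid)


# ---------------------------------------------------------------------------
# outline distance objective
# ---------------------------------------------------------------------------

def resample_closed(polyline: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to ``n`` points at equal arc length."""
    pts = np.asarray(polyline, dtype=float)
    if len(pts) < 3:
        raise ValidationError("outline needs at least 3 points to resample")
    closed = np.vstack([pts, pts[:1]])
    seg = np.sqrt(((np.diff(closed, axis=0)) ** 2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise ValidationError("degenerate outline with zero length")
    targets = np.arange(n) * total / n
    rows = np.interp(targets, cum, closed[:, 0])
    cols = np.interp(targets, cum, closed[:, 1])
    return np.column_stack([rows, cols])


def outline_nearest_distances(
    ref_points: np.ndarray, moving_points: np.ndarray
) -> np.ndarray:
    """Distance from each moving point to its nearest reference point."""
    tree = cKDTree(ref_points)
    d, _ = tree.query(moving_points)
    return d


def outline_objective(
    ref: WingGeometry,
    moving: WingGeometry,
    t: RigidTransform,
    n_points: int = DEFAULT_OUTLINE_POINTS,
    symmetric: bool = False,
) -> float:
    """Mean nearest-point distance between the two resampled outlines.

    One-directional (moving -> reference) by default, which is what the PSO
    minimizes; the symmetric version (average of both directions) is used for
    reporting the outline-distance metric.
    """
    ref_pts = resample_closed(ref.outline, n_points)
    mov_pts = resample_closed(moving.outline, n_points)
    mov_pts = transform_points(mov_pts, t, outline_centroid(moving))
    d1 = outline_nearest_distances(ref_pts, mov_pts)
    if not symmetric:
        return float(d1.mean())
    d2 = outline_nearest_distances(mov_pts, ref_pts)
    return float(0.5 * (d1.mean() + d2.mean()))


def align_centroids(ref: WingGeometry, moving: WingGeometry) -> RigidTransform:
    """Pure translation putting the moving outline centroid on the reference's."""
    delta = outline_centroid(ref) - outline_centroid(moving)
    return RigidTransform(x=float(delta[1]), y=float(delta[0]), theta=0.0)


# ---------------------------------------------------------------------------
# PSO
# ---------------------------------------------------------------------------

def default_bounds(
    ref: WingGeometry, moving: WingGeometry
) -> tuple[tuple[float, float], ...]:
    """Search box: translation within +-W/4 of the centroid-aligning shift,
    rotation within +-30 degrees."""
    if ref.image_shape is not None:
        w = ref.image_shape[1]
    else:
        w = float(np.ptp(ref.outline[:, 1])) * 2.0
    t0 = align_centroids(ref, moving)
    half = w / 4.0
    max_theta = np.deg2rad(30.0)
    return (
        (t0.x - half, t0.x + half),
        (t0.y - half, t0.y + half),
        (-max_theta, max_theta),
    )


def pso_superimpose(
    ref: WingGeometry,
    moving: WingGeometry,
    config: PSOConfig | None = None,
    n_points: int = DEFAULT_OUTLINE_POINTS,
) -> tuple[RigidTransform, np.ndarray]:
    """Find the rigid transform aligning ``moving`` onto ``ref`` by PSO.

    Global-best PSO over (x, y, theta): velocities start at zero, positions
    start uniform within the bounds (centered on the centroid-aligning
    translation), and each iteration applies

        v <- w*v + C1*r1*(pbest - pos) + C2*r2*(gbest - pos)

    with r1, r2 ~ U(0, 1) per dimension, positions clamped to the bounds and
    the inertia w multiplied by the damping factor.  Returns the best
    transform and the per-iteration best-objective history (non-increasing,
    one entry per iteration).
    """
    if config is None:
        config = PSOConfig()
    bounds = config.bounds if config.bounds is not None else default_bounds(ref, moving)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(lo >= hi):
        raise ValidationError("invalid PSO bounds: low >= high")

    # Fixed resampling + KD-tree reused across all objective evaluations.
    ref_pts = resample_closed(ref.outline, n_points)
    mov_pts = resample_closed(moving.outline, n_points)
    center = outline_centroid(moving)
    tree = cKDTree(ref_pts)

    def objective(vec: np.ndarray) -> float:
        t = RigidTransform(x=vec[0], y=vec[1], theta=vec[2])
        moved = transform_points(mov_pts, t, center)
        d, _ = tree.query(moved)
        return float(d.mean())

    rng = np.random.default_rng(config.seed)
    n, dim = config.n_particles, config.n_variables
    pos = lo + rng.uniform(size=(n, dim)) * (hi - lo)
    vel = np.zeros((n, dim))
    pbest = pos.copy()
    pbest_val = np.array([objective(p) for p in pos])
    g = int(np.argmin(pbest_val))
    gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])

    w = config.inertia
    history = np.empty(config.max_iterations)
    for it in range(config.max_iterations):
        r1 = rng.uniform(size=(n, dim))
        r2 = rng.uniform(size=(n, dim))
        vel = (
            w * vel
            + config.cognitive * r1 * (pbest - pos)
            + config.social * r2 * (gbest - pos)
        )
        pos = np.clip(pos + vel, lo, hi)
        vals = np.array([objective(p) for p in pos])
        improved = vals < pbest_val
        pbest[improved] = pos[improved]
        pbest_val[improved] = vals[improved]
        g = int(np.argmin(pbest_val))
        if pbest_val[g] < gbest_val:
            gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])
        history[it] = gbest_val
        w *= config.damping

    best = RigidTransform(x=float(gbest[0]), y=float(gbest[1]), theta=float(gbest[2]))
    return best, history


# ---------------------------------------------------------------------------
# correspondence matching
# ---------------------------------------------------------------------------

def _nearest_pairs(
    ref_points: np.ndarray,
    ref_ids: list[int],
    target_points: np.ndarray,
    target_ids: list[int],
) -> list[tuple[int, int, float]]:
    tree = cKDTree(target_points)
    d, idx = tree.query(ref_points)
    return [
        (ref_ids[i], target_ids[int(j)], float(dist))
        for i, (j, dist) in enumerate(zip(idx, d))
    ]


def match_cells(
    ref: WingGeometry, target: WingGeometry, reference: int = 1
) -> Correspondence:
    """Match each reference cell to the closest target cell by centroid.

    Both wings must already be in the superimposed frame.  Every reference
    cell appears exactly once; extra target cells are ignored in this
    direction (the pipeline runs the match in both directions).  Junctions
    are matched the same way when both wings have them.
    """
    corr = Correspondence(reference=reference)
    if ref.n_cells == 0 or target.n_cells == 0:
        if target.n_cells == 0:
            warnings.warn("target wing has no cells; empty correspondence",
                          stacklevel=2)
        return corr
    corr.cell_pairs = _nearest_pairs(
        ref.cell_centroids(),
        [c.cell_id for c in ref.cells],
        target.cell_centroids(),
        [c.cell_id for c in target.cells],
    )
    if ref.n_junctions and target.n_junctions:
        corr.junction_pairs = _nearest_pairs(
            ref.junction_points(),
            list(range(ref.n_junctions)),
            target.junction_points(),
            list(range(target.n_junctions)),
        )
    return corr


def match_junctions(
    ref: WingGeometry, target: WingGeometry, reference: int = 1
) -> list[tuple[int, int, float]]:
    """Nearest-point junction pairing (reference direction only)."""
    if ref.n_junctions == 0 or target.n_junctions == 0:
        return []
    return _nearest_pairs(
        ref.junction_points(),
        list(range(ref.n_junctions)),
        target.junction_points(),
        list(range(target.n_junctions)),
    )
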