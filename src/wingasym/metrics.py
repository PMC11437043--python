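"""Asymmetry quantification for a superimposed, matched wing pair.

For each of the four cell metrics (area, length, width, circularity) and each
reference direction, the values of matched cells are compared by ordinary
least squares regression (slope, intercept, r-squared) and by NRMSE — the
root-mean-square error of target minus reference, normalized by the
reference's range (max - min) so the four metrics are comparable despite
their different units.  Spatial asymmetry is summarized by the mean and
population standard deviation of matched centroid, junction and outline
nearest-point distances, and structural asymmetry by signed differences in
counts and whole-wing size metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ValidationError
from .segment import WingGeometry
from .superimpose import (
    Correspondence,
    RigidTransform,
    apply_transform,
    match_cells,
    outline_nearest_distances,
    resample_closed,
)

METRIC_NAMES = ("area", "length", "width", "circularity")


@dataclass(frozen=True)
class MetricVectorPair:
    """Matched metric values of corresponding cells, ordered by the pairing."""

    metric_name: str
    ref_values: np.ndarray
    target_values: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.ref_values, dtype=float)
        t = np.asarray(self.target_values, dtype=float)
        if r.shape != t.shape or r.ndim != 1:
            raise ValidationError("ref and target vectors must be equal-length 1-D")
        object.__setattr__(self, "ref_values", r)
        object.__setattr__(self, "target_values", t)


@dataclass
class ComparisonStats:
    """OLS fit plus NRMSE for one metric in one reference direction."""

    slope: float
    intercept: float
    r2: float
    nrmse: float


@dataclass
class PairResult:
    """All asymmetry quantities for one wing pair.

    ``comparisons[direction][metric]`` holds the regression/NRMSE block for
    reference direction 1 (wing 1 as reference) or 2.  ``distances`` maps
    'centroid' / 'junction' / 'outline' to (mean, population SD) in scaled
    units.  Deltas are signed wing1 - wing2 differences.
    """

    comparisons: dict[int, dict[str, ComparisonStats]] = field(default_factory=dict)
    distances: dict[str, tuple[float, float]] = field(default_factory=dict)
    delta_n_cells: int = 0
    delta_n_junctions: int = 0
    delta_wing_area: float = 0.0
    delta_wing_length: float = 0.0
    delta_wing_width: float = 0.0
    delta_wing_perimeter: float = 0.0
    n_cells_1: int = 0
    n_cells_2: int = 0
    transform: RigidTransform | None = None


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def regression(pair: MetricVectorPair) -> tuple[float, float, float]:
    """OLS of target on reference: (slope, intercept, r-squared)."""
    x, y = pair.ref_values, pair.target_values
    if len(x) < 2:
        raise ValidationError("regression needs at least 2 points")
    if np.ptp(x) == 0:
        raise ValidationError("degenerate regression: reference has zero variance")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def nrmse(pair: MetricVectorPair) -> float:
    """RMSE of (target - ref) divided by the reference range (max - min)."""
    x, y = pair.ref_values, pair.target_values
    if len(x) < 2:
        raise ValidationError("nrmse needs at least 2 points")
    rng = float(x.max() - x.min())
    if rng == 0:
        raise ValidationError("zero normalization range: constant reference vector")
    rmse = float(np.sqrt(np.mean((y - x) ** 2)))
    return rmse / rng


def distance_stats(
    correspondence: Correspondence,
    outline_distances: np.ndarray | None = None,
    scale: float | None = None,
) -> dict[str, tuple[float, float]]:
    """Mean and population SD of matched distances per category.

    Categories with no pairs are simply absent from the result.  Distances
    are multiplied by the scale (centroids/junctions/outlines live in pixel
    coordinates).
    """
    s = 1.0 if scale is None else float(scale)
    out: dict[str, tuple[float, float]] = {}
    for name, d in (
        ("centroid", correspondence.cell_distances),
        ("junction", correspondence.junction_distances),
        ("outline", np.asarray(outline_distances, dtype=float)
         if outline_distances is not None else np.zeros(0)),
    ):
        if len(d):
            d = d * s
            out[name] = (float(d.mean()), float(d.std()))
    return out


def count_and_size_deltas(wing1: WingGeometry, wing2: WingGeometry) -> dict:
    """Signed wing1 - wing2 differences of counts and whole-wing metrics."""
    return {
        "delta_n_cells": wing1.n_cells - wing2.n_cells,
        "delta_n_junctions": wing1.n_junctions - wing2.n_junctions,
        "delta_wing_area": wing1.wing_area - wing2.wing_area,
        "delta_wing_length": wing1.wing_length - wing2.wing_length,
        "delta_wing_width": wing1.wing_width - wing2.wing_width,
        "delta_wing_perimeter": wing1.wing_perimeter - wing2.wing_perimeter,
    }


def accuracy_percent(result_ref: float, result_test: float) -> float:
    """Percent deviation of a test value from a reference value."""
    if result_ref == 0:
        raise ValidationError("reference value is zero")
    return 100.0 * abs(result_ref - result_test) / abs(result_ref)


# ---------------------------------------------------------------------------
# pair evaluation
# ---------------------------------------------------------------------------

def metric_vectors(
    ref: WingGeometry, target: WingGeometry, corr: Correspondence
) -> dict[str, MetricVectorPair]:
    """Assemble the four matched metric vectors from a correspondence."""
    ref_by_id = {c.cell_id: c for c in ref.cells}
    tgt_by_id = {c.cell_id: c for c in target.cells}
    vectors = {}
    for name in METRIC_NAMES:
        rv = np.array(
            [getattr(ref_by_id[i], name) for i, _, _ in corr.cell_pairs]
        )
        tv = np.array(
            [getattr(tgt_by_id[j], name) for _, j, _ in corr.cell_pairs]
        )
        vectors[name] = MetricVectorPair(name, rv, tv)
    return vectors


def comparison_block(
    ref: WingGeometry, target: WingGeometry, corr: Correspondence
) -> dict[str, ComparisonStats]:
    """Regression + NRMSE for all four metrics in one reference direction."""
    block = {}
    for name, pair in metric_vectors(ref, target, corr).items():
        slope, intercept, r2 = regression(pair)
        block[name] = ComparisonStats(slope, intercept, r2, nrmse(pair))
    return block


def evaluate_pair(
    wing1: WingGeometry,
    wing2: WingGeometry,
    transform: RigidTransform | None = None,
    n_outline: int = 200,
) -> PairResult:
    """Full asymmetry evaluation of a wing pair.

    Applies the transform to wing 2, matches cells (and junctions) in both
    reference directions, computes regression and NRMSE for the four metrics
    per direction, distance statistics (centroid and junction distances from
    both directions pooled; symmetric outline nearest-point distances), and
    signed count/size deltas (which use the untransformed wings, as rigid
    motion leaves them unchanged).
    """
    moved2 = apply_transform(wing2, transform) if transform is not None else wing2
    corr1 = match_cells(wing1, moved2, reference=1)
    corr2 = match_cells(moved2, wing1, reference=2)

    result = PairResult(transform=transform)
    result.comparisons[1] = comparison_block(wing1, moved2, corr1)
    result.comparisons[2] = comparison_block(moved2, wing1, corr2)

    pooled = Correspondence(
        cell_pairs=corr1.cell_pairs
        + [(j, i, d) for i, j, d in corr2.cell_pairs],
        junction_pairs=corr1.junction_pairs
        + [(j, i, d) for i, j, d in corr2.junction_pairs],
    )
    o1 = resample_closed(wing1.outline, n_outline)
    o2 = resample_closed(moved2.outline, n_outline)
    outline_d = np.concatenate(
        [outline_nearest_distances(o1, o2), outline_nearest_distances(o2, o1)]
    )
    result.distances = distance_stats(pooled, outline_d, scale=wing1.scale)

    for key, value in count_and_size_deltas(wing1, wing2).items():
        setattr(result, key, value)
    result.n_cells_1 = wing1.n_cells
    result.n_cells_2 = wing2.n_cells
    return result
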