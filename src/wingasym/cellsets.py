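"""Partitioning wing cells into up to five sets for localized comparison.

A set groups at least three cells; a wing carries at most five disjoint sets
and cells may remain unassigned.  Sets are defined per wing, either by
explicit cell ids or by polygons that capture cell centroids, and correspond
across the two wings of a pair by index.  Per-set comparisons reuse exactly
the whole-pair machinery, restricted to the cells of the corresponding sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Point, Polygon

from .errors import ValidationError
from .metrics import ComparisonStats, comparison_block, distance_stats
from .segment import WingGeometry
from .superimpose import Correspondence, RigidTransform, apply_transform, match_cells

MAX_SETS = 5
MIN_CELLS_PER_SET = 3


@dataclass
class CellSetPartition:
    """Up to five disjoint, named groups of cell ids."""

    sets: list[list[int]]
    labels: list[str] = field(default_factory=list)
    definition_mode: str = "ids"

    def __post_init__(self) -> None:
        if not 1 <= len(self.sets) <= MAX_SETS:
            raise ValidationError(
                f"too many sets: {len(self.sets)} (maximum {MAX_SETS})"
            )
        seen: set[int] = set()
        for k, ids in enumerate(self.sets):
            if len(ids) < MIN_CELLS_PER_SET:
                raise ValidationError(
                    f"set {k + 1} below minimum size: {len(ids)} cells "
                    f"(need >= {MIN_CELLS_PER_SET})"
                )
            dup = seen.intersection(ids)
            if dup or len(set(ids)) != len(ids):
                raise ValidationError(
                    f"duplicate assignment: cell ids {sorted(dup) or ids} "
                    "appear in more than one set"
                )
            seen.update(ids)
        if not self.labels:
            self.labels = [f"Set {k + 1}" for k in range(len(self.sets))]


@dataclass
class SetResult:
    """Asymmetry statistics of one corresponding pair of cell sets."""

    label: str
    comparisons: dict[int, dict[str, ComparisonStats]]
    set_area_1: float
    set_area_2: float
    centroid_mean: float
    centroid_sd: float
    n_cells_1: int
    n_cells_2: int


def assign_sets(wing: WingGeometry, spec: dict) -> CellSetPartition:
    """Build a partition from a spec of explicit ids or centroid-capturing
    polygons.

    ``spec`` is ``{"mode": "ids", "sets": [[id, ...], ...]}`` or
    ``{"mode": "polygons", "sets": [[[row, col], ...], ...]}``; with polygons
    a cell joins the first polygon containing its centroid.
    """
    mode = spec.get("mode", "ids")
    raw_sets = spec.get("sets")
    if not raw_sets:
        raise ValidationError("partition spec has no sets")
    valid_ids = {c.cell_id for c in wing.cells}
    if mode == "ids":
        sets = [list(map(int, ids)) for ids in raw_sets]
        for ids in sets:
            unknown = set(ids) - valid_ids
            if unknown:
                raise ValidationError(f"unknown cell ids in set: {sorted(unknown)}")
        return CellSetPartition(sets=sets, definition_mode="ids")
    if mode == "polygons":
        polys = [Polygon([(r, c) for r, c in ring]) for ring in raw_sets]
        assigned: set[int] = set()
        sets = []
        for poly in polys:
            ids = []
            for cell in wing.cells:
                if cell.cell_id in assigned:
                    continue
                if poly.covers(Point(cell.centroid)):
                    ids.append(cell.cell_id)
                    assigned.add(cell.cell_id)
            sets.append(ids)
        return CellSetPartition(sets=sets, definition_mode="polygons")
    raise ValidationError(f"unknown partition mode: {mode!r}")


def load_partition_spec(path: str | Path) -> dict:
    """Read a JSON partition spec file."""
    with open(path) as fh:
        return json.load(fh)


def _restrict(wing: WingGeometry, ids: list[int]) -> WingGeometry:
    wanted = set(ids)
    sub = [c for c in wing.cells if c.cell_id in wanted]
    return WingGeometry(
        cells=sub,
        outline=wing.outline,
        junctions=[],
        wing_area=wing.wing_area,
        wing_length=wing.wing_length,
        wing_width=wing.wing_width,
        wing_perimeter=wing.wing_perimeter,
        scale=wing.scale,
        image_shape=wing.image_shape,
    )


def evaluate_sets(
    wing1: WingGeometry,
    wing2: WingGeometry,
    partition1: CellSetPartition,
    partition2: CellSetPartition,
    transform: RigidTransform | None = None,
) -> list[SetResult]:
    """Per-set asymmetry: regression/NRMSE of the four metrics in both
    directions, total set areas, and centroid-distance statistics.

    Sets correspond by index; both wings must define the same number of sets.
    """
    if len(partition1.sets) != len(partition2.sets):
        raise ValidationError(
            "set-count mismatch between wings: "
            f"{len(partition1.sets)} vs {len(partition2.sets)}"
        )
    moved2 = apply_transform(wing2, transform) if transform is not None else wing2
    results = []
    for k, label in enumerate(partition1.labels):
        sub1 = _restrict(wing1, partition1.sets[k])
        sub2 = _restrict(moved2, partition2.sets[k])
        corr1 = match_cells(sub1, sub2, reference=1)
        corr2 = match_cells(sub2, sub1, reference=2)
        comparisons = {
            1: comparison_block(sub1, sub2, corr1),
            2: comparison_block(sub2, sub1, corr2),
        }
        pooled = Correspondence(
            cell_pairs=corr1.cell_pairs + [(j, i, d) for i, j, d in corr2.cell_pairs]
        )
        dstats = distance_stats(pooled, scale=wing1.scale)
        cmean, csd = dstats.get("centroid", (float("nan"), float("nan")))
        results.append(
            SetResult(
                label=label,
                comparisons=comparisons,
                set_area_1=float(sum(c.area for c in sub1.cells)),
                set_area_2=float(sum(c.area for c in sub2.cells)),
                centroid_mean=cmean,
                centroid_sd=csd,
                n_cells_1=sub1.n_cells,
                n_cells_2=sub2.n_cells,
            )
        )
    return results
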