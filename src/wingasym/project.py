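"""End-to-end pairs pipeline, multi-pair projects and report writing.

``run_pair`` drives the full chain for one wing pair: load, binarize at the
configured threshold, mirror the wing designated as left, attach the scale,
segment cells and outline, skeletonize and detect junctions, superimpose
(automatically by PSO unless a manual transform is given) and evaluate all
asymmetry metrics, optionally per cell set.  A project is an ordered list of
labelled pairs; results aggregate into long-format tables and are written as
CSV plus a human-readable TXT rendering.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cellsets as cs
from . import io as wio
from . import metrics as wm
from . import segment as wseg
from . import skeleton as wskel
from . import superimpose as wsup
from .errors import ValidationError

_FLOAT_FMT = "%.12g"


@dataclass
class PairOptions:
    """Per-pair processing options with the pipeline defaults."""

    threshold: float = wio.DEFAULT_THRESHOLD
    mirror1: bool = False
    mirror2: bool = False
    scale: float | None = None
    seed: int = 0
    min_cell_area: int = wseg.DEFAULT_MIN_CELL_AREA
    spur_length: int = wskel.DEFAULT_SPUR_LENGTH
    superimpose: str = "auto"  # "auto" | "manual"
    manual_transform: wsup.RigidTransform | None = None
    sets1: dict | None = None
    sets2: dict | None = None
    n_outline: int = wsup.DEFAULT_OUTLINE_POINTS
    quiet: bool = True


@dataclass
class PairSpec:
    """One labelled wing pair: two image paths plus options."""

    label: str
    path1: str
    path2: str
    options: PairOptions = field(default_factory=PairOptions)


@dataclass
class PairOutput:
    """Everything computed for one pair."""

    label: str
    geometry1: wseg.WingGeometry
    geometry2: wseg.WingGeometry
    transform: wsup.RigidTransform
    history: np.ndarray | None
    result: wm.PairResult
    set_results: list[cs.SetResult] = field(default_factory=list)


@dataclass
class Project:
    """An ordered collection of labelled pairs and their results."""

    pairs: list[PairSpec] = field(default_factory=list)
    outputs: list[PairOutput] = field(default_factory=list)

    def add_pair(self, spec: PairSpec) -> None:
        if any(p.label == spec.label for p in self.pairs):
            raise ValidationError(f"duplicate pair label: {spec.label!r}")
        self.pairs.append(spec)

    def run(self) -> list[PairOutput]:
        self.outputs = [run_pair(spec) for spec in self.pairs]
        return self.outputs


def _log(quiet: bool, label: str, stage: str, t0: float) -> None:
    if not quiet:
        print(
            f"[wingasym] pair={label} stage={stage} "
            f"elapsed={time.perf_counter() - t0:.2f}s",
            file=sys.stderr,
        )


def analyze_pair(
    raw1: wio.RawImage,
    raw2: wio.RawImage,
    options: PairOptions | None = None,
    label: str = "pair",
) -> PairOutput:
    """Run the full pipeline on two in-memory grayscale images."""
    opt = options or PairOptions()
    t0 = time.perf_counter()
    if raw1.pixels.shape != raw2.pixels.shape:
        raise ValidationError(
            f"pair images must share dimensions: "
            f"{raw1.pixels.shape} vs {raw2.pixels.shape}"
        )
    imgs = []
    for raw, mirror in ((raw1, opt.mirror1), (raw2, opt.mirror2)):
        bw = wio.binarize(raw, opt.threshold)
        if mirror:
            bw = wio.mirror_horizontal(bw)
        if opt.scale is not None:
            bw = wio.set_scale(bw, opt.scale)
        imgs.append(bw)
    _log(opt.quiet, label, "binarize", t0)

    geoms = []
    for bw in imgs:
        geom = wseg.segment_all(bw, min_cell_area=opt.min_cell_area)
        skel = wskel.skeletonize(bw)
        geom.junctions = wskel.detect_junctions(skel, spur_length=opt.spur_length)
        geoms.append(geom)
    _log(opt.quiet, label, "segment", t0)

    history = None
    if opt.superimpose == "manual":
        if opt.manual_transform is None:
            raise ValidationError("manual superimposition needs a transform")
        transform = opt.manual_transform
    else:
        config = wsup.PSOConfig(seed=opt.seed)
        transform, history = wsup.pso_superimpose(
            geoms[0], geoms[1], config, n_points=opt.n_outline
        )
    _log(opt.quiet, label, "superimpose", t0)

    result = wm.evaluate_pair(
        geoms[0], geoms[1], transform, n_outline=opt.n_outline
    )
    set_results: list[cs.SetResult] = []
    if opt.sets1 is not None and opt.sets2 is not None:
        p1 = cs.assign_sets(geoms[0], opt.sets1)
        p2 = cs.assign_sets(geoms[1], opt.sets2)
        set_results = cs.evaluate_sets(geoms[0], geoms[1], p1, p2, transform)
    _log(opt.quiet, label, "metrics", t0)

    return PairOutput(
        label=label,
        geometry1=geoms[0],
        geometry2=geoms[1],
        transform=transform,
        history=history,
        result=result,
        set_results=set_results,
    )


def run_pair(spec: PairSpec) -> PairOutput:
    """Load both images of a pair from disk and run the pipeline."""
    try:
        raw1 = wio.load_image(spec.path1)
        raw2 = wio.load_image(spec.path2)
        return analyze_pair(raw1, raw2, spec.options, label=spec.label)
    except ValidationError as exc:
        raise ValidationError(f"pair {spec.label!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def cell_table(geom: wseg.WingGeometry) -> pd.DataFrame:
    """Per-cell metric table for one wing."""
    rows = [
        {
            "cell_id": c.cell_id,
            "centroid_row": c.centroid[0],
            "centroid_col": c.centroid[1],
            "area": c.area,
            "length": c.length,
            "width": c.width,
            "circularity": c.circularity,
            "perimeter": c.perimeter,
        }
        for c in geom.cells
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id", "centroid_row", "centroid_col", "area", "length",
            "width", "circularity", "perimeter",
        ],
    )


def wing_summary_table(geom: wseg.WingGeometry) -> pd.DataFrame:
    """Whole-wing summary for one wing."""
    return pd.DataFrame(
        [
            {
                "n_cells": geom.n_cells,
                "n_junctions": geom.n_junctions,
                "wing_area": geom.wing_area,
                "wing_length": geom.wing_length,
                "wing_width": geom.wing_width,
                "wing_perimeter": geom.wing_perimeter,
                "scale": geom.scale if geom.scale is not None else 1.0,
            }
        ]
    )


def comparison_table(result: wm.PairResult, direction: int) -> pd.DataFrame:
    """Regression + NRMSE rows for one reference direction."""
    rows = [
        {
            "metric": name,
            "slope": st.slope,
            "intercept": st.intercept,
            "r2": st.r2,
            "nrmse": st.nrmse,
        }
        for name, st in result.comparisons[direction].items()
    ]
    return pd.DataFrame(rows, columns=["metric", "slope", "intercept", "r2", "nrmse"])


def summary_table(result: wm.PairResult) -> pd.DataFrame:
    """Distances, deltas and the transform, one quantity per row."""
    rows = []
    for cat, (mean, sd) in result.distances.items():
        rows.append({"quantity": f"{cat}_distance_mean", "value": mean})
        rows.append({"quantity": f"{cat}_distance_sd", "value": sd})
    for key in (
        "delta_n_cells", "delta_n_junctions", "delta_wing_area",
        "delta_wing_length", "delta_wing_width", "delta_wing_perimeter",
        "n_cells_1", "n_cells_2",
    ):
        rows.append({"quantity": key, "value": getattr(result, key)})
    if result.transform is not None:
        rows.append({"quantity": "transform_x", "value": result.transform.x})
        rows.append({"quantity": "transform_y", "value": result.transform.y})
        rows.append(
            {
                "quantity": "transform_theta_degrees",
                "value": float(np.rad2deg(result.transform.theta)),
            }
        )
    return pd.DataFrame(rows, columns=["quantity", "value"])


def sets_table(set_results: list[cs.SetResult]) -> pd.DataFrame:
    """Long-format per-set comparison table."""
    rows = []
    for sr in set_results:
        for direction, block in sr.comparisons.items():
            for metric, st in block.items():
                rows.append(
                    {
                        "set_label": sr.label,
                        "direction": direction,
                        "metric": metric,
                        "slope": st.slope,
                        "intercept": st.intercept,
                        "r2": st.r2,
                        "nrmse": st.nrmse,
                        "set_area_1": sr.set_area_1,
                        "set_area_2": sr.set_area_2,
                        "centroid_mean": sr.centroid_mean,
                        "centroid_sd": sr.centroid_sd,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "set_label", "direction", "metric", "slope", "intercept", "r2",
            "nrmse", "set_area_1", "set_area_2", "centroid_mean", "centroid_sd",
        ],
    )


def aggregate(outputs: list[PairOutput]) -> dict[str, pd.DataFrame]:
    """Cross-pair long-format tables plus min/median/max summary stats."""
    if not outputs:
        raise ValidationError("no evaluated pairs to aggregate")
    pair_rows = []
    set_rows = []
    for out in outputs:
        res = out.result
        dist = {
            f"{cat}_{stat}": val
            for cat, (mean, sd) in res.distances.items()
            for stat, val in (("mean", mean), ("sd", sd))
        }
        for direction, block in res.comparisons.items():
            for metric, st in block.items():
                pair_rows.append(
                    {
                        "pair": out.label,
                        "direction": direction,
                        "metric": metric,
                        "r2": st.r2,
                        "slope": st.slope,
                        "nrmse": st.nrmse,
                        **dist,
                        "delta_n_cells": res.delta_n_cells,
                        "delta_n_junctions": res.delta_n_junctions,
                        "delta_wing_area": res.delta_wing_area,
                    }
                )
        st_df = sets_table(out.set_results)
        if len(st_df):
            st_df.insert(0, "pair", out.label)
            set_rows.append(st_df)
    pairs_df = pd.DataFrame(pair_rows)
    sets_df = (
        pd.concat(set_rows, ignore_index=True) if set_rows else pd.DataFrame()
    )
    numeric = pairs_df.select_dtypes("number")
    summary = pd.DataFrame(
        {"min": numeric.min(), "median": numeric.median(), "max": numeric.max()}
    )
    return {"pairs": pairs_df, "sets": sets_df, "summary": summary}


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_reports(
    outputs: list[PairOutput],
    out_dir: str | Path,
    formats: tuple[str, ...] = ("csv", "txt"),
) -> list[Path]:
    """Write per-pair and cross-pair report files; returns the paths written.

    Per pair: wing specification tables (cells + summary for each wing),
    comparison tables for each reference direction, a distances/deltas
    summary, a per-set table when sets were analyzed, and a TXT rendering of
    the same.  Output is byte-stable for identical inputs and seed.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create report directory {out_dir}: {exc}") from exc
    written: list[Path] = []
    for out in outputs:
        base = f"pair_{out.label}"
        if "csv" in formats:
            files = {
                f"{base}_wing1.csv": cell_table(out.geometry1),
                f"{base}_wing1_summary.csv": wing_summary_table(out.geometry1),
                f"{base}_wing2.csv": cell_table(out.geometry2),
                f"{base}_wing2_summary.csv": wing_summary_table(out.geometry2),
                f"{base}_compare_ref1.csv": comparison_table(out.result, 1),
                f"{base}_compare_ref2.csv": comparison_table(out.result, 2),
                f"{base}_summary.csv": summary_table(out.result),
            }
            if out.set_results:
                files[f"{base}_sets.csv"] = sets_table(out.set_results)
            for name, df in files.items():
                path = out_dir / name
                _write_csv(df, path)
                written.append(path)
        if "txt" in formats:
            path = out_dir / f"{base}_report.txt"
            path.write_text(render_txt(out))
            written.append(path)
    if outputs and "csv" in formats:
        agg = aggregate(outputs)
        path = out_dir / "aggregate_pairs.csv"
        _write_csv(agg["pairs"], path)
        written.append(path)
        if len(agg["sets"]):
            path = out_dir / "aggregate_sets.csv"
            _write_csv(agg["sets"], path)
            written.append(path)
    return written


def render_txt(out: PairOutput) -> str:
    """Human-readable report block for one pair."""
    lines = [f"Wing pair: {out.label}", "=" * (11 + len(out.label)), ""]
    for idx, geom in ((1, out.geometry1), (2, out.geometry2)):
        lines.append(
            f"Wing {idx}: {geom.n_cells} cells, {geom.n_junctions} junctions, "
            f"area {geom.wing_area:.6g}, length {geom.wing_length:.6g}, "
            f"width {geom.wing_width:.6g}, perimeter {geom.wing_perimeter:.6g}"
        )
    t = out.transform
    lines.append(
        f"Superimposition: x={t.x:.6g} y={t.y:.6g} "
        f"theta={np.rad2deg(t.theta):.6g} deg"
    )
    lines.append("")
    for direction in (1, 2):
        lines.append(f"Reference: wing {direction}")
        for metric, st in out.result.comparisons[direction].items():
            lines.append(
                f"  {metric:<12} slope={st.slope:.6g} intercept={st.intercept:.6g}"
                f" r2={st.r2:.6g} nrmse={st.nrmse:.6g}"
            )
    lines.append("")
    for cat, (mean, sd) in out.result.distances.items():
        lines.append(f"{cat} distance: mean={mean:.6g} sd={sd:.6g}")
    lines.append(
        f"delta cells={out.result.delta_n_cells} "
        f"delta junctions={out.result.delta_n_junctions} "
        f"delta wing area={out.result.delta_wing_area:.6g}"
    )
    for sr in out.set_results:
        lines.append("")
        lines.append(
            f"{sr.label}: areas {sr.set_area_1:.6g} vs {sr.set_area_2:.6g}, "
            f"centroid distance mean={sr.centroid_mean:.6g} sd={sr.centroid_sd:.6g}"
        )
        for direction, block in sr.comparisons.items():
            for metric, st in block.items():
                lines.append(
                    f"  ref{direction} {metric:<12} r2={st.r2:.6g} "
                    f"nrmse={st.nrmse:.6g}"
                )
    lines.append("")
    return "\n".join(lines)


def read_pair_result(out_dir: str | Path, label: str) -> wm.PairResult:
    """Reconstruct a :class:`PairResult` from its written CSV reports."""
    out_dir = Path(out_dir)
    base = f"pair_{label}"
    result = wm.PairResult()
    for direction in (1, 2):
        df = pd.read_csv(out_dir / f"{base}_compare_ref{direction}.csv")
        result.comparisons[direction] = {
            row["metric"]: wm.ComparisonStats(
                slope=row["slope"],
                intercept=row["intercept"],
                r2=row["r2"],
                nrmse=row["nrmse"],
            )
            for _, row in df.iterrows()
        }
    summary = pd.read_csv(out_dir / f"{base}_summary.csv")
    values = dict(zip(summary["quantity"], summary["value"]))
    for cat in ("centroid", "junction", "outline"):
        if f"{cat}_distance_mean" in values:
            result.distances[cat] = (
                float(values[f"{cat}_distance_mean"]),
                float(values[f"{cat}_distance_sd"]),
            )
    for key in (
        "delta_n_cells", "delta_n_junctions", "n_cells_1", "n_cells_2",
    ):
        setattr(result, key, int(values[key]))
    for key in (
        "delta_wing_area", "delta_wing_length", "delta_wing_width",
        "delta_wing_perimeter",
    ):
        setattr(result, key, float(values[key]))
    if "transform_x" in values:
        result.transform = wsup.RigidTransform(
            x=float(values["transform_x"]),
            y=float(values["transform_y"]),
            theta=float(np.deg2rad(values["transform_theta_degrees"])),
        )
    return result
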