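"""Rigid transforms, outline objective, PSO alignment and matching."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

import wingasym as wa
from wingasym.errors import ValidationError
from wingasym.superimpose import (
    outline_centroid,
    outline_nearest_distances,
    resample_closed,
    transform_points,
)

from conftest import exhaustive_nearest


class TestApplyTransform:
    def test_identity_leaves_geometry_unchanged(self, wing_geometry):
        out = wa.apply_transform(wing_geometry, wa.RigidTransform())
        assert np.allclose(out.outline, wing_geometry.outline)
        assert np.allclose(out.cell_centroids(), wing_geometry.cell_centroids())

    def test_full_turn_is_identity(self, wing_geometry):
        out = wa.apply_transform(
            wing_geometry, wa.RigidTransform(theta=2 * np.pi)
        )
        assert np.allclose(out.outline, wing_geometry.outline, atol=1e-9)

    def test_translation_inverse(self, wing_geometry):
        fwd = wa.apply_transform(wing_geometry, wa.RigidTransform(x=3, y=-2))
        back = wa.apply_transform(fwd, wa.RigidTransform(x=-3, y=2))
        assert np.allclose(back.outline, wing_geometry.outline, atol=1e-9)

    def test_metrics_unchanged(self, wing_geometry):
        out = wa.apply_transform(
            wing_geometry, wa.RigidTransform(x=5, y=7, theta=0.3)
        )
        assert out.wing_area == wing_geometry.wing_area
        assert [c.area for c in out.cells] == [c.area for c in wing_geometry.cells]
        assert [c.circularity for c in out.cells] == [
            c.circularity for c in wing_geometry.cells
        ]


class TestOutlineObjective:
    def test_identical_outlines_score_zero(self, wing_geometry):
        assert wa.outline_objective(
            wing_geometry, wing_geometry, wa.RigidTransform()
        ) == 0.0

    def test_translation_bounded_by_shift(self, wing_geometry):
        d = np.hypot(4.0, 3.0)
        obj = wa.outline_objective(
            wing_geometry, wing_geometry, wa.RigidTransform(x=4, y=3)
        )
        assert 0 < obj <= d + 1e-9

    def test_matches_brute_force_all_pairs(self):
        """Objective equals an exhaustive nearest-point computation on the
        same resampled points, for random simple polygons."""
        rng = np.random.default_rng(12)
        for _ in range(20):
            # star-convex random polygon: guaranteed simple
            n = rng.integers(6, 16)
            ang = np.sort(rng.uniform(0, 2 * np.pi, n))
            rad = rng.uniform(20, 60, n)
            p1 = np.column_stack([50 + rad * np.sin(ang), 50 + rad * np.cos(ang)])
            rad2 = rng.uniform(20, 60, n)
            p2 = np.column_stack([50 + rad2 * np.sin(ang), 50 + rad2 * np.cos(ang)])
            g1 = wa.WingGeometry(cells=[], outline=p1)
            g2 = wa.WingGeometry(cells=[], outline=p2)
            t = wa.RigidTransform(
                x=rng.uniform(-5, 5), y=rng.uniform(-5, 5), theta=rng.uniform(-0.3, 0.3)
            )
            r1 = resample_closed(p1, 200)
            r2 = transform_points(resample_closed(p2, 200), t, outline_centroid(g2))
            brute = np.sqrt(((r2[:, None] - r1[None]) ** 2).sum(-1)).min(1).mean()
            assert wa.outline_objective(g1, g2, t) == pytest.approx(brute, rel=1e-12)

    def test_degenerate_outline_rejected(self):
        g = wa.WingGeometry(cells=[], outline=np.array([[0.0, 0.0], [1.0, 1.0]]))
        with pytest.raises(ValidationError):
            wa.outline_objective(g, g, wa.RigidTransform())


class TestAlignCentroids:
    def test_identical_wings_need_no_shift(self, wing_geometry):
        t = wa.align_centroids(wing_geometry, wing_geometry)
        assert t.as_tuple() == (0.0, 0.0, 0.0)

    def test_offset_recovered_and_centroids_coincide(self, wing_geometry):
        moved = wa.apply_transform(wing_geometry, wa.RigidTransform(x=10, y=5))
        t = wa.align_centroids(wing_geometry, moved)
        assert t.x == pytest.approx(-10) and t.y == pytest.approx(-5)
        aligned = wa.apply_transform(moved, t)
        assert np.allclose(
            outline_centroid(aligned), outline_centroid(wing_geometry), atol=1e-9
        )


class TestPSO:
    def test_self_alignment_converges(self, wing_geometry):
        t, history = wa.pso_superimpose(
            wing_geometry, wing_geometry, wa.PSOConfig(seed=0)
        )
        assert history[-1] < 0.5
        assert len(history) == 40

    def test_history_non_increasing_and_reproducible(self, wing_geometry):
        moved = wa.apply_transform(
            wing_geometry, wa.RigidTransform(x=9, y=-4, theta=0.05)
        )
        t1, h1 = wa.pso_superimpose(wing_geometry, moved, wa.PSOConfig(seed=7))
        t2, h2 = wa.pso_superimpose(wing_geometry, moved, wa.PSOConfig(seed=7))
        assert np.all(np.diff(h1) <= 0)
        assert t1 == t2 and np.array_equal(h1, h2)

    def test_known_offset_recovered(self, wing_geometry):
        """A 12 px / 6 degree offset is undone to within 1 degree and a 2 px
        mean outline residual."""
        t_true = wa.RigidTransform(x=12, y=-7, theta=np.deg2rad(6))
        moving = wa.apply_transform(wing_geometry, t_true)
        rec, _ = wa.pso_superimpose(wing_geometry, moving, wa.PSOConfig(seed=1))
        assert abs(np.rad2deg(rec.theta + t_true.theta)) < 1.0
        realigned = wa.apply_transform(moving, rec)
        resid = outline_nearest_distances(
            resample_closed(wing_geometry.outline, 200),
            resample_closed(realigned.outline, 200),
        )
        assert resid.mean() < 2.0

    def test_resampling_density_improves_recovery(self, wing_geometry):
        """Median residual decreases (or stays) when the outline resampling
        is refined from 200 to 400 points."""
        rng = np.random.default_rng(5)
        residuals = {200: [], 400: []}
        for s in range(6):
            t_true = wa.RigidTransform(
                x=rng.uniform(-12, 12), y=rng.uniform(-12, 12),
                theta=np.deg2rad(rng.uniform(-8, 8)),
            )
            moving = wa.apply_transform(wing_geometry, t_true)
            for n in (200, 400):
                rec, _ = wa.pso_superimpose(
                    wing_geometry, moving, wa.PSOConfig(seed=s), n_points=n
                )
                realigned = wa.apply_transform(moving, rec)
                d = outline_nearest_distances(
                    resample_closed(wing_geometry.outline, 400),
                    resample_closed(realigned.outline, 400),
                )
                residuals[n].append(d.mean())
        assert np.median(residuals[400]) <= np.median(residuals[200]) + 0.05

    def test_invalid_bounds_rejected(self, wing_geometry):
        cfg = wa.PSOConfig(seed=0, bounds=((1, 1), (0, 1), (0, 1)))
        with pytest.raises(ValidationError):
            wa.pso_superimpose(wing_geometry, wing_geometry, cfg)


class TestMatching:
    def test_self_match_is_identity_with_zero_distance(self, wing_geometry):
        corr = wa.match_cells(wing_geometry, wing_geometry)
        assert len(corr.cell_pairs) == wing_geometry.n_cells
        for i, j, d in corr.cell_pairs:
            assert i == j and d == 0.0

    def test_every_reference_cell_matched_once(self, wing_geometry):
        moved = wa.apply_transform(wing_geometry, wa.RigidTransform(x=2, y=1))
        corr = wa.match_cells(wing_geometry, moved)
        ref_ids = [i for i, _, _ in corr.cell_pairs]
        assert sorted(ref_ids) == sorted(c.cell_id for c in wing_geometry.cells)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_exhaustive_nearest_neighbor(self, trial):
        rng = np.random.default_rng(trial)
        n, m = rng.integers(5, 40, size=2)
        ref = rng.uniform(0, 100, size=(n, 2))
        tgt = rng.uniform(0, 100, size=(m, 2))

        def geom_from(points):
            cells = [
                wa.CellRegion(
                    cell_id=k, interior_pixels=np.zeros((1, 2), int),
                    boundary_pixels=np.zeros((0, 2), int),
                    centroid=tuple(p), area=1, length=1, width=1,
                    circularity=1, perimeter=1,
                )
                for k, p in enumerate(points)
            ]
            return wa.WingGeometry(cells=cells, outline=np.zeros((3, 2)))

        corr = wa.match_cells(geom_from(ref), geom_from(tgt))
        oracle = exhaustive_nearest(ref, tgt)
        assert len(corr.cell_pairs) == len(oracle)
        for (i, j, d), (oi, oj, od) in zip(corr.cell_pairs, oracle):
            assert i == oi and d == pytest.approx(od)
            # ties may break differently; the distance must agree exactly
            if d != od or j != oj:
                assert np.isclose(
                    np.sqrt(((tgt[j] - ref[i]) ** 2).sum()), od
                )

    def test_empty_target_warns(self, wing_geometry):
        empty = wa.WingGeometry(cells=[], outline=wing_geometry.outline)
        with pytest.warns(UserWarning, match="no cells"):
            corr = wa.match_cells(wing_geometry, empty)
        assert corr.cell_pairs == []
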