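"""Regular-grid fitting, iterative refinement, node enumeration."""

import numpy as np
import pytest

import spotgrid as sg
from spotgrid.gridfit import (
    GridFitError,
    GridModel,
    enumerate_nodes,
    fit_regular_grid,
    iterative_refine,
)


def _lattice(n_cols=33, n_rows=35, pitch=14.0, origin=(50.0, 60.0),
             rotation_deg=0.0, jitter_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    cc, rr = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    cc, rr = cc.ravel().astype(float), rr.ravel().astype(float)
    t = np.radians(rotation_deg)
    x = origin[0] + np.cos(t) * cc * pitch - np.sin(t) * rr * pitch
    y = origin[1] + np.sin(t) * cc * pitch + np.cos(t) * rr * pitch
    if jitter_sd > 0:
        x = x + rng.normal(0, jitter_sd, x.shape)
        y = y + rng.normal(0, jitter_sd, y.shape)
    return np.column_stack([x, y])


class TestFitRegularGrid:
    def test_noiseless_lattice_recovered_exactly(self):
        fit = fit_regular_grid(_lattice())
        assert fit.model.pitch[0] == pytest.approx(14.0, abs=1e-6)
        assert fit.model.pitch[1] == pytest.approx(14.0, abs=1e-6)
        assert fit.model.rotation_deg == pytest.approx(0.0, abs=1e-6)
        assert fit.residuals.max() < 1e-6
        assert (fit.model.n_cols, fit.model.n_rows) == (33, 35)

    def test_rotated_jittered_lattice_recovered(self):
        fit = fit_regular_grid(_lattice(rotation_deg=2.0, jitter_sd=0.5, seed=1))
        assert fit.model.rotation_deg == pytest.approx(2.0, abs=0.2)
        assert fit.model.pitch[0] == pytest.approx(14.0, rel=0.01)
        assert fit.model.pitch[1] == pytest.approx(14.0, rel=0.01)

    def test_fit_beats_ground_truth_grid_with_outliers(self):
        rng = np.random.default_rng(7)
        lattice = _lattice(jitter_sd=0.3, seed=2)
        outliers = rng.uniform(50, 450, (115, 2))
        pts = np.vstack([lattice, outliers])
        fit = fit_regular_grid(pts)
        truth_model = GridModel(
            origin=(50.0, 60.0), pitch=(14.0, 14.0), rotation_deg=0.0,
            n_cols=33, n_rows=35,
        )
        _, _, nodes = truth_model.all_nodes()
        from scipy.spatial import cKDTree

        d, _ = cKDTree(nodes).query(pts)
        truth_obj = float(np.sum(d**2))
        assert fit.objective < truth_obj

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(20.0) * 14, np.zeros(20)])
        with pytest.raises(GridFitError, match="collinear"):
            fit_regular_grid(pts)

    def test_translation_equivariance(self):
        pts = _lattice(jitter_sd=0.2, seed=3)
        f0 = fit_regular_grid(pts)
        f1 = fit_regular_grid(pts + [31.0, -17.0])
        assert np.allclose(
            np.asarray(f1.model.origin) - np.asarray(f0.model.origin),
            [31.0, -17.0],
            atol=1e-6,
        )
        assert np.allclose(f0.model.pitch, f1.model.pitch, atol=1e-6)
        assert f0.model.rotation_deg == pytest.approx(
            f1.model.rotation_deg, abs=1e-6
        )


class TestIterativeRefine:
    def test_clean_lattice_terminates_without_removal(self):
        fit = iterative_refine(fit_regular_grid(_lattice()))
        assert len(fit.points) == 33 * 35
        assert (fit.model.n_cols, fit.model.n_rows) == (33, 35)

    def test_spurious_exterior_point_removed(self):
        pts = np.vstack([_lattice(), [[50.0 + 33 * 14.0, 60.0 + 17 * 14.0]]])
        rough = fit_regular_grid(pts)
        assert rough.model.n_cols == 34
        fit = iterative_refine(rough)
        assert (fit.model.n_cols, fit.model.n_rows) == (33, 35)
        # the exterior point is gone
        assert not np.any(
            np.all(np.isclose(fit.points, [50.0 + 33 * 14.0, 60.0 + 17 * 14.0]), axis=1)
        )

    def test_removal_count_ceiling_arithmetic(self):
        # N = 1156 points -> ceil(0.001 * 1156) = 2 removed per iteration
        pts = np.vstack([_lattice(), [[50.0 + 33 * 14.0, 60.0 + 17 * 14.0]]])
        fit = iterative_refine(fit_regular_grid(pts))
        drops = [
            fit.iteration_log[i - 1].n_points - fit.iteration_log[i].n_points
            for i in range(1, len(fit.iteration_log))
            if fit.iteration_log[i - 1].n_points != fit.iteration_log[i].n_points
        ]
        assert drops and all(d == 2 for d in drops)

    def test_unreachable_targets_raise_with_log(self):
        pts = _lattice(n_cols=5, n_rows=5)
        with pytest.raises(GridFitError, match="unreachable") as exc:
            iterative_refine(fit_regular_grid(pts))
        assert len(exc.value.iteration_log) >= 1

    def test_objective_monotone_across_refits(self):
        rng = np.random.default_rng(5)
        pts = np.vstack(
            [_lattice(jitter_sd=0.4, seed=4), rng.uniform(60, 440, (60, 2))]
        )
        fit = iterative_refine(fit_regular_grid(pts))
        objs = [r.objective for r in fit.iteration_log[1:]]
        assert all(b <= a * (1 + 1e-9) for a, b in zip(objs, objs[1:]))

    def test_parameter_recovery_with_jitter_and_outliers(self):
        # jitter 5% of pitch, 10% outliers: every true node recovered
        # within half a pitch
        rng = np.random.default_rng(11)
        lattice = _lattice(jitter_sd=0.7, seed=6)
        outliers = rng.uniform(50, 450, (115, 2))
        fit = iterative_refine(fit_regular_grid(np.vstack([lattice, outliers])))
        nodes = enumerate_nodes(fit.model)
        truth = _lattice()  # jitter-free true centers
        score = sg.score_recovery(
            nodes.rename(columns={"pixel_x": "pixel_x", "pixel_y": "pixel_y"}),
            truth,
            match_radius_px=7.0,
        )
        assert score.fn_rate == 0.0
        assert score.fp_rate == 0.0


class TestEnumerateNodes:
    def test_full_node_set(self):
        model = GridModel((10.0, 20.0), (14.0, 14.0), 0.0, 33, 35)
        nodes = enumerate_nodes(model)
        assert len(nodes) == 1155
        first = nodes[(nodes.x == 1) & (nodes.y == 1)].iloc[0]
        assert (first.pixel_x, first.pixel_y) == (10.0, 20.0)

    def test_neighbor_spacing_equals_pitch(self):
        model = GridModel((0.0, 0.0), (14.0, 15.0), 3.0, 33, 35)
        a = model.node(1, 1)
        b = model.node(2, 1)
        c = model.node(1, 2)
        assert np.linalg.norm(b - a) == pytest.approx(14.0, abs=1e-9)
        assert np.linalg.norm(c - a) == pytest.approx(15.0, abs=1e-9)
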