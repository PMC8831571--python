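"""Generator correctness: rendering, ground truth, scoring, fixtures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spotgrid as sg
from spotgrid.synthetic import (
    ArtifactConfig,
    artifact_region_mask,
    render_array_image,
    score_recovery,
    w_profile,
)


class TestRender:
    def test_lattice_cardinality(self, clean_render):
        _, truth = clean_render
        assert len(truth.true_spot_centers) == 33 * 35

    def test_rotation_matches_rotation_matrix(self):
        _, t0 = render_array_image(seed=1)
        _, t2 = render_array_image(seed=1, rotation_deg=2.0)
        p0 = t0.true_spot_centers[["x_px", "y_px"]].to_numpy()
        p2 = t2.true_spot_centers[["x_px", "y_px"]].to_numpy()
        # apply the stated rotation to the unrotated lattice independently
        th = np.radians(2.0)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        c = p0.mean(axis=0)
        expected = (p0 - c) @ rot.T
        expected -= expected.min(axis=0)
        observed = p2 - p2.min(axis=0)
        assert np.allclose(observed, expected, atol=1e-9)

    def test_bubble_region_area(self):
        art = ArtifactConfig(n_bubbles=1, bubble_radius_px=(10.0, 10.0))
        img, truth = render_array_image(artifacts=art, seed=3)
        bubbles = [a for a in truth.artifact_inventory if a[0] == "bubble"]
        assert len(bubbles) == 1
        mask = artifact_region_mask(*bubbles[0], img.pixels.shape[:2])
        assert mask.sum() == pytest.approx(np.pi * 100, rel=0.05)

    def test_bit_identical_under_fixed_seed(self):
        art = ArtifactConfig(tissue=True, coloration=True, n_smears=1, n_bubbles=1)
        img1, t1 = render_array_image(artifacts=art, seed=9)
        img2, t2 = render_array_image(artifacts=art, seed=9)
        assert np.array_equal(img1.pixels, img2.pixels)
        assert t1.true_spot_centers.equals(t2.true_spot_centers)

    def test_forced_canvas_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            render_array_image(seed=1, canvas_shape=(100, 100))

    def test_ground_truth_json_round_trip(self, tmp_path):
        art = ArtifactConfig(tissue=True, n_bubbles=1)
        _, truth = render_array_image(artifacts=art, seed=4)
        truth.to_json(tmp_path / "gt.json")
        back = sg.SyntheticGroundTruth.from_json(tmp_path / "gt.json")
        assert back.true_spot_centers.astype(float).equals(
            truth.true_spot_centers.astype(float)
        )
        assert np.allclose(back.tissue_polygon, truth.tissue_polygon)
        assert back.seed == truth.seed


class TestScoreRecovery:
    def _truth_points(self, n=1000, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 2000, (n, 2))
        return pts

    def test_identity_scores_zero(self, clean_render):
        _, truth = clean_render
        pts = truth.true_spot_centers[["x_px", "y_px"]].to_numpy()
        score = score_recovery(pts, truth)
        assert (score.fp_rate, score.fn_rate) == (0.0, 0.0)

    def test_missing_ten_of_thousand(self):
        tru = self._truth_points(1000)
        score = score_recovery(tru[:-10], tru, match_radius_px=1.0)
        assert score.fn_rate == pytest.approx(1.0)
        assert score.fp_rate == 0.0

    def test_five_spurious_reports(self):
        tru = self._truth_points(1000)
        far = np.array([[1e5 + i, 1e5] for i in range(5)])
        score = score_recovery(np.vstack([tru, far]), tru, match_radius_px=1.0)
        assert score.fp_rate == pytest.approx(100 * 5 / 1005)
        assert score.fn_rate == 0.0

    def test_empty_reported(self):
        tru = self._truth_points(50)
        score = score_recovery(np.empty((0, 2)), tru, match_radius_px=5.0)
        assert (score.fp_rate, score.fn_rate) == (0.0, 100.0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        st.floats(min_value=-1e4, max_value=1e4),
        st.floats(min_value=-1e4, max_value=1e4),
    )
    def test_translation_invariance(self, dx, dy):
        tru = self._truth_points(200, seed=3)
        rep = tru[:-7]
        s0 = score_recovery(rep, tru, match_radius_px=2.0)
        s1 = score_recovery(rep + [dx, dy], tru + [dx, dy], match_radius_px=2.0)
        assert (s0.fp_rate, s0.fn_rate) == (s1.fp_rate, s1.fn_rate)


class TestSimulateExpression:
    def test_no_tissue_gives_all_zero_matrix(self, clean_render):
        _, truth = clean_render
        mat = sg.simulate_expression(sg.DEFAULT_DESIGN, truth, 100.0, seed=1)
        assert (mat.to_numpy() == 0).all()

    def test_under_tissue_mean_total(self, tissue_render):
        _, truth = tissue_render
        mat = sg.simulate_expression(sg.DEFAULT_DESIGN, truth, 100.0, seed=2)
        under = truth.under_tissue_nodes()
        totals = mat.to_numpy().sum(axis=1)
        assert (totals[~under] == 0).all()
        assert (totals[under] > 0).all()
        se = np.sqrt(100.0 / under.sum())
        assert abs(totals[under].mean() - 100.0) < 3 * se

    def test_seed_determinism(self, tissue_render):
        _, truth = tissue_render
        a = sg.simulate_expression(sg.DEFAULT_DESIGN, truth, 50.0, seed=5)
        b = sg.simulate_expression(sg.DEFAULT_DESIGN, truth, 50.0, seed=5)
        assert a.equals(b)


class TestLineProfiles:
    def test_seed_determinism(self):
        a = sg.simulate_line_profiles(3.0, 2, 0.05, seed=8)
        b = sg.simulate_line_profiles(3.0, 2, 0.05, seed=8)
        for (n1, f1), (n2, f2) in zip(a, b):
            assert np.array_equal(n1.intensities, n2.intensities)
            assert np.array_equal(f1.intensities, f2.intensities)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(min_value=6.0, max_value=25.0))
    def test_w_profile_minima_sit_at_boundaries(self, hw):
        pos = np.linspace(0, 80, 161)
        vals = w_profile(pos, 40 - hw, 40.0, 40 + hw)
        # boundary samples are local minima of the sampled curve
        for b in (40 - hw, 40 + hw):
            i = int(np.argmin(np.abs(pos - b)))
            lo = max(0, i - 4)
            assert vals[lo : i + 5].min() == pytest.approx(
                vals[i], abs=0.02
            )
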