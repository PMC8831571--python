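"""Saturation model: thinning, Lineweaver–Burk fit, read extrapolation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import spotgrid as sg
from spotgrid.saturation import (
    SaturationError,
    SaturationModel,
    SaturationPoint,
    curve_to_frame,
    downsample_counts,
    fit_saturation,
    reads_for_saturation,
    sample_curve,
)


@pytest.fixture(scope="module")
def copy_counts():
    """Per-molecule read multiplicities of a synthetic library."""
    rng = np.random.default_rng(42)
    return 1 + rng.poisson(2.0, 3000)


class TestDownsample:
    def test_full_fraction_is_identity(self, copy_counts):
        p = downsample_counts(copy_counts, 1.0)
        assert p.raw_reads == copy_counts.sum()
        assert p.unique_molecules == len(copy_counts)

    def test_out_of_range_fraction_rejected(self, copy_counts):
        for frac in (0.0, -0.5, 1.5):
            with pytest.raises((SaturationError, ValueError)):
                downsample_counts(copy_counts, frac)

    def test_closed_form_expectation(self, copy_counts):
        # E[unique] = sum_m (1 - (1-f)^{c_m}) under binomial thinning
        f = 0.5
        expected = np.sum(1 - (1 - f) ** copy_counts)
        var = np.sum((1 - (1 - f) ** copy_counts) * (1 - f) ** copy_counts)
        vals = [
            downsample_counts(copy_counts, f, seed=s).unique_molecules
            for s in range(25)
        ]
        se = np.sqrt(var / len(vals))
        assert abs(np.mean(vals) - expected) < 3 * se

    def test_seed_determinism(self, copy_counts):
        a = downsample_counts(copy_counts, 0.3, seed=7)
        b = downsample_counts(copy_counts, 0.3, seed=7)
        assert a == b


class TestFit:
    def test_noiseless_round_trip_identity(self):
        pts = [
            SaturationPoint(r, 20000 * r / (1e6 + r))
            for r in (1e5, 1e6, 1e7)
        ]
        fit = fit_saturation(pts)
        assert fit.model.v_max == pytest.approx(20000, rel=1e-6)
        assert fit.model.k_m == pytest.approx(1e6, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_noisy_recovery_within_five_percent(self):
        data = sg.simulate_saturation_data(
            20000, 1e6, [1e5, 3e5, 1e6, 3e6, 1e7], noise_sd=0.01, seed=3
        )
        pts = [SaturationPoint(r, s) for r, s in data]
        fit = fit_saturation(pts, nonlinear_refine=True)
        assert fit.model.v_max == pytest.approx(20000, rel=0.05)
        assert fit.model.k_m == pytest.approx(1e6, rel=0.05)

    def test_too_few_distinct_points_rejected(self):
        pts = [SaturationPoint(1e6, 9000)] * 3
        with pytest.raises(SaturationError):
            fit_saturation(pts)

    def test_non_saturating_data_rejected(self):
        # superlinear growth: 1/S vs 1/R has negative slope
        pts = [SaturationPoint(r, r**1.5 / 1e3) for r in (1e4, 1e5, 1e6)]
        with pytest.raises(SaturationError, match="saturating"):
            fit_saturation(pts)

    def test_summary_mentions_parameters(self):
        pts = [SaturationPoint(r, 20000 * r / (1e6 + r)) for r in (1e5, 1e6, 1e7)]
        text = fit_saturation(pts).summary()
        assert "V_max" in text and "K_M" in text


class TestReadsForSaturation:
    def test_half_saturation_needs_km_reads(self):
        model = SaturationModel(20000, 1e6)
        assert reads_for_saturation(model, 10000) == pytest.approx(1e6)

    def test_worked_example(self):
        model = SaturationModel(15000, 2e6)
        assert reads_for_saturation(model, 12000) == pytest.approx(8e6)

    def test_target_at_or_above_vmax_rejected(self):
        model = SaturationModel(15000, 2e6)
        for bad in (15000, 20000):
            with pytest.raises(SaturationError, match="unreachable"):
                reads_for_saturation(model, bad)

    def test_small_target_needs_few_reads(self):
        model = SaturationModel(15000, 2e6)
        assert reads_for_saturation(model, 1e-6) < 1.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.floats(min_value=1.0, max_value=14000.0),
        st.floats(min_value=1.0, max_value=999.0),
    )
    def test_strictly_increasing_in_target(self, s, delta):
        model = SaturationModel(15000, 2e6)
        assert reads_for_saturation(model, s + delta) > reads_for_saturation(
            model, s
        )


class TestSampleCurve:
    def test_nine_points_by_default(self, copy_counts):
        pts = sample_curve(copy_counts, seed=5)
        assert len(pts) == 9

    def test_monotone_in_fraction(self, copy_counts):
        pts = sample_curve(copy_counts, seed=5)
        mols = [p.unique_molecules for p in pts]
        # non-decreasing within sampling error: allow tiny inversions
        assert all(b >= a - 2 for a, b in zip(mols, mols[1:]))

    def test_full_fraction_endpoint_matches_library(self, copy_counts):
        pts = sample_curve(copy_counts, seed=5)
        assert pts[-1].fraction == 1.0
        assert pts[-1].raw_reads == copy_counts.sum()
        assert pts[-1].unique_molecules == len(copy_counts)

    def test_matrix_mode_counts_genes(self, tissue_render):
        _, truth = tissue_render
        mat = sg.simulate_expression(sg.DEFAULT_DESIGN, truth, 100.0, seed=3)
        pts = sample_curve(mat, seed=6)
        frame = curve_to_frame(pts)
        assert frame["unique_genes"].iloc[-1] == (mat.sum(axis=0) > 0).sum()
        assert frame["raw_reads"].iloc[-1] == mat.to_numpy().sum()


class TestSimulatedData:
    def test_half_saturation_identity(self):
        (r, s), = sg.simulate_saturation_data(20000, 1e6, [1e6], 0.0, 0)
        assert s == pytest.approx(10000)

    def test_asymptote(self):
        (_, s), = sg.simulate_saturation_data(20000, 1e6, [1e12], 0.0, 0)
        assert s == pytest.approx(20000, rel=1e-4)

    def test_worked_hyperbola_point(self):
        (_, s), = sg.simulate_saturation_data(20000, 1e6, [3e6], 0.0, 0)
        assert s == pytest.approx(15000)

    def test_noiseless_curve_fits_back_exactly(self):
        data = sg.simulate_saturation_data(
            8000, 5e5, [1e5, 5e5, 2e6, 1e7], 0.0, 0
        )
        fit = fit_saturation([SaturationPoint(r, s) for r, s in data])
        assert fit.model.v_max == pytest.approx(8000, rel=1e-9)
        assert fit.model.k_m == pytest.approx(5e5, rel=1e-9)
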