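"""Angular coverage, wrapping score, ring thickness and g-ratio."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pillarmyelin as pm
from pillarmyelin.errors import ValidationError
from pillarmyelin.wrapping import ScoreBins

EXPECTED_SCORE = {0.0: 0, 0.25: 1, 0.5: 2, 0.75: 2, 1.0: 3}


class TestAngularCoverage:
    def test_coverage_matches_truth_within_one_bin(self, clean_field, clean_grid,
                                                   clean_measurements):
        _, truth = clean_field
        merged = clean_measurements.merge(
            truth.to_frame()[["pillar_id", "coverage"]]
            .rename(columns={"coverage": "true_c"}), on="pillar_id")
        err = np.abs(merged["coverage"] - merged["true_c"])
        assert err.max() <= 1.0 / 72.0

    def test_gap_complements_single_arc(self, clean_field, clean_measurements):
        """One contiguous arc of fraction c leaves a gap of (1-c)*360°."""
        _, truth = clean_field
        merged = clean_measurements.merge(
            truth.to_frame()[["pillar_id", "coverage"]]
            .rename(columns={"coverage": "true_c"}), on="pillar_id")
        expect = (1.0 - merged["true_c"]) * 360.0
        assert np.abs(merged["max_gap_deg"] - expect).max() <= 360.0 / 72.0

    def test_out_of_bounds_annulus_rejected(self, clean_field):
        stack, _ = clean_field
        proj = pm.max_project(stack, "MBP", z_lo=4.0)
        with pytest.raises(ValidationError):
            pm.angular_coverage(proj, (1.0, 1.0), 3.0, 5.0)

    def test_split_arcs_still_sum_to_coverage(self):
        spec = pm.make_array_spec(5.0, 10.0, 22.0, 0.26, rows=1, cols=1)
        truth = pm.make_field_truth(spec, coverage=0.5, n_arcs=2, seed=1)
        stack, _ = pm.render_field(spec, truth, pm.NoiseModel.none(), seed=1)
        proj = pm.max_project(stack, "MBP", z_lo=4.0)
        r = spec.realized_diameter_um / 2
        c, gap = pm.angular_coverage(proj, tuple(truth.centers_um[0]),
                                     r, r + 2.0, threshold=0.5)
        assert c == pytest.approx(0.5, abs=2 / 72)
        assert gap <= 180.0  # split into two arcs, no half-circle gap remains


class TestScore:
    def test_score_classes_recovered_exactly(self, clean_field, clean_measurements):
        """Confusion matrix of measured vs truth-class scores is identity."""
        _, truth = clean_field
        merged = clean_measurements.merge(
            truth.to_frame()[["pillar_id", "coverage"]]
            .rename(columns={"coverage": "true_c"}), on="pillar_id")
        for _, row in merged.iterrows():
            assert row["score"] == EXPECTED_SCORE[row["true_c"]]

    @pytest.mark.parametrize("c,gap,expect", [
        (0.0, 360.0, 0),
        (0.04, 350.0, 0),
        (0.25, 270.0, 1),
        (0.5, 180.0, 2),
        (1.0, 0.0, 3),
        (0.96, 30.0, 2),   # near-full coverage but the ring does not close
        (0.96, 10.0, 3),
    ])
    def test_bin_rules(self, c, gap, expect):
        assert pm.assign_score(c, gap) == expect

    @settings(derandomize=True, max_examples=100)
    @given(c1=st.floats(0, 1), c2=st.floats(0, 1), gap=st.floats(0, 10))
    def test_monotone_in_coverage_at_fixed_gap(self, c1, c2, gap):
        lo, hi = sorted([c1, c2])
        assert pm.assign_score(lo, gap) <= pm.assign_score(hi, gap)

    def test_custom_edges_validated(self):
        with pytest.raises(ValidationError):
            ScoreBins(edges=(0.5, 0.4, 0.9))


class TestRingThickness:
    def test_recovers_rendered_thickness(self, clean_field, clean_grid,
                                         clean_measurements):
        _, truth = clean_field
        px = 0.25
        merged = clean_measurements.merge(
            truth.to_frame()[["pillar_id", "coverage", "thickness_um"]]
            .rename(columns={"coverage": "true_c", "thickness_um": "true_t"}),
            on="pillar_id")
        wrapped = merged[merged["true_c"] > 0]
        assert np.isfinite(wrapped["thickness_um"]).all()
        assert np.abs(wrapped["thickness_um"] - wrapped["true_t"]).max() <= px

    def test_unwrapped_pillar_thickness_undefined(self, clean_measurements,
                                                  clean_field):
        _, truth = clean_field
        merged = clean_measurements.merge(
            truth.to_frame()[["pillar_id", "coverage"]]
            .rename(columns={"coverage": "true_c"}), on="pillar_id")
        bare = merged[merged["true_c"] == 0]
        assert bare["thickness_um"].isna().all()
        assert bare["g_ratio"].isna().all()


class TestGRatio:
    def test_zero_thickness_identity(self):
        assert pm.g_ratio(5.0, 0.0) == 1.0

    @pytest.mark.parametrize("D,t,expect", [
        (5.0, 0.6646, 0.790),   # matches the 5 µm pillar estimate
        (3.0, 0.75, 0.667),     # matches the 3 µm pillar estimate
    ])
    def test_worked_values(self, D, t, expect):
        assert pm.g_ratio(D, t) == pytest.approx(expect, abs=5e-4)

    def test_negative_thickness_rejected(self):
        with pytest.raises(ValidationError):
            pm.g_ratio(5.0, -0.1)

    @settings(derandomize=True, max_examples=100)
    @given(D=st.floats(0.5, 20), g=st.floats(0.05, 1.0))
    def test_inversion_round_trip(self, D, g):
        t = pm.invert_g_ratio(D, g)
        assert pm.g_ratio(D, t) == pytest.approx(g, rel=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(D=st.floats(0.5, 20), t1=st.floats(0, 5), t2=st.floats(0, 5))
    def test_strictly_decreasing_in_thickness(self, D, t1, t2):
        lo, hi = sorted([t1, t2])
        if hi - lo > 1e-9 * D:  # resolvable at double precision
            assert pm.g_ratio(D, hi) < pm.g_ratio(D, lo)
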