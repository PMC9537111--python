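"""Unit and property tests for the circle-arc equating core."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from arcequate import (AnchorTriplet, AnchorError, ConversionTable,
                       DegenerateAnchorError, InsufficientDataError,
                       OutOfArcDomainError, apply_conversion,
                       build_conversion_table, cohort_from_arrays,
                       convert_score, extract_anchors, fit_circle_arc,
                       linear_component, round_half_away)
from conftest import circle_through_points


@st.composite
def valid_anchor_triplets(draw, min_gap: float = 0.5,
                          min_deviation: float = 1e-3) -> AnchorTriplet:
    """Strategy over non-degenerate anchor triplets inside [0, 30]."""
    x1 = draw(st.floats(0, 28, allow_nan=False, allow_infinity=False))
    x2 = draw(st.floats(x1 + min_gap, 29, allow_nan=False))
    x3 = draw(st.floats(x2 + min_gap, 30, allow_nan=False))
    y1 = draw(st.floats(0, 30, allow_nan=False))
    y2 = draw(st.floats(0, 30, allow_nan=False))
    y3 = draw(st.floats(0, 30, allow_nan=False))
    chord = y1 + (y3 - y1) / (x3 - x1) * (x2 - x1)
    if abs(y2 - chord) < min_deviation:
        # place the midpoint a fixed distance off the chord so the circle
        # stays finite (chord value lies within [0, 30] by construction)
        y2 = chord + min_deviation if chord + min_deviation <= 30 \
            else chord - min_deviation
    return AnchorTriplet(x1=x1, y1=y1, x2=x2, y2=y2, x3=x3, y3=y3)


class TestRounding:
    @pytest.mark.parametrize("value,expected", [
        (0.5, 1), (-0.5, -1), (1.49, 1), (2.5, 3), (-2.5, -3), (0.0, 0),
        (15.601, 16), (0.462, 0),
    ])
    def test_half_away_from_zero(self, value, expected):
        assert round_half_away(value) == expected

    def test_vectorized(self):
        out = round_half_away(np.array([0.5, -0.5, 1.2]))
        assert out.dtype.kind == "i"
        assert list(out) == [1, -1, 1]


class TestAnchorTriplet:
    def test_rejects_non_increasing_x(self):
        with pytest.raises(AnchorError):
            AnchorTriplet(x1=5, y1=1, x2=5, y2=2, x3=10, y3=3)

    def test_rejects_equal_endpoints(self):
        with pytest.raises(DegenerateAnchorError):
            AnchorTriplet(x1=5, y1=1, x2=5, y2=2, x3=5, y3=3)

    def test_rejects_out_of_range(self):
        with pytest.raises(AnchorError):
            AnchorTriplet(x1=2, y1=31, x2=12, y2=8, x3=28, y3=25)


class TestLinearComponent:
    def test_endpoint_identity(self, total_anchors):
        assert linear_component(total_anchors, 2) == pytest.approx(1)
        assert linear_component(total_anchors, 28) == pytest.approx(25)

    def test_midpoint_value(self, total_anchors):
        # two-point-line arithmetic: 1 + (24/26)*10
        assert linear_component(total_anchors, 12) == pytest.approx(
            1 + 24 / 26 * 10, abs=1e-12)


class TestFitCircleArc:
    @pytest.mark.parametrize("name,xc,yc,r", [
        ("total", 15.0, 34.75, 37.09895),
        ("high", 14.5, 46.13, 47.79476),
        ("low", 14.0, -263.91, 264.1382),
    ])
    def test_published_parameters(self, published_models, name, xc, yc, r):
        m = published_models[name]
        assert m.xc == pytest.approx(xc, abs=1e-9)
        assert round(m.yc, 2) == pytest.approx(yc)
        assert round(m.r, 4 if name == "low" else 5) == pytest.approx(r)

    def test_collinear_anchors_degenerate(self):
        m = fit_circle_arc(AnchorTriplet(x1=0, y1=0, x2=15, y2=15, x3=30, y3=30))
        assert m.degenerate
        assert m.branch == 0
        assert m.y2_star == 0.0

    def test_branch_follows_midpoint_side(self, published_models):
        assert published_models["total"].branch == -1  # midpoint below chord
        assert published_models["low"].branch == +1    # midpoint above chord

    def test_matches_geometric_oracle(self):
        a = AnchorTriplet(x1=1, y1=2, x2=10, y2=9, x3=20, y3=22)
        m = fit_circle_arc(a)
        xc, yc, r = circle_through_points(
            (a.x1, 0.0), (a.x2, m.y2_star), (a.x3, 0.0))
        assert m.xc == pytest.approx(xc, rel=1e-9)
        assert m.yc == pytest.approx(yc, rel=1e-9)
        assert m.r == pytest.approx(r, rel=1e-9)

    def test_circle_passes_through_transformed_anchors(self, published_models):
        for m in published_models.values():
            for px, py in [(m.anchors.x1, 0.0), (m.anchors.x2, m.y2_star),
                           (m.anchors.x3, 0.0)]:
                assert math.hypot(px - m.xc, py - m.yc) == pytest.approx(
                    m.r, abs=1e-9)

    def test_xc_is_endpoint_midpoint(self, published_models):
        for m in published_models.values():
            assert m.xc == pytest.approx(
                (m.anchors.x1 + m.anchors.x3) / 2, abs=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(anchors=valid_anchor_triplets())
    def test_closed_form_equals_oracle_property(self, anchors):
        m = fit_circle_arc(anchors)
        xc, yc, r = circle_through_points(
            (anchors.x1, 0.0), (anchors.x2, m.y2_star), (anchors.x3, 0.0))
        assert m.xc == pytest.approx(xc, rel=1e-6, abs=1e-6)
        assert m.yc == pytest.approx(yc, rel=1e-6, abs=1e-6)
        assert m.r == pytest.approx(r, rel=1e-6, abs=1e-6)


class TestConvertScore:
    @settings(max_examples=100, derandomize=True)
    @given(anchors=valid_anchor_triplets(min_deviation=0.05))
    def test_interpolates_all_three_anchors(self, anchors):
        # midpoint deviation bounded away from zero: near-collinear anchors
        # give huge radii where 1e-9 absolute interpolation is not
        # representable in double precision
        m = fit_circle_arc(anchors)
        # the method assumes a minor arc: the center lies on the opposite
        # side of the baseline from the midpoint bulge; otherwise the
        # endpoints fall on the other circle branch
        assume(m.yc * m.y2_star < 0)
        for px, py in anchors.as_points():
            assert convert_score(m, px) == pytest.approx(py, abs=1e-9)

    def test_published_midpoint(self, total_model):
        assert convert_score(total_model, 12) == pytest.approx(8.0, abs=1e-9)

    def test_published_cells(self, published_models):
        assert round_half_away(convert_score(published_models["total"], 20)) == 16
        assert round_half_away(convert_score(published_models["high"], 30)) == 23

    def test_degenerate_model_is_linear(self):
        m = fit_circle_arc(AnchorTriplet(x1=0, y1=0, x2=15, y2=15, x3=30, y3=30))
        assert convert_score(m, 7.3) == pytest.approx(7.3)

    def test_out_of_domain_raises(self):
        # steep small circle: strong midpoint deviation, narrow x-range
        m = fit_circle_arc(AnchorTriplet(x1=10, y1=10, x2=12, y2=25, x3=14, y3=10))
        assert m.r < 12
        with pytest.raises(OutOfArcDomainError):
            convert_score(m, 30.0)

    def test_degenerate_continuity(self):
        # as the midpoint deviation shrinks to +-1e-6 the arc converges to
        # the chord pointwise
        base = AnchorTriplet(x1=2, y1=1, x2=12, y2=8, x3=28, y3=25)
        lin_mid = float(linear_component(base, 12))
        for sign in (+1, -1):
            nearly = AnchorTriplet(x1=2, y1=1, x2=12, y2=lin_mid + sign * 1e-6,
                                   x3=28, y3=25)
            m = fit_circle_arc(nearly)
            assert not m.degenerate
            for x in (0, 5, 12, 20, 30):
                assert convert_score(m, x) == pytest.approx(
                    float(linear_component(base, x)), abs=1e-3)


class TestExtractAnchors:
    def test_no_spread_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            extract_anchors([(10, 7)] * 12)

    def test_three_points_midpoint_from_means(self):
        # extremes come from the data; the midpoint is the rounded means
        # ((2+12+28)/3 = 14, (1+8+25)/3 = 11.33 -> 11)
        a = extract_anchors([(2, 1), (12, 8), (28, 25)])
        assert a.as_points() == [(2, 1), (14, 11), (28, 25)]

    def test_means_coinciding_with_a_data_point(self):
        # when the sample means round onto an observed pair, the anchors
        # are exactly the extremes plus that pair
        pairs = [(2, 1), (6, 4), (12, 8), (28, 25)]  # means (12, 9.5 -> 10)
        a = extract_anchors(pairs)
        assert a.as_points() == [(2, 1), (12, 10), (28, 25)]

    def test_rule_matches_brute_force_scan(self):
        # fixture built under the generator constraint: means round to
        # (12, 8); extreme source scores 2 and 28 each appear once
        rng = np.random.default_rng(7)
        pairs = [(2, 1), (28, 25)]
        body = rng.integers(3, 28, size=198)
        noise = rng.normal(0, 1.5, size=198)
        pairs += [(int(m), int(np.clip(round(0.9 * m - 2.5 + e), 0, 30)))
                  for m, e in zip(body, noise)]
        xs = np.array([p[0] for p in pairs], dtype=float)
        ys = np.array([p[1] for p in pairs], dtype=float)
        # brute-force re-derivation of the documented rule
        exp_x1, exp_x3 = xs.min(), xs.max()
        exp_y1 = round_half_away(float(np.median(ys[xs == exp_x1])))
        exp_y3 = round_half_away(float(np.median(ys[xs == exp_x3])))
        exp_x2 = round_half_away(float(xs.mean()))
        exp_y2 = round_half_away(float(ys.mean()))
        a = extract_anchors(pairs)
        assert a.as_points() == [(exp_x1, exp_y1), (exp_x2, exp_y2),
                                 (exp_x3, exp_y3)]

    def test_extreme_target_is_median_of_companions(self):
        pairs = [(2, 0), (2, 3), (2, 4), (12, 8), (15, 9), (28, 25)]
        a = extract_anchors(pairs)
        assert a.y1 == 3  # median of {0, 3, 4}

    def test_explicit_mode_passthrough(self, total_anchors):
        assert extract_anchors([], mode="explicit",
                               explicit=total_anchors) is total_anchors


class TestConversionTable:
    def test_published_total_column_cells(self, published_models):
        t = build_conversion_table(published_models["total"])
        for s, expected in [(0, 0), (1, 0), (2, 1), (12, 8), (20, 16),
                            (28, 25), (30, 28)]:
            assert t[s] == expected

    def test_published_low_cell(self, published_models):
        assert build_conversion_table(published_models["low"])[15] == 9

    def test_identity_for_collinear_anchors(self):
        m = fit_circle_arc(AnchorTriplet(x1=0, y1=0, x2=15, y2=15, x3=30, y3=30))
        t = build_conversion_table(m)
        assert all(t[s] == s for s in range(31))

    def test_total_on_range_and_bounded(self, published_models):
        for m in published_models.values():
            t = build_conversion_table(m)
            assert t.scores() == list(range(31))
            assert all(0 <= t[s] <= 30 for s in range(31))

    def test_published_tables_non_decreasing(self, published_models):
        for m in published_models.values():
            vals = build_conversion_table(m).as_array()
            assert (np.diff(vals) >= 0).all()

    def test_out_of_domain_falls_back_to_chord(self):
        m = fit_circle_arc(AnchorTriplet(x1=10, y1=10, x2=12, y2=25, x3=14, y3=10))
        t = build_conversion_table(m)
        lo = m.domain()[0]
        s = int(np.floor(lo)) - 1
        assert t[s] == int(np.clip(
            round_half_away(float(linear_component(m.anchors, s))), 0, 30))

    def test_csv_round_trip(self, published_models, tmp_path):
        t = build_conversion_table(published_models["total"], label="total")
        path = tmp_path / "table.csv"
        t.to_csv(path)
        back = ConversionTable.from_csv(path)
        assert back.entries == dict(t.entries)
        assert back.label == "total"


class TestApplyConversion:
    def test_empty_cohort(self, published_models):
        t = build_conversion_table(published_models["total"])
        empty = cohort_from_arrays([], [])
        assert apply_conversion(t, empty).size == 0

    def test_published_lookup(self, published_models):
        t = build_conversion_table(published_models["total"])
        cohort = cohort_from_arrays([12, 20, 30], [0, 0, 0])
        assert list(apply_conversion(t, cohort)) == [8, 16, 28]

    def test_identity_table_preserves_scores(self):
        m = fit_circle_arc(AnchorTriplet(x1=0, y1=0, x2=15, y2=15, x3=30, y3=30))
        t = build_conversion_table(m)
        cohort = cohort_from_arrays([0, 7, 19, 30], [0, 0, 0, 0])
        assert list(apply_conversion(t, cohort)) == [0, 7, 19, 30]
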