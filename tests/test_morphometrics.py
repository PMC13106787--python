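"""Shape metrics: tracing/stitching, circularity, sections, length, volume."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import curvemorph as cm
from tests.conftest import make_prism_cell


def _circle_outline(r, n=256, z=0.0):
    th = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(th), r * np.sin(th), np.full(n, z)])


def _draped_outline(R, L, half, n=16):
    """Rectangle draped over a cylinder of radius R, half-angle per side."""
    th = np.linspace(-half, half, n)
    x = np.linspace(0, L, n)
    pts = [[0, R * math.sin(t), R * math.cos(t)] for t in th]
    pts += [[xx, R * math.sin(half), R * math.cos(half)] for xx in x[1:-1]]
    pts += [[L, R * math.sin(t), R * math.cos(t)] for t in th[::-1]]
    pts += [[xx, -R * math.sin(half), R * math.cos(half)] for xx in x[::-1][1:-1]]
    return np.array(pts)


class TestTraceApical:
    def test_planar_square(self):
        sq = np.array([[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0]], float)
        tr = cm.trace_apical(sq)
        assert tr.n_segments == 1
        assert tr.area == pytest.approx(100.0)
        assert tr.perimeter == pytest.approx(40.0)

    def test_flat_disc_area(self):
        tr = cm.trace_apical(_circle_outline(7.0))
        assert tr.area == pytest.approx(math.pi * 49.0, rel=0.005)

    def test_draped_outline_stitched_within_2pct_of_surface_integral(self):
        """30° of arc on each side of the cut; dense-integration oracle."""
        R, L = 30.0, 20.0
        half = math.pi / 6  # half-angle: the split leaves 30° per side
        outline = _draped_outline(R, L, half, n=24)
        true_area = R * 2 * half * L  # exact developable-surface area
        # dense numerical oracle: sum of strip areas
        th = np.linspace(-half, half, 20001)
        oracle = np.trapezoid(np.full_like(th, R * L), th)
        assert oracle == pytest.approx(true_area, rel=1e-9)
        tr = cm.trace_apical(outline, curvature_threshold=1.0, max_segments=2)
        assert tr.n_segments == 2
        assert tr.area == pytest.approx(true_area, rel=0.02)

    def test_more_segments_reduce_flattening_error(self):
        R, L, half = 30.0, 20.0, math.pi / 3
        outline = _draped_outline(R, L, half, n=24)
        true_area = R * 2 * half * L
        err2 = abs(cm.trace_apical(outline, 1.0, 2).area - true_area)
        err4 = abs(cm.trace_apical(outline, 0.2, 4).area - true_area)
        assert err4 < err2

    def test_self_intersecting_projection_errors(self):
        bowtie = np.array(
            [[0, 0, 0], [10, 10, 0], [10, 0, 0], [0, 10, 0]], float
        )
        with pytest.raises(cm.StitchingError):
            cm.trace_apical(bowtie)


class TestCircularity:
    def test_circle_is_one(self):
        tr = cm.trace_apical(_circle_outline(5.0, n=4096))
        assert cm.compute_circularity(tr) == pytest.approx(1.0, abs=1e-4)

    def test_square_closed_form(self):
        assert cm.compute_circularity((100.0, 40.0)) == pytest.approx(math.pi / 4)

    def test_four_to_one_rectangle_closed_form(self):
        # a=4, b=1: 4*pi*4 / 100 = 16*pi/100
        assert cm.compute_circularity((4.0, 10.0)) == pytest.approx(
            16 * math.pi / 100
        )

    def test_nonfinite_errors(self):
        with pytest.raises(ValueError):
            cm.compute_circularity((float("nan"), 10.0))
        with pytest.raises(ValueError):
            cm.compute_circularity((1.0, 0.0))

    @given(st.integers(3, 12), st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_isoperimetric_inequality_random_convex_polygons(self, n, seed):
        """Circularity of any simple polygon is at most 1."""
        rng = np.random.default_rng(seed)
        # stratified angles covering the full circle -> simple star polygon
        th = 2 * math.pi * (np.arange(n) + rng.uniform(0.05, 0.95, n)) / n
        r = rng.uniform(0.5, 3.0, n)
        poly = np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros(n)])
        tr = cm.trace_apical(poly)
        assert cm.compute_circularity(tr) <= 1.0 + 1e-6


class TestCrossSections:
    def test_upright_cuboid(self):
        ap = np.array([[0, 0, 5], [10, 0, 5], [10, 6, 5], [0, 6, 5]], float)
        cell = make_prism_cell(ap, ap - [0, 0, 5])
        sx, sy = cm.cross_section_measures(cell)
        assert sx.basal_width == pytest.approx(10.0)
        assert sx.apical_width == pytest.approx(10.0)
        assert sx.lateral_lengths == pytest.approx((5.0, 5.0))
        assert sy.basal_width == pytest.approx(6.0)

    def test_truncated_wedge_matches_construction(self):
        # basal 12 wide, apical 8 wide, height 5, centred taper
        ap = np.array([[-4, -3, 5], [4, -3, 5], [4, 3, 5], [-4, 3, 5]], float)
        ba = np.array([[-6, -3, 0], [6, -3, 0], [6, 3, 0], [-6, 3, 0]], float)
        cell = make_prism_cell(ap, ba)
        sx, sy = cm.cross_section_measures(cell)
        assert sx.basal_width == pytest.approx(12.0)
        assert sx.apical_width == pytest.approx(8.0)
        lat = math.hypot(2.0, 5.0)
        assert sx.lateral_lengths == pytest.approx((lat, lat))

    def test_tilted_prism_lateral_length_trigonometric(self):
        ap = np.array([[0, 0, 5], [10, 0, 5], [10, 6, 5], [0, 6, 5]], float)
        off = 5 * math.tan(math.pi / 6)  # 30° tilt
        cell = make_prism_cell(ap, ap - [off, 0, 5])
        sx, _ = cm.cross_section_measures(cell)
        assert sx.lateral_lengths == pytest.approx(
            (5 / math.cos(math.pi / 6),) * 2
        )

    def test_circularly_symmetric_outline_warns(self):
        ap = _circle_outline(5.0, n=64, z=3.0)
        cell = make_prism_cell(ap, _circle_outline(5.0, n=64, z=0.0))
        with pytest.warns(UserWarning, match="symmetric"):
            cm.cross_section_measures(cell)


class TestLengthAndVolume:
    def test_apicobasal_length_examples(self):
        s1 = cm.CrossSectionMeasure("X", 10, 10, (5.0, 5.0))
        s2 = cm.CrossSectionMeasure("Y", 6, 6, (5.0, 5.0))
        assert cm.apicobasal_length((s1, s2)) == pytest.approx(5.0)
        s3 = cm.CrossSectionMeasure("X", 10, 10, (4.0, 5.0))
        s4 = cm.CrossSectionMeasure("Y", 6, 6, (6.0, 5.0))
        assert cm.apicobasal_length((s3, s4)) == pytest.approx(5.0)

    @given(st.lists(st.floats(0.1, 50.0), min_size=4, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_apicobasal_length_equals_brute_sum(self, lats):
        s1 = cm.CrossSectionMeasure("X", 1, 1, tuple(lats[:2]))
        s2 = cm.CrossSectionMeasure("Y", 1, 1, tuple(lats[2:]))
        total = 0.0
        for v in lats:
            total += v
        assert cm.apicobasal_length((s1, s2)) == pytest.approx(total / 4)

    def test_missing_section_errors(self):
        s1 = cm.CrossSectionMeasure("X", 10, 10, (5.0, 5.0))
        with pytest.raises(ValueError):
            cm.apicobasal_length((s1,))
        with pytest.raises(ValueError):
            cm.apicobasal_length((s1, None))

    def test_volume_estimator_examples(self):
        s1 = cm.CrossSectionMeasure("X", 10, 10, (5.0, 5.0))
        s2 = cm.CrossSectionMeasure("Y", 10, 10, (5.0, 5.0))
        assert cm.estimate_volume((s1, s2), 5.0) == pytest.approx(500.0)
        w1 = cm.CrossSectionMeasure("X", 12, 8, (5.0, 5.0))
        w2 = cm.CrossSectionMeasure("Y", 12, 8, (5.0, 5.0))
        assert cm.estimate_volume((w1, w2), 5.0) == pytest.approx(480.0)
        z1 = cm.CrossSectionMeasure("X", 12, 0, (5.0, 5.0))
        z2 = cm.CrossSectionMeasure("Y", 12, 0, (5.0, 5.0))
        assert cm.estimate_volume((z1, z2), 5.0) == 0.0

    def test_negative_length_errors(self):
        s1 = cm.CrossSectionMeasure("X", 10, 10, (5.0, 5.0))
        with pytest.raises(ValueError):
            cm.estimate_volume((s1, s1), -1.0)

    @given(st.floats(0.1, 10.0), st.floats(0.1, 10.0), st.floats(0.5, 8.0))
    @settings(max_examples=60, deadline=None)
    def test_estimator_bias_on_square_frustum_family(self, wb, wa, h):
        """The box estimator equals the true volume only for the cuboid and
        undercounts square frusta by exactly h/3*(wb-wa)^2 (mean-width
        product vs mean of products)."""
        s = cm.CrossSectionMeasure("X", wb, wa, (h, h))
        est = cm.estimate_volume((s, s), h)
        true_frustum = h / 3.0 * (wb**2 + wb * wa + wa**2)
        assert true_frustum - est == pytest.approx(h / 3.0 * (wb - wa) ** 2,
                                                   rel=1e-9, abs=1e-9)
        if abs(wb - wa) > 1e-6:
            assert est < true_frustum


class TestScaleCovariance:
    @given(st.floats(0.3, 4.0))
    @settings(max_examples=30, deadline=None)
    def test_metrics_scale_with_k(self, k):
        ap = np.array([[0, 0, 5], [12, 0, 5], [12, 6, 5], [0, 6, 5]], float)
        cell = make_prism_cell(ap, ap - [0, 0, 5])
        rec = cm.measure_cell(cell)
        scaled = make_prism_cell(k * ap, k * (ap - [0, 0, 5]), "t1")
        rec_k = cm.measure_cell(scaled)
        assert rec_k.apical_area == pytest.approx(k**2 * rec.apical_area, rel=1e-9)
        assert rec_k.apicobasal_length == pytest.approx(
            k * rec.apicobasal_length, rel=1e-9
        )
        assert rec_k.volume == pytest.approx(k**3 * rec.volume, rel=1e-9)
        assert rec_k.circularity == pytest.approx(rec.circularity, rel=1e-9)


class TestPopulationRoundTrip:
    def test_measured_mean_area_matches_generating_mean_within_2pct(
        self, clean_heart
    ):
        _, cells = clean_heart
        oc = [c for c in cells if c.true_region == "OC"]
        measured = np.mean([cm.trace_apical(c).area for c in oc])
        truth = np.mean([c.true_area for c in oc])
        assert measured == pytest.approx(truth, rel=0.02)
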