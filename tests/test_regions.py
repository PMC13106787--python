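"""Landmark placement, boundary construction, assignment, mosaic selection."""

import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

import curvemorph as cm
from curvemorph.geometry import HeartModel


def _heart(R=100.0, r=50.0, angle=2.5, stage="48", d=13.0, **kw):
    return HeartModel(stage=stage, bend_radius=R, tube_radius=r,
                      bend_angle=angle, cell_diameter_typical=d, **kw)


class TestLandmarks48:
    def test_db_oc_at_two_thirds_hand_arithmetic(self):
        # PB_OC at s=9 and DB_OFT at s=99 give DB_OC at 9 + (2/3)*90 = 69
        heart = _heart(R=24, r=9, angle=3.0)  # oc arc length = 99
        lm = cm.locate_landmarks_48(heart, cell_diameter=9.0)
        assert lm.PB_OC == pytest.approx(9.0)
        assert lm.DB_OFT_OC == pytest.approx(99.0)
        assert lm.DB_OC == pytest.approx(69.0, abs=1e-12)

    def test_db_ic_at_half_closed_form(self):
        heart = _heart(R=26.0, r=10.0, angle=5.0)  # ic arc length = 80
        lm = cm.locate_landmarks_48(heart)
        assert lm.DB_OFT_IC == pytest.approx(80.0)
        assert lm.DB_IC == pytest.approx(40.0, abs=1e-12)

    def test_zero_cell_diameter_puts_pb_oc_at_avc(self):
        heart = _heart()
        lm = cm.locate_landmarks_48(heart, cell_diameter=0.0)
        assert lm.PB_OC == 0.0
        assert np.allclose(lm.pb_oc_2d, heart.oc_point_2d(0.0))

    def test_cell_diameter_exceeding_arc_errors(self):
        heart = _heart()
        with pytest.raises(ValueError, match="OC arc"):
            cm.locate_landmarks_48(heart, cell_diameter=heart.oc_arc_length)

    def test_point_constructions(self):
        heart = _heart()
        lm = cm.locate_landmarks_48(heart)
        mid = lm.PB_OC + 0.5 * (lm.DB_OC - lm.PB_OC)
        assert np.allclose(lm.point_i, heart.oc_point_2d(mid))
        assert np.allclose(lm.point_ii,
                           lm.pb_ic_2d + (lm.point_i - lm.pb_ic_2d) / 3.0)
        assert np.allclose(lm.point_iii, 0.5 * (lm.db_ic_2d + lm.db_oc_2d))


class TestLandmarks36:
    def test_points_linear_interpolation(self):
        heart = _heart(stage="36")
        lm = cm.locate_landmarks_36(heart)
        seg = lm.pb_ic_2d - lm.pb_oc_2d
        assert np.allclose(lm.point_i, lm.pb_oc_2d + seg / 3.0, atol=1e-9)
        assert np.allclose(lm.point_ii, lm.pb_oc_2d + 2 * seg / 3.0, atol=1e-9)
        seg_d = lm.db_ic_2d - lm.db_oc_2d
        assert np.allclose(lm.point_iii, lm.db_oc_2d + seg_d / 3.0, atol=1e-9)
        assert np.allclose(lm.point_iv, lm.db_oc_2d + 2 * seg_d / 3.0, atol=1e-9)

    def test_known_interpolation_example(self):
        """Points at thirds of a 30-unit segment land at 10 and 20."""
        a, b = np.array([0.0, 0.0]), np.array([30.0, 0.0])
        assert np.allclose(a + (b - a) / 3.0, [10.0, 0.0])
        heart = _heart(stage="37")
        lm = cm.locate_landmarks_36(heart)
        d = np.linalg.norm(lm.pb_ic_2d - lm.pb_oc_2d)
        assert np.linalg.norm(lm.point_i - lm.pb_oc_2d) == pytest.approx(d / 3)
        assert np.linalg.norm(lm.point_ii - lm.pb_oc_2d) == pytest.approx(2 * d / 3)

    def test_fraction_identities_over_random_geometries(self):
        """2/3, 1/2 and thirds rules hold to 1e-9 for 100 random hearts."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            r = rng.uniform(20, 60)
            big_r = r * rng.uniform(1.5, 3.0)
            angle = rng.uniform(1.2, 3.0)
            d = rng.uniform(0, 0.2) * angle * (big_r + r)
            heart = _heart(R=big_r, r=r, angle=angle, d=d)
            lm48 = cm.locate_landmarks_48(heart)
            assert abs(
                lm48.DB_OC - (lm48.PB_OC + (2 / 3) * (lm48.DB_OFT_OC - lm48.PB_OC))
            ) < 1e-9
            assert abs(
                lm48.DB_IC - (lm48.PB_IC + 0.5 * (lm48.DB_OFT_IC - lm48.PB_IC))
            ) < 1e-9
            mid = lm48.PB_OC + 0.5 * (lm48.DB_OC - lm48.PB_OC)
            assert np.linalg.norm(lm48.point_i - heart.oc_point_2d(mid)) < 1e-9
            assert np.linalg.norm(
                lm48.point_ii - (lm48.pb_ic_2d + (lm48.point_i - lm48.pb_ic_2d) / 3)
            ) < 1e-9
            lm36 = cm.locate_landmarks_36(heart)
            seg = lm36.pb_ic_2d - lm36.pb_oc_2d
            assert np.linalg.norm(lm36.point_i - (lm36.pb_oc_2d + seg / 3)) < 1e-9
            assert np.linalg.norm(lm36.point_ii - (lm36.pb_oc_2d + 2 * seg / 3)) < 1e-9


class TestBoundaries:
    def test_point_on_oc_arc_midway_is_oc(self, default_boundaries):
        lm = default_boundaries.landmarks
        mid = lm.PB_OC + 0.5 * (lm.DB_OC - lm.PB_OC)
        heart = _heart()
        assert default_boundaries.region_of(heart.oc_point_2d(mid)) == "OC"

    def test_point_distal_to_db_ic_is_neither(self, default_boundaries):
        """Point-in-polygon oracle: distal IC arc points fall outside."""
        lm = default_boundaries.landmarks
        heart = _heart()
        s = lm.DB_IC + 0.25 * (lm.DB_OFT_IC - lm.DB_IC)
        p = heart.ic_point_2d(s)
        assert not default_boundaries.ic_polygon.covers(Point(p))  # oracle
        assert default_boundaries.region_of(p) == "neither"

    def test_36hpf_strip_between_medial_borders_is_neither(self):
        heart = _heart(stage="36", R=85, r=42.5, angle=2.3, d=11)
        b = cm.build_region_boundaries(cm.locate_landmarks(heart))
        lm = b.landmarks
        # midway between the two medial borders (I->III and II->IV)
        strip_pt = 0.25 * (lm.point_i + lm.point_iii + lm.point_ii + lm.point_iv)
        assert b.region_of(strip_pt) == "neither"
        assert b.region_of(0.5 * (lm.point_i + lm.point_iii) * 0.999
                           + 0.001 * lm.pb_oc_2d) != "IC"

    def test_predicates_mutually_exclusive(self):
        rng = np.random.default_rng(3)
        for stage in ("48", "36"):
            heart = _heart(stage=stage)
            b = cm.build_region_boundaries(cm.locate_landmarks(heart))
            assert b.oc_polygon.intersection(b.ic_polygon).area < 1e-9
            pts = rng.uniform(-160, 160, size=(500, 2))
            for p in pts:
                assert b.region_of(p) in ("OC", "IC", "neither")


class TestAssignCells:
    def test_cell_fully_inside_oc_has_fraction_one(
        self, default_heart, default_assignment
    ):
        _, cells = default_heart
        oc_ids = {c.cell_id for c in cells if c.true_region == "OC"}
        sub = default_assignment[default_assignment.cell_id.isin(oc_ids)]
        assert (sub.in_region_area_fraction > 0.999).all()
        assert (sub.region == "OC").all()

    def test_straddling_cell_with_40pct_inside_is_neither(self, default_boundaries):
        """Polygon-clip oracle: a square 40% inside the OC cut -> neither."""
        b = default_boundaries
        a, n = b.cut_point, b.cut_normal
        d = np.array([-n[1], n[0]])
        mid = a + d * 60.0  # a point on the cut line
        # 10x10 square extending 4 µm to the convex side, 6 µm to the other
        corners = []
        for du in (-5.0, 5.0):
            for dv in (-6.0, 4.0):
                corners.append(mid + du * d + dv * n)
        square2d = np.array([corners[0], corners[1], corners[3], corners[2]])
        apical = np.column_stack([square2d, np.zeros(4)])
        cell = cm.Cardiomyocyte("straddle", apical, apical - [0, 0, 1])
        from shapely.geometry import Polygon

        frac_oracle = (
            Polygon(square2d).intersection(b.oc_polygon).area / Polygon(square2d).area
        )
        assert frac_oracle == pytest.approx(0.4, abs=1e-6)
        out = cm.assign_cells([cell], b)
        assert out.loc[0, "region"] == "neither"
        assert out.loc[0, "in_region_area_fraction"] == pytest.approx(0.4, abs=1e-6)

    def test_default_heart_counts_in_printed_ranges(self, default_assignment):
        counts = default_assignment["region"].value_counts()
        assert 50 <= counts.get("OC", 0) <= 60
        assert 25 <= counts.get("IC", 0) <= 30

    def test_zero_area_cell_errors(self, default_boundaries):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [1, 0, 0]], float)
        cell = cm.Cardiomyocyte("z0", line, line - [0, 0, 1])
        with pytest.raises(ValueError, match="zero projected"):
            cm.assign_cells([cell], default_boundaries)

    def test_assignment_matches_truth_on_clean_heart(
        self, default_heart, default_assignment
    ):
        _, cells = default_heart
        truth = {c.cell_id: c.true_region for c in cells}
        agree = np.mean(
            [truth[r.cell_id] == r.region for r in default_assignment.itertuples()]
        )
        assert agree >= 0.95

    def test_oc_ic_assigned_sets_disjoint(self, default_assignment):
        oc = set(default_assignment[default_assignment.region == "OC"].cell_id)
        ic = set(default_assignment[default_assignment.region == "IC"].cell_id)
        assert not (oc & ic)

    def test_rigid_motion_equivariance(self):
        """Rotating/translating the mount moves landmarks with it and leaves
        region assignments unchanged."""
        cfg = cm.GeneratorConfig(seed=4)
        heart, cells = cm.generate_heart(cfg)
        b0 = cm.build_region_boundaries(cm.locate_landmarks(heart))
        asg0 = cm.assign_cells(cells, b0)

        angle, offset = 0.7, np.array([35.0, -12.0])
        moved_heart = heart.with_frame(angle, tuple(offset))
        rot = np.array([[math.cos(angle), -math.sin(angle)],
                        [math.sin(angle), math.cos(angle)]])
        moved_cells = []
        for c in cells:
            ap = c.apical_outline.copy()
            ba = c.basal_outline.copy()
            ap[:, :2] = ap[:, :2] @ rot.T + offset
            ba[:, :2] = ba[:, :2] @ rot.T + offset
            moved_cells.append(
                cm.Cardiomyocyte(c.cell_id, ap, ba, embryo_id=c.embryo_id,
                                 wall_heights=c.wall_heights)
            )
        lm0 = cm.locate_landmarks(heart)
        lm1 = cm.locate_landmarks(moved_heart)
        assert np.allclose(lm1.point_i, lm0.point_i @ rot.T + offset, atol=1e-8)
        assert np.allclose(lm1.pb_oc_2d, lm0.pb_oc_2d @ rot.T + offset, atol=1e-8)
        b1 = cm.build_region_boundaries(lm1)
        asg1 = cm.assign_cells(moved_cells, b1)
        merged = asg0.merge(asg1, on="cell_id", suffixes=("_0", "_1"))
        assert (merged.region_0 == merged.region_1).all()
        assert np.allclose(merged.in_region_area_fraction_0,
                           merged.in_region_area_fraction_1, atol=1e-6)


class TestMosaicSelection:
    def test_no_donors_gives_empty_sets(self, default_heart, default_assignment):
        _, cells = default_heart
        donors, hosts = cm.select_mosaic_cells(cells, default_assignment)
        assert donors == set() and hosts == set()

    def test_bfs_depth_two_matches_oracle(self, default_heart, default_assignment):
        """Host cells within two contact steps of a donor, per a BFS oracle."""
        _, cells = default_heart
        cells = [cm.Cardiomyocyte(c.cell_id, c.apical_outline, c.basal_outline,
                                  embryo_id=c.embryo_id,
                                  wall_heights=c.wall_heights,
                                  true_region=c.true_region,
                                  neighbors=list(c.neighbors))
                 for c in cells]
        oc_cells = [c for c in cells if c.true_region == "OC"]
        donor = oc_cells[len(oc_cells) // 2]
        donor.clone_label = "donor"
        donors, hosts = cm.select_mosaic_cells(cells, default_assignment)
        # brute-force two-step neighbourhood
        nbrs = {c.cell_id: set(c.neighbors) for c in cells}
        ring1 = nbrs[donor.cell_id]
        ring2 = set().union(*(nbrs[x] for x in ring1)) - {donor.cell_id}
        region = dict(zip(default_assignment.cell_id, default_assignment.region))
        expected = {
            cid for cid in (ring1 | ring2)
            if region.get(cid) != "neither" and cid != donor.cell_id
        }
        assert donors == {donor.cell_id}
        assert hosts == expected
        assert len(hosts) > 0

    def test_donor_outside_regions_excluded_from_analysis_set(
        self, default_heart, default_assignment
    ):
        _, cells = default_heart
        cells = [cm.Cardiomyocyte(c.cell_id, c.apical_outline, c.basal_outline,
                                  true_region=c.true_region,
                                  wall_heights=c.wall_heights,
                                  neighbors=list(c.neighbors))
                 for c in cells]
        stray = next(c for c in cells if c.true_region == "neither")
        stray.clone_label = "donor"
        donors, _ = cm.select_mosaic_cells(cells, default_assignment)
        assert stray.cell_id not in donors
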