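"""Band means, membrane profiles, myocardium summaries, outliers, rfu."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import curvemorph as cm
from curvemorph.model import CrossSectionImage


def _quad_image(value=None, w=40, h=30, pixel_size=0.3, channels=None):
    """Rectangular test cell spanning most of the image."""
    bl, br, al, ar = (5.0, 5.0), (35.0, 5.0), (5.0, 25.0), (35.0, 25.0)
    polylines = {
        "basal": np.array([bl, br]),
        "apical": np.array([al, ar]),
        "lateral-left": np.array([bl, al]),
        "lateral-right": np.array([br, ar]),
    }
    if channels is None:
        channels = {"F-actin": np.full((h, w), float(value))}
    return CrossSectionImage(
        cell_id="u0", axis="X", pixel_size=pixel_size,
        channels=channels, polylines=polylines,
    )


class TestBandMean:
    def test_uniform_image_returns_constant(self):
        img = _quad_image(value=11.5)
        for dom in cm.DOMAINS:
            bm = cm.band_mean(
                img, cm.MembraneBand(img.polylines[dom], dom), "F-actin"
            )
            assert bm.value == pytest.approx(11.5)

    def test_split_image_band_mean_matches_pixel_enumeration(self):
        arr = np.full((30, 40), 10.0)
        arr[:, 20:] = 20.0
        img = _quad_image(channels={"F-actin": arr})
        band = cm.MembraneBand(img.polylines["basal"], "basal")
        bm = cm.band_mean(img, band, "F-actin")
        # enumeration oracle over the audited pixel set
        vals = [arr[r, c] for r, c in bm.pixels]
        assert bm.value == pytest.approx(sum(vals) / len(vals))
        # the band is symmetric about the half boundary -> mean 15
        assert bm.value == pytest.approx(15.0, abs=0.3)

    def test_corner_exclusion_skips_corner_signal(self):
        arr = np.full((30, 40), 10.0)
        # poison 1 µm (≈3.3 px) corners of the basal membrane
        arr[:10, :10] = 99.0
        arr[:10, 30:] = 99.0
        img = _quad_image(channels={"F-actin": arr})
        band = cm.MembraneBand(img.polylines["basal"], "basal",
                               corner_exclusion=3.0)
        bm = cm.band_mean(img, band, "F-actin")
        assert bm.value == pytest.approx(10.0)

    def test_band_pixels_lie_inside_cell_contour(self):
        img = _quad_image(value=1.0)
        bm = cm.band_mean(
            img, cm.MembraneBand(img.polylines["apical"], "apical"), "F-actin"
        )
        rows, cols = bm.pixels[:, 0], bm.pixels[:, 1]
        assert rows.min() >= 5 - 2 and rows.max() <= 25
        assert cols.min() >= 5 and cols.max() <= 35

    def test_overtrimmed_band_errors(self):
        img = _quad_image(value=1.0)
        band = cm.MembraneBand(img.polylines["basal"], "basal",
                               corner_exclusion=5.0)  # 2*5 µm > 9 µm edge
        with pytest.raises(ValueError, match="corner exclusion"):
            cm.band_mean(img, band, "F-actin")


class TestProfileCell:
    def _pair(self, basal, lateral, apical):
        imgs = []
        for axis in ("X", "Y"):
            arr = np.zeros((30, 40))
            img = _quad_image(channels={"F-actin": arr})
            img.axis = axis
            # paint 2-px bands inside each membrane
            arr[5:8, 5:36] = basal
            arr[23:26, 5:36] = apical
            arr[5:26, 5:8] = lateral
            arr[5:26, 33:36] = lateral
            imgs.append(img)
        return imgs

    def test_equal_means_give_thirds(self):
        ix, iy = self._pair(4.0, 4.0, 4.0)
        prof = cm.profile_cell(ix, iy, width=0.5, corner_exclusion=1.5)
        cp = prof.channels["F-actin"]
        assert cp.pct_basal == pytest.approx(100 / 3, abs=1e-6)
        assert cp.pct_lateral == pytest.approx(100 / 3, abs=1e-6)
        assert cp.pct_apical == pytest.approx(100 / 3, abs=1e-6)

    def test_six_three_one_gives_60_30_10_and_ratio(self):
        ix, iy = self._pair(6.0, 3.0, 1.0)
        prof = cm.profile_cell(ix, iy, width=0.5, corner_exclusion=1.5)
        cp = prof.channels["F-actin"]
        assert cp.pct_basal == pytest.approx(60.0, abs=1e-6)
        assert cp.pct_lateral == pytest.approx(30.0, abs=1e-6)
        assert cp.pct_apical == pytest.approx(10.0, abs=1e-6)
        assert cp.basal_ratio == pytest.approx(6.0 / (3.0 + 1.0), abs=1e-9)

    def test_percentages_sum_to_100(self, default_cfg, default_heart):
        _, cells = default_heart
        chosen = [c for c in cells if c.true_region in ("OC", "IC")][:6]
        for cell in chosen:
            ix = cm.render_cross_section(cell, "X", default_cfg)
            iy = cm.render_cross_section(cell, "Y", default_cfg)
            prof = cm.profile_cell(ix, iy, background=default_cfg.background)
            for cp in prof.channels.values():
                assert cp.pct_basal + cp.pct_lateral + cp.pct_apical == (
                    pytest.approx(100.0, abs=1e-6)
                )

    def test_all_zero_cell_flagged_not_dropped(self):
        ix, iy = self._pair(0.0, 0.0, 0.0)
        prof = cm.profile_cell(ix, iy, width=0.5, corner_exclusion=1.5)
        assert prof.flagged
        assert np.isnan(prof.channels["F-actin"].pct_basal)

    def test_basal_ratio_gain_invariant(self):
        ix1, iy1 = self._pair(6.0, 3.0, 2.0)
        ix2, iy2 = self._pair(6.0, 3.0, 2.0)
        for img in (ix2, iy2):
            img.channels["F-actin"] = img.channels["F-actin"] * 3.7
        r1 = cm.profile_cell(ix1, iy1, width=0.5, corner_exclusion=1.5)
        r2 = cm.profile_cell(ix2, iy2, width=0.5, corner_exclusion=1.5)
        assert r1.channels["F-actin"].basal_ratio == pytest.approx(
            r2.channels["F-actin"].basal_ratio, rel=1e-12
        )

    def test_mismatched_cells_error(self):
        ix, iy = self._pair(1, 1, 1)
        iy.cell_id = "other"
        with pytest.raises(ValueError, match="different cells"):
            cm.profile_cell(ix, iy)

    def test_noisy_basal_ratio_recovery_within_5pct(self, default_cfg):
        """Over 50 seeded noisy OC cells the mean recovered basal ratio sits
        within 5% of the ratio implied by the configured fractions."""
        cfg = default_cfg
        cells = cm.generate_population(cfg, 50, region="OC")
        ratios = []
        for cell in cells:
            ix = cm.render_cross_section(cell, "X", cfg)
            iy = cm.render_cross_section(cell, "Y", cfg)
            prof = cm.profile_cell(ix, iy, background=cfg.background)
            ratios.append(prof.channels["F-actin"].basal_ratio)
        f_b, f_l, f_a = cfg.fractions("OC", "F-actin")
        implied = f_b / (f_l + f_a)
        assert np.mean(ratios) == pytest.approx(implied, rel=0.05)


class TestMyocardiumSummary:
    def test_uniform_mask_mean(self):
        img = np.full((20, 20), 3.25)
        assert cm.masked_mean(img, np.ones_like(img, bool)) == 3.25

    def test_two_compartment_weighted_mean(self):
        img = np.concatenate([np.full((10, 20), 10.0), np.full((10, 20), 30.0)])
        mask = np.ones_like(img, bool)
        # weighted-mean oracle: equal halves -> 20
        assert cm.masked_mean(img, mask) == pytest.approx(
            (10.0 * 200 + 30.0 * 200) / 400
        )

    def test_mask_excludes_other_tissue(self):
        img = np.full((10, 10), 7.0)
        img[:, 5:] = 100.0  # endocardial region
        mask = np.zeros_like(img, bool)
        mask[:, :5] = True
        assert cm.masked_mean(img, mask) == 7.0

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            cm.masked_mean(np.ones((4, 4)), np.zeros((4, 4), bool))

    def test_per_embryo_summaries(self):
        embryos = {
            f"e{k}": (np.full((5, 5), float(k + 1)), np.ones((5, 5), bool))
            for k in range(4)
        }
        summaries = cm.myocardium_summary(embryos, "F-actin", replicate_id="r1")
        assert [s.raw_mean for s in summaries] == [1.0, 2.0, 3.0, 4.0]
        out = cm.normalize_summaries(summaries)
        rfu = [s.rfu for s in out]
        assert min(rfu) == 1.0 and max(rfu) == 10.0


class TestOutliers:
    def test_no_flags_for_tight_group(self):
        assert not cm.screen_outliers([10, 11, 12, 11, 10]).any()

    def test_flags_only_the_extreme_value(self):
        vals = [10, 11, 12, 11, 100]
        flags = cm.screen_outliers(vals)
        # quartile arithmetic oracle
        q1, q3 = np.percentile(vals, [25, 75])
        iqr = q3 - q1
        expected = (np.array(vals) < q1 - 1.5 * iqr) | (
            np.array(vals) > q3 + 1.5 * iqr
        )
        assert list(flags) == list(expected)
        assert list(flags) == [False, False, False, False, True]

    def test_identical_values_never_flagged(self):
        assert not cm.screen_outliers([5.0] * 7).any()

    def test_small_group_warns_and_passes(self):
        with pytest.warns(UserWarning, match="fewer than 3"):
            flags = cm.screen_outliers([1.0, 2.0])
        assert not flags.any()


class TestMinMaxRfu:
    def test_endpoints(self):
        assert list(cm.minmax_rfu([5.0, 20.0])) == [1.0, 10.0]

    def test_worked_example(self):
        assert list(cm.minmax_rfu([5.0, 10.0, 20.0])) == [1.0, 4.0, 10.0]

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="constant"):
            cm.minmax_rfu([3.0, 3.0, 3.0])

    @given(
        st.lists(st.integers(-10_000, 10_000), min_size=2, max_size=30,
                 unique=True),
        st.floats(0.01, 100.0),
        st.floats(-1e4, 1e4),
    )
    @settings(max_examples=80, deadline=None)
    def test_bounds_order_and_affine_invariance(self, ints, a, b):
        values = [0.37 * v for v in ints]  # distinct, well-separated inputs
        out = cm.minmax_rfu(values)
        assert out.min() == pytest.approx(1.0)
        assert out.max() == pytest.approx(10.0)
        assert list(np.argsort(out)) == list(np.argsort(values))
        transformed = cm.minmax_rfu(a * np.asarray(values) + b)
        assert np.allclose(out, transformed, atol=1e-6)
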