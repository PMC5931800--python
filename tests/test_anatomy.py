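"""Tests for the anatomical quantifications."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon

from retinads.anatomy import (
    ContactVolume,
    IntensityProfile,
    ProjectionRecord,
    arbor_territory_area,
    band_distance,
    classify_dendrite_angle,
    contact_rate,
    find_profile_peaks,
    flipped_control,
    ipl_profile,
    orientation_summary,
    percent_decrease,
    plexus_coverage,
    projection_frequency_table,
)


class TestDendriteOrientation:
    @pytest.mark.parametrize(
        "angle,expected",
        [(0.0, "IPL"), (44.9, "IPL"), (45.0, "TANGENTIAL"), (90.0, "TANGENTIAL"),
         (135.0, "TANGENTIAL"), (135.1, "ONBL"), (180.0, "ONBL")],
    )
    def test_quadrant_classification(self, angle, expected):
        assert classify_dendrite_angle(angle) == expected

    @pytest.mark.parametrize("angle", [-1.0, 180.5])
    def test_out_of_range_rejected(self, angle):
        with pytest.raises(ValueError):
            classify_dendrite_angle(angle)

    @settings(derandomize=True, max_examples=50)
    @given(
        angle=st.floats(0, 180),
        low=st.floats(1, 89),
        high=st.floats(91, 179),
    )
    def test_cuts_partition_without_gaps(self, angle, low, high):
        label = classify_dendrite_angle(angle, low, high)
        assert label in ("IPL", "TANGENTIAL", "ONBL")

    def test_all_toward_ipl(self):
        fractions, _, _ = orientation_summary([10.0] * 7)
        assert fractions == {"IPL": 1.0, "TANGENTIAL": 0.0, "ONBL": 0.0}

    def test_one_per_category(self):
        fractions, _, _ = orientation_summary([10.0, 90.0, 170.0])
        assert fractions["IPL"] == pytest.approx(1 / 3)
        assert fractions["TANGENTIAL"] == pytest.approx(1 / 3)
        assert fractions["ONBL"] == pytest.approx(1 / 3)

    def test_uniform_angles_split_by_quadrant_measure(self):
        # default cuts at 45/135 give quadrant measures 0.25 / 0.50 / 0.25
        rng = np.random.default_rng(0)
        angles = rng.uniform(0, 180, 1000)
        fractions, _, _ = orientation_summary(angles)
        tol = 4 * np.sqrt(0.5 * 0.5 / 1000)
        assert abs(fractions["IPL"] - 0.25) < tol
        assert abs(fractions["TANGENTIAL"] - 0.50) < tol
        assert abs(fractions["ONBL"] - 0.25) < tol


class TestIplProfile:
    def test_single_bright_row(self):
        img = np.full((50, 10), 7.0)
        img[20, :] = 19.0
        p = ipl_profile(img)
        assert p.intensity[20] == 1.0
        others = np.delete(p.intensity, 20)
        np.testing.assert_allclose(others, 0.0, atol=1e-12)

    def test_intensity_scaling_invariance(self):
        rng = np.random.default_rng(1)
        img = rng.random((60, 12)) + np.exp(-((np.arange(60)[:, None] - 25) ** 2) / 30)
        a = ipl_profile(img)
        b = ipl_profile(img * 37.5)
        np.testing.assert_allclose(a.intensity, b.intensity, atol=1e-12)
        c = ipl_profile(img * 2.0 + 11.0)  # affine rescale
        np.testing.assert_allclose(a.intensity, c.intensity, atol=1e-12)

    def test_flat_roi_rejected(self):
        with pytest.raises(ValueError):
            ipl_profile(np.full((30, 5), 3.0))

    def test_roi_restriction(self):
        img = np.zeros((40, 40))
        img[:, 5:10] = np.linspace(0, 1, 40)[:, None]
        p = ipl_profile(img, roi=(slice(None), slice(5, 10)))
        assert p.intensity[-1] == 1.0


class TestProfilePeaks:
    @staticmethod
    def _profile(values):
        depth = np.linspace(0, 100, len(values))
        return IntensityProfile.from_raw(depth, np.asarray(values, dtype=float))

    def test_single_maximum(self):
        depth = np.linspace(0, 100, 101)
        vals = np.exp(-((depth - 62.0) ** 2) / 20.0)
        p = IntensityProfile.from_raw(depth, vals)
        np.testing.assert_allclose(find_profile_peaks(p), [62.0])

    def test_plateau_reported_at_center(self):
        depth = np.linspace(0, 100, 101)
        vals = np.zeros(101)
        vals[40:51] = 1.0  # equal maxima spanning 40-50% depth
        p = IntensityProfile.from_raw(depth, vals)
        np.testing.assert_allclose(find_profile_peaks(p), [45.0])

    def test_no_peak_above_floor(self):
        depth = np.linspace(0, 100, 101)
        vals = np.linspace(0, 1, 101)  # monotone ramp: no interior peak
        p = IntensityProfile.from_raw(depth, vals)
        assert find_profile_peaks(p).size == 0

    def test_band_distance(self):
        a = self._profile(np.exp(-((np.linspace(0, 100, 201) - 56) ** 2) / 18))
        b = self._profile(np.exp(-((np.linspace(0, 100, 201) - 69) ** 2) / 18))
        assert band_distance(a, b) == pytest.approx(13.0, abs=0.5)
        assert band_distance(a, a) == 0.0

    def test_band_distance_requires_peaks(self):
        ramp = self._profile(np.linspace(0, 1, 101))
        peaked = self._profile(np.exp(-((np.linspace(0, 100, 101) - 50) ** 2) / 18))
        with pytest.raises(ValueError):
            band_distance(ramp, peaked)


class TestArborTerritory:
    def test_unit_square(self):
        tips = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        assert arbor_territory_area(tips) == pytest.approx(1.0)

    def test_regular_hexagon_closed_form(self):
        r = 7.5
        ang = np.deg2rad(np.arange(0, 360, 60))
        tips = r * np.column_stack([np.cos(ang), np.sin(ang)])
        assert arbor_territory_area(tips) == pytest.approx(1.5 * np.sqrt(3) * r**2)

    def test_star_shaped_matches_polygon_oracle(self):
        rng = np.random.default_rng(4)
        ang = np.sort(rng.uniform(0, 2 * np.pi, 25))
        radii = rng.uniform(5, 20, 25)
        tips = np.column_stack([radii * np.cos(ang), radii * np.sin(ang)]) + [40.0, -3.0]
        centered = tips - tips.mean(axis=0)
        ordered = tips[np.argsort(np.arctan2(centered[:, 1], centered[:, 0]))]
        oracle = Polygon(ordered).area  # independent area computation
        assert arbor_territory_area(rng.permutation(tips)) == pytest.approx(oracle, rel=1e-9)

    def test_invariances(self):
        rng = np.random.default_rng(5)
        ang = np.sort(rng.uniform(0, 2 * np.pi, 12))
        tips = np.column_stack([np.cos(ang), np.sin(ang)]) * rng.uniform(3, 9, 12)[:, None]
        base = arbor_territory_area(tips)
        assert arbor_territory_area(tips + [100, 200]) == pytest.approx(base)
        rot = np.deg2rad(33.0)
        rmat = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        assert arbor_territory_area(tips @ rmat.T) == pytest.approx(base)
        assert arbor_territory_area(tips * 2.5) == pytest.approx(base * 2.5**2)

    @pytest.mark.parametrize(
        "tips", [np.array([[0.0, 0], [1, 1]]), np.array([[0.0, 0], [1, 1], [2, 2], [3, 3]])]
    )
    def test_degenerate_tip_sets_rejected(self, tips):
        with pytest.raises(ValueError):
            arbor_territory_area(tips)


class TestPlexusCoverage:
    def test_half_white_image(self):
        img = np.zeros((64, 64))
        img[:32] = 1.0
        assert plexus_coverage(img) == pytest.approx(50.0)

    def test_hole_area_bookkeeping(self):
        img = np.ones((100, 100), dtype=bool)
        img[:20, :50] = False  # 1000 of 10000 pixels
        assert plexus_coverage(img) == pytest.approx(90.0)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            plexus_coverage(np.ones((10, 10)))

    def test_fixed_threshold_override(self):
        img = np.tile(np.array([0.1, 0.4, 0.8, 0.9]), (8, 1))
        assert plexus_coverage(img, threshold=0.5) == pytest.approx(50.0)


class TestContactRate:
    def test_full_mask_rate_and_control(self):
        mask = np.ones((4, 8, 8), dtype=bool)
        tips = np.array([[0, 1, 1], [2, 3, 4], [3, 7, 7]])
        cv = ContactVolume(tips, mask)
        assert contact_rate(cv).percent == 100.0
        assert flipped_control(cv).percent == 100.0

    def test_symmetric_mask_control_equals_observed(self):
        mask = np.zeros((2, 9, 9), dtype=bool)
        mask[:, 3:6, 3:6] = True  # invariant under in-plane flips
        rng = np.random.default_rng(6)
        tips = np.column_stack([rng.integers(0, 2, 30), rng.integers(0, 9, 30), rng.integers(0, 9, 30)])
        cv = ContactVolume(tips, mask)
        assert flipped_control(cv).percent == contact_rate(cv).percent

    def test_dilation_tolerance(self):
        mask = np.zeros((1, 9, 9), dtype=bool)
        mask[0, 4, 4] = True
        cv = ContactVolume(np.array([[0, 4, 5]]), mask)
        assert contact_rate(cv).percent == 0.0
        assert contact_rate(cv, dilation_voxels=1).percent == 100.0

    def test_tips_outside_volume_rejected(self):
        with pytest.raises(ValueError):
            ContactVolume(np.array([[0, 0, 99]]), np.zeros((2, 4, 4), dtype=bool))


class TestProjectionTable:
    @staticmethod
    def _records(n_true, n_total, genotype="wt", age="P1"):
        recs = []
        for i in range(n_total):
            strat = i < n_true
            recs.append(ProjectionRecord(f"c{i}", age, genotype, True, strat, False))
        return recs

    def test_printed_count_fractions(self):
        # 49 of 51 and 78 of 79 stratified -> 96% and 99% to the nearest point
        table = projection_frequency_table(
            self._records(49, 51, genotype="OFF") + self._records(78, 79, genotype="ON"),
            group_by=("genotype",),
        )
        off = table[table.genotype == "OFF"].iloc[0]
        on = table[table.genotype == "ON"].iloc[0]
        assert round(off.stratified_pct) == 96
        assert round(on.stratified_pct) == 99
        assert off.n_cells == 51 and on.n_cells == 79

    def test_zero_fraction(self):
        table = projection_frequency_table(self._records(0, 20), group_by=("genotype",))
        row = table.iloc[0]
        assert row.stratified_pct == 0.0
        assert row.stratified_se_pct == 0.0

    def test_binomial_se(self):
        table = projection_frequency_table(self._records(30, 40), group_by=("genotype",))
        p = 0.75
        assert table.iloc[0].stratified_se_pct == pytest.approx(100 * np.sqrt(p * (1 - p) / 40))

    def test_stratified_requires_ipl_innervation(self):
        with pytest.raises(ValueError):
            ProjectionRecord("c", "P1", "wt", innervates_ipl=False, stratified=True,
                             soma_layer_projection=False)


class TestPercentDecrease:
    def test_printed_coverage_decreases(self):
        assert percent_decrease(70.6, 60.0) == pytest.approx(15.0, abs=0.05)
        assert percent_decrease(65.9, 56.9) == pytest.approx(13.7, abs=0.05)

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            percent_decrease(0.0, 1.0)


class TestStratificationCall:
    @staticmethod
    def _profile(center, width=3.0):
        depth = np.linspace(0, 100, 201)
        from retinads.anatomy import IntensityProfile
        return IntensityProfile.from_raw(depth, np.exp(-((depth - center) ** 2) / (2 * width**2)))

    def test_band_at_reference_is_stratified(self):
        from retinads.anatomy import stratification_call
        assert stratification_call(self._profile(31.0), reference_depth_pct=31.0)

    def test_band_far_from_reference_is_not(self):
        from retinads.anatomy import stratification_call
        assert not stratification_call(self._profile(70.0), reference_depth_pct=31.0)

    def test_diffuse_profile_fails_signal_fraction(self):
        from retinads.anatomy import IntensityProfile, stratification_call
        depth = np.linspace(0, 100, 201)
        # narrow peak at the reference atop a broad pedestal: peak is in
        # place but most signal lies outside the band window
        raw = 0.2 * np.exp(-((depth - 31.0) ** 2) / 18.0) + np.exp(-((depth - 50) ** 2) / (2 * 40.0**2))
        raw[62] += 0.3
        p = IntensityProfile.from_raw(depth, raw)
        assert not stratification_call(p, reference_depth_pct=31.0)
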