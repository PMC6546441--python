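"""Transect sampling, element means, contrast and crypsis scores."""

import numpy as np
import pytest

from wingcrypsis.colorspace import chromatic_distance, hsb_to_rgb, rgb_to_xyY
from wingcrypsis.simulate import WingSimParams, generate_wing_image
from wingcrypsis.transect import (
    CrypsisScore,
    LandmarkSet,
    SegmentBoundaries,
    TransectProfile,
    crypsis_score,
    element_mean_colors,
    internal_contrast,
    sample_transect,
)


def _profile_from_rgb(rgb_rows):
    rgb = np.asarray(rgb_rows, dtype=float)
    n = len(rgb)
    return TransectProfile(np.arange(n), np.zeros((n, 2), dtype=int), rgb)


class TestLandmarks:
    def test_five_points_required(self):
        with pytest.raises(ValueError):
            LandmarkSet(((1, 1), (1, 2), (1, 3)))

    def test_consecutive_duplicates_rejected(self):
        with pytest.raises(ValueError):
            LandmarkSet(((1, 1), (1, 1), (1, 3), (1, 4), (1, 5)))


class TestSampleTransect:
    def test_constant_field_samples_constant(self, uniform_image):
        lm = LandmarkSet(((10, 2), (10, 8), (10, 14), (10, 20), (10, 27)))
        profile = sample_transect(uniform_image, lm)
        np.testing.assert_allclose(profile.rgb, np.tile((0.5, 0.325, 0.2), (len(profile), 1)))

    def test_axis_aligned_sample_count(self, uniform_image):
        # 4 collinear horizontal legs spanning columns 2..11 -> 10 pixels
        lm = LandmarkSet(((5, 2), (5, 4), (5, 6), (5, 9), (5, 11)))
        profile = sample_transect(uniform_image, lm)
        assert len(profile) == 10
        assert np.all(np.diff(profile.positions) == 1)

    def test_shared_landmark_sampled_once(self, uniform_image):
        lm = LandmarkSet(((5, 2), (5, 6), (5, 10), (8, 13), (12, 13)))
        profile = sample_transect(uniform_image, lm)
        uniq = {tuple(rc) for rc in profile.coords}
        assert len(uniq) == len(profile)

    def test_border_landmark_rejected(self, uniform_image):
        lm = LandmarkSet(((0, 2), (5, 6), (5, 10), (5, 15), (5, 20)))
        with pytest.raises(ValueError, match="border"):
            sample_transect(uniform_image, lm)

    def test_focus_samples_match_generator_color(self, noiseless_wings):
        wing = noiseless_wings[27]
        profile = sample_transect(wing.image, wing.landmarks)
        idx = wing.boundaries.indices("eyespot_focus")
        np.testing.assert_allclose(
            profile.rgb[idx],
            np.tile(wing.element_colors["eyespot_focus"], (len(idx), 1)),
            atol=1e-14,
        )


class TestElementMeans:
    def test_single_sample_interval(self):
        profile = _profile_from_rgb([(0.2, 0.3, 0.4), (0.6, 0.5, 0.4)])
        bounds = SegmentBoundaries({"wing_background": [(0, 1)]})
        means = element_mean_colors(profile, bounds)
        expected = rgb_to_xyY((0.2, 0.3, 0.4))
        assert means["wing_background"].x == expected.x

    def test_two_equal_intervals_average_in_rgb(self):
        c1, c2 = (0.2, 0.1, 0.05), (0.6, 0.3, 0.15)
        profile = _profile_from_rgb([c1, c1, (0, 0, 1), c2, c2])
        bounds = SegmentBoundaries({"wing_background": [(0, 2), (3, 5)]})
        means = element_mean_colors(profile, bounds)
        expected = rgb_to_xyY(np.mean([c1, c2], axis=0))
        assert means["wing_background"].x == pytest.approx(expected.x, abs=1e-15)
        assert means["wing_background"].y == pytest.approx(expected.y, abs=1e-15)

    def test_zero_noise_wing_elements_exact(self, noiseless_wings):
        for wing in noiseless_wings.values():
            profile = sample_transect(wing.image, wing.landmarks)
            means = element_mean_colors(profile, wing.boundaries)
            for label, pt in means.items():
                target = rgb_to_xyY(wing.element_colors[label])
                assert abs(pt.x - target.x) <= 1e-12
                assert abs(pt.y - target.y) <= 1e-12

    def test_empty_interval_rejected(self):
        profile = _profile_from_rgb([(0.2, 0.3, 0.4)])
        with pytest.raises(ValueError):
            SegmentBoundaries({"wing_background": [(0, 0)]}).validate(1)

    def test_overlapping_labels_rejected(self):
        bounds = SegmentBoundaries(
            {"wing_background": [(0, 3)], "central_band": [(2, 4)]}
        )
        with pytest.raises(ValueError, match="overlap"):
            bounds.validate(5)


class TestInternalContrast:
    def test_all_elements_equal_background_gives_zero(self):
        c = (0.4, 0.3, 0.2)
        profile = _profile_from_rgb([c] * 6)
        bounds = SegmentBoundaries(
            {"wing_background": [(0, 2)], "central_band": [(2, 4)], "eyespot_focus": [(4, 6)]}
        )
        scores = internal_contrast(profile, bounds)
        assert {s.element for s in scores} == {"central_band", "eyespot_focus"}
        assert all(s.distance == 0.0 for s in scores)

    def test_missing_background_label_rejected(self):
        profile = _profile_from_rgb([(0.4, 0.3, 0.2)] * 4)
        bounds = SegmentBoundaries({"central_band": [(0, 4)]})
        with pytest.raises(ValueError, match="wing_background"):
            internal_contrast(profile, bounds)

    def test_dry_season_wing_less_contrasting(self, noiseless_wings):
        by_td = {}
        for td, wing in noiseless_wings.items():
            profile = sample_transect(wing.image, wing.landmarks)
            by_td[td] = {s.element: s.distance for s in internal_contrast(profile, wing.boundaries)}
        for element in by_td[19]:
            assert by_td[19][element] < by_td[27][element]

    def test_invariant_under_uniform_intensity_scaling(self, noiseless_wings):
        wing = noiseless_wings[19]
        profile = sample_transect(wing.image, wing.landmarks)
        half = sample_transect(wing.image * 0.5, wing.landmarks)
        s1 = {s.element: s.distance for s in internal_contrast(profile, wing.boundaries)}
        s2 = {s.element: s.distance for s in internal_contrast(half, wing.boundaries)}
        for el in s1:
            assert s1[el] == pytest.approx(s2[el], abs=1e-12)


class TestCrypsisScore:
    def test_uniform_profile_at_reference_is_zero(self):
        ref = rgb_to_xyY((0.5, 0.325, 0.2))
        profile = _profile_from_rgb([(0.5, 0.325, 0.2)] * 5)
        assert crypsis_score(profile, ref).score == 0.0

    def test_constant_profile_reduces_to_point_distance(self):
        ref = rgb_to_xyY((1.0, 0.0, 0.0))
        profile = _profile_from_rgb([(1.0, 1.0, 1.0)] * 7)
        assert crypsis_score(profile, ref).score == pytest.approx(0.3273, abs=1e-3)

    def test_adding_reference_samples_decreases_score(self):
        ref_rgb = (0.5, 0.325, 0.2)
        ref = rgb_to_xyY(ref_rgb)
        base = _profile_from_rgb([(0.2, 0.5, 0.25)] * 5)
        extended = _profile_from_rgb([(0.2, 0.5, 0.25)] * 5 + [ref_rgb] * 3)
        s0 = crypsis_score(base, ref).score
        assert s0 > 0
        assert crypsis_score(extended, ref).score < s0

    def test_degenerate_black_samples_excluded(self):
        ref = rgb_to_xyY((0.5, 0.325, 0.2))
        with_black = _profile_from_rgb([(0.5, 0.325, 0.2)] * 4 + [(0.0, 0.0, 0.0)])
        result = crypsis_score(with_black, ref)
        assert result.score == 0.0
        assert result.n_samples == 4

    def test_dry_season_wing_more_cryptic_against_brown(self, noiseless_wings):
        brown = rgb_to_xyY(hsb_to_rgb(25.0, 0.60, 0.50))
        scores = {}
        for td, wing in noiseless_wings.items():
            profile = sample_transect(wing.image, wing.landmarks)
            scores[td] = crypsis_score(profile, brown).score
        assert scores[19] < scores[27]
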