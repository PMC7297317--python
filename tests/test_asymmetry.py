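import numpy as np
import pytest
from helpers import brute_force_moments, disk_mask
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from dermabcd import (
    asymmetry_features,
    central_moments,
    profile_correlation,
    projection_profiles,
    projection_skewness,
    sift_similarity,
    split_halves,
    total_similarity,
)
from dermabcd.asymmetry import HalfPair, _descriptors


class TestSplitHalves:
    def test_centred_square_halves_mirror(self):
        mask = np.zeros((21, 21), dtype=bool)
        mask[5:16, 5:16] = True
        vertical, horizontal = split_halves(mask)
        assert vertical.first.shape == vertical.second.shape
        assert horizontal.first.shape == horizontal.second.shape
        # left half mirrored equals right half (up to the padded centre line)
        v1 = vertical.first > 0
        v2 = vertical.second > 0
        assert abs(int(v1.sum()) - int(v2.sum())) <= mask.shape[0]

    def test_off_centre_lesion_centroid_split_nonempty_halves(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[2:12, 25:39] = True
        vertical, horizontal = split_halves(mask, center="centroid")
        for pair in (vertical, horizontal):
            assert (pair.first > 0).sum() >= 1
            assert (pair.second > 0).sum() >= 1

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            split_halves(np.zeros((8, 8), dtype=bool))

    def test_mismatched_halves_rejected(self):
        with pytest.raises(ValueError, match="identical dimensions"):
            HalfPair(np.zeros((3, 3)), np.zeros((3, 4)), axis="vertical")


class TestSiftSimilarity:
    def test_uniform_halves_score_zero(self):
        pair = HalfPair(np.full((40, 40), 90, dtype=np.uint8),
                        np.full((40, 40), 90, dtype=np.uint8), axis="vertical")
        assert sift_similarity(pair) == 0

    def test_identical_copy_matches_brute_force_enumeration(self, circle_lesion):
        """Self-match count verified by an independent nested-loop matcher."""
        vertical, _ = split_halves(circle_lesion)
        half = vertical.first
        pair = HalfPair(half, half.copy(), axis="vertical")
        count = sift_similarity(pair, ratio=0.7)

        desc = _descriptors(half)
        expected = 0
        if len(desc) >= 2:
            for i in range(len(desc)):
                dists = sorted(float(np.linalg.norm(desc[i] - desc[j]))
                               for j in range(len(desc)))
                if dists[0] < 0.7 * dists[1]:
                    expected += 1
        assert count == expected

    def test_symmetrized_count_swap_invariant(self, lopsided_lesion):
        vertical, _ = split_halves(lopsided_lesion)
        swapped = HalfPair(vertical.second, vertical.first, axis="vertical")
        assert sift_similarity(vertical) == sift_similarity(swapped)

    def test_total_is_sum_of_pair_scores(self, circle_lesion):
        vertical, horizontal = split_halves(circle_lesion)
        v_s = sift_similarity(vertical)
        h_s = sift_similarity(horizontal)
        total = total_similarity(circle_lesion)
        assert total == v_s + h_s
        assert total >= max(v_s, h_s) >= 0

    def test_blank_lesion_total_zero(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[20:44, 20:44] = True  # flat square: no texture, no keypoints
        assert total_similarity(mask) == 0


class TestProjectionProfiles:
    def test_all_foreground(self):
        prof = projection_profiles(np.ones((3, 3), dtype=bool))
        np.testing.assert_array_equal(prof.horizontal, [3, 3, 3])
        np.testing.assert_array_equal(prof.vertical, [3, 3, 3])

    def test_single_row(self):
        mask = np.zeros((1, 5), dtype=bool)
        mask[0] = True
        prof = projection_profiles(mask)
        np.testing.assert_array_equal(prof.horizontal, [5])
        np.testing.assert_array_equal(prof.vertical, [1, 1, 1, 1, 1])

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_row_and_column_sums_count_area(self, seed):
        mask = np.random.default_rng(seed).random((12, 17)) > 0.5
        prof = projection_profiles(mask)
        assert prof.horizontal.sum() == prof.vertical.sum() == mask.sum()


class TestProfileCorrelation:
    def test_circle_horizontal_vertical_profiles_correlate_to_one(self):
        mask = disk_mask(30)
        prof = projection_profiles(mask)
        assert profile_correlation(prof.horizontal, prof.vertical) == \
            pytest.approx(1.0, abs=1e-6)

    def test_self_correlation(self, rng):
        h = rng.integers(0, 50, 20)
        h[0] += 1  # ensure variance
        assert profile_correlation(h, h) == pytest.approx(1.0)

    def test_anti_correlation(self, rng):
        h = rng.integers(0, 50, 20).astype(float)
        h[0] += 1
        assert profile_correlation(h, -h + 60) == pytest.approx(-1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            profile_correlation(np.full(10, 3), np.arange(10))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="equal length"):
            profile_correlation(np.arange(5), np.arange(6))

    def test_transpose_symmetric_mask_scores_one(self, rng):
        m = rng.random((15, 15)) > 0.5
        m = m | m.T  # symmetric under transpose
        prof = projection_profiles(m)
        assert profile_correlation(prof.horizontal, prof.vertical) == \
            pytest.approx(1.0)


class TestMoments:
    def test_single_pixel(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 3] = True
        mom = central_moments(mask)
        assert mom.area == 1
        for key, val in mom.central.items():
            if sum(key) > 0:
                assert val == 0.0

    def test_first_central_moments_vanish(self, rng):
        mask = rng.random((20, 20)) > 0.4
        mom = central_moments(mask)
        assert abs(mom.central[(1, 0)]) < 1e-9
        assert abs(mom.central[(0, 1)]) < 1e-9

    def test_symmetric_ellipse_odd_moments_vanish(self):
        yy, xx = np.mgrid[0:41, 0:61]
        mask = ((xx - 30) / 25) ** 2 + ((yy - 20) / 15) ** 2 <= 1
        mom = central_moments(mask)
        assert abs(mom.central[(3, 0)]) <= 1e-6 * mom.area
        assert abs(mom.central[(0, 3)]) <= 1e-6 * mom.area

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_double_loop_oracle(self, seed):
        mask = np.random.default_rng(seed).random((16, 16)) > 0.5
        if not mask.any():
            pytest.skip("empty draw")
        mom = central_moments(mask)
        oracle = brute_force_moments(mask)
        for key, val in oracle.items():
            assert mom.central[key] == pytest.approx(val, abs=1e-6)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            central_moments(np.zeros((4, 4), dtype=bool))


class TestSkewness:
    def test_symmetric_mask_zero_skewness(self):
        sk_h, sk_v = projection_skewness(central_moments(disk_mask(20)))
        assert sk_h == pytest.approx(0.0, abs=1e-9)
        assert sk_v == pytest.approx(0.0, abs=1e-9)

    def test_right_tailed_shape_positive_horizontal_skewness(self):
        mask = np.zeros((30, 60), dtype=bool)
        mask[10:20, 5:15] = True  # block
        mask[13:17, 15:55] = True  # long thin tail to the right
        sk_h, _ = projection_skewness(central_moments(mask))
        assert sk_h > 0

    def test_mirroring_negates_horizontal_skewness(self, rng):
        mask = rng.random((24, 24)) > 0.55
        mask[3:9, 2:20] = True
        sk_h, sk_v = projection_skewness(central_moments(mask))
        mk_h, mk_v = projection_skewness(central_moments(mask[:, ::-1]))
        assert mk_h == pytest.approx(-sk_h, abs=1e-9)
        assert mk_v == pytest.approx(sk_v, abs=1e-9)

    def test_scale_invariance(self):
        """Skewness is dimensionless: invariant under uniform mask scaling."""
        def lopsided(r):
            yy, xx = np.mgrid[0: 4 * r, 0: 4 * r]
            c = 2 * r
            disk = (xx - c) ** 2 + (yy - c) ** 2 <= r**2
            halfdisk = disk & (xx <= c)
            return halfdisk

        sk30 = projection_skewness(central_moments(lopsided(30)))
        sk60 = projection_skewness(central_moments(lopsided(60)))
        assert sk30[0] == pytest.approx(sk60[0], abs=0.05)

    def test_degenerate_line_raises(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, :] = True
        with pytest.raises(ValueError, match="second moment"):
            projection_skewness(central_moments(mask))


class TestFeatureVector:
    def test_circle_fixture_symmetric_signature(self, circle_lesion):
        feats = asymmetry_features(circle_lesion)
        assert feats.projection_correlation == pytest.approx(1.0, abs=1e-3)
        assert feats.skewness_summary == pytest.approx(0.0, abs=0.01)
        assert feats.as_array().shape == (3,)

    def test_lopsided_fixture_more_skewed_than_circle(self, circle_lesion,
                                                      lopsided_lesion):
        sym = asymmetry_features(circle_lesion)
        asym = asymmetry_features(lopsided_lesion)
        assert asym.skewness_summary > sym.skewness_summary

    def test_empty_lesion_raises(self):
        with pytest.raises(ValueError, match="empty"):
            asymmetry_features(np.zeros((10, 10), dtype=bool))
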