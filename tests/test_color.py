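import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermabcd import (
    dominant_palette,
    lab_to_rgb,
    load_color_table,
    minkowski_distance,
    rgb_to_lab,
    suspicious_color_report,
)


class TestLabConversion:
    def test_white_point(self):
        lab = rgb_to_lab(np.array([[[255, 255, 255]]], dtype=np.uint8))[0, 0]
        assert lab[0] == pytest.approx(100.0, abs=0.01)
        assert abs(lab[1]) < 0.01 and abs(lab[2]) < 0.01

    def test_black(self):
        lab = rgb_to_lab(np.array([[[0, 0, 0]]], dtype=np.uint8))[0, 0]
        np.testing.assert_allclose(lab, 0.0, atol=1e-6)

    def test_round_trip_delta_e(self, rng):
        """Lab -> sRGB -> Lab round trip stays within dE < 0.5 for in-gamut colors."""
        from skimage.color import lab2rgb

        # in-gamut by construction: start from valid sRGB values
        labs = rgb_to_lab(rng.uniform(0.05, 0.95, (1, 50, 3)))
        back = rgb_to_lab(lab2rgb(labs))  # float path: no quantization
        delta_e = np.linalg.norm(back - labs, axis=-1)
        assert delta_e.max() < 0.5

    def test_round_trip_8bit_quantization_bounded(self, rng):
        labs = rgb_to_lab(rng.integers(10, 246, (1, 50, 3)).astype(np.uint8))
        back = rgb_to_lab(lab_to_rgb(labs))
        assert np.linalg.norm(back - labs, axis=-1).max() < 1.0


class TestDominantPalette:
    def test_seven_flat_patches_recovered(self):
        colors = np.array([[10, 0, 0], [30, 10, 10], [50, -20, 5], [70, 5, 30],
                           [90, 0, 0], [40, 30, -30], [60, -10, -10]], dtype=float)
        pixels = np.repeat(colors, 40, axis=0)
        pal = dominant_palette(pixels, k=7, seed=0)
        found = pal.colors[np.argsort(pal.colors[:, 0])]
        np.testing.assert_allclose(found, colors[np.argsort(colors[:, 0])], atol=1e-6)
        assert pal.proportions.sum() == pytest.approx(1.0)

    def test_centroids_are_cluster_means(self, rng):
        """k-means fixed point: each centroid equals the mean of its members."""
        pixels = rng.normal(0, 1, (200, 3)) + rng.choice([0, 20], (200, 1))
        pal = dominant_palette(pixels, k=4, seed=1)
        for i in range(4):
            members = pixels[pal.labels == i]
            if len(members):
                np.testing.assert_allclose(pal.colors[i], members.mean(0), atol=1e-6)

    def test_sse_competitive_with_reference_kmeans(self, rng):
        """Within-cluster SSE matches an independent seeded k-means run."""
        from scipy.cluster.vq import kmeans2

        centers = rng.choice([0.0, 15.0, 40.0], (200, 1))
        pixels = rng.normal(0, 1.0, (200, 3)) + centers
        pal = dominant_palette(pixels, k=3, seed=0)
        codebook, labels = kmeans2(pixels, 3, minit="++", seed=7)
        ref_sse = sum(((pixels[labels == i] - codebook[i]) ** 2).sum() for i in range(3))
        assert pal.inertia <= ref_sse * 1.05

    def test_fewer_distinct_colors_padded_and_flagged(self):
        pixels = np.repeat([[10.0, 0, 0], [50.0, 5, 5]], 30, axis=0)
        pal = dominant_palette(pixels, k=7, seed=0)
        assert pal.degenerate
        assert pal.colors.shape == (7, 3)
        assert pal.proportions.sum() == pytest.approx(1.0)

    def test_black_entry_flagged(self):
        pixels = np.vstack([np.zeros((50, 3)), np.full((50, 3), [40.0, 10, 10])])
        pal = dominant_palette(pixels, k=2, seed=0)
        assert pal.black_index is not None
        assert pal.colors[pal.black_index, 0] < 1.0


class TestMinkowski:
    def test_white_black_halved_is_fifty(self):
        d = minkowski_distance([100, 0, 0], [0, 0, 0], p=3)
        assert d == 100.0
        assert d / 2 == 50.0

    def test_reduces_to_euclidean_and_manhattan(self, rng):
        x, y = rng.normal(0, 10, 3), rng.normal(0, 10, 3)
        assert minkowski_distance(x, y, p=2) == pytest.approx(np.linalg.norm(x - y))
        assert minkowski_distance(x, y, p=1) == pytest.approx(np.abs(x - y).sum())

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.floats(1.0, 6.0))
    def test_metric_axioms(self, seed, p):
        rng = np.random.default_rng(seed)
        x, y, z = rng.normal(0, 20, (3, 3))
        assert minkowski_distance(x, x, p) == 0.0
        dxy = minkowski_distance(x, y, p)
        assert dxy == pytest.approx(minkowski_distance(y, x, p))
        assert dxy <= minkowski_distance(x, z, p) + minkowski_distance(z, y, p) + 1e-9

    def test_p_below_one_rejected(self):
        with pytest.raises(ValueError, match="p"):
            minkowski_distance([1, 0, 0], [0, 0, 0], p=0.5)


class TestSuspiciousColors:
    def test_single_dark_brown_lesion_counts_one(self, rng):
        pixels = np.array([30.0, 15.0, 20.0]) + rng.normal(0, 0.5, (500, 3))
        report = suspicious_color_report(pixels, seed=0)
        assert report.count == 1
        assert report.presence["dark_brown"]

    def test_five_percent_rule_gates_minor_color(self, rng):
        gray = np.array([60.0, 0.0, 0.0]) + rng.normal(0, 0.3, (960, 3))
        red = np.array([54.29, 80.81, 69.89]) + rng.normal(0, 0.3, (40, 3))
        report = suspicious_color_report(np.vstack([gray, red]), seed=0)
        assert not report.presence["red"]  # 4% < the 5% rule

    def test_three_painted_colors_counted(self, rng):
        fills = np.array([[30.0, 15, 25], [60.0, 25, 40], [50.0, -25, -10]])
        pixels = fills[rng.integers(0, 3, 600)] + rng.normal(0, 1.0, (600, 3))
        report = suspicious_color_report(pixels, seed=0)
        assert report.count == 3
        assert report.presence["dark_brown"]
        assert report.presence["light_brown"]
        assert report.presence["blue_gray"]

    def test_count_bounds_and_determinism(self, rng):
        pixels = rng.uniform([0, -30, -30], [90, 60, 60], (300, 3))
        r1 = suspicious_color_report(pixels, seed=3)
        r2 = suspicious_color_report(pixels, seed=3)
        assert 0 <= r1.count <= 6
        assert r1.presence == r2.presence

    def test_pixel_order_invariance(self, rng):
        fills = np.array([[30.0, 15, 25], [96.0, 1, 1]])
        pixels = fills[rng.integers(0, 2, 400)] + rng.normal(0, 1.0, (400, 3))
        shuffled = pixels[rng.permutation(len(pixels))]
        assert suspicious_color_report(pixels, seed=0).presence == \
            suspicious_color_report(shuffled, seed=0).presence

    def test_per_pixel_mode_adding_present_color_monotone(self, rng):
        pixels = np.array([30.0, 15, 25]) + rng.normal(0, 0.5, (200, 3))
        base = suspicious_color_report(pixels, per_pixel=True)
        more = suspicious_color_report(
            np.vstack([pixels, np.tile([30.0, 15, 25], (100, 1))]), per_pixel=True
        )
        assert more.count >= base.count

    def test_pure_black_palette_entry_excluded(self, rng):
        # half background black, half dark brown: black slot must not count
        black = np.zeros((300, 3)) + rng.normal(0, 0.1, (300, 3))
        brown = np.array([30.0, 15, 25]) + rng.normal(0, 0.5, (300, 3))
        report = suspicious_color_report(np.vstack([black, brown]), seed=0)
        assert report.presence["dark_brown"]
        assert not report.presence["black"]

    def test_empty_lesion_raises(self):
        with pytest.raises(ValueError, match="empty"):
            suspicious_color_report(np.empty((0, 3)))

    def test_table_ranges_well_formed(self):
        table = load_color_table()
        assert set(table.ranges) == {"black", "dark_brown", "light_brown"}
        assert set(table.references) == {"white", "red", "blue_gray"}
        for rng_ in table.ranges.values():
            assert (rng_.lo <= rng_.hi).all()
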