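"""Grad-CAM mechanics, patch selection, chromaticity, and cluster statistics."""

import numpy as np
import pytest

from filasense.nn import Conv2D, Dense, Flatten, ReLU, Sequential
from filasense.saliency_chroma import (extract_patches, gradcam,
                                       mahalanobis_distances,
                                       patch_chromaticity, silhouette_stats)


def toy_model(rng, side=4, channels=2, zero_bias=False):
    """conv -> relu -> flatten -> dense head; small enough to hand-verify."""
    conv = Conv2D(1, channels, rng=rng)
    dense = Dense(side * side * channels, 3, rng=rng)
    if zero_bias:
        conv.params[1][...] = 0.0
        dense.params[1][...] = 0.0
    return Sequential([("conv3_2", conv), ("relu3_2", ReLU()),
                       ("flatten", Flatten()), ("fc2", dense)])


class TestGradCam:
    def test_matches_hand_computed_activation_gradient_map(self, rng):
        """Oracle: for score_c = w_c . flatten(relu(conv x)), the gradient at
        the ReLU output is w_c reshaped; Grad-CAM is then
        relu(sum_ch mean(w_c[..., ch]) * act[..., ch]), max-normalised."""
        model = toy_model(rng)
        x = rng.random((4, 4, 1)).astype(np.float32)
        target = 1
        heat = gradcam(model, x, target_class=target, layer="relu3_2")

        act = model.forward(x[None], mode="eval", tap="relu3_2")[1][0]
        w_c = model.get_layer("fc2").params[0][:, target].reshape(4, 4, 2)
        cam = np.zeros((4, 4))
        for ch in range(2):
            cam += w_c[:, :, ch].mean() * act[:, :, ch]
        cam = np.maximum(cam, 0)
        if cam.max() > 0:
            cam = cam / cam.max()
        np.testing.assert_allclose(heat, cam, atol=1e-5)

    def test_zero_input_on_bias_free_model_gives_zero_heatmap(self, rng):
        model = toy_model(rng, zero_bias=True)
        heat = gradcam(model, np.zeros((4, 4, 1), np.float32), target_class=0)
        assert np.all(heat == 0)

    def test_heatmap_max_is_one_when_nondegenerate(self, rng):
        model = toy_model(rng)
        heat = gradcam(model, rng.random((4, 4, 1)).astype(np.float32))
        assert heat.max() == pytest.approx(1.0)
        assert heat.min() >= 0.0

    def test_heatmap_upsampled_to_input_size(self):
        from filasense.classifier import build_network, ArchitectureSpec
        model = build_network(ArchitectureSpec(input_side=32,
                                               block_filters=(4, 8, 16, 32)), seed=0)
        rng = np.random.default_rng(0)
        heat = gradcam(model, rng.random((32, 32, 3)).astype(np.float32))
        assert heat.shape == (32, 32)

    def test_non_relu_layer_rejected(self, rng):
        model = toy_model(rng)
        with pytest.raises(ValueError):
            gradcam(model, np.zeros((4, 4, 1)), layer="conv3_2")
        with pytest.raises(ValueError):
            gradcam(model, np.zeros((4, 4, 1)), layer="relu9_9")


class TestExtractPatches:
    def test_three_isolated_maxima_centre_the_windows(self):
        img = np.zeros((64, 64, 3))
        heat = np.zeros((64, 64))
        centres = [(10, 12), (40, 45), (55, 20)]
        for v, (r, c) in zip((1.0, 0.9, 0.8), centres):
            heat[r, c] = v
        patches = extract_patches(img, heat, k=3, patch_side=8)
        assert [(r0, c0) for _, (r0, c0) in patches] == [(6, 8), (36, 41), (51, 16)]

    def test_uniform_heatmap_takes_row_major_first_argmax(self):
        img = np.zeros((64, 64, 3))
        patches = extract_patches(img, np.ones((64, 64)), k=1, patch_side=8)
        assert patches[0][1] == (0, 0)

    def test_selected_windows_pairwise_disjoint_on_random_heatmaps(self, rng):
        for _ in range(20):
            heat = rng.random((96, 96))
            windows = [coords for _, coords in
                       extract_patches(np.zeros((96, 96, 3)), heat, k=3,
                                       patch_side=16)]
            # brute-force disjointness check
            for i, (r1, c1) in enumerate(windows):
                for r2, c2 in windows[i + 1:]:
                    cells1 = {(r, c) for r in range(r1, r1 + 16)
                              for c in range(c1, c1 + 16)}
                    cells2 = {(r, c) for r in range(r2, r2 + 16)
                              for c in range(c2, c2 + 16)}
                    assert not cells1 & cells2

    def test_fewer_windows_when_frame_too_small(self):
        img = np.zeros((64, 64, 3))
        patches = extract_patches(img, np.ones((64, 64)), k=3, patch_side=64)
        assert len(patches) == 1

    def test_border_peak_recentred_inside_frame(self):
        heat = np.zeros((64, 64))
        heat[0, 63] = 1.0
        patches = extract_patches(np.zeros((64, 64, 3)), heat, k=1, patch_side=16)
        assert patches[0][1] == (0, 48)

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            extract_patches(np.zeros((64, 64, 3)), np.zeros((32, 32)))


class TestPatchChromaticity:
    def test_exactly_thirty_nonblack_pixels_all_selected(self, rng):
        patch = np.zeros((8, 8, 3))
        idx = rng.choice(64, size=30, replace=False)
        patch.reshape(64, 3)[idx] = rng.uniform(0.1, 1.0, size=(30, 3))
        points = patch_chromaticity(patch, n_pixels=30)
        assert len(points) == 30

    def test_pure_red_pixels_map_to_unit_r(self):
        patch = np.zeros((4, 4, 3))
        patch[:, :, 0] = 1.0
        points = patch_chromaticity(patch, n_pixels=30)
        np.testing.assert_allclose(points, np.tile([1.0, 0.0], (16, 1)))

    def test_selection_matches_brute_force_brightness_sort(self, rng):
        patch = rng.random((16, 16, 3))
        points = patch_chromaticity(patch, n_pixels=30)
        flat = patch.reshape(-1, 3)
        bright = flat.sum(axis=1)
        top = flat[np.argsort(-bright, kind="stable")[:30]]
        expect = top[:, :2] / top.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(points, expect)

    def test_all_black_patch_gives_empty_list(self):
        assert len(patch_chromaticity(np.zeros((8, 8, 3)))) == 0

    def test_implied_rgb_triple_normalised(self, rng):
        points = patch_chromaticity(rng.random((16, 16, 3)), n_pixels=30)
        r, g = points[:, 0], points[:, 1]
        b = 1.0 - r - g
        assert np.all(r >= 0) and np.all(g >= 0) and np.all(b >= -1e-12)
        np.testing.assert_allclose(r + g + b, 1.0, atol=1e-12)


class TestSilhouette:
    def test_two_tight_distant_clusters_score_near_one(self, rng):
        a = rng.normal(0, 0.01, size=(20, 2))
        b = rng.normal(5, 0.01, size=(20, 2)) + [5, 0]
        pts = np.vstack([a, b])
        labels = ["a"] * 20 + ["b"] * 20
        rep = silhouette_stats(pts, labels)
        assert (rep.per_class["mean"] > 0.9).all()

    def test_four_point_textbook_oracle(self):
        """Hand computation of a(i), b(i) for two 2-point clusters."""
        pts = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
        labels = ["a", "a", "b", "b"]
        rep = silhouette_stats(pts, labels)
        # every point: a(i) = 1; b(i) = (10 + sqrt(101)) / 2
        b_i = (10.0 + np.sqrt(101.0)) / 2.0
        expect = (b_i - 1.0) / b_i
        assert rep.weighted_mean == pytest.approx(expect, abs=1e-12)
        assert rep.per_class.loc["a", "mean"] == pytest.approx(expect, abs=1e-12)
        assert rep.per_class.loc["a", "iqr"] == pytest.approx(0.0, abs=1e-12)
        assert rep.per_class.loc["a", "frac_positive"] == 1.0

    def test_weighted_mean_identity(self, rng):
        pts = rng.random((60, 2))
        labels = rng.choice(["a", "b", "c"], size=60)
        rep = silhouette_stats(pts, labels)
        weighted = (rep.per_class["mean"] * rep.per_class["n"]).sum() / \
            rep.per_class["n"].sum()
        assert rep.weighted_mean == pytest.approx(weighted, abs=1e-12)
        lo, hi = rep.ci95
        assert lo < rep.weighted_mean < hi

    def test_values_bounded_in_unit_interval(self, rng):
        pts = rng.random((50, 2))
        labels = rng.choice(["a", "b"], size=50)
        rep = silhouette_stats(pts, labels)
        assert (rep.per_class["mean"].abs() <= 1).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            silhouette_stats(np.random.rand(5, 2), ["a"] * 5)


class TestMahalanobis:
    def test_identical_centroids_give_zero(self, rng):
        base = rng.normal(0, 1, size=(30, 2))
        pts = np.vstack([base, base])
        labels = ["a"] * 30 + ["b"] * 30
        d = mahalanobis_distances(pts, labels)
        assert d.loc["a", "b"] == pytest.approx(0.0, abs=1e-9)

    def test_identity_pooled_covariance_reduces_to_euclidean(self):
        """Clusters built so the pooled covariance is exactly I: the
        Mahalanobis distance then equals the centroid Euclidean distance."""
        s = np.sqrt(1.5)
        cross = np.array([[s, 0.0], [-s, 0.0], [0.0, s], [0.0, -s]])
        mu = np.array([3.0, 4.0])
        pts = np.vstack([cross, cross + mu])
        labels = ["a"] * 4 + ["b"] * 4
        d = mahalanobis_distances(pts, labels)
        assert d.loc["a", "b"] == pytest.approx(5.0, abs=1e-9)

    def test_two_class_case_matches_hand_inverted_covariance(self):
        """Brute-force oracle: explicit adjugate inversion of the pooled 2x2
        covariance."""
        a = np.array([[0.0, 0.0], [2.0, 1.0], [1.0, 2.0], [3.0, 3.0]])
        b = a + np.array([4.0, 1.0])
        pts = np.vstack([a, b])
        labels = ["a"] * 4 + ["b"] * 4
        mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
        scatter = np.zeros((2, 2))
        for cloud, mu in ((a, mu_a), (b, mu_b)):
            for p in cloud:
                d = (p - mu)[:, None]
                scatter += d @ d.T
        S = scatter / (8 - 2)
        det = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
        S_inv = np.array([[S[1, 1], -S[0, 1]], [-S[1, 0], S[0, 0]]]) / det
        delta = mu_a - mu_b
        expect = float(np.sqrt(delta @ S_inv @ delta))
        d = mahalanobis_distances(pts, labels)
        assert d.loc["a", "b"] == pytest.approx(expect, abs=1e-9)

    def test_symmetric_with_zero_diagonal(self, rng):
        pts = rng.random((40, 2))
        labels = rng.choice(["a", "b", "c"], size=40)
        d = mahalanobis_distances(pts, labels).to_numpy()
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(d), 0.0, atol=1e-12)
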