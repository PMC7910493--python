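import numpy as np
import pytest

from dhikit.coregistration import (
    LandmarkSet,
    fit_tps,
    load_landmarks,
    rgb_to_grayscale,
    save_landmarks,
    transfer_rois,
    warp,
)


def random_landmarks(rng, n=18, scale=100.0):
    src = rng.uniform(0, scale, (n, 2))
    dst = src + rng.uniform(-10, 10, (n, 2))
    return LandmarkSet(source=src, target=dst)


class TestGrayscale:
    @pytest.mark.parametrize("rgb, expected", [
        ((255, 255, 255), 255),
        ((255, 0, 0), 76),      # 0.299 · 255, rounded
        ((0, 255, 0), 150),
        ((17, 17, 17), 17),
    ])
    def test_luminance_values(self, rgb, expected):
        img = np.full((2, 2, 3), rgb, dtype=np.uint8)
        out = rgb_to_grayscale(img)
        assert out.dtype == np.uint8
        assert np.all(out == expected)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            rgb_to_grayscale(np.zeros((4, 4)))


class TestFitTps:
    def test_identity(self):
        rng = np.random.default_rng(0)
        src = rng.uniform(0, 50, (10, 2))
        t = fit_tps(LandmarkSet(source=src, target=src.copy()))
        np.testing.assert_allclose(t.weights, 0.0, atol=1e-8)
        np.testing.assert_allclose(t.affine, [[0, 0], [1, 0], [0, 1]], atol=1e-8)

    def test_pure_translation_is_affine(self):
        rng = np.random.default_rng(1)
        src = rng.uniform(0, 50, (8, 2))
        t = fit_tps(LandmarkSet(source=src, target=src + [5.0, -3.0]))
        np.testing.assert_allclose(t.weights, 0.0, atol=1e-8)
        np.testing.assert_allclose(t.affine[0], [5.0, -3.0], atol=1e-8)

    def test_general_affine_has_zero_warp(self):
        rng = np.random.default_rng(2)
        src = rng.uniform(0, 100, (12, 2))
        a = np.array([[1.2, -0.3], [0.4, 0.9]])
        dst = src @ a.T + [7.0, -2.0]
        t = fit_tps(LandmarkSet(source=src, target=dst))
        np.testing.assert_allclose(t.weights, 0.0, atol=1e-7)

    def test_eighteen_random_pairs_interpolated(self):
        rng = np.random.default_rng(3)
        lm = random_landmarks(rng, n=18)
        t = fit_tps(lm, regularization=0.0)
        residual = np.abs(t(lm.source) - lm.target).max()
        assert residual < 1e-6

    def test_side_conditions(self):
        rng = np.random.default_rng(4)
        lm = random_landmarks(rng, n=18)
        t = fit_tps(lm)
        np.testing.assert_allclose(t.weights.sum(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(t.source.T @ t.weights, 0.0, atol=1e-6)

    def test_matches_scipy_rbf_interpolator(self):
        from scipy.interpolate import RBFInterpolator

        rng = np.random.default_rng(5)
        lm = random_landmarks(rng, n=15)
        t = fit_tps(lm)
        ref = RBFInterpolator(lm.source, lm.target,
                              kernel="thin_plate_spline", smoothing=0.0)
        query = rng.uniform(10, 90, (40, 2))
        # same spline family up to the kernel scale convention:
        # r² log r² = 2 · r² log r
        np.testing.assert_allclose(t(query), ref(query), atol=1e-6)

    def test_bending_energy_nonincreasing_in_regularization(self):
        rng = np.random.default_rng(6)
        lm = random_landmarks(rng, n=18)
        energies = [fit_tps(lm, reg).bending_energy() for reg in (0.0, 1.0, 10.0)]
        assert energies[0] >= energies[1] >= energies[2] - 1e-9

    def test_duplicate_landmarks_rejected(self):
        src = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(np.linalg.LinAlgError):
            fit_tps(LandmarkSet(source=src, target=src + 1))

    def test_landmark_tsv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(7)
        lm = random_landmarks(rng, n=5)
        save_landmarks(lm, tmp_path / "lm.tsv")
        back = load_landmarks(tmp_path / "lm.tsv")
        np.testing.assert_allclose(back.source, lm.source)
        np.testing.assert_allclose(back.target, lm.target)


class TestWarp:
    def test_identity_transform(self):
        rng = np.random.default_rng(8)
        img = rng.uniform(0, 255, (12, 12))
        src = np.array([[0, 0], [11, 0], [0, 11], [11, 11.0]])
        t = fit_tps(LandmarkSet(source=src, target=src.copy()))
        np.testing.assert_allclose(warp(img, t, (12, 12)), img, atol=1e-6)

    def test_integer_translation_shifts_exactly(self):
        rng = np.random.default_rng(9)
        img = rng.uniform(0, 255, (16, 16))
        # output pixel (x, y) samples input (x - 3, y - 2)
        src = np.array([[0, 0], [15, 0], [0, 15], [15, 15.0]])
        t = fit_tps(LandmarkSet(source=src, target=src - [3.0, 2.0]))
        out = warp(img, t, (16, 16))
        np.testing.assert_allclose(out[2:, 3:], img[:-2, :-3], atol=1e-9)

    def test_nearest_preserves_label_values(self):
        rng = np.random.default_rng(10)
        mask = rng.integers(0, 4, (20, 20))
        lm = random_landmarks(rng, n=10, scale=19.0)
        t = fit_tps(lm)
        out = warp(mask, t, (20, 20), mode="nearest")
        assert set(np.unique(out)) <= set(np.unique(mask)) | {0}

    def test_unknown_mode_rejected(self):
        src = np.array([[0, 0], [1, 0], [0, 1.0]])
        t = fit_tps(LandmarkSet(source=src, target=src))
        with pytest.raises(ValueError):
            warp(np.ones((2, 2)), t, (2, 2), mode="cubic")


class TestTransferRois:
    @staticmethod
    def identity_transform(extent=100.0):
        src = np.array([[0, 0], [extent, 0], [0, extent], [extent, extent]])
        return fit_tps(LandmarkSet(source=src, target=src.copy()))

    @staticmethod
    def downscale_transform(factor, extent=100.0):
        src = np.array([[0, 0], [extent, 0], [0, extent], [extent, extent]])
        return fit_tps(LandmarkSet(source=src, target=src / factor))

    def test_full_frame_roi_labels_all_covered(self):
        masks = {2: np.ones((40, 40), bool)}
        labels = transfer_rois(masks, self.downscale_transform(4.0), (10, 10))
        assert np.all(labels == 2)

    def test_block_majority_matches_brute_force(self):
        # two disjoint ROIs on a 40×40 histology grid, 4× downscale
        hist = np.full((40, 40), -1)
        hist[:, :17] = 0          # class 0 slab
        hist[:, 23:] = 1          # class 1 slab
        masks = {c: hist == c for c in (0, 1)}
        t = self.downscale_transform(4.0)
        labels = transfer_rois(masks, t, (10, 10))
        # brute force per-voxel counting over histology pixel centers
        expected = np.full((10, 10), -1)
        counts = np.zeros((2, 10, 10), int)
        for y in range(40):
            for x in range(40):
                if hist[y, x] < 0:
                    continue
                mx, my = int(round(x / 4.0)), int(round(y / 4.0))
                if mx < 10 and my < 10:
                    counts[hist[y, x], my, mx] += 1
        for my in range(10):
            for mx in range(10):
                c = counts[:, my, mx]
                if c.sum() and c[0] != c[1]:
                    expected[my, mx] = int(np.argmax(c))
        np.testing.assert_array_equal(labels, expected)

    def test_empty_roi_set_gives_no_labels(self):
        labels = transfer_rois({}, self.identity_transform(), (5, 5))
        assert np.all(labels == -1)

    def test_overlapping_rois_rejected(self):
        masks = {0: np.ones((4, 4), bool), 1: np.ones((4, 4), bool)}
        with pytest.raises(ValueError):
            transfer_rois(masks, self.identity_transform(), (4, 4))
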