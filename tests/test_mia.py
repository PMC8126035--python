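import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from hemocount import (
    PCAModel,
    RGBImage,
    ScoreImage,
    calibrate_threshold,
    fit_pca,
    refold_center,
    score_image,
    threshold_scores,
    unfold,
)
from hemocount.mia import project_scores
from hemocount.training import TrainingImage
from .conftest import random_image


def _training_image(rng, h=30, w=30):
    """All-valid random training image (every unfolded row retained)."""
    img = random_image(rng, h, w)
    return TrainingImage(mosaic=img, valid=np.ones((h, w), dtype=bool))


def _brute_force_pca(X):
    """Independent oracle: eigendecomposition of the sample covariance."""
    cov = np.cov(X, rowvar=False, ddof=1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


class TestUnfold:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        pixels=hnp.arrays(np.uint8, st.tuples(st.integers(1, 9), st.integers(1, 9), st.just(3))),
        radius=st.integers(0, 3),
    )
    def test_dimension_law(self, pixels, radius):
        img = RGBImage(pixels.copy())
        mat = unfold(img, window_radius=radius)
        assert mat.n_features == 3 * (2 * radius + 1) ** 2
        assert mat.rows.shape[0] == pixels.shape[0] * pixels.shape[1]

    def test_5x5_radius_2_gives_25x75(self, rng):
        mat = unfold(random_image(rng, 5, 5), window_radius=2)
        assert mat.rows.shape == (25, 75)

    def test_1x1_radius_0_is_the_pixel(self):
        img = RGBImage(np.array([[[10, 20, 30]]], dtype=np.uint8))
        mat = unfold(img, window_radius=0)
        np.testing.assert_array_equal(mat.rows, [[10, 20, 30]])

    def test_constant_image_gives_identical_rows(self):
        img = RGBImage(np.full((6, 6, 3), 77, dtype=np.uint8))
        mat = unfold(img, window_radius=2)
        assert np.all(mat.rows == mat.rows[0])

    def test_rows_follow_valid_mask(self, rng):
        img = random_image(rng, 10, 10)
        valid = rng.random((10, 10)) < 0.5
        mat = unfold(img, valid, window_radius=1)
        assert mat.rows.shape[0] == int(valid.sum())
        np.testing.assert_array_equal(mat.pixel_index, np.argwhere(valid))

    @pytest.mark.parametrize("radius", [0, 1, 2, 3])
    def test_refold_center_identity(self, rng, radius):
        img = random_image(rng, 9, 7)
        mat = unfold(img, window_radius=radius)
        np.testing.assert_array_equal(refold_center(mat), img.pixels.astype(float))


class TestFitPCA:
    def test_loadings_match_brute_force_oracle(self, rng):
        train = _training_image(rng, 25, 25)  # 625 x 75 unfolded
        model = fit_pca(train, window_radius=2, n_components=10)
        X = unfold(train.mosaic, train.valid, 2).rows
        vals, vecs = _brute_force_pca(X)
        rel = np.abs(model.eigenvalues - vals) / vals[0]
        assert rel.max() < 1e-8
        for j in range(10):
            cos = abs(model.loadings[:, j] @ vecs[:, j])
            assert cos > 1 - 1e-8

    def test_orthonormal_and_sorted(self, rng):
        model = fit_pca(_training_image(rng), 2, 10)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(10), atol=1e-8)
        assert np.all(np.diff(model.eigenvalues) <= 1e-9)
        assert np.all(model.eigenvalues >= -1e-9)

    def test_trace_identity(self, rng):
        train = _training_image(rng)
        model = fit_pca(train, 2, 10)
        X = unfold(train.mosaic, train.valid, 2).rows
        total_var = ((X - X.mean(axis=0)) ** 2).sum() / (X.shape[0] - 1)
        assert model.eigenvalues.sum() == pytest.approx(total_var, rel=1e-6)

    def test_constant_training_image(self):
        px = np.full((10, 10, 3), 120, dtype=np.uint8)
        train = TrainingImage(RGBImage(px), np.ones((10, 10), dtype=bool))
        model = fit_pca(train, 1, 5)
        assert np.all(np.abs(model.eigenvalues) < 1e-12)
        scores = project_scores(unfold(train.mosaic, None, 1), model, 1)
        np.testing.assert_allclose(scores, 0, atol=1e-9)

    def test_rank_one_data(self, rng):
        # gray image at radius 0: centered rows span the (1,1,1) direction
        g = rng.integers(10, 200, (12, 12), dtype=np.uint8)
        px = np.stack([g, g, g], axis=2).astype(np.uint8)
        train = TrainingImage(RGBImage(px), np.ones((12, 12), dtype=bool))
        model = fit_pca(train, 0, 3)
        assert model.eigenvalues[0] > 1e-6
        assert np.all(model.eigenvalues[1:] < 1e-9)
        cos = abs(model.loadings[:, 0] @ (np.ones(3) / np.sqrt(3)))
        assert cos == pytest.approx(1.0, abs=1e-10)


class TestScoreImage:
    def test_matches_matrix_product_oracle(self, rng):
        train = _training_image(rng)
        model = fit_pca(train, 2, 10)
        img = random_image(rng, 15, 18)
        valid = np.ones((15, 18), dtype=bool)
        si = score_image(img, valid, model, component=3)
        X = unfold(img, valid, 2).rows
        expected = (X - model.mean) @ model.loadings[:, 2]
        assert np.abs(si.values[valid] - expected).max() < 1e-9

    def test_image_equal_to_mean_scores_zero(self, rng):
        px = np.full((9, 9, 3), 101, dtype=np.uint8)
        train = TrainingImage(RGBImage(px), np.ones((9, 9), dtype=bool))
        model = fit_pca(train, 1, 3)
        si = score_image(RGBImage(px), np.ones((9, 9), dtype=bool), model)
        np.testing.assert_allclose(si.values, 0, atol=1e-9)

    def test_training_mean_score_nonnegative(self, rng):
        # the sign convention: centering makes the training mean score ~0
        train = _training_image(rng)
        model = fit_pca(train, 2, 10)
        scores = project_scores(unfold(train.mosaic, train.valid, 2), model)
        assert scores.mean() >= -1e-8

    def test_component_out_of_range(self, rng):
        train = _training_image(rng)
        model = fit_pca(train, 2, 5)
        with pytest.raises(IndexError):
            score_image(random_image(rng), np.ones((12, 12), bool), model, component=6)

    def test_invalid_pixels_carry_no_score(self, rng):
        train = _training_image(rng)
        model = fit_pca(train, 2, 5)
        img = random_image(rng, 10, 10)
        valid = np.zeros((10, 10), dtype=bool)
        valid[3:6, 3:6] = True
        si = score_image(img, valid, model)
        assert np.all(si.values[~valid] == 0)


class TestThreshold:
    def _scores(self, values):
        v = np.asarray(values, dtype=float)[None, :]
        return ScoreImage(values=v, valid=np.ones_like(v, dtype=bool), component=1)

    def test_tau_below_min_keeps_valid_mask(self):
        si = self._scores([1, 2, 3])
        np.testing.assert_array_equal(threshold_scores(si, 0.5), si.valid)

    def test_tau_above_max_empty(self):
        assert threshold_scores(self._scores([1, 2, 3]), 4.0).sum() == 0

    def test_ge_convention(self):
        assert threshold_scores(self._scores([1, 2, 3]), 2.0).sum() == 2

    def test_median_quantile_order_statistics(self, rng):
        train = _training_image(rng, 21, 21)
        model = fit_pca(train, 2, 10)
        tau = calibrate_threshold(model, train, quantile=0.5)
        scores = project_scores(unfold(train.mosaic, train.valid, 2), model)
        n = scores.size
        assert int((scores >= tau).sum()) == int(np.ceil(n / 2))
        assert model.score_threshold == tau

    def test_tiny_quantile_keeps_nearly_all(self, rng):
        train = _training_image(rng)
        model = fit_pca(train, 2, 10)
        tau = calibrate_threshold(model, train, quantile=1e-6)
        scores = project_scores(unfold(train.mosaic, train.valid, 2), model)
        assert (scores >= tau).sum() >= scores.size - 1

    def test_constant_scores_threshold_is_constant(self):
        px = np.full((8, 8, 3), 33, dtype=np.uint8)
        train = TrainingImage(RGBImage(px), np.ones((8, 8), dtype=bool))
        model = fit_pca(train, 1, 3)
        assert calibrate_threshold(model, train, 0.3) == pytest.approx(0.0, abs=1e-12)


class TestPersistence:
    def test_json_roundtrip_bit_exact(self, rng, tmp_path):
        train = _training_image(rng)
        model = fit_pca(train, 2, 10)
        calibrate_threshold(model, train)
        p = tmp_path / "model.json"
        model.to_json(p)
        back = PCAModel.from_json(p)
        np.testing.assert_array_equal(back.mean, model.mean)
        np.testing.assert_array_equal(back.loadings, model.loadings)
        np.testing.assert_array_equal(back.eigenvalues, model.eigenvalues)
        assert back.score_threshold == model.score_threshold
        assert back.selected_pc == model.selected_pc

    def test_refit_is_bitwise_deterministic(self, tmp_path):
        rng1, rng2 = np.random.default_rng(7), np.random.default_rng(7)
        m1 = fit_pca(_training_image(rng1), 2, 8)
        m2 = fit_pca(_training_image(rng2), 2, 8)
        m1.to_json(tmp_path / "a.json")
        m2.to_json(tmp_path / "b.json")
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()
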