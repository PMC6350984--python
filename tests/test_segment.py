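import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from artexus.config import PipelineConfig, SegmentConfig
from artexus.segment import (
    EvalMetrics,
    SegmentationResult,
    cluster_patches,
    evaluate,
    featurize_image,
    paint_mask,
    tile,
)


class TestTile:
    @pytest.mark.parametrize(
        "shape, size, expected",
        [((760, 500), 20, (38, 25)), ((40, 40), 20, (2, 2)), ((39, 40), 20, (1, 2))],
    )
    def test_grid_shape(self, shape, size, expected):
        grid = tile(np.zeros(shape), size)
        assert (grid.n_rows, grid.n_cols) == expected

    def test_patch_count_for_typical_clinical_raster(self):
        assert tile(np.zeros((760, 500)), 20).n_patches == 950

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            tile(np.zeros((10, 40)), 20)

    def test_patches_are_disjoint_and_cover_grid(self):
        grid = tile(np.zeros((45, 63)), 20)
        seen = np.zeros((45, 63), dtype=int)
        for r in range(grid.n_rows):
            for c in range(grid.n_cols):
                sl = grid.patch_slices(r, c)
                seen[sl] += 1
        assert seen.max() == 1
        assert seen.sum() == grid.n_patches * 400


class TestFeaturize:
    def test_feature_matrix_shape(self, small_cfg, rng):
        img = rng.random((40, 40))
        feats, grid = featurize_image(img, small_cfg)
        assert feats.shape == (4, 30)
        assert grid.n_patches == 4

    def test_failure_reports_patch_coordinates(self, small_cfg):
        img = np.full((40, 40), 0.5)  # constant patches cannot be AR-fitted
        with pytest.raises(RuntimeError, match=r"patch \(0, 0\)"):
            featurize_image(img, small_cfg)

    def test_uniform_texture_has_low_feature_dispersion(self, default_cfg):
        """Within one texture class the features scatter (speckle) but stay
        within the same order of magnitude; across classes they separate by
        much more (see the end-to-end tests)."""
        from artexus.synthdata import TextureParams, gen_texture

        img = gen_texture(TextureParams(band=(0.1, 0.3)), (100, 100), seed=5)
        feats, _ = featurize_image(img, default_cfg)
        cv = feats.std(axis=0) / feats.mean(axis=0)
        assert np.median(cv) < 1.0


class TestCluster:
    def test_separable_blobs_recovered(self):
        rng = np.random.default_rng(0)
        grid = tile(np.zeros((40, 200)), 20)  # 2 x 10 patches
        blob = rng.normal(0, 0.05, size=(grid.n_patches, 30))
        blob[:10] = np.abs(blob[:10]) + 5.0
        blob[10:] = np.abs(blob[10:]) + 0.5
        res = cluster_patches(blob, grid, seed=0)
        labels = res.patch_labels.ravel()
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_two_patches_split(self):
        grid = tile(np.zeros((20, 40)), 20)
        res = cluster_patches(np.array([[1.0] * 30, [9.0] * 30]), grid, seed=0)
        assert set(res.patch_labels.ravel()) == {0, 1}

    def test_zero_variance_column_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        grid = tile(np.zeros((20, 80)), 20)
        feats = np.abs(rng.normal(2, 1, size=(4, 30))) + 0.1
        feats[:, 7] = 3.0
        with pytest.warns(RuntimeWarning, match="zero-spread"):
            cluster_patches(feats, grid, seed=0)

    def test_fixed_seed_is_bit_identical(self, rng):
        grid = tile(np.zeros((60, 60)), 20)
        feats = np.abs(rng.normal(1, 0.3, size=(9, 30))) + 0.1
        r1 = cluster_patches(feats, grid, seed=5)
        r2 = cluster_patches(feats, grid, seed=5)
        np.testing.assert_array_equal(r1.patch_labels, r2.patch_labels)
        np.testing.assert_array_equal(r1.pixel_mask, r2.pixel_mask)

    def test_pixel_mask_constant_per_patch(self, rng):
        grid = tile(np.zeros((45, 45)), 20)
        feats = np.abs(rng.normal(1, 0.5, size=(4, 30))) + 0.1
        res = cluster_patches(feats, grid, seed=0)
        for r in range(grid.n_rows):
            for c in range(grid.n_cols):
                block = res.pixel_mask[grid.patch_slices(r, c)]
                assert len(np.unique(block)) == 1
        assert np.all(res.pixel_mask[40:, :] == 0)  # excluded border strip


class TestEvaluate:
    def grid_result(self, labels):
        labels = np.asarray(labels)
        grid = tile(np.zeros((labels.shape[0] * 20, labels.shape[1] * 20)), 20)
        return SegmentationResult(labels, paint_mask(grid, labels), grid, "raw")

    def test_perfect_prediction(self):
        res = self.grid_result([[1, 0], [0, 1]])
        m = evaluate(res, res.pixel_mask)
        assert (m.dice, m.sensitivity, m.specificity) == (1.0, 1.0, 1.0)

    def test_complement_prediction_without_oracle(self):
        res = self.grid_result([[1, 0], [0, 1]])
        m = evaluate(res.pixel_mask, 1 - res.pixel_mask, oracle=False)
        assert m.dice == 0.0

    def test_oracle_fixes_swapped_cluster_identity(self):
        res = self.grid_result([[1, 0], [0, 1]])
        gt = 1 - res.pixel_mask
        assert evaluate(res, gt).dice == 1.0

    def test_formula_arithmetic(self):
        # TP=6, FP=2, FN=2 pixels -> dice = 12/16
        pred = np.zeros((1, 10)),
        pred = np.array([[1] * 8 + [0] * 2])
        gt = np.array([[1] * 6 + [0] * 2 + [1] * 2])
        m = evaluate(pred, gt, oracle=False)
        assert m.dice == pytest.approx(0.75)
        assert (m.tp, m.fp, m.fn) == (6, 2, 2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            evaluate(np.zeros((4, 4)), np.zeros((5, 4)))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_metrics_bounded_and_dice_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 2, size=(8, 8))
        b = rng.integers(0, 2, size=(8, 8))
        m_ab = evaluate(a, b, oracle=False)
        m_ba = evaluate(b, a, oracle=False)
        for m in (m_ab, m_ba):
            assert 0 <= m.dice <= 1 and 0 <= m.sensitivity <= 1 and 0 <= m.specificity <= 1
        assert m_ab.dice == pytest.approx(m_ba.dice)


def test_centroid_reference_assignment(rng):
    cfg = PipelineConfig(segment=SegmentConfig(assignment="centroid_reference"))
    grid = tile(np.zeros((40, 200)), 20)
    feats = np.full((20, 30), 0.5)
    feats[:10] *= 20.0
    feats += np.abs(rng.normal(0, 0.01, feats.shape))
    from artexus.segment import _scale_features

    z = _scale_features(feats)
    ref = z[:10].mean(axis=0)  # reference centroid of the "tissue" group
    res = cluster_patches(feats, grid, seed=0, cfg=cfg, reference_centroid=ref)
    assert res.assignment == "centroid_reference"
    assert np.all(res.patch_labels.ravel()[:10] == 1)
    assert np.all(res.patch_labels.ravel()[10:] == 0)
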