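"""Smoothing, downsampling, vectorization, scaling, age residualization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petgpr import (
    FeatureMatrix,
    MetabolicVolume,
    devectorize,
    downsample_by_two,
    gaussian_smooth,
    global_mean_scale,
    preprocess_volumes,
    residualize_age,
    residualize_features,
    scale_features,
    vectorize,
)
from petgpr.preprocess import AgeResidualizer, downsample_mask, fwhm_to_sigma


def discrete_gaussian_kernel(sigma):
    """Truncated, normalized 1-D Gaussian sampled at integer offsets
    (radius 4 sigma), evaluated independently of any filtering code."""
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


class TestSmooth:
    def test_constant_volume_preserved(self):
        # nearest-mode boundary handling: constants survive to machine
        # precision (the discrete kernel sums to 1 up to rounding)
        vol = np.full((9, 9, 9), 3.14)
        out = gaussian_smooth(vol, 12.0, (2.0, 2.0, 2.0))
        np.testing.assert_allclose(out, vol, rtol=1e-12, atol=0)

    def test_zero_fwhm_is_identity(self, rng):
        vol = rng.standard_normal((6, 7, 8))
        np.testing.assert_array_equal(gaussian_smooth(vol, 0.0), vol)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(np.zeros((3, 3, 3)), -1.0)

    def test_impulse_response_matches_discrete_kernel(self):
        # 12 mm FWHM on 2 mm voxels: sigma = 12/2/2.3548... = 2.548 voxels
        vol = np.zeros((21, 21, 21))
        vol[10, 10, 10] = 1.0
        out = gaussian_smooth(vol, 12.0, (2.0, 2.0, 2.0))
        sigma = fwhm_to_sigma(12.0, (2.0, 2.0, 2.0))[0]
        assert sigma == pytest.approx(12.0 / 2.0 / 2.3548, abs=1e-4)
        k = discrete_gaussian_kernel(sigma)
        assert out[10, 10, 10] == pytest.approx(k.max() ** 3, abs=1e-12)
        # continuous-density approximation (2 pi sigma^2)^(-3/2)
        assert out[10, 10, 10] == pytest.approx(
            (2 * np.pi * sigma**2) ** -1.5, rel=1e-2
        )
        assert out.argmax() == np.ravel_multi_index((10, 10, 10), out.shape)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)


class TestDownsample:
    def test_full_scale_grid_geometry(self):
        out = downsample_by_two(np.zeros((91, 109, 91)))
        assert out.shape == (45, 54, 45)

    def test_constant_preserved(self):
        out = downsample_by_two(np.full((4, 6, 8), 2.5))
        np.testing.assert_array_equal(out, np.full((2, 3, 4), 2.5))

    def test_block_average_example(self):
        vol = np.zeros((4, 4, 4))
        vol[:2, :2, :2] = np.arange(1, 9).reshape(2, 2, 2)
        out = downsample_by_two(vol)
        assert out[0, 0, 0] == pytest.approx(4.5)
        assert np.count_nonzero(out) == 1

    def test_mean_preserved_for_even_dims(self, rng):
        vol = rng.standard_normal((8, 10, 6))
        out = downsample_by_two(vol)
        assert out.mean() == pytest.approx(vol.mean(), rel=1e-10, abs=1e-12)

    def test_small_dims_rejected(self):
        with pytest.raises(ValueError):
            downsample_by_two(np.zeros((1, 4, 4)))

    def test_mask_downsampling_majority_rule(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[:2, :2, :2] = True  # one full block
        mask[2, 2, 2] = True  # 1/8 of another block
        out = downsample_mask(mask)
        assert out[0, 0, 0] and not out[1, 1, 1]


class TestVectorize:
    def test_partial_mask_raster_order(self):
        vol = np.arange(8.0).reshape(2, 2, 2)
        mask = np.zeros((2, 2, 2), dtype=bool)
        mask[0, 0, 0] = mask[0, 1, 1] = mask[1, 0, 0] = True
        row, idx = vectorize(vol, mask)
        np.testing.assert_array_equal(row, [0.0, 3.0, 4.0])
        np.testing.assert_array_equal(idx, [[0, 0, 0], [0, 1, 1], [1, 0, 0]])

    def test_full_mask_length(self, rng):
        vol = rng.standard_normal((3, 4, 5))
        row, _ = vectorize(vol, np.ones((3, 4, 5), dtype=bool))
        assert row.shape == (60,)

    def test_roundtrip_bit_identical(self, rng):
        vol = rng.standard_normal((5, 6, 7))
        mask = rng.random((5, 6, 7)) > 0.5
        row, idx = vectorize(vol, mask)
        back = devectorize(row, idx, vol.shape)
        np.testing.assert_array_equal(back[mask], vol[mask])
        assert np.all(back[~mask] == 0)

    def test_dim_mismatch_and_empty_mask(self):
        with pytest.raises(ValueError):
            vectorize(np.zeros((2, 2, 2)), np.zeros((3, 3, 3), dtype=bool))
        with pytest.raises(ValueError, match="empty"):
            vectorize(np.zeros((2, 2, 2)), np.zeros((2, 2, 2), dtype=bool))


class TestGlobalMeanScale:
    def test_constant_row(self):
        np.testing.assert_allclose(global_mean_scale([3.0, 3.0, 3.0]), 1.0)

    def test_two_values(self):
        np.testing.assert_allclose(global_mean_scale([1.0, 3.0]), [0.5, 1.5])

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError):
            global_mean_scale(np.zeros(5))

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0.1, 100), min_size=2, max_size=20))
    def test_unit_mean_and_idempotence(self, row):
        scaled = global_mean_scale(row)
        assert scaled.mean() == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(global_mean_scale(scaled), scaled,
                                   atol=1e-12)


class TestResidualizeAge:
    def test_linear_in_age_gives_zeros(self):
        ages = np.array([10.0, 20.0, 30.0, 40.0])
        col = (2.0 + 0.5 * ages)[:, None]
        np.testing.assert_allclose(residualize_age(col, ages), 0.0, atol=1e-10)

    def test_constant_column_gives_zeros(self):
        ages = np.array([10.0, 20.0, 30.0, 40.0])
        np.testing.assert_allclose(
            residualize_age(np.full((4, 2), 7.0), ages), 0.0, atol=1e-10
        )

    def test_matches_normal_equations_oracle(self, rng):
        ages = rng.uniform(8, 44, size=16)
        Y = rng.standard_normal((16, 10))
        A = np.column_stack([np.ones(16), ages])
        oracle = Y - A @ np.linalg.inv(A.T @ A) @ A.T @ Y
        np.testing.assert_allclose(residualize_age(Y, ages), oracle, atol=1e-10)

    def test_orthogonality_and_idempotence(self, rng):
        ages = rng.uniform(8, 44, size=12)
        Y = rng.standard_normal((12, 5))
        R = residualize_age(Y, ages)
        assert np.abs(R.sum(axis=0)).max() < 1e-8
        assert np.abs((ages - ages.mean()) @ R).max() < 1e-8
        np.testing.assert_allclose(residualize_age(R, ages), R, atol=1e-8)

    def test_identical_ages_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            residualize_age(np.ones((4, 2)), np.full(4, 30.0))

    def test_fold_safe_transformer_matches_full_fit(self, rng):
        ages = rng.uniform(8, 44, size=10)
        Y = rng.standard_normal((10, 6))
        res = AgeResidualizer().fit(Y, ages)
        np.testing.assert_allclose(
            res.transform(Y, ages), residualize_age(Y, ages), atol=1e-10
        )


def _feature_matrix(rng, stage="raw", n=6, p=8):
    values = rng.uniform(0.5, 2.0, size=(n, p))
    idx = np.argwhere(np.ones((2, 2, 2), dtype=bool))
    return FeatureMatrix(
        values=values, voxel_index=idx, subject_ids=[f"s{i}" for i in range(n)],
        grid_dims=(2, 2, 2), voxel_size_mm=(4.0, 4.0, 4.0), stage=stage,
    )


class TestStageGating:
    def test_pipeline_order_enforced(self, rng):
        fm = _feature_matrix(rng)
        ages = rng.uniform(8, 44, size=fm.n_subjects)
        with pytest.raises(ValueError, match="scaled"):
            residualize_features(fm, ages)  # must scale first
        scaled = scale_features(fm)
        with pytest.raises(ValueError, match="raw"):
            scale_features(scaled)  # cannot scale twice
        resid = residualize_features(scaled, ages)
        assert resid.stage == "residualized"
        with pytest.raises(ValueError, match="scaled"):
            residualize_features(resid, ages)

    def test_scaled_rows_have_unit_mean(self, rng):
        scaled = scale_features(_feature_matrix(rng))
        np.testing.assert_allclose(scaled.values.mean(axis=1), 1.0, atol=1e-10)

    def test_unknown_stage_rejected(self, rng):
        with pytest.raises(ValueError, match="stage"):
            _feature_matrix(rng, stage="cooked")


class TestPreprocessVolumes:
    def test_geometry_and_stage(self, rng):
        vols = [
            MetabolicVolume(rng.uniform(50, 150, size=(8, 10, 8)),
                            (2.0, 2.0, 2.0), f"sub-{i:02d}")
            for i in range(5)
        ]
        mask = np.ones((8, 10, 8), dtype=bool)
        ages = rng.uniform(8, 44, size=5)
        fm = preprocess_volumes(vols, mask, fwhm_mm=6.0, ages=ages)
        assert fm.grid_dims == (4, 5, 4)
        assert fm.voxel_size_mm == (4.0, 4.0, 4.0)
        assert fm.stage == "residualized"
        assert fm.n_voxels == 80
        assert np.abs((ages - ages.mean()) @ fm.values).max() < 1e-8

    def test_mask_may_be_given_at_either_grid(self, rng):
        vols = [
            MetabolicVolume(rng.uniform(50, 150, size=(8, 8, 8)),
                            (2.0, 2.0, 2.0), f"sub-{i:02d}")
            for i in range(4)
        ]
        small_mask = np.zeros((4, 4, 4), dtype=bool)
        small_mask[1:3, 1:3, 1:3] = True
        fm = preprocess_volumes(vols, small_mask, fwhm_mm=0.0)
        assert fm.n_voxels == 8
        assert fm.stage == "scaled"
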