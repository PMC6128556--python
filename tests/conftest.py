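import numpy as np
import pytest

from petgpr import (
    BatteryPCA,
    MetabolicVolume,
    average_weight_map,
    downsample_by_two,
    loocv,
    permutation_test,
    preprocess_volumes,
    simulate_cohort,
)
from petgpr.preprocess import downsample_mask, vectorize


def cosine(a, b):
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def run_cohort_pipeline(cfg, component=1, B=None, perm_seed=0, sigma2=0.001):
    """Generator -> preprocess -> PCA -> LOOCV (-> permutation) in memory.

    Returns a dict with the cohort, feature matrix, PCA result, CVResult,
    fold weights, weight map, recovery cosine, and (if B) the
    PermutationResult.
    """
    cohort = simulate_cohort(cfg)
    volumes = [
        MetabolicVolume(v, cfg.voxel_size_mm, s)
        for v, s in zip(cohort.volumes, cohort.scores["subject_id"])
    ]
    ages = cohort.demographics["age"].to_numpy(dtype=float)
    fm = preprocess_volumes(volumes, cohort.mask, fwhm_mm=cfg.smooth_fwhm_mm,
                            downsample=True, ages=ages)
    pca_res = BatteryPCA().fit(cohort.scores.drop(columns="subject_id")).result_
    y = pca_res.scores[:, component - 1]
    cv, fold_w = loocv(fm, y, sigma2=sigma2)
    wmap = average_weight_map(fold_w, fm.voxel_index, fm.grid_dims)
    pattern_row, _ = vectorize(
        downsample_by_two(cohort.pattern.volume), downsample_mask(cohort.mask)
    )
    out = {
        "cohort": cohort,
        "features": fm,
        "pca": pca_res,
        "targets": y,
        "cv": cv,
        "fold_weights": fold_w,
        "weight_map": wmap,
        "pattern_row": pattern_row,
        "recovery_cosine": cosine(wmap.in_mask, pattern_row)
        if np.any(pattern_row) else np.nan,
    }
    if B is not None:
        out["perm"] = permutation_test(fm, y, B=B, seed=perm_seed,
                                       sigma2=sigma2)
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
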