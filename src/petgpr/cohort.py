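"""Synthetic FDG-PET cohort generator.

Emulates the structure the downstream analysis assumes for a small
clinical cohort (by default 16 subjects aged 8-44, as in an NF1 outpatient
sample): each subject has a latent cognitive factor ``g`` expressed both
in a 17-measure neuropsychological battery (through a loading vector plus
measurement noise) and in brain metabolism (through a spatially
structured, signed voxel pattern scaled by ``signal_beta``).  Volumes
additionally carry a baseline uptake level, a spatially smooth linear age
effect, and smoothed Gaussian noise.

Voxel model for subject i, voxel v (before smoothing):

    uptake_iv = baseline + a_v * (age_i - mean age)
                + sum_f beta_f * g_if * P_fv + noise_iv

where P_f is a planted pattern of +1/-1 ellipsoidal regions and a_v a
smooth random field with SD ``age_slope_sd``.  Scores for measure j:

    score_ij = sum_f loadings_fj * g_if + noise_ij

Everything is driven by a single integer seed and is bit-reproducible.
The generator makes no attempt at PET physics or anatomy: it produces
already co-registered, artifact-free grids whose only structure is the
structure stated above.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import gaussian_smooth

__all__ = [
    "MEASURE_NAMES",
    "DEFAULT_LOADINGS",
    "CohortConfig",
    "TruePattern",
    "Cohort",
    "make_ellipsoid_mask",
    "plant_pattern",
    "simulate_cohort",
    "write_cohort",
    "strong_signal_config",
    "null_config",
]

# Battery modelled on a standard paediatric/adult neuropsychological
# assessment: Wechsler IQs, pegboard dexterity (timed, hence negative
# loadings), Stroop-type attention (timed), spatial and digit spans,
# complex-figure copy/recall, verbal fluency, and list learning.
MEASURE_NAMES = [
    "VIQ",
    "PIQ",
    "TOL",
    "NHPT_dom",
    "NHPT_nondom",
    "FDT_decoding",
    "FDT_inhibiting",
    "CBTT_fwd",
    "CBTT_bwd",
    "ROCF_copy",
    "ROCF_immediate",
    "ROCF_delayed",
    "VFT_semantic",
    "VFT_FAS",
    "DST_fwd",
    "DST_bwd",
    "RAVLT_A6",
]

# Loadings of the general factor on each measure: strongest on IQ,
# moderate on memory/fluency/span, negative on timed measures (longer
# times = worse performance).
DEFAULT_LOADINGS = np.array(
    [
        0.85, 0.80, 0.45, -0.40, -0.35, -0.30, -0.35, 0.50, 0.45,
        0.55, 0.60, 0.55, 0.65, 0.60, 0.55, 0.50, 0.70,
    ]
)

_CLIP_FLOOR = 1e-6


def make_ellipsoid_mask(grid_dims, center, radii) -> np.ndarray:
    """Boolean ellipsoid: voxel included iff sum(((x-c)/r)^2) <= 1.

    Radii larger than the grid simply clip to it (the ellipsoid then
    contains the whole grid); radii must be positive and the resulting
    mask non-empty.
    """
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    grids = np.ogrid[tuple(slice(0, d) for d in grid_dims)]
    dist2 = sum(
        ((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii)
    )
    mask = dist2 <= 1.0
    if not mask.any():
        raise ValueError("ellipsoid does not contain any voxel")
    return mask


def _default_rois(grid_dims):
    """One positive and one negative ellipsoid, placed off-centre inside
    the default brain mask and mutually disjoint."""
    dims = np.asarray(grid_dims, dtype=float)
    return [
        (tuple(0.38 * dims), tuple(0.15 * dims), +1),
        (tuple(0.62 * dims), tuple(0.15 * dims), -1),
    ]


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions.

    grid_dims defaults to a small test-scale grid; use (91, 109, 91) to
    mimic full 2 mm MNI-space volumes.  ``loadings`` may be a single
    vector (one general factor) or a (n_factors, n_measures) array with
    up to 3 rows; ``signal_beta`` and ``pattern_rois`` then accept one
    entry per factor.
    """

    n_subjects: int = 16
    grid_dims: tuple[int, int, int] = (24, 28, 24)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    age_range: tuple[float, float] = (8.0, 44.0)
    n_measures: int = 17
    loadings: np.ndarray | None = None
    score_noise_sd: float = 0.75
    baseline_level: float = 100.0
    age_slope_sd: float = 0.15
    signal_beta: float | tuple = 2.0
    pattern_rois: list | None = None
    volume_noise_sd: float = 2.0
    smooth_fwhm_mm: float = 12.0
    seed: int = 0

    def resolved_loadings(self) -> np.ndarray:
        if self.loadings is None:
            base = DEFAULT_LOADINGS
            if self.n_measures != base.shape[0]:
                # tile/truncate the default profile to the requested width
                reps = int(np.ceil(self.n_measures / base.shape[0]))
                base = np.tile(base, reps)[: self.n_measures]
            L = base[None, :]
        else:
            L = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        return L

    def resolved_rois(self) -> list[list[tuple]]:
        """Per-factor list of (center, radii, sign) ROI triples.

        ``pattern_rois`` may be a flat list of triples (shared by every
        factor) or a list of per-factor lists.
        """
        n_factors = self.resolved_loadings().shape[0]
        rois = self.pattern_rois
        if rois is None:
            rois = _default_rois(self.grid_dims)
        def _is_triple(item) -> bool:
            return (isinstance(item, (list, tuple)) and len(item) == 3
                    and np.isscalar(item[2]))
        if all(_is_triple(r) for r in rois):
            per_factor = [list(rois)] * n_factors
        else:
            per_factor = [list(r) for r in rois]
        if len(per_factor) != n_factors:
            raise ValueError(
                f"pattern_rois specifies {len(per_factor)} factors but "
                f"loadings specify {n_factors}"
            )
        return per_factor

    def resolved_betas(self) -> np.ndarray:
        n_factors = self.resolved_loadings().shape[0]
        beta = np.atleast_1d(np.asarray(self.signal_beta, dtype=float))
        if beta.shape[0] == 1 and n_factors > 1:
            beta = np.repeat(beta, n_factors)
        return beta

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        L = self.resolved_loadings()
        if L.shape[0] > 3:
            raise ValueError("at most 3 latent factors are supported")
        if L.shape[1] != self.n_measures:
            raise ValueError(
                f"loadings width {L.shape[1]} != n_measures {self.n_measures}"
            )
        if np.any(np.abs(L) > 1):
            raise ValueError("loadings must lie in [-1, 1]")
        for name in ("score_noise_sd", "volume_noise_sd", "age_slope_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.baseline_level <= 0:
            raise ValueError("baseline_level must be > 0")
        if np.any(self.resolved_betas() < 0):
            raise ValueError("signal_beta must be >= 0")
        if self.smooth_fwhm_mm < 0:
            raise ValueError("smooth_fwhm_mm must be >= 0")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")
        dims = np.asarray(self.grid_dims)
        for factor_rois in self.resolved_rois():
            for center, radii, sign in factor_rois:
                c = np.asarray(center, dtype=float)
                r = np.asarray(radii, dtype=float)
                if np.any(r <= 0):
                    raise ValueError("ROI radii must be positive")
                if np.any(c - r < -0.5) or np.any(c + r > dims - 0.5):
                    raise ValueError(
                        f"ROI at {tuple(center)} with radii {tuple(radii)} "
                        f"does not fit inside grid {tuple(self.grid_dims)}"
                    )
                if sign not in (+1, -1):
                    raise ValueError("ROI sign must be +1 or -1")


def strong_signal_config(seed: int = 0, **overrides) -> CohortConfig:
    """Cohort with a strongly expressed latent factor.

    Metabolic coupling at ten times the voxel noise SD (with the noise
    itself halved relative to the default) and a cleaner battery
    (score_noise_sd 0.4), so both the image side and the score side carry
    the factor clearly.  This is the positive control: the planted
    pattern should be recoverable from the weight map and LOOCV accuracy
    should be high.
    """
    params = dict(volume_noise_sd=0.5, signal_beta=5.0, score_noise_sd=0.4,
                  seed=seed)
    params.update(overrides)
    return CohortConfig(**params)


def null_config(seed: int = 0, **overrides) -> CohortConfig:
    """Cohort with no brain-score coupling at all.

    signal_beta = 0 and all loadings 0: volumes and scores are generated
    independently, so any apparent prediction accuracy is chance.  This
    is the negative control used for permutation-test calibration.
    """
    params = dict(signal_beta=0.0, seed=seed)
    params.update(overrides)
    cfg = CohortConfig(**params)
    cfg.loadings = np.zeros((1, cfg.n_measures))
    return cfg


@dataclass
class TruePattern:
    """The planted signed voxel pattern and the brain mask it lives in."""

    volume: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        if self.volume.shape != self.mask.shape:
            raise ValueError("pattern and mask dims differ")


@dataclass
class Cohort:
    """Everything simulate_cohort produces, ground truth included."""

    volumes: np.ndarray  # (n_subjects, *grid_dims)
    scores: pd.DataFrame
    demographics: pd.DataFrame
    pattern: TruePattern
    g: np.ndarray  # (n_subjects, n_factors)
    config: CohortConfig

    @property
    def mask(self) -> np.ndarray:
        return self.pattern.mask


def default_brain_mask(grid_dims) -> np.ndarray:
    """Central ellipsoid covering roughly the brain-like share of the grid."""
    dims = np.asarray(grid_dims, dtype=float)
    return make_ellipsoid_mask(
        grid_dims, center=(dims - 1) / 2.0, radii=0.42 * dims
    )


def plant_pattern(config: CohortConfig, factor: int = 0) -> TruePattern:
    """Materialise one factor's +1/-1 ellipsoid pattern inside the mask.

    Overlapping ROIs of conflicting sign are rejected; the pattern is
    zero outside the brain mask.  Deterministic given the config.
    """
    config.validate()
    mask = default_brain_mask(config.grid_dims)
    P = np.zeros(config.grid_dims, dtype=float)
    for center, radii, sign in config.resolved_rois()[factor]:
        roi = make_ellipsoid_mask(config.grid_dims, center, radii)
        conflict = roi & (P != 0) & (P != sign)
        if conflict.any():
            raise ValueError("overlapping ROIs with conflicting signs")
        P[roi] = sign
    P[~mask] = 0.0
    return TruePattern(volume=P, mask=mask)


def simulate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Draw one synthetic cohort (volumes + scores + demographics + truth).

    All randomness flows from ``config.seed`` through a single
    numpy Generator with a fixed draw order, so identical configs give
    bit-identical output.  Uptake values are floored at a small positive
    epsilon (with a warning) should noise ever drive them negative.
    """
    if config is None:
        config = CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    L = config.resolved_loadings()  # (n_factors, n_measures)
    n_factors = L.shape[0]
    betas = config.resolved_betas()

    # fixed draw order: demographics, latent factors, scores, fields, noise
    ages = rng.uniform(*config.age_range, size=n)
    sex = rng.integers(0, 2, size=n)
    education = np.clip(2.0 + 0.3 * (ages - config.age_range[0])
                        + rng.normal(0, 1.5, size=n), 1.0, None)
    g = rng.standard_normal((n, n_factors))
    score_noise = rng.normal(0.0, config.score_noise_sd, size=(n, config.n_measures))
    scores = g @ L + score_noise

    patterns = [plant_pattern(config, f) for f in range(n_factors)]
    mask = patterns[0].mask

    # smooth spatial age-slope field, rescaled in-mask to age_slope_sd
    raw_field = rng.standard_normal(config.grid_dims)
    a_v = gaussian_smooth(raw_field, config.smooth_fwhm_mm, config.voxel_size_mm)
    sd = a_v[mask].std()
    if sd > 0:
        a_v = a_v * (config.age_slope_sd / sd)

    noise = rng.normal(0.0, config.volume_noise_sd,
                       size=(n,) + tuple(config.grid_dims))

    age_c = ages - ages.mean()
    signal = np.zeros((n,) + tuple(config.grid_dims))
    for f in range(n_factors):
        signal += betas[f] * g[:, f][:, None, None, None] * patterns[f].volume
    volumes = (config.baseline_level
               + age_c[:, None, None, None] * a_v
               + signal + noise)
    for i in range(n):
        volumes[i] = gaussian_smooth(
            volumes[i], config.smooth_fwhm_mm, config.voxel_size_mm
        )
    if np.any(volumes < _CLIP_FLOOR):
        n_clipped = int(np.sum(volumes < _CLIP_FLOOR))
        warnings.warn(
            f"clipped {n_clipped} non-positive uptake values to {_CLIP_FLOOR}",
            RuntimeWarning,
        )
        volumes = np.maximum(volumes, _CLIP_FLOOR)

    subject_ids = [f"sub-{i + 1:02d}" for i in range(n)]
    measure_names = (MEASURE_NAMES if config.n_measures == len(MEASURE_NAMES)
                     else [f"m{j + 1:02d}" for j in range(config.n_measures)])
    scores_df = pd.DataFrame(scores, columns=measure_names)
    scores_df.insert(0, "subject_id", subject_ids)
    demo_df = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "age": ages,
            "sex": np.where(sex == 1, "M", "F"),
            "education": education,
        }
    )
    return Cohort(
        volumes=volumes,
        scores=scores_df,
        demographics=demo_df,
        pattern=patterns[0],
        g=g,
        config=config,
    )


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict:
    """Write a cohort to disk: NIfTI volumes + mask + pattern, CSV tables,
    and a truth.json with the latent factors and the config echo."""
    from .io import save_nifti  # local import: nibabel only needed on I/O

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = cohort.config
    paths = {"volumes": []}
    for i, sid in enumerate(cohort.scores["subject_id"]):
        p = outdir / f"{sid}.nii.gz"
        save_nifti(cohort.volumes[i], cfg.voxel_size_mm, p)
        paths["volumes"].append(str(p))
    save_nifti(cohort.mask.astype(np.float32), cfg.voxel_size_mm,
               outdir / "mask.nii.gz")
    save_nifti(cohort.pattern.volume, cfg.voxel_size_mm,
               outdir / "pattern.nii.gz")
    cohort.scores.to_csv(outdir / "scores.csv", index=False)
    cohort.demographics.to_csv(outdir / "demographics.csv", index=False)
    truth = {
        "g": cohort.g.tolist(),
        "config": {
            k: (list(v) if isinstance(v, tuple) else
                v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in vars(cfg).items()
            if k != "pattern_rois"
        },
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    paths.update(
        mask=str(outdir / "mask.nii.gz"),
        pattern=str(outdir / "pattern.nii.gz"),
        scores=str(outdir / "scores.csv"),
        demographics=str(outdir / "demographics.csv"),
        truth=str(outdir / "truth.json"),
    )
    return paths
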