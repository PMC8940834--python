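"""Paired image-quality metrics, agreement statistics, and a segmental score.

Implements the quantitative assessment used for denoised SPECT-MPI data:

* RMSE, PSNR and a single-window (global-moment) SSIM with absolute
  stabilizing constants C1 = 0.01 and C2 = 0.02;
* Pearson product-moment correlation;
* Bland-Altman agreement (bias, 1.96-sd limits of agreement) with a paired
  t-test;
* percent-change reporting between dose arms;
* a simplified 17-segment (AHA) summed-score surrogate computed from a
  short-axis volume with uptake thresholds 70/50/30/10 % of maximal uptake.

The PSNR normalizing constant ("peak") defaults to the maximum of the test
data; the formula default is ``20 log10(peak / RMSE)``.  A variant that
divides by the MSE instead of the RMSE is selectable for comparison with
reports that print the formula that way (the two differ by a monotone
transform, so rankings and percent-change comparisons on published means are
unaffected).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MetricsReport",
    "AgreementReport",
    "SegmentScores",
    "rmse",
    "psnr",
    "ssim_global",
    "pearson",
    "bland_altman",
    "percent_change",
    "segment_scores",
    "compare",
]

SEGMENT_SCORE_THRESHOLDS = (0.70, 0.50, 0.30, 0.10)  # score 0..4 boundaries


@dataclass
class MetricsReport:
    """Per-pair image-quality metrics."""

    psnr_db: float
    rmse: float
    ssim: float
    pearson_rho: float
    peak_convention: str = "test_max"
    formula_variant: str = "peak_over_rmse"


@dataclass
class AgreementReport:
    """Cohort-level agreement between paired measurements."""

    bias: float
    loa_low: float
    loa_high: float
    pearson_rho: float
    t_stat: float
    p_value: float
    n: int


@dataclass
class SegmentScores:
    """17-segment uptake fractions, per-segment scores (0-4) and summed score."""

    segment_uptake: np.ndarray
    segment_score: np.ndarray
    summed_score: int
    segment_voxels: np.ndarray = field(repr=False, default=None)


def _check_pair(ref: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    if ref.size < 1:
        raise ValueError("empty input")
    return ref, test


def rmse(ref: np.ndarray, test: np.ndarray) -> float:
    """Root-mean-square error sqrt(mean((ref - test)^2)), in count units."""
    ref, test = _check_pair(ref, test)
    return float(np.sqrt(np.mean((ref - test) ** 2)))


def psnr(
    ref: np.ndarray,
    test: np.ndarray,
    peak_convention: str = "test_max",
    formula_variant: str = "peak_over_rmse",
) -> float:
    """Peak signal-to-noise ratio in dB.

    ``peak_convention``: "test_max" (maximum count of the low-dose/predicted
    data, the default) or "ref_max".  ``formula_variant``: "peak_over_rmse"
    (default, standard) or "peak_over_mse" (as sometimes printed).
    Identical inputs give +inf.
    """
    ref, test = _check_pair(ref, test)
    if peak_convention == "test_max":
        peak = float(test.max())
    elif peak_convention == "ref_max":
        peak = float(ref.max())
    else:
        raise ValueError(f"unknown peak convention {peak_convention!r}")
    if peak <= 0:
        raise ValueError("peak value is zero; PSNR undefined")
    mse = float(np.mean((ref - test) ** 2))
    if mse == 0:
        return math.inf
    if formula_variant == "peak_over_rmse":
        return float(20.0 * np.log10(peak / np.sqrt(mse)))
    if formula_variant == "peak_over_mse":
        return float(20.0 * np.log10(peak / mse))
    raise ValueError(f"unknown formula variant {formula_variant!r}")


def ssim_global(ref: np.ndarray, test: np.ndarray, c1: float = 0.01, c2: float = 0.02) -> float:
    """Single-window structural similarity with absolute constants.

    Uses global means, variances (population, n denominator) and covariance
    of the two arrays:
    ``(2 mu_y mu_t + C1)(2 cov + C2) / ((mu_y^2 + mu_t^2 + C1)(var_y + var_t + C2))``.
    No sliding window and no rescaling of C1/C2 by the dynamic range.
    """
    ref, test = _check_pair(ref, test)
    if ref.size < 2:
        raise ValueError("SSIM needs at least 2 elements")
    mu_r, mu_t = ref.mean(), test.mean()
    var_r, var_t = ref.var(), test.var()
    cov = float(np.mean((ref - mu_r) * (test - mu_t)))
    return float(
        (2 * mu_r * mu_t + c1) * (2 * cov + c2)
        / ((mu_r**2 + mu_t**2 + c1) * (var_r + var_t + c2))
    )


def pearson(ref: np.ndarray, test: np.ndarray) -> float:
    """Pearson product-moment correlation coefficient."""
    ref, test = _check_pair(ref, test)
    if ref.size < 2:
        raise ValueError("correlation needs at least 2 elements")
    if ref.std() == 0 or test.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(ref.ravel(), test.ravel()).statistic)


def bland_altman(ref_values: np.ndarray, test_values: np.ndarray) -> AgreementReport:
    """Bland-Altman agreement of paired measurements.

    bias = mean(test - ref); limits of agreement = bias +/- 1.96 * sd of the
    differences (sample sd, n-1 denominator; 0 when n differences are all
    equal).  Also reports the Pearson correlation of the paired values and a
    two-sided paired t-test.
    """
    ref = np.asarray(ref_values, dtype=float).ravel()
    test = np.asarray(test_values, dtype=float).ravel()
    if ref.shape != test.shape:
        raise ValueError("paired vectors must have equal length")
    if ref.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = test - ref
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.allclose(diff, diff[0]):
        sd = 0.0
        t_stat, p_value = (math.inf if bias != 0 else 0.0), (0.0 if bias != 0 else 1.0)
    else:
        t = stats.ttest_rel(test, ref)
        t_stat, p_value = float(t.statistic), float(t.pvalue)
    try:
        rho = pearson(ref, test)
    except ValueError:
        rho = math.nan
    return AgreementReport(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        pearson_rho=rho,
        t_stat=t_stat,
        p_value=p_value,
        n=ref.size,
    )


def percent_change(baseline: float, new: float, direction: str = "increase") -> float:
    """Percent change of ``new`` relative to ``baseline``.

    ``direction="increase"`` reports ``100 (new - baseline) / baseline``;
    ``direction="decrease"`` reports ``100 (baseline - new) / baseline`` so a
    stated reduction comes out positive.
    """
    if baseline == 0:
        raise ValueError("baseline must be nonzero")
    if direction == "increase":
        return float(100.0 * (new - baseline) / baseline)
    if direction == "decrease":
        return float(100.0 * (baseline - new) / baseline)
    raise ValueError(f"unknown direction {direction!r}")


def compare(ref: np.ndarray, test: np.ndarray, **psnr_kwargs) -> MetricsReport:
    """Convenience bundle of the four paired metrics."""
    return MetricsReport(
        psnr_db=psnr(ref, test, **psnr_kwargs),
        rmse=rmse(ref, test),
        ssim=ssim_global(ref, test),
        pearson_rho=pearson(ref, test),
        peak_convention=psnr_kwargs.get("peak_convention", "test_max"),
        formula_variant=psnr_kwargs.get("formula_variant", "peak_over_rmse"),
    )


def _uptake_to_score(frac: float) -> int:
    for score, thr in enumerate(SEGMENT_SCORE_THRESHOLDS):
        if frac >= thr:
            return score
    return 4


def segment_labels(
    shape: tuple[int, int, int],
    apex_base_range: tuple[int, int],
    center: tuple[float, float] | None = None,
    angle_offset_deg: float = 0.0,
) -> np.ndarray:
    """17-segment AHA label volume for a short-axis stack (z = long axis).

    Slices from ``apex_base_range[0]`` (apical tip) to ``apex_base_range[1]``
    (base, exclusive) are divided into an apex cap (segment 17), an apical
    third with four 90-degree sectors (13-16), a mid third with six
    60-degree sectors (7-12), and a basal third with six 60-degree sectors
    (1-6).  Angles are measured with atan2 in each short-axis plane.
    Returns an integer volume with labels 1..17 (0 outside the range).
    """
    nx, ny, nz = shape
    lo, hi = apex_base_range
    if not (0 <= lo < hi <= nz):
        raise ValueError(f"apex_base_range {apex_base_range} outside [0, {nz})")
    cx, cy = center if center is not None else ((nx - 1) / 2.0, (ny - 1) / 2.0)
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    theta = (np.degrees(np.arctan2(ys - cy, xs - cx)) - angle_offset_deg) % 360.0
    labels = np.zeros(shape, dtype=np.int16)
    extent = hi - lo
    # slice bands: apex cap, apical, mid, basal (apex at lo)
    bounds = [lo, lo + max(1, extent // 6), lo + extent // 3, lo + 2 * extent // 3, hi]
    sector6 = (theta // 60.0).astype(np.int16)      # 0..5
    sector4 = (theta // 90.0).astype(np.int16)      # 0..3
    for z in range(lo, hi):
        if z < bounds[1]:
            labels[:, :, z] = 17
        elif z < bounds[2]:
            labels[:, :, z] = 13 + sector4
        elif z < bounds[3]:
            labels[:, :, z] = 7 + sector6
        else:
            labels[:, :, z] = 1 + sector6
    return labels


def segment_scores(
    sa_volume: np.ndarray,
    apex_base_range: tuple[int, int],
    myocardial_mask: np.ndarray | None = None,
    mask_threshold: float = 0.05,
    center: tuple[float, float] | None = None,
    angle_offset_deg: float = 0.0,
) -> SegmentScores:
    """Simplified 17-segment summed-score surrogate from a short-axis volume.

    Mean uptake is pooled per AHA segment over the myocardial mask
    (defaulting to voxels above ``mask_threshold`` of the volume maximum),
    expressed as a fraction of the maximal segment uptake, and scored 0-4
    with thresholds 70/50/30/10 %.  The summed score is the sum of the 17
    per-segment scores.  This is a transparent stand-in for proprietary
    clinical scoring software, not a reproduction of it.
    """
    vol = np.asarray(sa_volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("expected a 3D short-axis volume")
    labels = segment_labels(vol.shape, apex_base_range, center, angle_offset_deg)
    if myocardial_mask is None:
        myocardial_mask = vol > mask_threshold * vol.max()
    if not myocardial_mask.any():
        raise ValueError("empty myocardial mask")
    uptake = np.zeros(17)
    voxels = np.zeros(17, dtype=int)
    for seg in range(1, 18):
        m = (labels == seg) & myocardial_mask
        voxels[seg - 1] = int(m.sum())
        uptake[seg - 1] = float(vol[m].mean()) if m.any() else 0.0
    peak = uptake.max()
    if peak <= 0:
        raise ValueError("no uptake in any segment")
    frac = uptake / peak
    scores = np.array([_uptake_to_score(f) for f in frac], dtype=int)
    return SegmentScores(
        segment_uptake=frac,
        segment_score=scores,
        summed_score=int(scores.sum()),
        segment_voxels=voxels,
    )
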