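"""Voxel-wise similarity metrics and segment-wise error statistics.

NRMSE is normalized by the reference dynamic range, PSNR uses a
configurable peak (100 on the uptake scale by default) and SSIM follows the
literature defaults (11x11 Gaussian window, sigma 1.5, K1=0.01, K2=0.03),
computed per slice and averaged over the stack.  Joint histograms keep raw
counts; the log10(count+1) display transform is applied only at plot time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage.metrics import structural_similarity

from .stacks import UPTAKE_MAX, ImageStack

PSNR_INF_SENTINEL = float("inf")


@dataclass
class SimilarityReport:
    nrmse: float
    psnr_db: float
    ssim: float
    joint_hist: np.ndarray | None = None
    bin_edges: np.ndarray | None = None
    options: dict = field(default_factory=dict)


def _paired_arrays(ref, test) -> tuple[np.ndarray, np.ndarray]:
    a = ref.voxels if isinstance(ref, ImageStack) else np.asarray(ref)
    b = test.voxels if isinstance(test, ImageStack) else np.asarray(test)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return np.asarray(a, dtype=float), np.asarray(b, dtype=float)


def nrmse(ref, test) -> float:
    """Root-mean-square error divided by the reference dynamic range."""
    a, b = _paired_arrays(ref, test)
    rng = a.max() - a.min()
    if rng == 0:
        raise ValueError("reference has zero dynamic range")
    return float(np.sqrt(np.mean((a - b) ** 2)) / rng)


def psnr(ref, test, peak: float = UPTAKE_MAX) -> float:
    """10 * log10(peak^2 / MSE) in dB; +inf sentinel for identical inputs."""
    a, b = _paired_arrays(ref, test)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0:
        return PSNR_INF_SENTINEL
    return float(10.0 * np.log10(peak * peak / mse))


def ssim(ref, test, data_range: float = UPTAKE_MAX) -> float:
    """Mean per-slice structural similarity (Gaussian window, sigma 1.5)."""
    a, b = _paired_arrays(ref, test)
    if a.ndim == 2:
        a = a[None]
        b = b[None]
    vals = [
        structural_similarity(
            s, t, data_range=data_range, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, K1=0.01, K2=0.03,
        )
        for s, t in zip(a, b)
    ]
    return float(np.mean(vals))


def joint_histogram(
    ref, test, n_bins: int = 64, value_range: tuple[float, float] = (0.0, UPTAKE_MAX)
) -> tuple[np.ndarray, np.ndarray]:
    """2-D voxel-value counts over [0,100]^2; returns (counts, bin_edges).

    ``counts[i, j]`` is the number of voxels whose reference value falls in
    bin i and test value in bin j.  Counts always sum to the voxel count.
    """
    a, b = _paired_arrays(ref, test)
    counts, edges, _ = np.histogram2d(
        a.ravel(), b.ravel(), bins=n_bins, range=[value_range, value_range]
    )
    return counts, edges


def log_display(counts: np.ndarray) -> np.ndarray:
    """log10(count + 1) transform used for joint-histogram display."""
    return np.log10(np.asarray(counts, dtype=float) + 1.0)


def similarity_report(
    ref: ImageStack, test: ImageStack, *, peak: float = UPTAKE_MAX, n_bins: int = 64
) -> SimilarityReport:
    counts, edges = joint_histogram(ref, test, n_bins=n_bins)
    return SimilarityReport(
        nrmse=nrmse(ref, test),
        psnr_db=psnr(ref, test, peak=peak),
        ssim=ssim(ref, test),
        joint_hist=counts,
        bin_edges=edges,
        options={"psnr_peak": peak, "nrmse_normalizer": "reference_range"},
    )


# ---------------------------------------------------------------------------
# Segment-wise paired comparison
# ---------------------------------------------------------------------------

@dataclass
class SegmentTestResult:
    segment: int
    p_value: float
    significant: bool
    test_name: str
    mean_difference: float


def _paired_difference_test(diff: np.ndarray, alpha: float) -> tuple[float, str]:
    """Paired t-test when normality of the differences is plausible
    (Shapiro-Wilk at alpha), Wilcoxon signed-rank otherwise."""
    diff = np.asarray(diff, dtype=float)
    if np.allclose(diff, diff[0]):
        # degenerate: constant differences; t-test undefined variance
        if diff[0] == 0:
            return 1.0, "degenerate"
        return 0.0, "degenerate"
    normal_p = stats.shapiro(diff).pvalue
    if normal_p >= alpha:
        return float(stats.ttest_rel(diff, np.zeros_like(diff)).pvalue), "paired_t"
    return float(stats.wilcoxon(diff).pvalue), "wilcoxon"


def paired_segment_comparison(
    errors_a: np.ndarray,
    errors_b: np.ndarray | None = None,
    *,
    alpha: float = 0.05,
    min_cases: int = 5,
) -> list[SegmentTestResult]:
    """Per-segment paired tests across cases.

    ``errors_a`` is a (17, n_cases) array.  With ``errors_b`` given the
    per-case paired differences a-b are tested against zero per segment;
    with ``errors_b`` omitted ``errors_a`` itself is tested against zero.
    Two-sided p-values at the given alpha.
    """
    a = np.atleast_2d(np.asarray(errors_a, dtype=float))
    if a.shape[0] != 17:
        raise ValueError("expected 17 rows (one per segment)")
    diff = a if errors_b is None else a - np.atleast_2d(np.asarray(errors_b, dtype=float))
    n = diff.shape[1]
    if n < min_cases:
        raise ValueError(f"need at least {min_cases} cases, got {n}")
    results = []
    for seg in range(17):
        p, name = _paired_difference_test(diff[seg], alpha)
        results.append(
            SegmentTestResult(
                segment=seg + 1,
                p_value=p,
                significant=bool(p < alpha),
                test_name=name,
                mean_difference=float(diff[seg].mean()),
            )
        )
    return results
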