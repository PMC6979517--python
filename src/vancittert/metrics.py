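"""Image-quality metrics: PSNR and SSIM on the 8-bit intensity convention.

The peak is fixed at 255 regardless of the floating-point representation, and
the test image is clipped to [0, 255] before comparison, matching the usual
benchmark convention for restoration results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["QualityReport", "psnr", "ssim", "quality_report", "PEAK"]

PEAK = 255.0


def _pair(reference: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(reference, dtype=np.float64)
    tst = np.asarray(test, dtype=np.float64)
    if ref.shape != tst.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {tst.shape}")
    return ref, np.clip(tst, 0.0, PEAK)


def psnr(reference: np.ndarray, test: np.ndarray, peak: float = PEAK) -> float:
    """Peak signal-to-noise ratio ``10 log10(peak² / MSE)`` in decibels.

    Identical images give ``math.inf``.
    """
    if peak <= 0:
        raise ValueError("peak must be > 0")
    ref, tst = _pair(reference, test)
    mse = float(np.mean((ref - tst) ** 2))
    if mse == 0:
        return math.inf
    return 10.0 * math.log10(peak**2 / mse)


def ssim(reference: np.ndarray, test: np.ndarray) -> float:
    """Mean structural similarity with the classic parameterisation.

    11x11 Gaussian window of std 1.5, stabilising constants (K1, K2) =
    (0.01, 0.03) at peak 255, population covariances.
    """
    ref, tst = _pair(reference, test)
    if min(ref.shape) < 11:
        raise ValueError("SSIM needs an image of at least 11x11")
    return float(
        structural_similarity(
            ref,
            tst,
            data_range=PEAK,
            gaussian_weights=True,
            sigma=1.5,
            win_size=11,
            use_sample_covariance=False,
        )
    )


@dataclass(frozen=True)
class QualityReport:
    psnr_db: float
    ssim: float


def quality_report(reference: np.ndarray, test: np.ndarray) -> QualityReport:
    return QualityReport(psnr_db=psnr(reference, test), ssim=ssim(reference, test))
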