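"""Automated parameter setting: noise estimation and the σ_thr trigger.

In automated mode the observation's noise standard deviation is estimated
once and becomes the denoising threshold ``σ_thr``.  During the iteration the
iterate's noise level is re-estimated every step, and denoising fires
whenever the estimate exceeds the threshold — no manual (σ, s) tuning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

__all__ = ["AutoSchedule", "estimate_noise_std", "should_denoise"]

#: Wavelet used for the finest-scale detail band of the noise estimator.
_ESTIMATOR_WAVELET = "db2"


def estimate_noise_std(image: np.ndarray) -> float:
    """Robust estimate of additive white-Gaussian noise standard deviation.

    Median absolute deviation of the finest-scale diagonal wavelet detail
    coefficients divided by 0.6745 (the Gaussian MAD consistency constant).
    Image structure leaks only weakly into the diagonal detail band, so the
    estimate is robust to the scene content.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 16:
        raise ValueError("noise estimation needs a 2-D image of at least 16x16")
    _, (_, _, diag) = pywt.dwt2(img, _ESTIMATOR_WAVELET, mode="periodization")
    return float(np.median(np.abs(diag)) / 0.6745)


@dataclass(frozen=True)
class AutoSchedule:
    """Denoising trigger: fire when the iterate's noise estimate exceeds σ_thr."""

    sigma_thr: float
    estimator: str = "wavelet-mad"

    def __post_init__(self) -> None:
        if self.sigma_thr < 0:
            raise ValueError("sigma_thr must be >= 0")
        if self.estimator != "wavelet-mad":
            raise ValueError(f"unknown noise estimator {self.estimator!r}")

    @classmethod
    def from_observation(cls, observation: np.ndarray, denoiser=None,
                         sigma: float | None = None) -> "AutoSchedule":
        """Derive σ_thr from the observation.

        Without a denoiser, σ_thr is the observation's own estimated noise
        level.  Given the run's denoiser, σ_thr is instead that operator's
        *noise floor* on this observation (the estimate after denoising it
        once) — the tighter threshold the restoration engine defaults to,
        since a threshold at the raw noise level fires too rarely to contain
        the spectrally coloured noise the iteration amplifies.
        """
        if denoiser is None:
            return cls(sigma_thr=estimate_noise_std(observation))
        return cls(sigma_thr=estimate_noise_std(denoiser.apply(observation, sigma)))


def should_denoise(iterate: np.ndarray, schedule: AutoSchedule) -> bool:
    """True iff the iterate's estimated noise std strictly exceeds σ_thr."""
    return estimate_noise_std(iterate) > schedule.sigma_thr
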