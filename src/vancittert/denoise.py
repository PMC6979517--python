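"""Pluggable noise-reduction operators.

The restoration scheme only requires that its denoiser ``R_N`` be
*admissible*: applied to ``I + N`` it must return ``I + o(N)`` with
``Var(o(N)) ∝ Δ σ²`` for a reduction factor ``Δ ≪ 1``.  Any operator meeting
that contract can be plugged in, independently of the deblurring iteration.

Provided operators:

``wavelet``
    Orthogonal multilevel wavelet soft-thresholding (the classical shrinkage
    filter).  When no strength is given, the threshold is the universal one
    ``δ = σ̂ √(2 log RC)`` with ``σ̂`` estimated from the image itself.  Its
    reduction factor is ``Δ = (2 log RC + 1)(log RC + 1) / RC``
    (:func:`shrinkage_strength`), vanishing for images of modest size.
``bm3d``
    Thin adapter to the external BM3D implementation (block-matching and
    collaborative Wiener filtering).  BM3D internals are deliberately not
    re-implemented; if the ``bm3d`` package is absent a clear error is raised.
``identity`` / ``zero``
    Trivial operators used as controls in tests and diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pywt

__all__ = [
    "Denoiser",
    "get_denoiser",
    "register_denoiser",
    "available_denoisers",
    "wavelet_shrink",
    "shrinkage_strength",
    "universal_threshold",
    "bm3d_denoise",
    "verify_admissibility",
    "WAVELET",
    "WAVELET_LEVELS",
]

#: Orthogonal compactly-supported wavelet and decomposition depth used by the
#: shrinkage filter.  Periodisation keeps the transform square and unitary so
#: Parseval-based variance arguments carry over exactly.
WAVELET = "db4"
WAVELET_LEVELS = 3
_WAVELET_MODE = "periodization"


def wavelet_shrink(image: np.ndarray, delta: float) -> np.ndarray:
    """Soft-threshold all detail coefficients of ``image`` at level ``delta``.

    The coarsest approximation band is left untouched; with ``delta = 0`` the
    transform round-trips and the image is returned unchanged up to float
    round-off.
    """
    if delta < 0:
        raise ValueError("threshold delta must be >= 0")
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 8:
        raise ValueError("wavelet shrinkage needs a 2-D image of at least 8x8")
    level = max(1, min(WAVELET_LEVELS, pywt.dwtn_max_level(img.shape, WAVELET)))
    coeffs = pywt.wavedec2(img, WAVELET, mode=_WAVELET_MODE, level=level)
    shrunk = [coeffs[0]]
    for detail in coeffs[1:]:
        shrunk.append(tuple(pywt.threshold(d, delta, mode="soft") for d in detail))
    out = pywt.waverec2(shrunk, WAVELET, mode=_WAVELET_MODE)
    return out[: img.shape[0], : img.shape[1]]


def shrinkage_strength(rows: int, cols: int) -> float:
    """Noise-reduction factor Δ of the wavelet shrinkage filter.

    ``Δ = (2 log RC + 1)(log RC + 1) / RC`` with the natural logarithm; the
    variance of the noise surviving shrinkage is proportional to ``Δ σ²``.
    """
    if rows <= 0 or cols <= 0:
        raise ValueError("image dimensions must be positive")
    n = float(rows) * float(cols)
    log_n = np.log(n)
    return (2.0 * log_n + 1.0) * (log_n + 1.0) / n


def universal_threshold(sigma: float, rows: int, cols: int) -> float:
    """Universal soft threshold ``σ √(2 log RC)`` for Gaussian noise level σ."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    n = float(rows) * float(cols)
    return float(sigma * np.sqrt(2.0 * np.log(n))) if n > 1 else 0.0


def _wavelet_apply(image: np.ndarray, sigma: float | None) -> np.ndarray:
    if sigma is None:
        from .autoparam import estimate_noise_std

        sigma = estimate_noise_std(image)
    delta = universal_threshold(sigma, *np.asarray(image).shape)
    return wavelet_shrink(image, delta)


def bm3d_denoise(image: np.ndarray, sigma: float) -> np.ndarray:
    """Delegate to the external BM3D implementation at noise level ``sigma``."""
    if sigma is None or sigma <= 0:
        raise ValueError("bm3d requires sigma > 0")
    try:
        import bm3d  # noqa: PLC0415
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise ImportError(
            "the 'bm3d' package is not installed; install it "
            "(pip install bm3d) or select the 'wavelet' denoiser"
        ) from exc
    img = np.asarray(image, dtype=np.float64)
    return np.asarray(bm3d.bm3d(img, sigma_psd=sigma), dtype=np.float64)


@dataclass(frozen=True)
class Denoiser:
    """A named noise-reduction operator with an optional fixed strength.

    ``strength`` is a noise standard deviation in intensity units; its exact
    interpretation is the operator's own (threshold scale for wavelet, noise
    level for BM3D).  ``None`` means the operator chooses per call, e.g. by
    estimating the noise level of its input.
    """

    name: str
    fn: Callable[[np.ndarray, float | None], np.ndarray]
    strength: float | None = None

    def apply(self, image: np.ndarray, sigma: float | None = None) -> np.ndarray:
        """Denoise ``image``; an explicit ``sigma`` overrides the fixed strength."""
        out = self.fn(np.asarray(image, dtype=np.float64),
                      self.strength if sigma is None else sigma)
        return np.asarray(out, dtype=np.float64)

    def with_strength(self, sigma: float | None) -> "Denoiser":
        return Denoiser(self.name, self.fn, sigma)


_REGISTRY: dict[str, Callable[[np.ndarray, float | None], np.ndarray]] = {
    "identity": lambda image, sigma: image,
    "zero": lambda image, sigma: np.zeros_like(image),
    "wavelet": _wavelet_apply,
    "bm3d": lambda image, sigma: bm3d_denoise(image, 7.5 if sigma is None else sigma),
}


def register_denoiser(name: str, fn: Callable[[np.ndarray, float | None], np.ndarray]) -> None:
    """Register a custom denoiser under ``name`` (overwrites an existing one)."""
    _REGISTRY[name] = fn


def available_denoisers() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


def get_denoiser(name: str, strength: float | None = None) -> Denoiser:
    try:
        fn = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown denoiser {name!r}; available: {', '.join(available_denoisers())}"
        ) from None
    return Denoiser(name, fn, strength)


def verify_admissibility(
    denoiser: Denoiser,
    truth: np.ndarray,
    sigma: float,
    n_trials: int = 20,
    seed: int | np.random.Generator = 0,
) -> float:
    """Monte-Carlo estimate of a denoiser's noise-reduction factor.

    Draws ``n_trials`` independent white-Gaussian noise fields ``N`` of
    standard deviation ``sigma``, applies the denoiser to ``truth + N`` and
    returns the mean of ``Var(R_N(truth + N) - truth) / sigma²``.  An
    admissible operator scores well below 1; the identity operator scores
    approximately 1 and serves as a negative control.
    """
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    truth = np.asarray(truth, dtype=np.float64)
    rng = np.random.default_rng(seed)
    ratios = []
    for _ in range(n_trials):
        noisy = truth + rng.normal(0.0, sigma, size=truth.shape)
        residual = denoiser.apply(noisy, sigma) - truth
        ratios.append(np.var(residual) / sigma**2)
    return float(np.mean(ratios))
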