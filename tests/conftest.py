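"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import vancittert as vc


def brute_force_circular_convolve(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct spatial-domain circular convolution by explicit loops.

    Independent oracle for the FFT-based blur operator: sums
    ``kernel[i, j] * image[(r - i + ci) % R, (c - j + cj) % C]`` with the
    kernel origin at its centre element.
    """
    image = np.asarray(image, dtype=np.float64)
    kernel = np.asarray(kernel, dtype=np.float64)
    rows, cols = image.shape
    kr, kc = kernel.shape
    ci, cj = kr // 2, kc // 2
    out = np.zeros_like(image)
    for r in range(rows):
        for c in range(cols):
            acc = 0.0
            for i in range(kr):
                for j in range(kc):
                    acc += kernel[i, j] * image[(r - i + ci) % rows, (c - j + cj) % cols]
            out[r, c] = acc
    return out


ALL_PSFS = {
    "cauchy15": {},
    "uniform9": {},
    "separable1461": {},
    "gaussian1.6": {"kind": "gaussian", "std": 1.6},
    "gaussian0.4": {"kind": "gaussian", "std": 0.4},
}


def make_named_psf(name: str) -> np.ndarray:
    params = dict(ALL_PSFS[name])
    kind = params.pop("kind", name)
    return vc.make_psf(kind, **params)


@pytest.fixture(scope="session")
def blobs64() -> np.ndarray:
    return vc.synth_image(vc.FixtureSpec(kind="blobs", size=(64, 64), seed=7))


@pytest.fixture(scope="session")
def blobs128() -> np.ndarray:
    return vc.synth_image(vc.FixtureSpec(kind="blobs", size=(128, 128), seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
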