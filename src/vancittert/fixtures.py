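"""Deterministic synthetic ground-truth images.

Every test and demo runs without downloading benchmark photographs: these
generators produce seeded scenes that exercise the same image features the
standard test images are used for — smooth regions, sharp edges, periodic
texture and small high-contrast glyphs.  The ``blobs`` kind emulates a
fluorescence-microscopy field: isolated Gaussian spots on a dark background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import Scenario, build_scenario, degrade

__all__ = ["FixtureSpec", "synth_image", "scenario_suite", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("blobs", "edges", "grating", "bars")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one reproducible synthetic image."""

    kind: str = "blobs"
    size: tuple[int, int] = (128, 128)
    seed: int = 0
    contrast: float = 200.0

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; expected one of {FIXTURE_KINDS}")
        if self.size[0] < 16 or self.size[1] < 16:
            raise ValueError("fixture size must be at least 16x16")
        if not 0 < self.contrast <= 255:
            raise ValueError("contrast must be in (0, 255]")


def _blobs(rng: np.random.Generator, shape: tuple[int, int], contrast: float) -> np.ndarray:
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)
    n_spots = max(4, (rows * cols) // 1500)
    img = np.zeros(shape, dtype=np.float64)
    for _ in range(n_spots):
        cy, cx = rng.uniform(0, rows), rng.uniform(0, cols)
        sd = rng.uniform(1.5, 0.04 * min(shape) + 2.0)
        amp = rng.uniform(0.4, 1.0)
        img += amp * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sd**2)))
    img /= img.max()
    background = 0.1 * (255.0 - contrast)
    return background + contrast * img


def _edges(rng: np.random.Generator, shape: tuple[int, int], contrast: float) -> np.ndarray:
    rows, cols = shape
    n_steps = int(rng.integers(3, 7))
    levels = np.linspace(0.0, contrast, n_steps)
    img = np.zeros(shape, dtype=np.float64)
    edges_c = np.sort(rng.choice(np.arange(1, cols), size=n_steps - 1, replace=False))
    bounds = np.concatenate(([0], edges_c, [cols]))
    for i in range(n_steps):
        img[:, bounds[i] : bounds[i + 1]] = levels[i]
    # a horizontal step as well, so both axes see a discontinuity
    r_split = int(rng.integers(rows // 4, 3 * rows // 4))
    img[r_split:, :] = contrast - img[r_split:, :]
    return img + 0.1 * (255.0 - contrast)


def _grating(rng: np.random.Generator, shape: tuple[int, int], contrast: float) -> np.ndarray:
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)
    fy = rng.uniform(1.5, 6.0) / rows
    fx = rng.uniform(1.5, 6.0) / cols
    phase = rng.uniform(0, 2 * np.pi)
    wave = np.sin(2 * np.pi * (fy * yy + fx * xx) + phase)
    mid = 0.1 * (255.0 - contrast) + contrast / 2.0
    return mid + (contrast / 2.0) * wave


def _bars(rng: np.random.Generator, shape: tuple[int, int], contrast: float) -> np.ndarray:
    rows, cols = shape
    img = np.full(shape, 0.1 * (255.0 - contrast), dtype=np.float64)
    n_glyphs = max(6, (rows * cols) // 1000)
    for _ in range(n_glyphs):
        h = int(rng.integers(2, max(3, rows // 10)))
        w = int(rng.integers(1, max(2, cols // 16)))
        r0 = int(rng.integers(0, rows - h))
        c0 = int(rng.integers(0, cols - w))
        img[r0 : r0 + h, c0 : c0 + w] = img[0, 0] + rng.uniform(0.5, 1.0) * contrast
    return img


_GENERATORS = {"blobs": _blobs, "edges": _edges, "grating": _grating, "bars": _bars}


def synth_image(spec: FixtureSpec) -> np.ndarray:
    """Generate the deterministic image described by ``spec`` (values in [0, 255])."""
    rng = np.random.default_rng(spec.seed)
    img = _GENERATORS[spec.kind](rng, spec.size, spec.contrast)
    return np.clip(img, 0.0, 255.0)


def scenario_suite(
    seed: int = 0,
    *,
    size: tuple[int, int] = (128, 128),
    kind: str = "blobs",
) -> list[tuple[np.ndarray, np.ndarray, Scenario]]:
    """One degraded synthetic fixture per benchmark scenario.

    Returns ``(truth, observation, scenario)`` triples for scenarios 1-6,
    all derived reproducibly from ``seed``.
    """
    suite = []
    for index in range(1, 7):
        scenario = build_scenario(index)
        truth = synth_image(FixtureSpec(kind=kind, size=size, seed=seed + index))
        observation = degrade(
            truth, scenario.make_psf(), scenario.noise_variance, seed=seed * 1000 + index
        )
        suite.append((truth, observation, scenario))
    return suite
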