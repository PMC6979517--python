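"""Image file I/O, run manifests and configuration files.

All pixel data is handled on the 0-255 float convention regardless of file
bit depth: 8-bit values pass through unchanged, 16-bit values are divided by
257 (so 65535 maps to 255), and RGB inputs are collapsed to luminance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np
import yaml

from . import __version__
from .restore import RestorationConfig

__all__ = [
    "read_image",
    "write_image",
    "read_psf_image",
    "RunManifest",
    "load_config",
]

_LUMA = np.array([0.299, 0.587, 0.114])


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as a float 2-D array on the 0-255 scale."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[..., :3]
        if arr.shape[2] != 3:
            raise ValueError(f"unsupported channel count {arr.shape[2]} in {path}")
        arr = np.tensordot(arr.astype(np.float64), _LUMA, axes=([2], [0]))
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim} in {path}")
    if arr.dtype == np.uint8:
        return arr.astype(np.float64)
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 257.0
    if np.issubdtype(arr.dtype, np.floating):
        return arr.astype(np.float64)
    raise ValueError(f"unsupported bit depth {arr.dtype} in {path}")


def write_image(path: str | Path, image: np.ndarray, *, bitdepth: int = 8) -> None:
    """Write a 0-255 float image as 8-bit PNG/TIFF or 16-bit TIFF."""
    path = Path(path)
    img = np.clip(np.asarray(image, dtype=np.float64), 0.0, 255.0)
    if bitdepth == 8:
        iio.imwrite(path, np.rint(img).astype(np.uint8))
    elif bitdepth == 16:
        if path.suffix.lower() not in {".tif", ".tiff"}:
            raise ValueError("16-bit output requires a .tif/.tiff path")
        iio.imwrite(path, np.rint(img * 257.0).astype(np.uint16))
    else:
        raise ValueError("bitdepth must be 8 or 16")


def read_psf_image(path: str | Path) -> np.ndarray:
    """Load a PSF kernel from a grayscale image file; normalised to unit sum."""
    from .imaging import psf_from_array

    return psf_from_array(read_image(path))


@dataclass
class RunManifest:
    """Everything needed to reproduce one restoration run exactly."""

    input_path: str
    psf_spec: dict[str, Any]
    config: RestorationConfig
    seed: int
    version: str = __version__
    metrics: dict[str, float] = field(default_factory=dict)
    denoise_events: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["config"] = dataclasses.asdict(self.config)
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        payload = json.loads(text)
        payload["config"] = RestorationConfig(**payload["config"])
        return cls(**payload)


_CONFIG_KEYS = {f.name for f in dataclasses.fields(RestorationConfig)}


def load_config(path: str | Path, overrides: dict[str, Any] | None = None) -> RestorationConfig:
    """Load a flat YAML/JSON config mirroring RestorationConfig; flags override."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    return RestorationConfig(**data)
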