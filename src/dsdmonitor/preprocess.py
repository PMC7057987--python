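"""Frame normalization and stochastic training-time augmentation.

Raw 8-bit frames are normalized to [0, 1] by dividing by 255.  During
training each frame may then independently receive any combination of:
horizontal mirror, vertical mirror, a random crop to 0.85 of width and
height resized back to the original resolution, a contrast multiplication
drawn from [0.9, 1.1], and a global brightness offset drawn from
[-0.05, 0.05].  Each augmentation fires with its own probability
(default 0.5 — the application rate is a free choice here, only the
operation set and parameter ranges are fixed), so a frame may receive
none, one, or several of them.  Outputs are clipped back to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["AugmentationConfig", "normalize", "augment"]


@dataclass(frozen=True)
class AugmentationConfig:
    mirror_horizontal: bool = True
    mirror_vertical: bool = True
    crop_factor: float = 0.85
    contrast_range: tuple[float, float] = (0.9, 1.1)
    brightness_range: tuple[float, float] = (-0.05, 0.05)
    probability: float = 0.5  # independent per-augmentation application rate

    def __post_init__(self) -> None:
        if not 0.0 < self.crop_factor <= 1.0:
            raise ValueError("crop_factor must lie in (0, 1]")
        lo, hi = self.contrast_range
        if lo <= 0 or hi < lo:
            raise ValueError("contrast_range must be positive and ordered")
        blo, bhi = self.brightness_range
        if not blo <= 0.0 <= bhi:
            raise ValueError("brightness_range must contain 0")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")


def normalize(raw: np.ndarray) -> np.ndarray:
    """Map 8-bit intensities to [0, 1] by dividing by 255.

    Accepts any array with values in [0, 255]; raises on out-of-range input.
    """
    arr = np.asarray(raw)
    if arr.size and (arr.min() < 0 or arr.max() > 255):
        raise ValueError("raw intensities must lie in [0, 255]")
    return (arr / 255.0).astype(np.float32)


def _bilinear_resize(img: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    h, w = img.shape
    oh, ow = out_shape
    # align-corners sampling grid; degenerate 1-pixel axes map to coordinate 0
    ys = np.linspace(0, h - 1, oh) if oh > 1 else np.zeros(1)
    xs = np.linspace(0, w - 1, ow) if ow > 1 else np.zeros(1)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    return ndimage.map_coordinates(img, [yy, xx], order=1, mode="nearest").astype(
        img.dtype
    )


def augment(
    frame: np.ndarray,
    cfg: AugmentationConfig = AugmentationConfig(),
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Apply the stochastic augmentation stack to one normalized frame.

    Each enabled augmentation fires independently with ``cfg.probability``.
    Output shape equals input shape and values are clipped to [0, 1].
    Deterministic for a fixed ``rng`` state.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = np.asarray(frame, dtype=np.float32)
    h, w = out.shape

    if cfg.mirror_horizontal and rng.random() < cfg.probability:
        out = out[:, ::-1]
    if cfg.mirror_vertical and rng.random() < cfg.probability:
        out = out[::-1, :]
    if cfg.crop_factor < 1.0 and rng.random() < cfg.probability:
        ch = max(int(np.floor(cfg.crop_factor * h)), 1)
        cw = max(int(np.floor(cfg.crop_factor * w)), 1)
        oy = int(rng.integers(0, h - ch + 1))
        ox = int(rng.integers(0, w - cw + 1))
        out = _bilinear_resize(out[oy : oy + ch, ox : ox + cw], (h, w))
    if rng.random() < cfg.probability:
        out = out * rng.uniform(*cfg.contrast_range)
    if rng.random() < cfg.probability:
        out = out + rng.uniform(*cfg.brightness_range)

    return np.clip(out, 0.0, 1.0).astype(np.float32)
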