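"""Batch-level augmentation: flips and random-angle rotation.

Each training image is expanded into {original, horizontal flip, vertical
flip, random rotation}; rotation angles are drawn uniformly from the
configured range (default ±30°) with bilinear interpolation and zero fill,
so the black fundus background stays black. Everything is driven by an
explicit seed: the same seed reproduces byte-identical batches. Labels are
geometric invariants of these transforms and are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import as_pixels

__all__ = ["AugmentConfig", "flip", "rotate_random", "augment_batch"]


@dataclass
class AugmentConfig:
    do_hflip: bool = True
    do_vflip: bool = True
    do_rotate: bool = True
    rotation_range: float = 30.0  # degrees, angle ~ U(-range, +range)
    fill_value: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.rotation_range <= 180):
            raise ValueError("rotation_range must lie in [0, 180]")


def flip(image, axis: str) -> np.ndarray:
    """Mirror along 'horizontal' (left-right) or 'vertical' (up-down)."""
    px = as_pixels(image)
    if axis == "horizontal":
        return px[:, ::-1].copy()
    if axis == "vertical":
        return px[::-1].copy()
    raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")


def rotate_random(image, cfg: AugmentConfig | None = None,
                  rng: np.random.Generator | None = None
                  ) -> tuple[np.ndarray, float]:
    """Rotate about the image center by a uniform random angle.

    Returns the rotated raster and the drawn angle in degrees. With a
    degenerate range (0) the output equals the input up to interpolation
    rounding.
    """
    cfg = cfg or AugmentConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    angle = float(rng.uniform(-cfg.rotation_range, cfg.rotation_range))
    px = as_pixels(image)
    rotated = ndimage.rotate(px.astype(np.float64), angle, axes=(1, 0),
                             reshape=False, order=1, mode="constant",
                             cval=cfg.fill_value)
    return np.clip(np.rint(rotated), 0, 255).astype(px.dtype), angle


def augment_batch(images, cfg: AugmentConfig | None = None) -> list:
    """Expand a batch: per image emit original, flips, and a rotation.

    With all flags on the output is 4x the input, ordered
    [original, hflip, vflip, rotated] per image. Deterministic for a
    fixed ``cfg.seed``.
    """
    if len(images) == 0:
        raise ValueError("empty batch")
    cfg = cfg or AugmentConfig()
    rng = np.random.default_rng(cfg.seed)
    out = []
    for img in images:
        px = as_pixels(img)
        out.append(px.copy())
        if cfg.do_hflip:
            out.append(flip(px, "horizontal"))
        if cfg.do_vflip:
            out.append(flip(px, "vertical"))
        if cfg.do_rotate:
            out.append(rotate_random(px, cfg, rng)[0])
    return out
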