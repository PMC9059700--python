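"""Fundus image enhancement operators.

Four enhancement families are provided, matching the preprocessing
variants evaluated for chronic-ocular-disease screening:

* color-channel extraction (the green plane best separates vessels,
  exudates and hemorrhages);
* contrast-limited adaptive histogram equalization (CLAHE): per-tile
  histogram equalization ``I_eq = floor((L-1) * CDF(I))`` with the
  histogram peaks clipped at a contrast factor before the CDF is built,
  and bilinear blending of neighbouring tile mappings;
* Gaussian unsharp blending ``I_gs = alpha*I + beta*(G_sigma * I) + gamma``
  with ``alpha=4, beta=-4, sigma=10, gamma=128`` — a band-pass sharpening
  that maps constant images to the flat offset ``gamma``;
* multiscale retinex (MSR): ``sum_n W_n (log(I+eps) - log(G_sigma_n*I + eps))``
  over scales ``[5, 35, 150]`` with equal weights, min-max rescaled to
  8-bit (a constant image has a raw map of exactly zero).

``apply_variant`` composes disc cropping with these operators into the
named preprocessing variants used throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import FundusImage, as_pixels

__all__ = [
    "ClaheConfig",
    "GaussianBlendConfig",
    "MsrConfig",
    "extract_channel",
    "clahe",
    "gaussian_blend",
    "msr",
    "msr_raw",
    "apply_variant",
    "VARIANTS",
]


@dataclass
class ClaheConfig:
    clip_limit: float | None = 2.0  # None disables clipping
    tile_grid: tuple[int, int] = (5, 5)
    levels: int = 256

    def __post_init__(self) -> None:
        if self.clip_limit is not None and self.clip_limit <= 0:
            raise ValueError("clip_limit must be positive")
        if min(self.tile_grid) < 1:
            raise ValueError("tile_grid must be at least (1, 1)")


@dataclass
class GaussianBlendConfig:
    alpha: float = 4.0
    beta: float = -4.0
    sigma: float = 10.0
    gamma: float = 128.0
    kernel_truncate: float = 4.0  # kernel half-width in sigmas


@dataclass
class MsrConfig:
    scales: tuple[float, ...] = (5.0, 35.0, 150.0)
    weights: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    epsilon: float = 1.0
    per_channel: bool = True

    def __post_init__(self) -> None:
        if len(self.scales) != len(self.weights):
            raise ValueError("scales and weights must have equal length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


def extract_channel(image, channel: str) -> np.ndarray:
    """Select one RGB plane, values unchanged."""
    px = as_pixels(image)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("channel extraction requires an RGB image")
    try:
        idx = "RGB".index(channel.upper())
    except ValueError:
        raise ValueError(f"unknown channel {channel!r}") from None
    return px[..., idx].copy()


# --------------------------------------------------------------------------
# CLAHE
# --------------------------------------------------------------------------

def _tile_lut(tile: np.ndarray, cfg: ClaheConfig) -> np.ndarray:
    """Equalization lookup table of one tile: floor((L-1) * clipped CDF)."""
    L = cfg.levels
    hist = np.bincount(tile.ravel(), minlength=L).astype(np.float64)
    total = hist.sum()
    if cfg.clip_limit is not None:
        clip = max(1.0, cfg.clip_limit * total / L)
        excess = np.maximum(hist - clip, 0.0).sum()
        hist = np.minimum(hist, clip) + excess / L
    cdf = np.cumsum(hist) / total
    return np.floor((L - 1) * cdf)


def _clahe_plane(plane: np.ndarray, cfg: ClaheConfig) -> np.ndarray:
    h, w = plane.shape
    gr, gc = cfg.tile_grid
    th, tw = int(np.ceil(h / gr)), int(np.ceil(w / gc))
    padded = np.pad(plane, ((0, gr * th - h), (0, gc * tw - w)), mode="reflect"
                    ) if (gr * th > h or gc * tw > w) else plane

    luts = np.empty((gr, gc, cfg.levels))
    for i in range(gr):
        for j in range(gc):
            luts[i, j] = _tile_lut(
                padded[i * th:(i + 1) * th, j * tw:(j + 1) * tw], cfg)

    if gr == 1 and gc == 1:
        return luts[0, 0][plane]

    # bilinear interpolation between the four surrounding tile mappings
    rows = np.arange(h)
    cols = np.arange(w)
    ty = np.clip((rows + 0.5) / th - 0.5, 0, gr - 1)
    tx = np.clip((cols + 0.5) / tw - 0.5, 0, gc - 1)
    y0 = np.floor(ty).astype(int)
    x0 = np.floor(tx).astype(int)
    y1 = np.minimum(y0 + 1, gr - 1)
    x1 = np.minimum(x0 + 1, gc - 1)
    fy = (ty - y0)[:, None]
    fx = (tx - x0)[None, :]

    v = plane
    out = ((1 - fy) * (1 - fx) * luts[y0[:, None], x0[None, :], v]
           + (1 - fy) * fx * luts[y0[:, None], x1[None, :], v]
           + fy * (1 - fx) * luts[y1[:, None], x0[None, :], v]
           + fy * fx * luts[y1[:, None], x1[None, :], v])
    return out


def clahe(image, cfg: ClaheConfig | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    Applied independently to each plane of an RGB image. Input must be
    integer-valued in ``[0, levels - 1]``; output has the same range and
    dtype uint8 (or the input integer dtype when ``levels != 256``).
    """
    cfg = cfg or ClaheConfig()
    px = as_pixels(image)
    if not np.issubdtype(px.dtype, np.integer):
        raise ValueError("CLAHE expects an integer-valued image")
    if px.ndim == 3:
        out = np.stack([_clahe_plane(px[..., k], cfg) for k in range(px.shape[2])],
                       axis=-1)
    else:
        out = _clahe_plane(px, cfg)
    out = np.clip(np.rint(out), 0, cfg.levels - 1)
    return out.astype(np.uint8 if cfg.levels <= 256 else px.dtype)


# --------------------------------------------------------------------------
# Gaussian unsharp blend
# --------------------------------------------------------------------------

def _smooth(plane: np.ndarray, sigma: float, truncate: float) -> np.ndarray:
    # reflective borders make smoothing of a constant image exact
    return ndimage.gaussian_filter(plane, sigma=sigma, mode="reflect",
                                   truncate=truncate)


def gaussian_blend(image, cfg: GaussianBlendConfig | None = None) -> np.ndarray:
    """``alpha*I + beta*(G_sigma * I) + gamma``, clipped to [0, 255]."""
    cfg = cfg or GaussianBlendConfig()
    px = as_pixels(image).astype(np.float64)
    if px.ndim == 3:
        blurred = np.stack([_smooth(px[..., k], cfg.sigma, cfg.kernel_truncate)
                            for k in range(px.shape[2])], axis=-1)
    else:
        blurred = _smooth(px, cfg.sigma, cfg.kernel_truncate)
    out = cfg.alpha * px + cfg.beta * blurred + cfg.gamma
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


# --------------------------------------------------------------------------
# Multiscale retinex
# --------------------------------------------------------------------------

def msr_raw(image, cfg: MsrConfig | None = None) -> np.ndarray:
    """Raw (float) retinex map before 8-bit rescaling.

    ``sum_n W_n (log(I + eps) - log(G_sigma_n * I + eps))``; exactly zero
    for a constant image. Linear in the weights.
    """
    cfg = cfg or MsrConfig()
    px = as_pixels(image).astype(np.float64)
    planes = (px[..., None] if px.ndim == 2 else px)
    raw = np.zeros_like(planes)
    for wgt, sigma in zip(cfg.weights, cfg.scales):
        for k in range(planes.shape[2]):
            blurred = _smooth(planes[..., k], sigma, 4.0)
            raw[..., k] += wgt * (np.log(planes[..., k] + cfg.epsilon)
                                  - np.log(blurred + cfg.epsilon))
    return raw[..., 0] if px.ndim == 2 else raw


def msr(image, cfg: MsrConfig | None = None) -> np.ndarray:
    """Multiscale retinex, min-max rescaled to [0, 255].

    A degenerate raw map (max == min, e.g. constant input) maps to all
    zeros rather than dividing by zero.
    """
    raw = msr_raw(image, cfg)
    lo, hi = float(raw.min()), float(raw.max())
    if hi - lo < 1e-12:
        return np.zeros(raw.shape, dtype=np.uint8)
    out = (raw - lo) / (hi - lo) * 255.0
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


# --------------------------------------------------------------------------
# Named preprocessing variants
# --------------------------------------------------------------------------

VARIANTS = ("original", "cropped", "green", "green_clahe", "green_gaussian",
            "rgb_clahe", "rgb_gaussian", "msr", "vessel_seg", "vessel_inpaint")


def apply_variant(image, variant: str, crop: bool = True) -> np.ndarray:
    """Compose disc cropping with the named enhancement chain."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    px = as_pixels(image)
    if variant == "original":
        return px.copy()

    from .roi_segment import crop_roi
    cropped = crop_roi(px)[0].pixels if crop else px

    if variant == "cropped":
        return cropped
    if variant == "green":
        return extract_channel(cropped, "G")
    if variant == "green_clahe":
        return clahe(extract_channel(cropped, "G"))
    if variant == "green_gaussian":
        return gaussian_blend(extract_channel(cropped, "G"))
    if variant == "rgb_clahe":
        return clahe(cropped)
    if variant == "rgb_gaussian":
        return gaussian_blend(cropped)
    if variant == "msr":
        return msr(cropped)

    from .vessel_ops import clean_mask, inpaint_vessels, segment_vessels
    mask = clean_mask(segment_vessels(cropped))
    if variant == "vessel_seg":
        return mask.raster
    return as_pixels(inpaint_vessels(cropped, mask))
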