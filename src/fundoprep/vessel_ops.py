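"""Vessel-mask segmentation, cleanup, and inpainting.

The cleanup rule mirrors the two-stage mask post-processing used before
vessel-based preprocessing variants: intensities below 20 are zeroed, then
any connected component with fewer than 100 pixels is removed (a 100-pixel
component survives). Segmentation backends are pluggable — any callable
mapping an RGB raster to a same-size single-channel response works; the
built-in ``naive_backend`` is a classical stand-in (CLAHE on the green
plane, black top-hat, global threshold), not a trained vessel segmenter.
Inpainting uses a biharmonic diffusion fill from the surrounding
background and touches only masked pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.filters import threshold_otsu
from skimage.restoration import inpaint_biharmonic

from .types import FundusImage, as_pixels

__all__ = [
    "VesselMask",
    "naive_backend",
    "segment_vessels",
    "clean_mask",
    "inpaint_vessels",
    "INTENSITY_THRESHOLD",
    "MIN_COMPONENT_PX",
]

INTENSITY_THRESHOLD = 20
MIN_COMPONENT_PX = 100


@dataclass
class VesselMask:
    """Single-channel vessel response map (0-255)."""

    raster: np.ndarray
    connectivity: int = 8  # 8-connectivity suits thin diagonal vessels

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster)
        if self.raster.ndim != 2:
            raise ValueError("vessel mask must be single-channel")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def binary(self) -> np.ndarray:
        return self.raster > 0


def naive_backend(pixels: np.ndarray) -> np.ndarray:
    """Classical vessel-response stand-in: CLAHE(green) -> black top-hat.

    Vessels are darker than the retina, so a black top-hat on the
    contrast-equalized green plane responds on thin dark curvilinear
    structures. The response is Otsu-thresholded over the foreground and
    returned as a 0/255 map. This is a synthetic-data-grade stand-in for
    a trained segmentation network, exposed through the same contract.
    """
    from .enhance import clahe, extract_channel

    px = np.asarray(pixels)
    green = extract_channel(px, "G") if px.ndim == 3 else px
    eq = clahe(green).astype(np.float64)
    tophat = morphology.black_tophat(eq, morphology.disk(4))
    fg = green > INTENSITY_THRESHOLD
    resp = np.where(fg, tophat, 0.0)
    if not (resp > 0).any():
        return np.zeros(px.shape[:2], dtype=np.uint8)
    thr = threshold_otsu(resp[fg]) if fg.any() else 0.0
    return np.where(resp > thr, 255, 0).astype(np.uint8)


def segment_vessels(image, backend: Callable[[np.ndarray], np.ndarray]
                    = naive_backend) -> VesselMask:
    """Raw (un-cleaned) vessel mask from a pluggable backend."""
    px = as_pixels(image)
    raw = np.asarray(backend(px))
    if raw.shape[:2] != px.shape[:2] or raw.ndim != 2:
        raise ValueError(
            f"backend returned shape {raw.shape}, expected {px.shape[:2]}")
    return VesselMask(raw.astype(np.uint8))


def clean_mask(mask: VesselMask,
               intensity_threshold: int = INTENSITY_THRESHOLD,
               min_component_px: int = MIN_COMPONENT_PX) -> VesselMask:
    """Zero sub-threshold intensities, then drop small components.

    Order matters and follows the published cleanup: pixels below
    ``intensity_threshold`` are zeroed first, then any connected component
    of the remaining nonzero pixels with fewer than ``min_component_px``
    pixels is zeroed (a component of exactly ``min_component_px`` pixels
    survives). Idempotent, and only ever shrinks the nonzero set.
    """
    raster = mask.raster.copy()
    raster[raster < intensity_threshold] = 0
    structure = (np.ones((3, 3), dtype=int) if mask.connectivity == 8
                 else ndimage.generate_binary_structure(2, 1))
    labels, n = ndimage.label(raster > 0, structure=structure)
    if n:
        sizes = np.bincount(labels.ravel())
        small = sizes < min_component_px
        small[0] = False
        raster[small[labels]] = 0
    return VesselMask(raster, connectivity=mask.connectivity)


def inpaint_vessels(image, mask: VesselMask) -> FundusImage:
    """Replace masked pixels with a diffusion fill from the background.

    Pixels outside the mask are returned bit-identical to the input.
    Raises ``ValueError`` when the mask covers the whole image (no
    background left to diffuse from).
    """
    px = as_pixels(image)
    m = mask.binary
    if m.shape != px.shape[:2]:
        raise ValueError("mask shape does not match image")
    if m.all():
        raise ValueError("mask covers the entire image; nothing to fill from")
    if not m.any():
        out = px.copy()
    else:
        filled = inpaint_biharmonic(
            px.astype(np.float64), m,
            channel_axis=-1 if px.ndim == 3 else None)
        out = px.copy()
        out[m] = np.clip(np.rint(filled[m]), 0, 255).astype(np.uint8)
    name = image.filename if isinstance(image, FundusImage) else ""
    return FundusImage(out, filename=name)
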