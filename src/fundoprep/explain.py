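"""Grad-CAM heat maps, thresholded masks, and contour overlays.

Given the last convolutional layer's activations and the gradients of a
class score with respect to them (supplied through any backend — arrays
are accepted directly, so no trained network is needed to test the
arithmetic), the localization map is the rectified gradient-weighted sum
of activation channels. It is min-max normalized to [0, 255], resized to
the input image, and thresholded at 100 to form a mask; mask contours are
drawn on a copy of the image in green when the prediction score is >= 0.5
and in red otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, transform

from .types import as_pixels

__all__ = ["HeatMap", "gradcam", "heatmap_to_contours", "MASK_THRESHOLD"]

MASK_THRESHOLD = 100
_GREEN = np.array([0, 255, 0], dtype=np.uint8)
_RED = np.array([255, 0, 0], dtype=np.uint8)


@dataclass
class HeatMap:
    raw: np.ndarray         # rectified weighted activation sum (float)
    normalized: np.ndarray  # uint8 map, resized to the image size
    mask_threshold: int = MASK_THRESHOLD

    @property
    def mask(self) -> np.ndarray:
        return self.normalized >= self.mask_threshold


def gradcam(activations: np.ndarray, gradients: np.ndarray,
            output_size: tuple[int, int] | None = None) -> HeatMap:
    """Gradient-weighted class activation map.

    ``activations`` and ``gradients`` are (K, h, w) stacks from the last
    convolutional layer. Channel weights are the spatial means of the
    gradient maps; the raw map is the weighted channel sum with negative
    values rectified to zero. Normalization is per-image min-max to
    [0, 255] (a constant raw map — e.g. all-zero gradients — maps to all
    zeros), followed by bilinear resizing to ``output_size``. The mask is
    invariant to positive rescaling of the raw map.
    """
    acts = np.asarray(activations, dtype=np.float64)
    grads = np.asarray(gradients, dtype=np.float64)
    if acts.ndim != 3 or acts.shape[0] == 0:
        raise ValueError("expected a non-empty (K, h, w) activation stack")
    if acts.shape != grads.shape:
        raise ValueError("activations and gradients must share shape")

    weights = grads.mean(axis=(1, 2))
    raw = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)

    lo, hi = float(raw.min()), float(raw.max())
    if hi - lo < 1e-12:
        norm = np.zeros_like(raw)
    else:
        norm = (raw - lo) / (hi - lo) * 255.0
    if output_size is not None and norm.shape != tuple(output_size):
        norm = transform.resize(norm, output_size, order=1,
                                preserve_range=True)
    normalized = np.clip(np.rint(norm), 0, 255).astype(np.uint8)
    return HeatMap(raw=raw, normalized=normalized)


def heatmap_to_contours(image, hm: HeatMap, score: float
                        ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Draw mask contours on a copy of the image; green iff score >= 0.5.

    Returns the overlay and the contour polylines (row, col vertices).
    The input image is never modified; the overlay differs from it only
    on contour pixels.
    """
    px = as_pixels(image)
    if hm.normalized.shape != px.shape[:2]:
        raise ValueError("heat map is not aligned to the image")
    overlay = px.copy()
    if overlay.ndim == 2:
        overlay = np.stack([overlay] * 3, axis=-1)
    color = _GREEN if score >= 0.5 else _RED
    contours = measure.find_contours(hm.mask.astype(float), 0.5)
    for contour in contours:
        rr = np.clip(np.rint(contour[:, 0]).astype(int), 0,
                     overlay.shape[0] - 1)
        cc = np.clip(np.rint(contour[:, 1]).astype(int), 0,
                     overlay.shape[1] - 1)
        overlay[rr, cc] = color
    return overlay, contours
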