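"""Automatic fundus-disc cropping via the circular Hough transform.

Fundus photographs are a bright circular retina on a black background.
The cropper detects candidate circles on an edge map, keeps the first
candidate (in accumulator order) whose bounding box — expanded by a small
margin — contains every non-background pixel, crops to that box clamped to
the frame, and resizes to 256x256. When no circle qualifies, it falls back
to the tight bounding box of the non-background pixels (the whole frame
for an empty image). An Otsu largest-contour baseline is provided for
comparison; it is known to clip the foreground on dark images.

Detection parameters (accumulator ratio 1, min center distance 20,
accumulator threshold 30, edge-gradient threshold 50, min radius
``min(H,W)/4``, max radius ``max(H,W)``) follow the tool's validated
defaults for 256x256 fundus frames.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from skimage import feature, measure, transform

from .types import CircleCandidate, CropBox, FundusImage, as_pixels

__all__ = [
    "HoughParams",
    "detect_circles",
    "select_fundus_circle",
    "crop_roi",
    "otsu_contour_crop",
    "TARGET_SIZE",
]

TARGET_SIZE = (256, 256)


@dataclass
class HoughParams:
    """Circle-detection and box-acceptance parameters."""

    dp_inverse_ratio: float = 1.0
    min_center_distance: int = 20
    accumulator_threshold: float = 30.0
    gradient_threshold: float = 50.0
    min_radius: Optional[int] = None  # default floor(min(H, W) / 4)
    max_radius: Optional[int] = None  # default max(H, W)
    outside_margin: int = 5
    nonzero_threshold: int = 0
    radius_step: int = 2

    def resolved(self, shape: tuple[int, int]) -> "HoughParams":
        h, w = shape
        rmin = self.min_radius if self.min_radius is not None else min(h, w) // 4
        rmax = self.max_radius if self.max_radius is not None else max(h, w)
        if rmin >= rmax:
            raise ValueError("min_radius must be smaller than max_radius")
        return replace(self, min_radius=rmin, max_radius=rmax)


def _gray(image) -> np.ndarray:
    px = as_pixels(image)
    if px.size == 0:
        raise ValueError("empty image")
    if px.ndim == 2:
        return px.astype(np.float64)
    # standard luma conversion
    return (0.299 * px[..., 0] + 0.587 * px[..., 1]
            + 0.114 * px[..., 2]).astype(np.float64)


def detect_circles(image, params: HoughParams | None = None
                   ) -> list[CircleCandidate]:
    """Candidate circles sorted by accumulator score.

    Edges come from the intensity gradient (Sobel magnitude thresholded at
    ``gradient_threshold``); each edge pixel votes in one accumulator per
    candidate radius. Returned centers are at least ``min_center_distance``
    apart and accumulator support is at least ``accumulator_threshold``
    votes.
    """
    params = (params or HoughParams()).resolved(_gray(image).shape)
    gray = _gray(image)
    h, w = gray.shape

    gy, gx = np.gradient(gray)
    magnitude = np.hypot(gx, gy)
    edges = magnitude >= params.gradient_threshold
    if not edges.any():
        return []

    # detectors cannot vote for circles larger than the frame allows;
    # cap the search while keeping the configured bounds
    rmax_eff = min(params.max_radius, int(np.hypot(h, w) / 2))
    radii = np.arange(params.min_radius, rmax_eff + 1, params.radius_step)
    accum = transform.hough_circle(edges, radii)
    scores, ccs, crs, rads = transform.hough_circle_peaks(
        accum, radii,
        min_xdistance=params.min_center_distance,
        min_ydistance=params.min_center_distance,
        threshold=None,
        num_peaks=5, total_num_peaks=24)

    out: list[CircleCandidate] = []
    for s, cx, cy, r in zip(scores, ccs, crs, rads):
        votes = s * 2 * np.pi * r  # normalized peak -> approx. vote count
        if votes < params.accumulator_threshold:
            continue
        if any(np.hypot(cy - c.center[0], cx - c.center[1])
               < params.min_center_distance for c in out):
            continue
        out.append(CircleCandidate(center=(float(cy), float(cx)),
                                   radius=float(r),
                                   accumulator_score=float(s)))
    out.sort(key=lambda c: (-c.accumulator_score, -c.radius))
    return out


def _circle_box(circle: CircleCandidate, shape: tuple[int, int]) -> CropBox:
    h, w = shape
    (cy, cx), r = circle.center, circle.radius
    return CropBox(
        row_lo=int(max(0, np.floor(cy - r))),
        row_hi=int(min(h, np.ceil(cy + r) + 1)),
        col_lo=int(max(0, np.floor(cx - r))),
        col_hi=int(min(w, np.ceil(cx + r) + 1)),
        chosen_circle=circle,
        method="hough",
    )


def _outside_count(nonzero: np.ndarray, box: CropBox, margin: int) -> int:
    h, w = nonzero.shape
    keep = np.zeros((h, w), dtype=bool)
    keep[max(0, box.row_lo - margin): min(h, box.row_hi + margin),
         max(0, box.col_lo - margin): min(w, box.col_hi + margin)] = True
    return int(np.count_nonzero(nonzero & ~keep))


def select_fundus_circle(image, candidates: list[CircleCandidate],
                         params: HoughParams | None = None
                         ) -> Optional[CircleCandidate]:
    """First candidate whose margin-expanded box contains all foreground.

    Foreground means intensity above ``nonzero_threshold`` in grayscale.
    If no candidate passes, the one excluding the fewest foreground pixels
    wins (ties broken toward the larger radius, preferring not to lose
    retinal content). Returns ``None`` for an empty candidate list.
    """
    if not candidates:
        return None
    params = (params or HoughParams()).resolved(_gray(image).shape)
    nonzero = _gray(image) > params.nonzero_threshold
    best, best_out = None, None
    for cand in candidates:
        box = _circle_box(cand, nonzero.shape)
        n_out = _outside_count(nonzero, box, params.outside_margin)
        if n_out == 0:
            return cand
        if (best_out is None or n_out < best_out
                or (n_out == best_out and cand.radius > best.radius)):
            best, best_out = cand, n_out
    return best


def _fallback_box(image, nonzero_threshold: int) -> CropBox:
    gray = _gray(image)
    h, w = gray.shape
    mask = gray > nonzero_threshold
    if not mask.any():
        return CropBox(0, h, 0, w, method="fallback")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return CropBox(int(rows[0]), int(rows[-1]) + 1,
                   int(cols[0]), int(cols[-1]) + 1, method="fallback")


def _apply_box(image, box: CropBox,
               resize_to: Optional[tuple[int, int]]) -> FundusImage:
    px = as_pixels(image)
    cropped = px[box.slices()]
    if resize_to is not None and cropped.shape[:2] != resize_to:
        cropped = transform.resize(cropped.astype(np.float64), resize_to,
                                   order=1, anti_aliasing=True,
                                   preserve_range=True)
        cropped = np.clip(np.rint(cropped), 0, 255)
    out = cropped.astype(np.uint8)
    name = image.filename if isinstance(image, FundusImage) else ""
    eye = image.eye if isinstance(image, FundusImage) else ""
    return FundusImage(out, filename=name, eye=eye)


def crop_roi(image, params: HoughParams | None = None,
             resize_to: Optional[tuple[int, int]] = TARGET_SIZE
             ) -> tuple[FundusImage, CropBox]:
    """Crop to the detected fundus circle's bounding box, then resize.

    Always returns: if no acceptable circle is found the tight bounding
    box of foreground pixels is used (whole frame when the image is
    empty), with ``method`` set to ``"fallback"``.
    """
    params = (params or HoughParams()).resolved(_gray(image).shape)
    candidates = detect_circles(image, params)
    chosen = select_fundus_circle(image, candidates, params)
    if chosen is not None:
        box = _circle_box(chosen, _gray(image).shape)
        if _outside_count(_gray(image) > params.nonzero_threshold, box,
                          params.outside_margin) > 0:
            box = _fallback_box(image, params.nonzero_threshold)
    else:
        box = _fallback_box(image, params.nonzero_threshold)
    return _apply_box(image, box, resize_to), box


def otsu_contour_crop(image,
                      resize_to: Optional[tuple[int, int]] = TARGET_SIZE
                      ) -> tuple[FundusImage, CropBox]:
    """Baseline: bounding box of the largest Otsu-foreground component.

    Known deficiency on dark images: the global Otsu threshold can land
    inside the retina and clip the foreground.
    """
    from skimage.filters import threshold_otsu

    gray = _gray(image)
    h, w = gray.shape
    if gray.max() == gray.min():
        box = CropBox(0, h, 0, w, method="fallback")
        return _apply_box(image, box, resize_to), box
    fg = gray > threshold_otsu(gray)
    labels = measure.label(fg, connectivity=2)
    if labels.max() == 0:
        box = CropBox(0, h, 0, w, method="fallback")
        return _apply_box(image, box, resize_to), box
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    box = CropBox(int(rows[0]), int(rows[-1]) + 1,
                  int(cols[0]), int(cols[-1]) + 1, method="otsu")
    return _apply_box(image, box, resize_to), box
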