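"""Seedable generator of fundus-like test images with exact ground truth.

Real color fundus photographs are a bright, roughly circular retinal disc on
a near-black camera background, with dark branching vessels and, in disease,
bright (exudate/drusen-like) or dark (hemorrhage-like) lesions. This module
renders that geometry programmatically so every downstream stage — disc
cropping, enhancement, vessel cleanup, relabeling, training, explanation —
can be exercised against known truth without any dataset download.

Rendered images satisfy two contracts the preprocessing algorithms rely on:
the background is strictly darker than intensity 20 outside the disc plus a
one-pixel anti-alias ring, and output is byte-identical for a fixed seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .types import CLASS_ORDER, FundusImage, LabelVector

__all__ = [
    "SynthSpec",
    "SynthGroundTruth",
    "KEYWORD_VOCABULARY",
    "generate_fundus",
    "random_spec",
    "generate_dataset",
]

#: One diagnostic phrase per class, shared with dataset_labels' default map.
KEYWORD_VOCABULARY: dict[str, str] = {
    "N": "normal fundus",
    "D": "moderate non proliferative retinopathy",
    "G": "glaucoma",
    "C": "cataract",
    "A": "dry age-related macular degeneration",
    "H": "hypertensive retinopathy",
    "M": "pathological myopia",
    "O": "macular epiretinal membrane",
}

_BACKGROUND_CEILING = 20  # exclusive upper bound for off-disc intensities


@dataclass
class SynthSpec:
    """Parameters of one rendered fundus phantom.

    ``clip_fraction`` is the fraction of the disc area allowed to fall
    outside the frame (off-center or clipped discs are common in real
    fundus photography); a disc entirely outside the frame is invalid.
    """

    image_size: tuple[int, int] = (256, 256)
    disc_center: tuple[float, float] = (128.0, 128.0)
    disc_radius: float = 100.0
    clip_fraction: float = 0.0
    n_vessels: int = 6
    lesion_counts: Mapping[str, int] = field(default_factory=dict)
    illumination_gradient: float = 0.15
    noise_sd: float = 2.0
    background_noise_sd: float = 0.0  # truncated below 20, off by default
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size
        if self.disc_radius < min(h, w) / 8:
            raise ValueError("disc_radius must be at least image_size/8")
        if not (0.0 <= self.clip_fraction <= 0.3):
            raise ValueError("clip_fraction must lie in [0, 0.3]")
        r, c = self.disc_center
        if (r + self.disc_radius <= 0 or r - self.disc_radius >= h
                or c + self.disc_radius <= 0 or c - self.disc_radius >= w):
            raise ValueError("disc lies entirely outside the frame")
        for tag in self.lesion_counts:
            if tag not in CLASS_ORDER:
                raise ValueError(f"unknown lesion class tag {tag!r}")


@dataclass
class SynthGroundTruth:
    """Exact truth for one rendered phantom."""

    disc_circle: tuple[tuple[float, float], float]  # ((row, col), radius)
    vessel_mask: np.ndarray  # bool, nonzero only inside the disc
    lesion_coords: list[tuple[int, int, str]]
    label: LabelVector
    vessel_free: np.ndarray  # identical render without vessels (uint8 RGB)


def _disc_alpha(shape: tuple[int, int], center, radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dist = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
    # 1 inside, linear ramp to 0 across a single anti-alias pixel
    return np.clip(radius + 1.0 - dist, 0.0, 1.0)


def _stamp_disk(canvas_mask: np.ndarray, row: float, col: float, rad: float):
    h, w = canvas_mask.shape
    r0, r1 = max(0, int(row - rad)), min(h, int(row + rad) + 2)
    c0, c1 = max(0, int(col - rad)), min(w, int(col + rad) + 2)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.ogrid[r0:r1, c0:c1]
    canvas_mask[r0:r1, c0:c1] |= ((rr - row) ** 2 + (cc - col) ** 2) <= rad**2


def _draw_vessels(spec: SynthSpec, inside: np.ndarray,
                  rng: np.random.Generator, extra: int = 0,
                  widen: float = 0.0) -> np.ndarray:
    """Random-walk polylines from near the disc center outward.

    Width 1-3 px so connected components have controllable pixel counts.
    """
    h, w = spec.image_size
    mask = np.zeros((h, w), dtype=bool)
    cy, cx = spec.disc_center
    n = spec.n_vessels + extra
    for _ in range(n):
        ang = rng.uniform(0, 2 * np.pi)
        pos = np.array([cy + rng.normal(0, 3), cx + rng.normal(0, 3)])
        width = rng.uniform(0.5, 1.5) + widen  # stamp radius -> 1-3 px wide
        n_steps = int(spec.disc_radius * rng.uniform(0.9, 1.4))
        for _step in range(n_steps):
            ang += rng.normal(0.0, 0.18)
            pos += np.array([np.sin(ang), np.cos(ang)])
            if ((pos[0] - cy) ** 2 + (pos[1] - cx) ** 2
                    > (spec.disc_radius - 2) ** 2):
                break
            _stamp_disk(mask, pos[0], pos[1], width)
    mask &= inside
    return mask


def _place_lesions(spec: SynthSpec, rng: np.random.Generator
                   ) -> list[tuple[int, int, str]]:
    coords: list[tuple[int, int, str]] = []
    h, w = spec.image_size
    cy, cx = spec.disc_center
    for tag, count in spec.lesion_counts.items():
        for _ in range(int(count)):
            # rejection-sample a point inside the disc and inside the frame
            for _try in range(100):
                rad = spec.disc_radius * np.sqrt(rng.uniform(0.0, 0.7))
                ang = rng.uniform(0, 2 * np.pi)
                r = int(cy + rad * np.sin(ang))
                c = int(cx + rad * np.cos(ang))
                if 0 <= r < h and 0 <= c < w:
                    coords.append((r, c, tag))
                    break
    return coords


def generate_fundus(spec: SynthSpec) -> tuple[FundusImage, SynthGroundTruth]:
    """Render one phantom and its exact ground truth.

    Deterministic: the same spec (including seed) yields byte-identical
    pixels. Raises ``ValueError`` for an invalid spec (e.g. the disc
    entirely outside the frame).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    cy, cx = spec.disc_center

    alpha = _disc_alpha((h, w), (cy, cx), spec.disc_radius)
    inside = alpha >= 1.0

    # base retinal coloring with a lateral illumination gradient
    rr, cc = np.mgrid[0:h, 0:w]
    grad = 1.0 + spec.illumination_gradient * (cc - cx) / max(w, 1)
    base = np.empty((h, w, 3), dtype=np.float64)
    base[..., 0] = 190.0 * grad
    base[..., 1] = 110.0 * grad
    base[..., 2] = 45.0 * grad

    # bright optic nerve head, offset from the disc center
    onh_r = spec.disc_radius * 0.18
    onh_cy = cy - spec.disc_radius * 0.15
    onh_cx = cx + spec.disc_radius * 0.45
    onh = np.clip(onh_r - np.sqrt((rr - onh_cy) ** 2 + (cc - onh_cx) ** 2),
                  0, 1)
    base += onh[..., None] * np.array([55.0, 90.0, 60.0])

    lesion_coords = _place_lesions(spec, rng)
    extra_vessels, widen = 0, 0.0
    for r, c, tag in lesion_coords:
        if tag == "D":  # hemorrhage-like dark dot + exudate-like bright dot
            dark = rng.uniform(0, 1) < 0.6
            rad = rng.uniform(2.0, 4.5)
            blob = np.clip(rad - np.sqrt((rr - r) ** 2 + (cc - c) ** 2), 0, 1)
            if dark:
                base -= blob[..., None] * np.array([120.0, 80.0, 30.0])
            else:
                base += blob[..., None] * np.array([60.0, 120.0, 120.0])
        elif tag == "A":  # drusen: soft bright blobs near the macula
            rad = rng.uniform(3.0, 6.0)
            d2 = (rr - r) ** 2 + (cc - c) ** 2
            base += np.exp(-d2 / (2 * rad**2))[..., None] * np.array(
                [60.0, 90.0, 70.0])
        elif tag == "G":  # enlarged bright cup
            rad = spec.disc_radius * rng.uniform(0.25, 0.32)
            blob = np.clip(rad - np.sqrt((rr - onh_cy) ** 2
                                         + (cc - onh_cx) ** 2), 0, 1)
            base += blob[..., None] * np.array([60.0, 110.0, 90.0])
        elif tag == "M":  # myopic crescent at the nerve-head rim
            d = np.sqrt((rr - onh_cy) ** 2 + (cc - onh_cx) ** 2)
            ring = np.clip(1.0 - np.abs(d - onh_r * 1.8) / 6.0, 0, 1)
            side = (cc - onh_cx) > 0
            base += (ring * side)[..., None] * np.array([70.0, 80.0, 90.0])
        elif tag == "O":  # gray membrane-like patch
            rad = rng.uniform(6.0, 12.0)
            d2 = (rr - r) ** 2 + (cc - c) ** 2
            base += np.exp(-d2 / (2 * rad**2))[..., None] * np.array(
                [-40.0, 20.0, 80.0])
        elif tag == "H":
            extra_vessels += 3
            widen = 1.0
    if "C" in spec.lesion_counts and spec.lesion_counts["C"]:
        # cataract: global milky haze over the disc
        base = 0.55 * base + 0.45 * 170.0

    if spec.noise_sd > 0:
        base += rng.normal(0.0, spec.noise_sd, size=base.shape)

    img = base * alpha[..., None]

    if spec.background_noise_sd > 0:
        bg_noise = np.abs(rng.normal(0.0, spec.background_noise_sd,
                                     size=(h, w)))
        bg_noise = np.minimum(bg_noise, _BACKGROUND_CEILING - 1.0)
        img += (alpha == 0)[..., None] * bg_noise[..., None]

    vessel_free = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    vessel_mask = (_draw_vessels(spec, inside, rng, extra_vessels, widen)
                   if spec.n_vessels + extra_vessels > 0
                   else np.zeros((h, w), dtype=bool))
    img = img.copy()
    img[vessel_mask] *= np.array([0.45, 0.35, 0.5])
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    disease_tags = [t for t, n in spec.lesion_counts.items()
                    if n and t != "N"]
    label = (LabelVector.from_classes(disease_tags) if disease_tags
             else LabelVector.from_string("10000000"))

    gt = SynthGroundTruth(
        disc_circle=((cy, cx), spec.disc_radius),
        vessel_mask=vessel_mask,
        lesion_coords=lesion_coords,
        label=label,
        vessel_free=vessel_free,
    )
    return FundusImage(pixels), gt


def random_spec(seed: int, image_size: tuple[int, int] = (256, 256),
                clip_fraction: float = 0.0,
                lesion_counts: Optional[Mapping[str, int]] = None
                ) -> SynthSpec:
    """Randomized disc geometry (center, radius, optional clipping)."""
    rng = np.random.default_rng(seed)
    h, w = image_size
    radius = rng.uniform(0.33, 0.46) * min(h, w)
    if clip_fraction > 0:
        # push the center toward an edge so part of the disc leaves the frame
        # sagitta <= 0.6 r keeps the clipped area fraction within 0.3
        off = radius * rng.uniform(0.2, 0.6) * clip_fraction / 0.3
        side = rng.integers(0, 2)
        cx = radius - off if side == 0 else w - radius + off
        cy = rng.uniform(h / 2 - 10, h / 2 + 10)
    else:
        margin = radius + 2.0
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
    return SynthSpec(
        image_size=image_size,
        disc_center=(float(cy), float(cx)),
        disc_radius=float(radius),
        clip_fraction=clip_fraction,
        n_vessels=int(rng.integers(4, 9)),
        lesion_counts=dict(lesion_counts or {}),
        illumination_gradient=float(rng.uniform(0.0, 0.25)),
        noise_sd=2.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


_DISEASE_LESIONS = {
    "D": {"D": 8}, "G": {"G": 1}, "C": {"C": 1}, "A": {"A": 6},
    "H": {"H": 1}, "M": {"M": 1}, "O": {"O": 2}, "N": {},
}


def generate_dataset(n: int, class_mix: Mapping[str, float], seed: int,
                     out_dir: str | os.PathLike) -> pd.DataFrame:
    """Write ``n`` synthetic patients (left+right PNGs) and a CSV manifest.

    Each patient draws one condition from ``class_mix``; diseased patients
    show the condition in the right eye and, 30% of the time, a healthy
    left eye — so two-eye union logic is exercised. The manifest columns
    match an ODIR-style layout: id, left_image, right_image, left_keywords,
    right_keywords, final_label (8-char bitstring, order N,D,G,C,A,H,M,O).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    tags = list(class_mix)
    probs = np.array([class_mix[t] for t in tags], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-8:
        raise ValueError("class_mix probabilities must sum to 1")
    os.makedirs(out_dir, exist_ok=True)

    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(n):
        cond = tags[rng.choice(len(tags), p=probs)]
        eye_conds = {"right": cond}
        eye_conds["left"] = ("N" if cond != "N" and rng.uniform() < 0.3
                             else cond)
        fnames, keywords, eye_labels = {}, {}, {}
        for eye in ("left", "right"):
            c = eye_conds[eye]
            spec = random_spec(int(rng.integers(0, 2**31 - 1)),
                               lesion_counts=_DISEASE_LESIONS[c])
            img, gt = generate_fundus(spec)
            fname = f"{pid}_{eye}.png"
            iio.imwrite(os.path.join(out_dir, fname), img.pixels)
            fnames[eye] = fname
            keywords[eye] = KEYWORD_VOCABULARY[c]
            eye_labels[eye] = gt.label
        final = _final_label(eye_labels["left"], eye_labels["right"])
        rows.append({
            "id": pid,
            "left_image": fnames["left"],
            "right_image": fnames["right"],
            "left_keywords": keywords["left"],
            "right_keywords": keywords["right"],
            "final_label": final.to_string(),
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


def _final_label(left: LabelVector, right: LabelVector) -> LabelVector:
    """Two-eye union with the normal-only-if-both-normal rule."""
    bits = left.bits | right.bits
    bits = bits.copy()
    bits[0] = 1 if (left.bits[0] and right.bits[0]) else 0
    if bits[1:].any():
        bits[0] = 0
    return LabelVector(bits)
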