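"""Shared containers for fundus rasters, crop boxes, and label vectors."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Class order of the 8-bit label vector.
CLASS_ORDER = ("N", "D", "G", "C", "A", "H", "M", "O")
CLASS_NAMES = {
    "N": "Normal", "D": "Diabetic retinopathy", "G": "Glaucoma",
    "C": "Cataract", "A": "Age-related macular degeneration",
    "H": "Hypertensive retinopathy", "M": "Pathological myopia",
    "O": "Other abnormality",
}
N_CLASSES = len(CLASS_ORDER)


@dataclass
class LabelVector:
    """8 binary flags ordered (N, D, G, C, A, H, M, O)."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.bits, dtype=np.uint8).ravel()
        if b.size != N_CLASSES or not np.isin(b, (0, 1)).all():
            raise ValueError("label vector must be 8 binary flags")
        self.bits = b

    @classmethod
    def from_string(cls, s: str) -> "LabelVector":
        if len(s) != N_CLASSES or set(s) - {"0", "1"}:
            raise ValueError(f"not an 8-char bitstring: {s!r}")
        return cls(np.array([int(c) for c in s], dtype=np.uint8))

    @classmethod
    def from_classes(cls, tags) -> "LabelVector":
        bits = np.zeros(N_CLASSES, dtype=np.uint8)
        for t in tags:
            bits[CLASS_ORDER.index(t)] = 1
        return cls(bits)

    def to_string(self) -> str:
        return "".join(str(int(b)) for b in self.bits)

    def __or__(self, other: "LabelVector") -> "LabelVector":
        return LabelVector(self.bits | other.bits)

    def __eq__(self, other) -> bool:  # type: ignore[override]
        return isinstance(other, LabelVector) and bool(
            (self.bits == other.bits).all())

    def __repr__(self) -> str:
        return f"LabelVector({self.to_string()})"


@dataclass
class FundusImage:
    """8-bit RGB raster with optional identity and ground truth."""

    pixels: np.ndarray
    filename: str = ""
    eye: str = ""  # "left" | "right" | ""
    ground_truth: Optional[object] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            raise ValueError("fundus raster must be 8-bit")

    @property
    def shape(self):
        return self.pixels.shape


def as_pixels(image) -> np.ndarray:
    """Accept a FundusImage or a bare ndarray; return the raster."""
    return image.pixels if isinstance(image, FundusImage) else np.asarray(image)


@dataclass
class CircleCandidate:
    center: tuple[float, float]  # (row, col)
    radius: float
    accumulator_score: float = 0.0


@dataclass
class CropBox:
    """Half-open, 0-based pixel bounds of a crop, plus provenance."""

    row_lo: int
    row_hi: int
    col_lo: int
    col_hi: int
    chosen_circle: Optional[CircleCandidate] = None
    method: str = "hough"  # hough | otsu | fallback

    def __post_init__(self) -> None:
        if not (self.row_lo < self.row_hi and self.col_lo < self.col_hi):
            raise ValueError("empty crop box")

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row_lo, self.row_hi), slice(self.col_lo, self.col_hi)

    @property
    def bounds(self) -> tuple[int, int, int, int]:
        return self.row_lo, self.row_hi, self.col_lo, self.col_hi
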