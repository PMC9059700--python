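"""Keyword relabeling, two-eye aggregation, and DR-grade binarization.

ODIR-style manifests carry free-text diagnostic keywords per eye plus a
declared 8-bit patient label. Relabeling maps each eye's phrases onto the
8 classes (N, D, G, C, A, H, M, O), takes the union across eyes — the
Normal flag survives only when *both* eyes read "normal fundus" and no
disease flag is set — and verifies the result against the declared label.
Mismatches are reported, never silently fixed.

DDR-style integer grades collapse to a screening decision: grade 0 is
normal, grades 1-4 abnormal, and grade 5 (ungradable image quality) is
excluded. The screening score from an 8-class prediction is
``1 - score(Normal)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import CLASS_ORDER, LabelVector, N_CLASSES

__all__ = [
    "KeywordMap",
    "DEFAULT_KEYWORD_MAP",
    "keywords_to_label",
    "union_and_verify",
    "aggregate_patient",
    "map_ddr_binary",
    "ddr_screening_score",
    "relabel_manifest",
    "PatientRecord",
]

log = logging.getLogger(__name__)


@dataclass
class KeywordMap:
    """Ordered phrase-pattern -> class-index map.

    Matching is case-insensitive substring matching over comma-separated
    phrases. Phrases matching no pattern map to the catch-all "Others"
    class, or raise in strict mode.
    """

    patterns: Sequence[tuple[str, str]]  # (substring, class tag)
    strict: bool = False

    def __post_init__(self) -> None:
        tags = {t for _, t in self.patterns}
        missing = set(CLASS_ORDER) - tags
        if missing:
            raise ValueError(f"classes without any pattern: {sorted(missing)}")

    def match_phrase(self, phrase: str) -> str:
        p = phrase.strip().lower()
        for substring, tag in self.patterns:
            if substring in p:
                return tag
        if self.strict:
            raise KeyError(f"unrecognized diagnostic phrase: {phrase!r}")
        return "O"


# ordered: "hypertensive" precedes "retinopathy" so hypertensive
# retinopathy maps to H, not D
DEFAULT_KEYWORD_MAP = KeywordMap(patterns=(
    ("normal fundus", "N"),
    ("hypertensive", "H"),
    ("retinopathy", "D"),
    ("glaucoma", "G"),
    ("cataract", "C"),
    ("macular degeneration", "A"),
    ("myopia", "M"),
    ("epiretinal membrane", "O"),
))


def keywords_to_label(text: str, keyword_map: KeywordMap | None = None
                      ) -> LabelVector:
    """Per-eye label: one bit per matched phrase (union over phrases)."""
    if not text or not text.strip():
        raise ValueError("empty keyword string")
    keyword_map = keyword_map or DEFAULT_KEYWORD_MAP
    bits = np.zeros(N_CLASSES, dtype=np.uint8)
    for phrase in text.split(","):
        if phrase.strip():
            bits[CLASS_ORDER.index(keyword_map.match_phrase(phrase))] = 1
    return LabelVector(bits)


def union_and_verify(left: LabelVector, right: LabelVector,
                     declared: Optional[LabelVector] = None
                     ) -> tuple[LabelVector, Optional[bool]]:
    """Two-eye union with the normal-handling rule, checked vs declared.

    Disease bits are OR-ed. The Normal bit is kept only when both eyes are
    Normal-only; a Normal reading in one eye alongside any disease is
    dropped. ``verified`` is ``None`` when no declared label is given.
    """
    bits = (left.bits | right.bits).copy()
    both_normal_only = bool(left.bits[0] and right.bits[0]
                            and not left.bits[1:].any()
                            and not right.bits[1:].any())
    bits[0] = 1 if both_normal_only else 0
    if bits[1:].any():
        bits[0] = 0
    result = LabelVector(bits)
    verified = None if declared is None else (result == declared)
    if verified is False:
        log.warning("label mismatch: union %s vs declared %s",
                    result.to_string(), declared.to_string())
    return result, verified


def aggregate_patient(left_scores: Optional[Sequence[float]],
                      right_scores: Optional[Sequence[float]]) -> np.ndarray:
    """Patient-level scores: label-wise maximum over available eyes.

    A missing eye (``None``) leaves the present eye's scores unchanged,
    so single-visit patients are handled by the same rule.
    """
    if left_scores is None and right_scores is None:
        raise ValueError("at least one eye's scores required")
    arrays = [np.asarray(s, dtype=float) for s in (left_scores, right_scores)
              if s is not None]
    if any(a.shape != (N_CLASSES,) for a in arrays):
        raise ValueError(f"score vectors must have length {N_CLASSES}")
    return arrays[0] if len(arrays) == 1 else np.maximum(*arrays)


def map_ddr_binary(grade: int) -> str:
    """DR grade -> screening class: 0 normal, 1-4 abnormal, 5 excluded."""
    if grade not in range(6):
        raise ValueError(f"grade must be in 0..5, got {grade}")
    if grade == 0:
        return "normal"
    if grade == 5:
        return "excluded"
    return "abnormal"


def ddr_screening_score(scores: Sequence[float]) -> float:
    """Abnormality score for DR screening: 1 - score of the Normal class."""
    s = np.asarray(scores, dtype=float)
    if s.shape != (N_CLASSES,):
        raise ValueError(f"expected {N_CLASSES} class scores")
    return float(1.0 - s[0])


@dataclass
class PatientRecord:
    id: object
    left_image: str
    right_image: str
    left_keywords: str
    right_keywords: str
    left_label: LabelVector
    right_label: LabelVector
    final_label: LabelVector
    verified: Optional[bool] = None


def relabel_manifest(manifest: pd.DataFrame,
                     keyword_map: KeywordMap | None = None
                     ) -> list[PatientRecord]:
    """Relabel every manifest row from its keyword strings and verify.

    Expects columns id, left_image, right_image, left_keywords,
    right_keywords and optionally final_label (8-char bitstring).
    """
    records = []
    for row in manifest.itertuples(index=False):
        left = keywords_to_label(row.left_keywords, keyword_map)
        right = keywords_to_label(row.right_keywords, keyword_map)
        declared = (LabelVector.from_string(str(row.final_label))
                    if "final_label" in manifest.columns else None)
        final, verified = union_and_verify(left, right, declared)
        records.append(PatientRecord(
            id=row.id, left_image=row.left_image, right_image=row.right_image,
            left_keywords=row.left_keywords, right_keywords=row.right_keywords,
            left_label=left, right_label=right,
            final_label=final, verified=verified))
    return records
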