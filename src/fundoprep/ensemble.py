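"""Majority-rule voting across aligned binary prediction sets.

Used to ensemble either three backbone architectures or three
preprocessing variants: per record and per label, the ensemble emits 1
exactly when at least two of the three members do. Three members means no
per-cell ties; other odd member counts are accepted behind a flag.
"""

from __future__ import annotations

import numpy as np

__all__ = ["majority_vote", "average_scores"]


def _stack(members, allow_any_odd: bool) -> np.ndarray:
    mats = [np.asarray(m) for m in members]
    k = len(mats)
    if k != 3 and not (allow_any_odd and k % 2 == 1 and k >= 1):
        raise ValueError("majority vote expects exactly 3 members")
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("vote members must share shape and record order")
    stacked = np.stack(mats)
    if not np.isin(stacked, (0, 1)).all():
        raise ValueError("vote members must be binary")
    return stacked


def majority_vote(members, allow_any_odd: bool = False) -> np.ndarray:
    """Per-cell majority of binary label matrices (1 iff sum >= k/2)."""
    stacked = _stack(members, allow_any_odd)
    k = stacked.shape[0]
    return (stacked.sum(axis=0) >= (k // 2 + 1)).astype(np.uint8)


def average_scores(members) -> np.ndarray:
    """Score-level alternative: plain mean of real-valued score matrices."""
    mats = [np.asarray(m, dtype=float) for m in members]
    if any(m.shape != mats[0].shape for m in mats):
        raise ValueError("score matrices must share shape")
    return np.mean(np.stack(mats), axis=0)
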