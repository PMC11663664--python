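"""Kennard-Stone calibration/validation partitioning.

Canonical maximin selection: seed the calibration set with the pair of
samples at maximal Euclidean distance, then repeatedly add the candidate
whose minimum distance to the already-selected set is largest. The
remainder forms the validation set. Fully deterministic; distance ties are
broken by the lowest row index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SplitResult:
    """Disjoint calibration/validation index partition."""

    calibration_idx: list[int]
    validation_idx: list[int]
    calibration_ids: list[str]
    validation_ids: list[str]
    ratio: float


def kennard_stone(
    X: np.ndarray, n_cal: int, sample_ids: list[str] | None = None
) -> SplitResult:
    """Select ``n_cal`` calibration samples by maximin Kennard-Stone."""
    x = np.atleast_2d(np.asarray(X, dtype=float))
    n = x.shape[0]
    if not 2 <= n_cal <= n - 1:
        raise ValueError(f"n_cal must be in [2, {n - 1}], got {n_cal}")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    if len(set(sample_ids)) != n:
        raise ValueError("duplicate sample ids")

    # full pairwise distance matrix; n is small (tens to hundreds) here
    sq = np.sum(x**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * x @ x.T, 0.0)

    # seed pair: row-major argmax = lexicographically smallest tie
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    selected = [int(min(i, j)), int(max(i, j))]
    in_set = np.zeros(n, dtype=bool)
    in_set[selected] = True
    # min squared distance from each candidate to the selected set
    min_d2 = np.minimum(d2[:, selected[0]], d2[:, selected[1]])

    while len(selected) < n_cal:
        min_d2[in_set] = -1.0
        nxt = int(np.argmax(min_d2))  # first index on ties
        selected.append(nxt)
        in_set[nxt] = True
        min_d2 = np.minimum(min_d2, d2[:, nxt])

    validation = [k for k in range(n) if not in_set[k]]
    return SplitResult(
        calibration_idx=selected,
        validation_idx=validation,
        calibration_ids=[sample_ids[k] for k in selected],
        validation_ids=[sample_ids[k] for k in validation],
        ratio=n_cal / n,
    )


def n_cal_for_ratio(n: int, ratio: float = 0.75) -> int:
    """Calibration count for a cal:(cal+val) fraction, e.g. 3:1 -> 0.75."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    return int(round(ratio * n))
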