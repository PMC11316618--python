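"""Distance-saturation profiles and the plateau decision.

For a reference cell in an ordered table, the profile is the euclidean
distance (on the raw expression rows, not PC scores) to every cell at
each ordered position.  In a banded matrix the distance stops growing
once bands no longer overlap -- the *distance saturation property*.  The
detector formalizes the visual "dotted line" judgement: it looks for the
longest terminal run of near-constant distances and calls saturation
when that run is long enough.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .errors import DimensionError, InsufficientDataError

REL_TOL = 0.05
MIN_RUN_FRAC = 0.25


@dataclass
class DistanceProfile:
    """Distances from one reference cell, aligned to an ordering.

    ``ref_index`` is the reference's cell (row) index, ``ref_position``
    its position within ``order``.
    """

    ref_index: int
    ref_position: int
    order: np.ndarray
    distances: np.ndarray

    def __post_init__(self):
        if self.distances[self.ref_position] != 0.0:
            raise DimensionError("self-distance must be zero at the reference")


@dataclass
class SaturationResult:
    """Terminal-plateau verdict for one distance profile."""

    is_saturated: bool
    onset_index: Optional[int]
    plateau_value: float
    plateau_relative_spread: float
    run_length: int


def distance_profile(ds: ExpressionDataset, order: np.ndarray,
                     ref_position: int = 0) -> DistanceProfile:
    """Euclidean distances from the cell at ``ref_position`` of ``order``
    to the cell at every ordered position (reference included)."""
    n = ds.n_cells
    order = np.asarray(order, dtype=int)
    if order.shape != (n,) or sorted(order.tolist()) != list(range(n)):
        raise DimensionError(f"order must be a permutation of 0..{n - 1}")
    if not 0 <= ref_position < n:
        raise DimensionError(f"ref_position {ref_position} out of range [0, {n})")
    rows = ds.matrix[order]
    ref_row = rows[ref_position]
    distances = np.linalg.norm(rows - ref_row, axis=1)
    distances[ref_position] = 0.0
    return DistanceProfile(ref_index=int(order[ref_position]),
                           ref_position=ref_position,
                           order=order, distances=distances)


def detect_saturation(p: DistanceProfile, rel_tol: float = REL_TOL,
                      min_run_frac: float = MIN_RUN_FRAC) -> SaturationResult:
    """Decide whether the profile's tail is a plateau.

    Looks at positions after the reference (in order direction away from
    it) and finds the longest terminal run whose distances all lie
    within ``rel_tol * max(distances)`` of the run's median; saturation
    holds iff that run covers at least ``min_run_frac`` of all cells.
    """
    tail = p.distances[p.ref_position + 1:]
    n = p.distances.size
    if tail.size < 4:
        raise InsufficientDataError(
            "need at least 4 cells beyond the reference to assess saturation")
    dmax = float(p.distances.max())
    tol = rel_tol * dmax
    # the longest admissible terminal run = smallest start whose run is
    # within tolerance of its own median (checked exhaustively: extending
    # a run shifts its median, so nesting arguments do not apply)
    best_start = tail.size - 1
    for start in range(tail.size):
        run = tail[start:]
        if np.max(np.abs(run - np.median(run))) <= tol:
            best_start = start
            break
    run = tail[best_start:]
    med = float(np.median(run))
    spread = float(np.max(np.abs(run - med)) / dmax) if dmax > 0 else 0.0
    saturated = run.size >= min_run_frac * n
    return SaturationResult(
        is_saturated=bool(saturated),
        onset_index=int(p.ref_position + 1 + best_start) if saturated else None,
        plateau_value=med,
        plateau_relative_spread=spread,
        run_length=int(run.size),
    )


def saturation_sweep(ds: ExpressionDataset, order: np.ndarray,
                     rel_tol: float = REL_TOL,
                     min_run_frac: float = MIN_RUN_FRAC) -> pd.DataFrame:
    """Saturation verdict for every admissible reference position.

    For references in the second half of the ordering the profile is
    evaluated on the reversed order, so the run always extends along the
    longer arm away from the reference.  Returns one row per reference
    position with the verdict fields.
    """
    order = np.asarray(order, dtype=int)
    n = ds.n_cells
    rows = []
    for pos in range(n):
        use_order, use_pos = order, pos
        if pos > n - 1 - pos:
            use_order, use_pos = order[::-1], n - 1 - pos
        prof = distance_profile(ds, use_order, use_pos)
        try:
            res = detect_saturation(prof, rel_tol, min_run_frac)
        except InsufficientDataError:
            continue
        rows.append({
            "ref_position": pos,
            "ref_index": int(order[pos]),
            "is_saturated": res.is_saturated,
            "onset_index": res.onset_index,
            "plateau_value": res.plateau_value,
            "plateau_relative_spread": res.plateau_relative_spread,
            "run_length": res.run_length,
        })
    return pd.DataFrame(rows)
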