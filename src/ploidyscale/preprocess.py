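"""Filtering and normalisation of the ratio matrix.

Two distinct normalisations serve the two analysis branches:

* **haploid anchoring** (scaling branch): the pooled distribution of 1N
  ratios is shifted multiplicatively so its median is exactly 1, and every
  other sample is shifted by the same factor.  Between-sample ratios are
  untouched, so the per-ploidy medians become relative protein amounts with
  the haploid state as the unit.
* **median centering** (differential branch): each sample column of the log2
  matrix is shifted additively so its median is 0, removing per-sample
  loading bias before the moderated t tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import SCALE_LINEAR, SCALE_LOG2, RatioMatrix


@dataclass(frozen=True)
class FilterReport:
    """Accounting of the valid-value filter.

    ``n_input = n_removed_flags + n_removed_valid_values + n_retained``.
    """

    n_input: int
    n_removed_flags: int
    n_removed_valid_values: int
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_input != self.n_removed_flags + self.n_removed_valid_values + self.n_retained:
            raise ValueError("filter report counts are inconsistent")


def filter_valid_values(
    matrix: RatioMatrix, min_valid: int = 2
) -> tuple[RatioMatrix, FilterReport]:
    """Keep proteins with >= ``min_valid`` finite values in at least one ploidy group.

    Quality-flagged rows still present in the matrix are removed first and
    counted separately.  Row order is preserved.

    The default of 2 follows the study design of triplicate measurements per
    ploidy state; requiring 3 ("more than two") is a configuration choice.
    """
    groups = {p: matrix.samples_for_ploidy(p) for p in matrix.ploidies}
    largest = max(len(cols) for cols in groups.values())
    if min_valid > largest:
        raise ValueError(
            f"min_valid={min_valid} exceeds the largest replicate group ({largest})"
        )

    n_input = matrix.n_proteins
    unflagged, flag_report = matrix.drop_flagged()

    finite = np.isfinite(unflagged.values.to_numpy(dtype=float))
    keep = np.zeros(unflagged.n_proteins, dtype=bool)
    col_index = {c: i for i, c in enumerate(unflagged.values.columns)}
    for cols in groups.values():
        idx = [col_index[c] for c in cols]
        keep |= finite[:, idx].sum(axis=1) >= min_valid

    out = RatioMatrix(
        values=unflagged.values.loc[keep],
        samples=list(unflagged.samples),
        scale=unflagged.scale,
        flags=unflagged.flags.loc[keep],
    )
    report = FilterReport(
        n_input=n_input,
        n_removed_flags=flag_report["total"],
        n_removed_valid_values=int((~keep).sum()),
        n_retained=int(keep.sum()),
    )
    return out, report


def anchor_to_haploid(matrix: RatioMatrix) -> tuple[RatioMatrix, float]:
    """Shift all ratios so the pooled haploid (1N) median is exactly 1.

    All 1N samples are pooled into a single distribution; the anchor factor
    is ``1 / median`` of its finite values and multiplies every value of
    every sample, so between-sample ratios are unchanged.  On a log2-scale
    matrix the equivalent additive shift is applied and the multiplicative
    factor is still returned.
    """
    base = min(matrix.ploidies)
    cols = matrix.samples_for_ploidy(base)
    pooled = matrix.values[cols].to_numpy(dtype=float).ravel()
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size == 0:
        raise ValueError(f"cannot anchor: no finite values in ploidy {base} samples")

    out = matrix.copy()
    if matrix.scale == SCALE_LINEAR:
        factor = 1.0 / float(np.median(pooled))
        out.values = matrix.values * factor
    else:
        shift = -float(np.median(pooled))
        out.values = matrix.values + shift
        factor = float(np.exp2(shift))
    return out, factor


def median_center(matrix: RatioMatrix, granularity: str = "per_sample") -> RatioMatrix:
    """Subtract each sample column's median so every column centers at 0.

    Requires a log2-scale matrix (centering is additive).  Idempotent.
    """
    if matrix.scale != SCALE_LOG2:
        raise ValueError("median centering requires a log2-scale matrix")
    if granularity != "per_sample":
        raise ValueError(f"unsupported granularity {granularity!r}")
    out = matrix.copy()
    arr = matrix.values.to_numpy(dtype=float)
    for j, sid in enumerate(matrix.sample_ids):
        col = arr[:, j]
        finite = np.isfinite(col)
        if not finite.any():
            raise ValueError(f"sample {sid!r} has no finite values to center")
        arr[:, j] = col - np.median(col[finite])
    out.values = pd.DataFrame(arr, index=matrix.values.index, columns=matrix.values.columns)
    return out
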