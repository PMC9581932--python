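"""Tabular input/output and the central ratio-matrix data model.

The pipeline starts from a MaxQuant ``proteinGroups.txt``-like table: one row
per protein group, one light/heavy (L/H) SILAC ratio column per sample, and
the usual quality-flag columns (potential contaminant, reverse database hit,
identified only by a modification site).  Sample-to-ploidy assignment is not
encoded in the column names; it comes from a separate metadata table.

All downstream stages operate on :class:`RatioMatrix`, a proteins x samples
grid of ratios carried either on the linear or the log2 scale, with an
explicit scale flag so a transform is never applied twice.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SCALE_LINEAR = "linear"
SCALE_LOG2 = "log2"

#: Tokens that parse to a missing value (MaxQuant and R dialects both occur).
MISSING_TOKENS = ("", "nan", "na")

#: MaxQuant flag-column conventions: column header -> internal flag name.
DEFAULT_FLAG_COLUMNS = {
    "Potential contaminant": "contaminant",
    "Reverse": "reverse",
    "Only identified by site": "site_only",
}

DEFAULT_RATIO_PREFIX = "Ratio L/H "
DEFAULT_ID_COLUMN = "Protein IDs"


class FormatError(ValueError):
    """The input table does not have the expected layout."""


class ReconciliationError(ValueError):
    """Sample metadata and ratio columns do not describe the same samples."""


@dataclass(frozen=True)
class SampleMeta:
    """One measured sample: identifier, ploidy (genome copies) and replicate."""

    sample_id: str
    ploidy: int
    replicate: int

    def __post_init__(self) -> None:
        if int(self.ploidy) < 1:
            raise ValueError(f"ploidy must be >= 1, got {self.ploidy} for {self.sample_id!r}")
        if int(self.replicate) < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate} for {self.sample_id!r}")
        object.__setattr__(self, "ploidy", int(self.ploidy))
        object.__setattr__(self, "replicate", int(self.replicate))


@dataclass
class RatioMatrix:
    """Proteins x samples grid of SILAC ratios with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by protein id with one column per sample id.
        Missing measurements are NaN.  On the linear scale all finite values
        must be strictly positive.
    samples
        Ordered sample metadata; ``sample_id`` must match ``values.columns``.
    scale
        ``"linear"`` (raw L/H ratios) or ``"log2"``.
    flags
        Boolean per-protein quality flags, columns ``contaminant``,
        ``reverse``, ``site_only``; same index as ``values``.
    """

    values: pd.DataFrame
    samples: list[SampleMeta]
    scale: str = SCALE_LINEAR
    flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in (SCALE_LINEAR, SCALE_LOG2):
            raise ValueError(f"unknown scale {self.scale!r}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in sample metadata")
        if list(self.values.columns) != ids:
            raise ReconciliationError(
                f"value columns {list(self.values.columns)} do not match sample metadata {ids}"
            )
        if not self.values.index.is_unique:
            raise ValueError("protein identifiers must be unique")
        if self.flags is None:
            self.flags = pd.DataFrame(
                False,
                index=self.values.index,
                columns=list(DEFAULT_FLAG_COLUMNS.values()),
            )
        if not self.flags.index.equals(self.values.index):
            raise ValueError("flags index must match the protein index")
        if self.scale == SCALE_LINEAR:
            arr = self.values.to_numpy(dtype=float)
            bad = np.isfinite(arr) & (arr <= 0)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    "non-positive linear-scale ratio at protein "
                    f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
                )

    # -- basic views ------------------------------------------------------

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def ploidies(self) -> list[int]:
        """Distinct ploidies, ascending."""
        return sorted({s.ploidy for s in self.samples})

    def samples_for_ploidy(self, ploidy: int) -> list[str]:
        return [s.sample_id for s in self.samples if s.ploidy == ploidy]

    def ploidy_of(self) -> pd.Series:
        """Sample id -> ploidy mapping as a Series aligned with the columns."""
        return pd.Series({s.sample_id: s.ploidy for s in self.samples})[self.sample_ids]

    def copy(self) -> "RatioMatrix":
        return RatioMatrix(
            values=self.values.copy(),
            samples=list(self.samples),
            scale=self.scale,
            flags=self.flags.copy(),
        )

    # -- scale transforms -------------------------------------------------

    def to_log2(self) -> "RatioMatrix":
        if self.scale == SCALE_LOG2:
            return self.copy()
        out = self.copy()
        out.values = np.log2(self.values)
        out.scale = SCALE_LOG2
        return out

    def to_linear(self) -> "RatioMatrix":
        if self.scale == SCALE_LINEAR:
            return self.copy()
        out = self.copy()
        out.values = np.exp2(self.values)
        out.scale = SCALE_LINEAR
        return out

    # -- flag handling ----------------------------------------------------

    def drop_flagged(self) -> tuple["RatioMatrix", dict[str, int]]:
        """Remove contaminant/reverse/site-only rows.

        Returns the reduced matrix and a removal report counting, per flag,
        how many removed rows carried it (a row with several flags is counted
        under each), plus ``"total"`` distinct rows removed.
        """
        flagged = self.flags.any(axis=1)
        report = {col: int(self.flags.loc[flagged, col].sum()) for col in self.flags.columns}
        report["total"] = int(flagged.sum())
        out = RatioMatrix(
            values=self.values.loc[~flagged],
            samples=list(self.samples),
            scale=self.scale,
            flags=self.flags.loc[~flagged],
        )
        return out, report


# -- readers / writers ----------------------------------------------------


def read_sample_metadata(meta_path) -> list[SampleMeta]:
    """Read a tab-separated sample sheet with columns sample_id, ploidy, replicate."""
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "ploidy", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"sample metadata lacks columns: {sorted(missing)}")
    return [
        SampleMeta(str(r.sample_id), int(r.ploidy), int(r.replicate))
        for r in meta.itertuples(index=False)
    ]


def read_ratio_table(
    path,
    meta_path,
    *,
    ratio_prefix: str = DEFAULT_RATIO_PREFIX,
    id_column: str = DEFAULT_ID_COLUMN,
    flag_columns: Mapping[str, str] = DEFAULT_FLAG_COLUMNS,
    flag_marker: str = "+",
    drop_flagged: bool = True,
) -> tuple[RatioMatrix, dict[str, int]]:
    """Read a protein-groups ratio table plus its sample metadata.

    Ratio columns are recognised by ``ratio_prefix``; the remainder of the
    header is the sample id and must be reconciled against the metadata
    table.  Cells that are empty or one of ``MISSING_TOKENS`` become NaN.
    Rows carrying a quality flag are removed by default and counted in the
    returned removal report; pass ``drop_flagged=False`` to keep them marked.

    Returns
    -------
    (RatioMatrix, removal_report)
        The matrix is on the linear scale.  ``removal_report`` counts removed
        rows per flag (all zeros when ``drop_flagged=False``).
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if id_column not in table.columns:
        raise FormatError(f"protein-id column {id_column!r} not found in {path}")

    samples = read_sample_metadata(meta_path)
    found = {
        c[len(ratio_prefix):]: c for c in table.columns if c.startswith(ratio_prefix)
    }
    meta_ids = [s.sample_id for s in samples]
    for sid in meta_ids:
        if sid not in found:
            raise ReconciliationError(f"sample {sid!r} in metadata has no ratio column")
    extra = sorted(set(found) - set(meta_ids))
    if extra:
        raise ReconciliationError(f"ratio columns without metadata: {extra}")

    ids = table[id_column].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise FormatError(f"duplicate protein id {dup!r}")

    def _parse(tok: str) -> float:
        # exact strtod parse; non-numeric tokens become missing
        try:
            return float(tok)
        except ValueError:
            return np.nan

    values = pd.DataFrame(index=pd.Index(ids, name=id_column))
    for sid in meta_ids:
        raw = table[found[sid]].str.strip()
        raw = raw.where(~raw.str.lower().isin(MISSING_TOKENS), other=np.nan)
        values[sid] = raw.map(_parse, na_action="ignore").astype(float).to_numpy()

    flags = pd.DataFrame(False, index=values.index, columns=list(flag_columns.values()))
    for col, name in flag_columns.items():
        if col in table.columns:
            flags[name] = (table[col].str.strip() == flag_marker).to_numpy()

    matrix = RatioMatrix(values=values, samples=samples, scale=SCALE_LINEAR, flags=flags)
    if drop_flagged:
        matrix, report = matrix.drop_flagged()
    else:
        report = {name: 0 for name in flags.columns}
        report["total"] = 0
    return matrix, report


def write_ratio_table(
    matrix: RatioMatrix,
    path,
    meta_path,
    *,
    ratio_prefix: str = DEFAULT_RATIO_PREFIX,
    id_column: str = DEFAULT_ID_COLUMN,
    flag_columns: Mapping[str, str] = DEFAULT_FLAG_COLUMNS,
) -> None:
    """Write a RatioMatrix in the same dialect :func:`read_ratio_table` reads."""
    if matrix.scale != SCALE_LINEAR:
        matrix = matrix.to_linear()
    out = pd.DataFrame({id_column: matrix.protein_ids})
    for sid in matrix.sample_ids:
        out[ratio_prefix + sid] = matrix.values[sid].to_numpy()
    inverse = {v: k for k, v in flag_columns.items()}
    for name in matrix.flags.columns:
        out[inverse.get(name, name)] = np.where(matrix.flags[name].to_numpy(), "+", "")
    out.to_csv(path, sep="\t", index=False, na_rep="")
    meta = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in matrix.samples],
            "ploidy": [s.ploidy for s in matrix.samples],
            "replicate": [s.replicate for s in matrix.samples],
        }
    )
    meta.to_csv(meta_path, sep="\t", index=False)


def write_results_table(records, path) -> None:
    """Write result records as a tab-separated UTF-8 table.

    ``records`` may be a DataFrame or an iterable of mappings/dataclasses
    sharing a schema.  Missing values are encoded as ``NA``; floats use the
    shortest round-trip representation so read-back is bit-identical.
    """
    frame = _as_frame(records)
    frame.to_csv(path, sep="\t", index=False, na_rep="NA", encoding="utf-8")


def read_results_table(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_results_table`."""
    return pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=True, float_precision="round_trip"
    )


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    columns = None
    for rec in records:
        if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
            rec = dataclasses.asdict(rec)
        rows.append(rec)
        if columns is None:
            columns = list(rec.keys())
        elif list(rec.keys()) != columns:
            raise ValueError("records do not share a schema")
    return pd.DataFrame(rows, columns=columns)
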