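"""Spike-in rescaling and fold-change classification of transcript data.

Emulates the comparative dynamic transcriptome analysis (cDTA) readout: a
foreign-species spike-in (e.g. fission-yeast mRNA added to budding-yeast
samples) is measured alongside the sample transcripts, so each sample's
capture efficiency can be divided out by proportional rescaling to the
spike-in standard.  After rescaling, between-sample mRNA fold changes are
absolute, and ploidy-responsive transcripts are the genes whose top-vs-
haploid fold change clears a +/-2-fold (1 log2 unit) cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import SampleMeta


@dataclass
class TranscriptMatrix:
    """Genes x samples intensity grid with per-gene spike-in flags."""

    intensities: pd.DataFrame
    samples: list[SampleMeta]
    spike: pd.Series  # boolean, True for internal-standard (spike-in) genes

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if list(self.intensities.columns) != ids:
            raise ValueError("intensity columns do not match sample metadata")
        if not self.spike.index.equals(self.intensities.index):
            raise ValueError("spike flags must be indexed by the gene index")
        if not self.spike.any():
            raise ValueError("at least one spike-in gene is required")
        arr = self.intensities.to_numpy(dtype=float)
        if (np.isfinite(arr) & (arr < 0)).any():
            raise ValueError("intensities must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def samples_for_ploidy(self, ploidy: int) -> list[str]:
        return [s.sample_id for s in self.samples if s.ploidy == ploidy]

    @property
    def ploidies(self) -> list[int]:
        return sorted({s.ploidy for s in self.samples})

    def copy(self) -> "TranscriptMatrix":
        return TranscriptMatrix(self.intensities.copy(), list(self.samples), self.spike.copy())


def spike_in_rescale(
    matrix: TranscriptMatrix, reference_sample: str | None = None
) -> tuple[TranscriptMatrix, pd.Series]:
    """Proportionally rescale each sample to the spike-in standard.

    Each sample's factor is (median spike intensity in the reference) /
    (median spike intensity in the sample); all of the sample's intensities
    (spike rows included, so the equalisation is visible) are multiplied by
    it.  After rescaling the spike medians are equal across samples.
    Returns the rescaled matrix and the per-sample factors.
    """
    if reference_sample is None:
        reference_sample = matrix.sample_ids[0]
    if reference_sample not in matrix.sample_ids:
        raise ValueError(f"unknown reference sample {reference_sample!r}")
    spikes = matrix.intensities.loc[matrix.spike]

    def spike_median(sid: str) -> float:
        col = spikes[sid].to_numpy(dtype=float)
        col = col[np.isfinite(col)]
        if col.size == 0:
            raise ValueError(f"sample {sid!r} has no finite spike-in intensities")
        return float(np.median(col))

    ref = spike_median(reference_sample)
    factors = pd.Series(
        {sid: ref / spike_median(sid) for sid in matrix.sample_ids}, name="factor"
    )
    out = matrix.copy()
    out.intensities = matrix.intensities * factors
    return out, factors


def classify_mrna_changes(
    matrix: TranscriptMatrix, fc_threshold_log2: float = 1.0
) -> tuple[list[str], list[str], list[str]]:
    """Genes whose top-vs-haploid mean intensity changes by >= the log2 cutoff.

    Per non-spike gene the log2 fold change of mean highest-ploidy over mean
    lowest-ploidy intensity is computed; genes at or beyond
    ``+/-fc_threshold_log2`` are returned as (up, down); genes with no
    finite or zero mean in either group are skipped and returned third.
    """
    ploidies = matrix.ploidies
    if len(ploidies) < 2:
        raise ValueError("need at least two ploidy levels")
    lo_cols = matrix.samples_for_ploidy(ploidies[0])
    hi_cols = matrix.samples_for_ploidy(ploidies[-1])
    genes = matrix.intensities.loc[~matrix.spike]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanmean(genes[lo_cols].to_numpy(dtype=float), axis=1)
        hi = np.nanmean(genes[hi_cols].to_numpy(dtype=float), axis=1)

    valid = np.isfinite(lo) & np.isfinite(hi) & (lo > 0) & (hi > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.log2(hi / lo)
    ids = np.array(genes.index)
    # absolute tolerance so an exactly threshold-fold gene is not lost to rounding
    tol = 1e-9
    up = [str(g) for g in ids[valid & (fc >= fc_threshold_log2 - tol)]]
    down = [str(g) for g in ids[valid & (fc <= -(fc_threshold_log2 - tol))]]
    skipped = [str(g) for g in ids[~valid]]
    return up, down, skipped
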