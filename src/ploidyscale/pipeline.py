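"""End-to-end orchestration of the scaling and PDR analyses.

``run_pipeline`` composes the stages into one reproducible run:

    read / generate -> flag filter -> valid-value filter
        -> (scaling branch)     anchor -> per-ploidy medians -> power fit
        -> (differential branch) log2 -> median center -> pairwise tests
           -> permutation q -> combined statistic -> smoothness -> trend
           -> PDR classification -> 2D enrichment (when a catalog exists)
        -> (transcriptome branch, optional) spike-in rescale -> +/-2FC genes

and writes the result tables plus a machine-readable JSON summary.  All
randomness flows from one seeded generator; two runs with the same config
and seed produce byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess, scaling, tables_io
from .differential import PloidyRegulationModel, TestConfig
from .enrichment import AnnotationCatalog, enrichment_2d, rank_scores
from .synthetic import SyntheticConfig, generate_annotation_catalog, generate_proteome_dataset
from .transcriptome import classify_mrna_changes, spike_in_rescale

log = logging.getLogger("ploidyscale")


@dataclass
class RunConfig:
    """One pipeline run: either real input paths or a synthetic scenario."""

    input_path: str | None = None
    meta_path: str | None = None
    annotation_path: str | None = None
    transcriptome_path: str | None = None
    transcriptome_meta_path: str | None = None
    synthetic: SyntheticConfig | None = None
    synthetic_annotation_terms: int = 0  # generate a catalog of this size for synthetic runs
    min_valid: int = 2
    test: TestConfig = field(default_factory=TestConfig)
    enrichment_min_members: int = 10
    enrichment_q_threshold: float = 0.02
    mrna_fc_threshold_log2: float = 1.0
    out_dir: str = "ploidyscale_out"
    seed: int = 0

    def __post_init__(self) -> None:
        real = self.input_path is not None
        if real == (self.synthetic is not None):
            raise ValueError("specify exactly one of input_path or a synthetic scenario")
        if real and self.meta_path is None:
            raise ValueError("meta_path is required with input_path")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and write result tables and ``summary.json`` to ``out_dir``.

    Returns the summary dict.  Any stage failure raises with a stage-named
    message (the CLI converts this to a non-zero exit).
    """
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    summary: dict = {"seed": config.seed}

    # -- input ------------------------------------------------------------
    stage = "input"
    try:
        catalog = None
        truth = None
        if config.synthetic is not None:
            matrix, truth = generate_proteome_dataset(config.synthetic)
            removal = {name: 0 for name in matrix.flags.columns} | {"total": 0}
            if config.synthetic_annotation_terms:
                catalog = generate_annotation_catalog(
                    config.synthetic_annotation_terms,
                    (10, 60),
                    [],
                    truth,
                    seed=int(seeds[1].generate_state(1)[0] % (2**31)),
                )
        else:
            matrix, removal = tables_io.read_ratio_table(config.input_path, config.meta_path)
            if config.annotation_path:
                catalog = AnnotationCatalog.from_gmt(config.annotation_path)
        summary["removal_report"] = removal

        stage = "filter"
        matrix, report = preprocess.filter_valid_values(matrix, config.min_valid)
        summary["filter_report"] = dataclasses.asdict(report)
        log.info("filter: retained %d of %d proteins", report.n_retained, report.n_input)

        # -- scaling branch ------------------------------------------------
        stage = "scaling"
        anchored, anchor_factor = preprocess.anchor_to_haploid(matrix)
        medians = scaling.ploidy_medians(anchored)
        fit = scaling.fit_power_law(medians)
        summary["anchor_factor"] = anchor_factor
        summary["scaling_fit"] = dataclasses.asdict(fit)
        frame = medians.to_frame()
        frame["fitted_amount"] = fit.predict(frame["ploidy"])
        tables_io.write_results_table(frame, out_dir / "scaling_fit.tsv")
        log.info("scaling: b=%.3f R2=%.3f", fit.exponent_b, fit.r_squared)

        # -- differential branch -------------------------------------------
        stage = "differential"
        centered = preprocess.median_center(matrix.to_log2())
        rng = np.random.default_rng(seeds[0])
        results = PloidyRegulationModel(centered, config.test).fit(rng=rng)
        sets = results.classify()
        tables_io.write_results_table(results.table, out_dir / "proteome_results.tsv")
        summary["pdr"] = {
            "n_proteins": len(results.table),
            "n_up": len(sets.up),
            "n_down": len(sets.down),
            "n_consistent_up": len(sets.consistent_up),
            "n_consistent_down": len(sets.consistent_down),
        }
        log.info("differential: %d up / %d down", len(sets.up), len(sets.down))

        # -- enrichment -----------------------------------------------------
        if catalog is not None and len(catalog):
            stage = "enrichment"
            ploidies = anchored.ploidies
            log2m = anchored.to_log2()

            def dim_scores(p):
                import warnings

                cols = log2m.samples_for_ploidy(p)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    return np.nanmean(log2m.values[cols].to_numpy(dtype=float), axis=1)

            sx = pd.Series(dim_scores(ploidies[0]), index=log2m.protein_ids)
            sy = pd.Series(dim_scores(ploidies[-1]), index=log2m.protein_ids)
            keep = sx.notna() & sy.notna()
            rx = pd.Series(rank_scores(sx[keep]), index=sx.index[keep])
            ry = pd.Series(rank_scores(sy[keep]), index=sy.index[keep])
            enr = enrichment_2d(
                rx, ry, catalog,
                min_members=config.enrichment_min_members,
                q_threshold=config.enrichment_q_threshold,
            )
            tables_io.write_results_table(enr, out_dir / "enrichment.tsv")
            summary["enrichment"] = {
                "n_terms": int(len(enr)),
                "n_significant": int(enr["significant"].sum()),
            }

        # -- transcriptome --------------------------------------------------
        if config.transcriptome_path:
            stage = "transcriptome"
            tmatrix = read_transcript_table(
                config.transcriptome_path, config.transcriptome_meta_path
            )
            rescaled, factors = spike_in_rescale(tmatrix)
            up, down, skipped = classify_mrna_changes(rescaled, config.mrna_fc_threshold_log2)
            tables_io.write_results_table(
                pd.DataFrame(
                    {"gene_id": up + down, "direction": ["up"] * len(up) + ["down"] * len(down)}
                ),
                out_dir / "transcriptome_changes.tsv",
            )
            summary["transcriptome"] = {
                "n_up": len(up),
                "n_down": len(down),
                "n_skipped": len(skipped),
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # runtime is logged, not written: summaries must be byte-identical across runs
    log.info("pipeline finished in %.2fs", time.time() - t0)
    summary["config"] = dataclasses.asdict(config)
    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return summary


def read_transcript_table(path, meta_path):
    """Read a transcript intensity TSV (gene_id, spike, one column per sample)."""
    from .transcriptome import TranscriptMatrix

    samples = tables_io.read_sample_metadata(meta_path)
    frame = pd.read_csv(path, sep="\t", na_values=["NA"])
    if "gene_id" not in frame.columns or "spike" not in frame.columns:
        raise tables_io.FormatError("transcript table needs gene_id and spike columns")
    frame = frame.set_index("gene_id")
    spike = frame["spike"].astype(bool)
    ids = [s.sample_id for s in samples]
    missing = [sid for sid in ids if sid not in frame.columns]
    if missing:
        raise tables_io.ReconciliationError(f"samples missing from transcript table: {missing}")
    return TranscriptMatrix(frame[ids].astype(float), samples, spike)


def write_transcript_table(matrix, path, meta_path) -> None:
    """Write a TranscriptMatrix in the dialect :func:`read_transcript_table` reads."""
    out = matrix.intensities.copy()
    out.insert(0, "spike", matrix.spike)
    out = out.reset_index().rename(columns={out.index.name or "index": "gene_id"})
    out.columns.values[0] = "gene_id"
    out.to_csv(path, sep="\t", index=False, na_rep="NA")
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in matrix.samples],
            "ploidy": [s.ploidy for s in matrix.samples],
            "replicate": [s.replicate for s in matrix.samples],
        }
    ).to_csv(meta_path, sep="\t", index=False)
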