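"""End-to-end orchestration: calibrate -> tracks -> FCD -> cutoff -> calls ->
score -> break -> summarize, with every artifact written to an output
directory and every chosen parameter logged."""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from . import assembly_breaking, calibration, error_calling, fcd_engine, formats_io
from .assembly_breaking import AssemblySummary
from .calibration import LibraryStats
from .error_calling import RegionCall
from .pileup_stats import (
    PerBaseTracks,
    accumulate_tracks,
    relative_frag_cov_error,
    relative_read_depth_error,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths, thresholds and flags of one evaluation run.

    Threshold defaults follow the published rules where stated (five perfect
    reads, 80% failing bases, coverage ratio 2 over 100 bp, derivative
    threshold 0.05, half-insert gap rule); everything is overridable.
    """

    assembly: str = ""
    alignments: str = ""
    perfect_alignments: Optional[str] = None  # optional short-insert library
    outdir: str = "asmcritic_out"
    min_mapq: int = 10
    min_pairs: int = 10_000
    min_windows: int = 1_000
    seed: int = 1
    gzip_plots: bool = False
    write_all_tracks: bool = False
    thresholds: Dict[str, float] = field(
        default_factory=lambda: dict(calibration.DEFAULT_THRESHOLDS)
    )

    def validate(self) -> None:
        if not os.path.exists(self.assembly):
            raise PipelineError("input-validation", f"missing assembly {self.assembly!r}")
        if not os.path.exists(self.alignments):
            raise PipelineError(
                "input-validation", f"missing alignments {self.alignments!r}"
            )
        for key, value in self.thresholds.items():
            if value <= 0:
                raise PipelineError("input-validation", f"threshold {key} must be > 0")


@dataclass
class PipelineResult:
    assembly: formats_io.Assembly
    tracks: PerBaseTracks
    lib: LibraryStats
    calls: List[RegionCall]
    broken: formats_io.Assembly
    break_log: List[Tuple[str, str, int, int]]
    summary: AssemblySummary


def evaluate(
    assembly: formats_io.Assembly,
    alignments_path: str,
    config: Optional[RunConfig] = None,
    perfect_alignments_path: Optional[str] = None,
) -> Tuple[PerBaseTracks, LibraryStats, List[RegionCall]]:
    """Library-level evaluation: tracks, calibrated stats, region calls and
    per-base scores for an in-memory assembly."""
    cfg = config or RunConfig()
    lib = calibration.estimate_library_stats(
        list(formats_io.stream_alignments(alignments_path, assembly)),
        assembly,
        min_pairs=cfg.min_pairs,
        min_mapq=cfg.min_mapq,
    )
    lib.thresholds = dict(cfg.thresholds)
    logger.info(
        "calibrated library: mean_insert=%.1f range=(%.0f, %.0f) read_len=%d",
        lib.mean_insert,
        *lib.insert_range,
        lib.read_len,
    )
    perfect_iter = (
        formats_io.stream_alignments(perfect_alignments_path, assembly)
        if perfect_alignments_path
        else None
    )
    tracks = accumulate_tracks(
        assembly,
        formats_io.stream_alignments(alignments_path, assembly),
        lib,
        perfect_alignments=perfect_iter,
    )
    calibration.update_coverage_means(lib, tracks, assembly)
    lib.gc_curve = calibration.fit_gc_bias(tracks, assembly)
    lib.gc_curve_depth = calibration.fit_gc_bias(
        tracks, assembly, coverage_metric="read_depth"
    )
    relative_frag_cov_error(tracks, assembly, lib)
    relative_read_depth_error(tracks, assembly, lib)
    fcd_engine.fcd_error_track(assembly, tracks, lib)
    calibration.calibrate_fcd_cutoff(
        tracks, lib, min_windows=cfg.min_windows, seed=cfg.seed
    )
    logger.info("FCD error cutoff: %.4f", lib.fcd_cutoff)
    calls = error_calling.call_fcd_and_coverage_errors(tracks, assembly, lib)
    error_calling.score_bases(tracks, lib, fcd_fail_regions=calls)
    calls += error_calling.call_collapsed_repeats(tracks, lib)
    calls += error_calling.call_warnings(tracks, lib)
    return tracks, lib, calls


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage and write all artifacts under ``config.outdir``.

    Outputs: ``errors.gff``, ``score``/``fcd_error`` plot tracks (all tracks
    with ``write_all_tracks``), ``summary.tsv``, ``broken_assembly.fa``,
    ``break_log.tsv``, ``calibration.tsv`` and ``gc_curve.tsv``."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    sentinel = os.path.join(config.outdir, "INCOMPLETE")
    open(sentinel, "w").close()
    stage = "read-assembly"
    try:
        assembly = formats_io.read_assembly(config.assembly)
        stage = "evaluate"
        tracks, lib, calls = evaluate(
            assembly,
            config.alignments,
            config,
            perfect_alignments_path=config.perfect_alignments,
        )
        stage = "break"
        broken, break_log = assembly_breaking.break_assembly(assembly, calls)
        stage = "summarize"
        summary = assembly_breaking.summarize(assembly, broken, calls, tracks)
        stage = "write-output"
        formats_io.write_gff(calls, os.path.join(config.outdir, "errors.gff"))
        formats_io.write_tracks(
            tracks,
            os.path.join(config.outdir, "plots"),
            metrics=None if config.write_all_tracks else [],
            gzip=config.gzip_plots,
        )
        formats_io.write_summary(summary, os.path.join(config.outdir, "summary.tsv"))
        formats_io.write_assembly(
            broken, os.path.join(config.outdir, "broken_assembly.fa")
        )
        formats_io.write_break_log(
            break_log, os.path.join(config.outdir, "break_log.tsv")
        )
        formats_io.write_stats_report(
            lib.report_rows(), os.path.join(config.outdir, "calibration.tsv")
        )
        if lib.gc_curve is not None:
            mids = 0.5 * (lib.gc_curve.bin_edges[:-1] + lib.gc_curve.bin_edges[1:])
            formats_io.write_stats_report(
                [(f"{m:.3f}", f"{v:.4f}") for m, v in zip(mids, lib.gc_curve.values)],
                os.path.join(config.outdir, "gc_curve.tsv"),
            )
        for key, value in sorted(dataclasses.asdict(config).items()):
            logger.info("config %s = %r", key, value)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-tag with the failing stage
        raise PipelineError(stage, str(exc)) from exc
    os.remove(sentinel)
    return PipelineResult(assembly, tracks, lib, calls, broken, break_log, summary)
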