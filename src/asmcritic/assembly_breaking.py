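"""Corrected assembly and corrected contiguity statistics.

Scaffolds are broken wherever an error is called over a gap (every join a
scaffolding-error region spans is unsupported, so each contained gap becomes
a split point, with the gap bases dropped); contig-internal error regions are
replaced with Ns so a gap closer can reassemble them locally.  N50 is then
recomputed on the broken assembly, giving the corrected N50.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .formats_io import Assembly
from .error_calling import Category, RegionCall
from .pileup_stats import FCD_NOT_ANALYZED, PerBaseTracks

BreakLogEntry = Tuple[str, str, int, int]  # original name, part, orig interval


def n50(lengths: Sequence[int]) -> int:
    """Sequence length above which half the assembly is represented:
    the first length, descending, at which the cumulative sum reaches half
    the total."""
    if len(lengths) == 0:
        raise ValueError("n50 of an empty length list is undefined")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if arr[-1] <= 0:
        raise ValueError("sequence lengths must be positive")
    half2 = arr.sum()  # compare 2*cumsum >= total to stay in integers
    idx = int(np.searchsorted(2 * np.cumsum(arr), half2, side="left"))
    return int(arr[idx])


def _merge_intervals(intervals: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    out: List[Tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def break_assembly(
    assembly: Assembly, calls: Sequence[RegionCall]
) -> Tuple[Assembly, List[BreakLogEntry]]:
    """Break at scaffolding errors and N-mask contig errors.

    Error regions over a gap (FCD failure or missing fragment coverage) split
    the scaffold at every contained gap, dropping the gap bases; error
    regions without a gap are masked with Ns of equal length.  Zero-length
    pieces are discarded and parts are named ``<name>.1``, ``<name>.2`` ...
    left to right.  Returns the new assembly and a log of (original name,
    part name, original interval) for each piece.
    """
    split_gaps: Dict[str, List[Tuple[int, int]]] = {}
    mask_regions: Dict[str, List[Tuple[int, int]]] = {}
    for call in calls:
        if call.category not in (
            Category.FCD_ERROR_OVER_GAP,
            Category.ZERO_FRAGMENT_COVERAGE,
            Category.FCD_ERROR_CONTIG,
        ):
            continue
        if call.end > len(assembly.sequences.get(call.ref_name, "")):
            raise ValueError(f"call {call} outside assembly bounds")
        gaps = [
            (g0, g1)
            for g0, g1 in assembly.gaps.get(call.ref_name, [])
            if g0 < call.end and g1 > call.start
        ]
        if gaps and call.category in (
            Category.FCD_ERROR_OVER_GAP,
            Category.ZERO_FRAGMENT_COVERAGE,
        ):
            split_gaps.setdefault(call.ref_name, []).extend(gaps)
        else:
            mask_regions.setdefault(call.ref_name, []).append(
                (call.start, call.end)
            )

    sequences: Dict[str, str] = {}
    log: List[BreakLogEntry] = []
    for name, seq in assembly.sequences.items():
        masked = seq
        for s, e in _merge_intervals(mask_regions.get(name, [])):
            masked = masked[:s] + "N" * (e - s) + masked[e:]
        cut_points = _merge_intervals(split_gaps.get(name, []))
        if not cut_points:
            sequences[name] = masked
            log.append((name, name, 0, len(seq)))
            continue
        pieces: List[Tuple[int, int]] = []
        prev = 0
        for g0, g1 in cut_points:
            if g0 > prev:
                pieces.append((prev, g0))
            prev = g1
        if prev < len(seq):
            pieces.append((prev, len(seq)))
        part = 0
        for s, e in pieces:
            if e <= s:
                continue
            part += 1
            part_name = f"{name}.{part}"
            sequences[part_name] = masked[s:e]
            log.append((name, part_name, s, e))
    return Assembly.from_sequences(sequences), log


@dataclass
class AssemblySummary:
    """Per-reference and total error counts plus contiguity statistics."""

    per_ref: Dict[str, Dict[str, float]]
    category_names: List[str]
    n50: int
    corrected_n50: int
    error_free_fraction: float
    total_length: int
    gap_count: int
    total_gap_length: int
    totals: Dict[str, float] = field(default_factory=dict)

    def as_rows(self) -> List[List[object]]:
        header = (
            ["sequence", "length", "gaps", "gap_length"]
            + self.category_names
            + ["error_free_fraction"]
        )
        rows: List[List[object]] = [header]
        for ref, d in self.per_ref.items():
            rows.append(
                [ref, int(d["length"]), int(d["gaps"]), int(d["gap_length"])]
                + [int(d[c]) for c in self.category_names]
                + [round(d["error_free_fraction"], 6)]
            )
        rows.append(
            ["TOTAL", self.total_length, self.gap_count, self.total_gap_length]
            + [int(self.totals[c]) for c in self.category_names]
            + [round(self.error_free_fraction, 6)]
        )
        rows.append(["#n50", self.n50, "", ""] + [""] * len(self.category_names) + [""])
        rows.append(
            ["#corrected_n50", self.corrected_n50, "", ""]
            + [""] * len(self.category_names)
            + [""]
        )
        return rows


def summarize(
    assembly: Assembly,
    broken: Assembly,
    calls: Sequence[RegionCall],
    tracks: Optional[PerBaseTracks] = None,
) -> AssemblySummary:
    """Error counts per category and reference, N50 before/after breaking and
    the error-free fraction (score-1 bases over non-gap analyzable bases)."""
    category_names = [c.value for c in Category]
    per_ref: Dict[str, Dict[str, float]] = {}
    totals = {c: 0.0 for c in category_names}
    free_num = 0
    free_den = 0
    for ref, seq in assembly.sequences.items():
        d: Dict[str, float] = {c: 0.0 for c in category_names}
        d["length"] = len(seq)
        gaps = assembly.gaps.get(ref, [])
        d["gaps"] = len(gaps)
        d["gap_length"] = sum(e - s for s, e in gaps)
        if tracks is not None:
            score = tracks.get("score", ref)
            analyzable = tracks.get("fcd_status", ref) != FCD_NOT_ANALYZED
            nongap = np.ones(len(seq), dtype=bool)
            for g0, g1 in gaps:
                nongap[g0:g1] = False
            den = int((analyzable & nongap).sum())
            num = int((analyzable & nongap & (score == 1.0)).sum())
            d["error_free_fraction"] = num / den if den else 0.0
            free_num += num
            free_den += den
        else:
            d["error_free_fraction"] = 0.0
        per_ref[ref] = d
    for call in calls:
        per_ref[call.ref_name][call.category.value] += 1
        totals[call.category.value] += 1
    lengths = list(assembly.lengths().values())
    broken_lengths = list(broken.lengths().values())
    return AssemblySummary(
        per_ref=per_ref,
        category_names=category_names,
        n50=n50(lengths),
        corrected_n50=n50(broken_lengths) if broken_lengths else 0,
        error_free_fraction=free_num / free_den if free_den else 0.0,
        total_length=assembly.total_length,
        gap_count=assembly.gap_count,
        total_gap_length=assembly.total_gap_length,
        totals=totals,
    )
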