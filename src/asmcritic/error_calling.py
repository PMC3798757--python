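"""Convert per-base tracks into error/warning regions and the per-base score.

A region is reported for a metric when an interval no shorter than the
metric's minimum window has at least 80% of its bases outside the acceptable
range.  FCD failures and missing fragment coverage are errors (over a gap:
scaffolding error; otherwise: contig error); every other metric produces
warnings for manual inspection.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .formats_io import Assembly
from .pileup_stats import FCD_NOT_ANALYZED, FCD_OK, FCD_ZERO_FRAG, PerBaseTracks


class Severity(enum.Enum):
    ERROR = "Error"
    WARNING = "Warning"


class Category(enum.Enum):
    FCD_ERROR_OVER_GAP = "FCD_error_over_gap"
    FCD_ERROR_CONTIG = "FCD_error_contig"
    ZERO_FRAGMENT_COVERAGE = "zero_fragment_coverage"
    COLLAPSED_REPEAT = "collapsed_repeat"
    SOFT_CLIP_EXCESS = "soft_clip_excess"
    WRONG_ORIENTATION_EXCESS = "wrong_orientation_excess"
    ORPHAN_EXCESS = "orphan_excess"
    LOW_PERFECT_COVERAGE = "low_perfect_coverage"
    READ_DEPTH_OUTLIER = "read_depth_outlier"


ERROR_CATEGORIES = {
    Category.FCD_ERROR_OVER_GAP,
    Category.FCD_ERROR_CONTIG,
    Category.ZERO_FRAGMENT_COVERAGE,
}

_DESCRIPTIONS = {
    Category.FCD_ERROR_OVER_GAP: "FCD failure over gap (scaffolding error)",
    Category.FCD_ERROR_CONTIG: "FCD failure within contig",
    Category.ZERO_FRAGMENT_COVERAGE: "no fragment coverage",
    Category.COLLAPSED_REPEAT: "fragment coverage at least twice the GC-corrected expectation",
    Category.SOFT_CLIP_EXCESS: "excessive soft clipping",
    Category.WRONG_ORIENTATION_EXCESS: "excess of wrongly oriented reads",
    Category.ORPHAN_EXCESS: "excess of orphaned reads",
    Category.LOW_PERFECT_COVERAGE: "low perfect and unique read coverage",
    Category.READ_DEPTH_OUTLIER: "read depth outside the acceptable range",
}


@dataclass
class RegionCall:
    """An error or warning interval (0-based half-open) with its support."""

    ref_name: str
    start: int
    end: int
    category: Category
    severity: Severity
    statistic: Optional[float] = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.description:
            self.description = _DESCRIPTIONS.get(self.category, self.category.value)
        expected = (
            Severity.ERROR if self.category in ERROR_CATEGORIES else Severity.WARNING
        )
        if self.severity is not expected:
            raise ValueError(
                f"{self.category.value} must have severity {expected.name}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def call_metric_regions(
    fail_mask: Sequence[bool] | np.ndarray,
    min_window: int,
    fail_fraction: float = 0.8,
) -> List[Tuple[int, int]]:
    """Maximal regions where some window fails its acceptance test.

    An interval qualifies when it is at least ``min_window`` long and at
    least ``fail_fraction`` of its bases fail (inclusive).  Overlapping
    qualifying intervals are merged; each merged region is trimmed so both
    endpoints are failing bases.

    The implementation is an O(n log n) prefix-sum scan over every interval:
    with t[i] = D*fail[i] - N (fail_fraction = N/D in lowest terms) an
    interval [i, j) qualifies iff S[j] - S[i] >= 0, and for each right end j
    the union of its qualifying intervals is [first i with S[i] <= S[j], j).
    Integer arithmetic keeps the inclusive 80% boundary exact.
    """
    fail = np.asarray(fail_mask, dtype=bool)
    n = fail.size
    if n == 0 or min_window <= 0:
        return []
    frac = Fraction(fail_fraction).limit_denominator(10**6)
    num, den = frac.numerator, frac.denominator
    t = np.where(fail, den - num, -num).astype(np.int64)
    S = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(t, out=S[1:])
    M = np.minimum.accumulate(S)

    w = min_window
    js = np.arange(w, n + 1)
    qualifying = js[M[js - w] <= S[js]]
    if qualifying.size == 0:
        return []
    # first index i with S[i] <= S[j]: first dip of the prefix-min below S[j]
    i_min = np.searchsorted(-M, -S[qualifying], side="left")

    merged: List[List[int]] = []
    for a, j in zip(i_min.tolist(), qualifying.tolist()):
        if merged and a <= merged[-1][1]:
            while len(merged) > 1 and a <= merged[-2][1]:
                merged.pop()
            merged[-1][0] = min(merged[-1][0], a)
            merged[-1][1] = j
        else:
            merged.append([a, j])

    fail_idx = np.flatnonzero(fail)
    regions: List[Tuple[int, int]] = []
    for a, b in merged:
        k0 = np.searchsorted(fail_idx, a, side="left")
        k1 = np.searchsorted(fail_idx, b, side="left") - 1
        if k0 > k1:
            continue
        regions.append((int(fail_idx[k0]), int(fail_idx[k1]) + 1))
    return regions


def _regions_within_analyzable(
    fail: np.ndarray,
    analyzable: np.ndarray,
    min_window: int,
    fail_fraction: float,
) -> List[Tuple[int, int]]:
    """Run the region caller separately on each maximal analyzable run, so
    reported regions never overlap NOT_ANALYZED spans."""
    regions: List[Tuple[int, int]] = []
    n = fail.size
    bounds = np.flatnonzero(np.diff(np.concatenate(([0], analyzable.view(np.int8), [0]))))
    for s, e in zip(bounds[0::2], bounds[1::2]):
        for a, b in call_metric_regions(fail[s:e], min_window, fail_fraction):
            regions.append((int(s + a), int(s + b)))
    del n
    return regions


def _overlapping_gaps(
    gaps: List[Tuple[int, int]], start: int, end: int
) -> List[Tuple[int, int]]:
    return [(g0, g1) for g0, g1 in gaps if g0 < end and g1 > start]


def call_fcd_and_coverage_errors(
    tracks: PerBaseTracks,
    assembly: Assembly,
    lib: "LibraryStats",
    fcd_min_window: Optional[int] = None,
) -> List[RegionCall]:
    """ERROR regions: FCD failures (over a gap or within a contig) and runs
    of zero fragment coverage.

    A base fails the FCD test when its error exceeds the calibrated cutoff or
    it has no covering fragment at all; regions containing at least one gap
    base are scaffolding errors.  Zero-fragment runs of at least
    ``min_zero_window`` bases are reported separately (a short dropout at
    modest depth is sampling noise, not evidence of error).
    """
    if lib.fcd_cutoff is None:
        raise ValueError("lib.fcd_cutoff has not been calibrated")
    wlen = fcd_min_window or max(10, round(lib.mean_insert / 2))
    frac = float(lib.thresholds["fail_fraction"])
    min_zero = int(lib.thresholds["min_zero_window"])
    calls: List[RegionCall] = []
    for ref in tracks.lengths:
        err = tracks.get("fcd_error_std", ref)
        status = tracks.get("fcd_status", ref)
        analyzable = status != FCD_NOT_ANALYZED
        fail = ((status == FCD_OK) & (err > lib.fcd_cutoff)) | (
            status == FCD_ZERO_FRAG
        )
        gaps = assembly.gaps.get(ref, [])
        for a, b in _regions_within_analyzable(fail, analyzable, wlen, frac):
            over_gap = bool(_overlapping_gaps(gaps, a, b))
            category = (
                Category.FCD_ERROR_OVER_GAP if over_gap else Category.FCD_ERROR_CONTIG
            )
            peak = float(err[a:b].max()) if (status[a:b] == FCD_OK).any() else 0.0
            calls.append(
                RegionCall(ref, a, b, category, Severity.ERROR, statistic=peak)
            )
        # zero-fragment runs
        zero = (status == FCD_ZERO_FRAG).astype(np.int8)
        bounds = np.flatnonzero(np.diff(np.concatenate(([0], zero, [0]))))
        for s, e in zip(bounds[0::2], bounds[1::2]):
            if e - s >= min_zero:
                calls.append(
                    RegionCall(
                        ref,
                        int(s),
                        int(e),
                        Category.ZERO_FRAGMENT_COVERAGE,
                        Severity.ERROR,
                        statistic=float(e - s),
                    )
                )
    return calls


def call_collapsed_repeats(
    tracks: PerBaseTracks,
    lib: "LibraryStats",
    metric: str = "read_depth_ratio",
) -> List[RegionCall]:
    """WARNING regions where GC-corrected coverage is at least twice the
    expectation for 80% of at least 100 bp.

    Uses the read-depth ratio by default: across a collapsed tandem repeat
    read depth carries the full copy-number signal while fragment coverage
    loses the pairs that straddle the copy junction.
    """
    ratio_thr = float(lib.thresholds["repeat_ratio"])
    wlen = int(lib.thresholds["repeat_window"])
    frac = float(lib.thresholds["fail_fraction"])
    calls: List[RegionCall] = []
    for ref in tracks.lengths:
        ratio = tracks.get(metric, ref)
        analyzable = tracks.get("fcd_status", ref) != FCD_NOT_ANALYZED
        fail = ratio >= ratio_thr
        for a, b in _regions_within_analyzable(fail, analyzable, wlen, frac):
            calls.append(
                RegionCall(
                    ref,
                    a,
                    b,
                    Category.COLLAPSED_REPEAT,
                    Severity.WARNING,
                    statistic=float(ratio[a:b].mean()),
                )
            )
    return calls


def call_warnings(tracks: PerBaseTracks, lib: "LibraryStats") -> List[RegionCall]:
    """WARNING regions for the less serious per-base inconsistencies:
    orphaned reads, wrong orientation, soft clipping, low perfect coverage
    and read-depth outliers."""
    thr = lib.thresholds
    frac = float(thr["fail_fraction"])
    mean_depth = lib.mean_read_depth or 0.0
    calls: List[RegionCall] = []
    for ref in tracks.lengths:
        analyzable = tracks.get("fcd_status", ref) != FCD_NOT_ANALYZED
        depth = tracks.get("read_depth_fwd", ref) + tracks.get("read_depth_rev", ref)

        def report(fail, wlen, category, stat_track):
            for a, b in _regions_within_analyzable(fail, analyzable, wlen, frac):
                calls.append(
                    RegionCall(
                        ref,
                        a,
                        b,
                        category,
                        Severity.WARNING,
                        statistic=float(stat_track[a:b].mean()),
                    )
                )

        orphan = np.maximum(
            tracks.get("prop_orphan_fwd", ref), tracks.get("prop_orphan_rev", ref)
        )
        report(orphan > thr["max_prop"], 100, Category.ORPHAN_EXCESS, orphan)

        wrong = np.maximum(
            tracks.get("prop_wrong_orient_fwd", ref),
            tracks.get("prop_wrong_orient_rev", ref),
        )
        report(
            wrong > thr["max_prop"], 100, Category.WRONG_ORIENTATION_EXCESS, wrong
        )

        clip = tracks.get("clip_count", ref)
        report(
            clip > thr["clip_ratio"] * np.maximum(depth, 1.0),
            1,
            Category.SOFT_CLIP_EXCESS,
            clip,
        )

        perfect = tracks.get("perfect_unique_depth", ref)
        report(
            perfect < thr["min_perfect_depth"],
            100,
            Category.LOW_PERFECT_COVERAGE,
            perfect,
        )

        if mean_depth > 0:
            out_of_range = (depth < thr["depth_low"] * mean_depth) | (
                depth > thr["depth_high"] * mean_depth
            )
            report(out_of_range, 100, Category.READ_DEPTH_OUTLIER, depth)
    return calls


def score_bases(
    tracks: PerBaseTracks,
    lib: "LibraryStats",
    fcd_fail_regions: Optional[List[RegionCall]] = None,
) -> None:
    """Fill ``tracks.score``: 1 where the perfect-coverage and FCD tests both
    pass; otherwise the fraction of the eight-test battery that passes.

    Tests: T1 perfect+unique depth >= 5; T2 the FCD test (zero fragment
    coverage fails); T3 read depth within [0.25x, 4x] of the mean; T4 proper
    proportion >= 0.5 on at least one strand; T5/T6 orphan and
    wrong-orientation proportions <= 0.5 on both strands; T7 clip count <=
    0.5x read depth; T8 nonzero inner fragment coverage.  NOT_ANALYZED bases
    are emitted as 0 with the ``analyzable`` flag cleared.

    When ``fcd_fail_regions`` (the called FCD/zero-coverage ERROR regions)
    is given, T2 fails exactly inside those regions, keeping the score
    consistent with the reported calls; without it T2 falls back to the
    per-base comparison of the standardised FCD error against the cutoff.
    """
    if lib.fcd_cutoff is None:
        raise ValueError("lib.fcd_cutoff has not been calibrated")
    thr = lib.thresholds
    mean_depth = lib.mean_read_depth or 0.0
    for ref in tracks.lengths:
        status = tracks.get("fcd_status", ref)
        err = tracks.get("fcd_error_std", ref)
        depth = tracks.get("read_depth_fwd", ref) + tracks.get("read_depth_rev", ref)
        t1 = tracks.get("perfect_unique_depth", ref) >= thr["min_perfect_depth"]
        if fcd_fail_regions is None:
            t2 = (status == FCD_OK) & (err <= lib.fcd_cutoff)
        else:
            t2 = status == FCD_OK
            for call in fcd_fail_regions:
                if call.ref_name == ref and call.category in ERROR_CATEGORIES:
                    t2[call.start : call.end] = False
        t3 = (depth >= thr["depth_low"] * mean_depth) & (
            depth <= thr["depth_high"] * mean_depth
        )
        t4 = (tracks.get("prop_proper_fwd", ref) >= thr["min_prop_proper"]) | (
            tracks.get("prop_proper_rev", ref) >= thr["min_prop_proper"]
        )
        t5 = (tracks.get("prop_orphan_fwd", ref) <= thr["max_prop"]) & (
            tracks.get("prop_orphan_rev", ref) <= thr["max_prop"]
        )
        t6 = (tracks.get("prop_wrong_orient_fwd", ref) <= thr["max_prop"]) & (
            tracks.get("prop_wrong_orient_rev", ref) <= thr["max_prop"]
        )
        t7 = tracks.get("clip_count", ref) <= thr["clip_ratio"] * depth
        t8 = tracks.get("inner_frag_cov", ref) > 0
        passes = sum(t.astype(np.float64) for t in (t1, t2, t3, t4, t5, t6, t7, t8))
        score = np.where(t1 & t2, 1.0, passes / 8.0)
        score[status == FCD_NOT_ANALYZED] = 0.0
        tracks.metric("score")[ref][:] = score
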