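"""Library calibration: insert-size statistics, GC-bias curve and the
automatic FCD-error cutoff.

The cutoff rule follows the turning-point idea: sample windows across the
genome, compute for each window the FCD-error value at which it would be
called an error (the value exceeded by 80% of its bases), plot the proportion
of failing windows against the cutoff, and pick the first cutoff — scanning
from the largest — where the magnitudes of the normalised first and second
derivatives are both at least 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .formats_io import AlignmentRecord, Assembly
from .fragment_model import PairClass, classify_pair
from .fcd_engine import FragmentLengthDist, default_fcd_width
from .pileup_stats import FCD_OK, PerBaseTracks, iter_pairs, per_base_gc

logger = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """Raised when the input sample cannot support calibration."""


DEFAULT_THRESHOLDS: Dict[str, float] = {
    "min_perfect_depth": 5,  # perfect+unique reads for a locally error-free base
    "depth_low": 0.25,  # acceptable read depth, x mean
    "depth_high": 4.0,
    "max_prop": 0.5,  # orphan / wrong-orientation proportion limit per strand
    "min_prop_proper": 0.5,  # required proper proportion on >=1 strand
    "clip_ratio": 0.5,  # clip ends per read depth
    "repeat_ratio": 2.0,  # GC-corrected coverage ratio calling a collapsed repeat
    "repeat_window": 100,
    "fail_fraction": 0.8,  # bases outside range needed to report a region
    "min_zero_window": 10,  # zero-fragment run length reported as an error
    "deriv_threshold": 0.05,  # FCD cutoff derivative rule
}


@dataclass
class GCBiasCurve:
    """Expected fragment coverage per GC-content bin."""

    bin_edges: np.ndarray  # len nbins + 1, spanning [0, 1]
    values: np.ndarray  # len nbins, positive

    def expected(self, gc: np.ndarray | float) -> np.ndarray:
        idx = np.clip(
            np.digitize(np.asarray(gc, dtype=float), self.bin_edges) - 1,
            0,
            len(self.values) - 1,
        )
        return self.values[idx]

    @classmethod
    def constant(cls, value: float, nbins: int = 50) -> "GCBiasCurve":
        return cls(
            bin_edges=np.linspace(0.0, 1.0, nbins + 1),
            values=np.full(nbins, value),
        )


@dataclass
class LibraryStats:
    """Calibrated statistics of one paired-read library."""

    frag_len_dist: FragmentLengthDist
    mean_insert: float
    insert_range: Tuple[float, float]
    read_len: int
    min_mapq: int = 10
    mean_read_depth: Optional[float] = None
    mean_frag_cov: Optional[float] = None
    mean_outer_frag_cov: Optional[float] = None  # set by the FCD engine
    gc_curve: Optional[GCBiasCurve] = None
    gc_curve_depth: Optional[GCBiasCurve] = None  # expected read depth per GC
    fcd_cutoff: Optional[float] = None
    thresholds: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )
    _fcd_width: Optional[int] = field(default=None, repr=False)

    @property
    def fcd_width(self) -> int:
        if self._fcd_width is None:
            self._fcd_width = default_fcd_width(self.frag_len_dist)
        return self._fcd_width

    def report_rows(self) -> List[Tuple[str, object]]:
        rows: List[Tuple[str, object]] = [
            ("mean_insert", round(self.mean_insert, 3)),
            ("insert_range_low", self.insert_range[0]),
            ("insert_range_high", self.insert_range[1]),
            ("read_len", self.read_len),
            ("min_mapq", self.min_mapq),
            ("fcd_width", self.fcd_width),
        ]
        if self.mean_read_depth is not None:
            rows.append(("mean_read_depth", round(self.mean_read_depth, 3)))
        if self.mean_frag_cov is not None:
            rows.append(("mean_inner_frag_cov", round(self.mean_frag_cov, 3)))
        if self.fcd_cutoff is not None:
            rows.append(("fcd_cutoff", round(self.fcd_cutoff, 6)))
        for k, v in self.thresholds.items():
            rows.append((f"threshold.{k}", v))
        return rows


def estimate_library_stats(
    alignments_sample: Sequence[AlignmentRecord],
    assembly: Assembly,
    sample_fraction: float = 1.0,
    min_pairs: int = 10_000,
    min_mapq: int = 10,
    quantile_width: float = 0.99,
) -> LibraryStats:
    """Estimate the fragment-length distribution and insert range.

    Candidate pairs are inward-facing, same-reference pairs with outer
    distance below a generous ceiling (4x the median); the acceptable proper
    range is the central ``quantile_width`` mass of the empirical
    distribution.  Coverage means and the GC curve are filled in later, once
    the per-base tracks exist.
    """
    del assembly  # reserved for window-based subsampling of very deep input
    outer: List[int] = []
    read_lens: List[int] = []
    rng = np.random.default_rng(0)
    for r1, r2 in iter_pairs(iter(alignments_sample)):
        if r2 is None:
            continue
        if sample_fraction < 1.0 and rng.random() > sample_fraction:
            continue
        cls = classify_pair(r1, r2, (0, float("inf")))
        if cls not in (PairClass.PROPER, PairClass.WRONG_DISTANCE):
            continue
        outer.append(max(r1.ref_end, r2.ref_end) - min(r1.ref_start, r2.ref_start))
        read_lens.append(r1.query_length)
        read_lens.append(r2.query_length)
    if len(outer) < min_pairs:
        raise CalibrationError(
            f"only {len(outer)} candidate proper pairs found; at least "
            f"{min_pairs} are needed (map more reads or lower the floor)"
        )
    arr = np.asarray(outer, dtype=np.int64)
    ceiling = 4 * np.median(arr)
    arr = arr[arr <= ceiling]
    dist = FragmentLengthDist.from_lengths(arr)
    tail = (1.0 - quantile_width) / 2.0
    low = float(np.quantile(arr, tail))
    high = float(np.quantile(arr, 1.0 - tail))
    read_len = int(np.median(np.asarray(read_lens)))
    return LibraryStats(
        frag_len_dist=dist,
        mean_insert=float(arr.mean()),
        insert_range=(low, high),
        read_len=read_len,
        min_mapq=min_mapq,
    )


def update_coverage_means(
    lib: LibraryStats, tracks: PerBaseTracks, assembly: Assembly
) -> None:
    """Fill per-base coverage means over non-gap bases."""
    depth_sum = 0.0
    frag_sum = 0.0
    n = 0
    for ref, length in tracks.lengths.items():
        nongap = np.ones(length, dtype=bool)
        for g0, g1 in assembly.gaps.get(ref, []):
            nongap[g0:g1] = False
        depth = tracks.get("read_depth_fwd", ref) + tracks.get("read_depth_rev", ref)
        depth_sum += depth[nongap].sum()
        frag_sum += tracks.get("inner_frag_cov", ref)[nongap].sum()
        n += int(nongap.sum())
    lib.mean_read_depth = depth_sum / max(n, 1)
    lib.mean_frag_cov = frag_sum / max(n, 1)


def fit_gc_bias(
    tracks: PerBaseTracks,
    assembly: Assembly,
    gc_window: int = 100,
    nbins: int = 50,
    min_windows_per_bin: int = 20,
    floor_fraction: float = 0.05,
    coverage_metric: str = "inner_frag_cov",
    lowess_frac: float = 0.3,
) -> GCBiasCurve:
    """LOWESS fit of fragment coverage against window GC content.

    Non-overlapping ``gc_window``-base windows that contain no gap base give a
    (GC fraction, mean coverage) scatter; the LOWESS line through it,
    averaged per GC bin, is the expected coverage.  Bins with fewer than
    ``min_windows_per_bin`` windows inherit the nearest populated bin and the
    whole curve is floored at ``floor_fraction`` of the global mean.
    """
    gc_list: List[np.ndarray] = []
    cov_list: List[np.ndarray] = []
    for ref, length in tracks.lengths.items():
        nwin = length // gc_window
        if nwin == 0:
            continue
        if coverage_metric == "read_depth":
            track = tracks.get("read_depth_fwd", ref) + tracks.get(
                "read_depth_rev", ref
            )
        else:
            track = tracks.get(coverage_metric, ref)
        cov = track[: nwin * gc_window].reshape(nwin, gc_window)
        seq = np.frombuffer(
            assembly.sequences[ref][: nwin * gc_window].encode(), dtype=np.uint8
        ).reshape(nwin, gc_window)
        has_gap = (seq == ord("N")).any(axis=1)
        gc = ((seq == ord("G")) | (seq == ord("C"))).mean(axis=1)
        gc_list.append(gc[~has_gap])
        cov_list.append(cov.mean(axis=1)[~has_gap])
    gc_all = np.concatenate(gc_list) if gc_list else np.empty(0)
    cov_all = np.concatenate(cov_list) if cov_list else np.empty(0)
    if gc_all.size == 0:
        raise CalibrationError("no gap-free windows available for GC fitting")
    global_mean = float(cov_all.mean())
    edges = np.linspace(0.0, 1.0, nbins + 1)
    if np.unique(gc_all).size < 3:
        return GCBiasCurve(bin_edges=edges, values=np.full(nbins, global_mean))
    fitted = lowess(
        cov_all, gc_all, frac=lowess_frac, return_sorted=False, is_sorted=False
    )
    idx = np.clip(np.digitize(gc_all, edges) - 1, 0, nbins - 1)
    counts = np.bincount(idx, minlength=nbins)
    sums = np.bincount(idx, weights=fitted, minlength=nbins)
    values = np.full(nbins, np.nan)
    populated = counts >= min_windows_per_bin
    if not populated.any():
        populated = counts > 0
    values[populated] = sums[populated] / counts[populated]
    # thin bins inherit the nearest populated bin
    pop_idx = np.flatnonzero(populated)
    for i in np.flatnonzero(~populated):
        values[i] = values[pop_idx[np.argmin(np.abs(pop_idx - i))]]
    floor = floor_fraction * global_mean
    return GCBiasCurve(bin_edges=edges, values=np.maximum(values, floor))


# ---------------------------------------------------------------------------
# FCD cutoff
# ---------------------------------------------------------------------------


def window_fail_cutoff(values: Sequence[float]) -> float:
    """The FCD-error value at which a window would be called an error.

    Returns the largest c such that at least 80% of the window's values are
    >= c — the empirical 20th percentile with lower interpolation, so a
    constant window yields its constant.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("window is empty")
    return float(np.percentile(arr, 20, method="lower"))


def sample_window_cutoffs(
    tracks: PerBaseTracks,
    lib: LibraryStats,
    window_len: Optional[int] = None,
    step: Optional[int] = None,
    max_windows: int = 100_000,
    seed: int = 0,
    metric: str = "fcd_error_std",
) -> np.ndarray:
    """Window fail-cutoffs sampled across the genome (50% overlapping windows
    of half the mean insert by default; uniform subsample beyond the cap).

    Windows whose bases are all sentinels are skipped; sentinel bases inside
    a window are excluded from its percentile.
    """
    wlen = window_len or max(10, round(lib.mean_insert / 2))
    stp = step or max(1, wlen // 2)
    cutoffs: List[float] = []
    for ref in tracks.lengths:
        err = tracks.get(metric, ref)
        ok = tracks.get("fcd_status", ref) == FCD_OK
        n = len(err)
        for start in range(0, max(n - wlen + 1, 0), stp):
            window_ok = ok[start : start + wlen]
            if not window_ok.any():
                continue
            cutoffs.append(window_fail_cutoff(err[start : start + wlen][window_ok]))
    arr = np.asarray(cutoffs)
    if arr.size > max_windows:
        rng = np.random.default_rng(seed)
        arr = arr[rng.choice(arr.size, size=max_windows, replace=False)]
    return arr


def choose_fcd_cutoff(
    window_cutoffs: Sequence[float],
    grid_size: int = 100,
    deriv_threshold: float = 0.05,
    min_windows: int = 1_000,
    grid_quantile: float = 0.999,
) -> float:
    """Automatic FCD-error cutoff by the derivative rule.

    Builds P(t) — the proportion of windows whose fail-cutoff is at least t —
    on an even grid from 0 to the ``grid_quantile`` of the window cutoffs,
    takes central finite-difference first and second derivatives, normalises
    each to maximum magnitude 1, and returns the first grid point, scanning
    from the largest t, where both normalised magnitudes are >= the
    threshold.  Falls back to the 99th percentile of window cutoffs when the
    condition is never met.
    """
    arr = np.sort(np.asarray(window_cutoffs, dtype=float))
    if arr.size < min_windows:
        raise CalibrationError(
            f"only {arr.size} sampled windows; at least {min_windows} needed"
        )
    upper = float(np.percentile(arr, 100 * grid_quantile))
    if upper <= 0:
        logger.warning("all window cutoffs are ~0; falling back to percentile rule")
        return float(np.percentile(arr, 99))
    t = np.linspace(0.0, upper, grid_size)
    p = 1.0 - np.searchsorted(arr, t, side="left") / arr.size
    d1 = np.gradient(p, t)
    d2 = np.gradient(d1, t)
    # cancellation noise floor: the smallest derivative a genuine
    # one-window step of P can produce is (1/n)/(2h); anything far below
    # that is floating-point residue, not signal
    h = t[1] - t[0]
    for d, floor in ((d1, 1.0 / arr.size / (2 * h)), (d2, 1.0 / arr.size / h**2)):
        d[np.abs(d) < 1e-3 * floor] = 0.0
        m = np.abs(d).max()
        if m > 0:
            d /= m
    # tiny slack so exact-ratio ties at the threshold are inclusive despite
    # floating-point rounding
    eps = 1e-9 * deriv_threshold
    hits = (np.abs(d1) >= deriv_threshold - eps) & (
        np.abs(d2) >= deriv_threshold - eps
    )
    idx = np.flatnonzero(hits)
    if idx.size == 0:
        logger.warning(
            "derivative rule never satisfied; falling back to the 99th "
            "percentile of window cutoffs"
        )
        return float(np.percentile(arr, 99))
    return float(t[idx[-1]])


def null_window_cutoff_threshold(
    lib: LibraryStats,
    n_genome_windows: int,
    alpha: float = 0.1,
    mc_windows: int = 6_000,
    strip_len: int = 60_000,
    seed: int = 0,
    window_len: Optional[int] = None,
    step: Optional[int] = None,
) -> float:
    """Null FCD-error level that pure sampling noise will not reach.

    After calibration the no-error model is fully specified: fragments fall
    uniformly at the observed rate with the fitted length distribution.
    This simulates that null on gap-free strips, computes the same
    standardised window fail-cutoffs the genome scan uses, and extrapolates
    their exponential upper tail to the survival probability
    ``alpha / n_genome_windows`` — the level a genome's worth of windows
    exceeds with probability about ``alpha`` under the null.  Unlike any
    quantile of the real genome's window cutoffs, the Monte-Carlo null is
    uncontaminated by true errors.
    """
    from .fcd_engine import _fast_fcd_error, ideal_fcd  # local: avoid cycle

    dist = lib.frag_len_dist
    W = lib.fcd_width
    mean_cov = lib.mean_outer_frag_cov
    if mean_cov is None or mean_cov <= 0:
        raise CalibrationError("mean outer fragment coverage is not available")
    rate = mean_cov / dist.mean  # fragments starting per base
    wlen = window_len or max(10, round(lib.mean_insert / 2))
    stp = step or max(1, wlen // 2)
    margin = W + dist.max_length
    ideal_vals = ideal_fcd(dist, W).values[W:]
    rng = np.random.default_rng(seed)
    cutoffs: List[float] = []
    n_total = strip_len + 2 * margin
    while len(cutoffs) < mc_windows:
        n_frag = rng.poisson(rate * (n_total - dist.max_length))
        starts = np.sort(rng.integers(0, n_total - dist.max_length, size=n_frag))
        lengths = rng.choice(dist.lengths, size=n_frag, p=dist.weights)
        ends = starts + lengths
        err, cov = _fast_fcd_error(
            starts, ends, n_total, ideal_vals, lib.mean_insert, W
        )
        std = err * np.sqrt(cov / mean_cov)
        core = slice(margin, n_total - margin)
        std_core = std[core]
        ok = cov[core] > 0
        for s in range(0, len(std_core) - wlen + 1, stp):
            w_ok = ok[s : s + wlen]
            if w_ok.any():
                cutoffs.append(window_fail_cutoff(std_core[s : s + wlen][w_ok]))
    arr = np.asarray(cutoffs)
    u = float(np.percentile(arr, 90))
    excess = arr[arr > u] - u
    if excess.size == 0:
        return u
    m = float(excess.mean())
    p_u = excess.size / arr.size
    target = alpha / max(n_genome_windows, 1)
    return u + m * max(0.0, math.log(p_u / target))


def calibrate_fcd_cutoff(
    tracks: PerBaseTracks,
    lib: LibraryStats,
    grid_size: int = 100,
    min_windows: int = 1_000,
    seed: int = 0,
) -> float:
    """Sample windows, choose the cutoff and store it on ``lib``.

    The operational cutoff is the derivative-rule value floored at the
    Monte-Carlo null threshold: at moderate fragment depth the turning
    point of the window-failure curve sits inside the upper tail of pure
    sampling noise, and a cutoff below that tail would report noise as
    errors.
    """
    cutoffs = sample_window_cutoffs(tracks, lib, seed=seed)
    chosen = choose_fcd_cutoff(
        cutoffs,
        grid_size=grid_size,
        deriv_threshold=float(lib.thresholds["deriv_threshold"]),
        min_windows=min_windows,
    )
    floor = null_window_cutoff_threshold(lib, len(cutoffs), seed=seed)
    lib.fcd_cutoff = max(chosen, floor)
    return lib.fcd_cutoff
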