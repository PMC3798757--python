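"""Fragment coverage distribution (FCD) curves and the per-base FCD error.

At a focal base, the observed FCD is the fraction of base-covering fragments
that also cover each nearby offset; the ideal FCD is the same quantity under
uniform fragment placement with the calibrated fragment-length distribution.
The FCD error is the L1 area between the two curves, normalised by the mean
insert size.  Because no read can map onto an N-gap, the ideal curve is
corrected near gaps by enumerating only the fragment placements whose two
terminal read footprints avoid every gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .formats_io import Assembly
from .fragment_model import FragmentInterval
from .pileup_stats import FCD_NOT_ANALYZED, FCD_OK, FCD_ZERO_FRAG, PerBaseTracks

Interval = Tuple[int, int]


class FCDDegenerateError(ValueError):
    """No admissible fragment placement covers the focal base."""


@dataclass
class FragmentLengthDist:
    """Empirical fragment-length distribution as a weighted histogram."""

    lengths: np.ndarray  # distinct lengths, ascending
    weights: np.ndarray  # probabilities, sum 1
    _placements: Optional[Tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default=None, repr=False, compare=False
    )

    @classmethod
    def from_lengths(cls, samples: Sequence[int]) -> "FragmentLengthDist":
        arr = np.asarray(samples, dtype=np.int64)
        if arr.size == 0 or arr.min() < 1:
            raise ValueError("fragment lengths must be a nonempty list of >=1")
        lengths, counts = np.unique(arr, return_counts=True)
        return cls(lengths=lengths, weights=counts / counts.sum())

    @property
    def mean(self) -> float:
        return float(np.dot(self.lengths, self.weights))

    @property
    def max_length(self) -> int:
        return int(self.lengths[-1])

    def quantile(self, q: float) -> float:
        cdf = np.cumsum(self.weights)
        idx = int(np.searchsorted(cdf, q, side="left"))
        return float(self.lengths[min(idx, len(self.lengths) - 1)])

    def placements(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All (length, start-offset, weight) fragment placements covering the
        focal base, start offsets in [-(L-1), 0].  Cached."""
        if self._placements is None:
            L_arr: List[np.ndarray] = []
            s_arr: List[np.ndarray] = []
            w_arr: List[np.ndarray] = []
            for L, w in zip(self.lengths, self.weights):
                L = int(L)
                s = np.arange(-(L - 1), 1, dtype=np.int64)
                L_arr.append(np.full(L, L, dtype=np.int64))
                s_arr.append(s)
                w_arr.append(np.full(L, w, dtype=np.float64))
            self._placements = (
                np.concatenate(L_arr),
                np.concatenate(s_arr),
                np.concatenate(w_arr),
            )
        return self._placements


@dataclass
class FCDCurve:
    """Values over integer offsets [-W, W] around the focal base."""

    offsets: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.offsets) != len(self.values):
            raise ValueError("offsets and values must have equal length")

    @property
    def half_width(self) -> int:
        return int(self.offsets[-1])


def ideal_fcd(frag_len_dist: FragmentLengthDist, W: int) -> FCDCurve:
    """Ideal FCD for uniform placement of the given length mixture.

    For a fixed length L the value at offset x is max(0, L - |x|) / L; for a
    mixture the expectation is weighted by length, since longer fragments are
    proportionally more likely to cover the focal base.
    """
    if W <= 0:
        raise ValueError("curve half-width W must be positive")
    offsets = np.arange(-W, W + 1)
    L = frag_len_dist.lengths[:, None].astype(np.float64)
    w = frag_len_dist.weights[:, None]
    num = (w * np.maximum(0.0, L - np.abs(offsets)[None, :])).sum(axis=0)
    den = float((frag_len_dist.weights * frag_len_dist.lengths).sum())
    return FCDCurve(offsets=offsets, values=num / den)


def _corrected_values(
    frag_len_dist: FragmentLengthDist,
    W: int,
    gaps: Sequence[Interval],
    read_len: int,
) -> np.ndarray:
    """Enumerate admissible placements: neither terminal read footprint of the
    fragment may overlap any gap (intervals in offset coordinates)."""
    L, s, w = frag_len_dist.placements()
    ok = np.ones(len(L), dtype=bool)
    for g0, g1 in gaps:
        left = (s < g1) & (s + read_len > g0)
        right = (s + L - read_len < g1) & (s + L > g0)
        ok &= ~(left | right)
    total = w[ok].sum()
    if total <= 0:
        raise FCDDegenerateError("no admissible placement covers the focal base")
    lo = np.maximum(s[ok], -W) + W
    hi = np.minimum(s[ok] + L[ok], W + 1) + W
    diff = np.zeros(2 * W + 2)
    np.add.at(diff, lo, w[ok])
    np.add.at(diff, hi, -w[ok])
    return np.cumsum(diff[:-1]) / total


def gap_corrected_ideal(
    frag_len_dist: FragmentLengthDist,
    W: int,
    gaps_near_focal: Sequence[Interval],
    read_len: int,
) -> FCDCurve:
    """Ideal FCD corrected for gaps near the focal base.

    ``gaps_near_focal`` are half-open intervals in offset coordinates
    (relative to the focal base, which must not itself lie in a gap).  With
    no gaps the result equals :func:`ideal_fcd`.
    """
    if W <= 0:
        raise ValueError("curve half-width W must be positive")
    for g0, g1 in gaps_near_focal:
        if g0 <= 0 < g1:
            raise ValueError("focal base lies inside a gap")
    offsets = np.arange(-W, W + 1)
    values = _corrected_values(frag_len_dist, W, gaps_near_focal, read_len)
    return FCDCurve(offsets=offsets, values=values)


def observed_fcd(
    fragments_covering_b: Sequence[FragmentInterval] | Tuple[np.ndarray, np.ndarray],
    b: int,
    W: int,
) -> FCDCurve:
    """Observed FCD at base ``b`` from the fragments that cover it.

    Accepts either FragmentInterval objects or a (starts, ends) array pair.
    Raises ``ValueError`` on an empty list (zero fragment coverage is a
    caller-level sentinel, not a curve).
    """
    if isinstance(fragments_covering_b, tuple):
        starts, ends = fragments_covering_b
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
    else:
        starts = np.array([f.start for f in fragments_covering_b], dtype=np.int64)
        ends = np.array([f.end for f in fragments_covering_b], dtype=np.int64)
    if starts.size == 0:
        raise ValueError("no fragments cover the focal base")
    if np.any((starts > b) | (ends <= b)):
        raise ValueError("every fragment must cover the focal base")
    lo = np.maximum(starts - b, -W) + W
    hi = np.minimum(ends - b, W + 1) + W
    diff = np.zeros(2 * W + 2)
    np.add.at(diff, lo, 1.0)
    np.add.at(diff, hi, -1.0)
    return FCDCurve(
        offsets=np.arange(-W, W + 1), values=np.cumsum(diff[:-1]) / starts.size
    )


def fcd_error_at_base(
    observed: FCDCurve, ideal: FCDCurve, mean_insert: float
) -> float:
    """L1 area between observed and ideal curves over the mean insert size.

    Depth normalisation is inherent in the observed curve's division by its
    fragment count; dividing by the mean insert makes values comparable
    between libraries.
    """
    if mean_insert <= 0:
        raise ValueError("mean_insert must be positive")
    if len(observed.offsets) != len(ideal.offsets) or np.any(
        observed.offsets != ideal.offsets
    ):
        raise ValueError("curves must share the same offset grid")
    return float(np.abs(observed.values - ideal.values).sum() / mean_insert)


# ---------------------------------------------------------------------------
# Whole-genome FCD error track
# ---------------------------------------------------------------------------


def _fast_fcd_error(
    starts: np.ndarray,
    ends: np.ndarray,
    n: int,
    ideal_vals: np.ndarray,
    mean_insert: float,
    W: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised per-base FCD error ignoring gaps, plus fragment coverage.

    For offset x > 0 the count of fragments covering both b and b+x equals
    the coverage at b of the fragments truncated by x on the right, and the
    negative-offset counts are the same array shifted; this turns the scan
    into one coverage pass per offset.
    """
    cov_diff = np.bincount(starts, minlength=n + 1).astype(np.float64) - np.bincount(
        ends, minlength=n + 1
    ).astype(np.float64)
    cov = np.cumsum(cov_diff[:n])
    err = np.zeros(n)
    covered = cov > 0
    safe_cov = np.where(covered, cov, 1.0)
    lengths = ends - starts
    for x in range(1, W + 1):
        sel = lengths > x
        if not sel.any():
            # no fragment reaches this offset: both sides contribute ideal
            err[covered] += 2.0 * ideal_vals[x] * (W + 1 - x)
            break
        cx_diff = np.bincount(starts[sel], minlength=n + 1).astype(
            np.float64
        ) - np.bincount(ends[sel] - x, minlength=n + 1).astype(np.float64)
        cx = np.cumsum(cx_diff[:n])
        err += np.abs(cx / safe_cov - ideal_vals[x])
        shifted = np.empty(n)
        shifted[:x] = 0.0
        shifted[x:] = cx[:-x]
        err += np.abs(shifted / safe_cov - ideal_vals[x])
    err[~covered] = 0.0
    return err / mean_insert, cov


def _slow_fcd_error(
    b: int,
    starts: np.ndarray,
    ends: np.ndarray,
    dist: FragmentLengthDist,
    W: int,
    gaps: Sequence[Interval],
    read_len: int,
    mean_insert: float,
) -> Optional[float]:
    """Single-base FCD error with gap-corrected ideal; None if degenerate."""
    lo = np.searchsorted(starts, b - dist.max_length - 1, side="left")
    hi = np.searchsorted(starts, b, side="right")
    sub_s = starts[lo:hi]
    sub_e = ends[lo:hi]
    keep = sub_e > b
    if not keep.any():
        return None
    obs = observed_fcd((sub_s[keep], sub_e[keep]), b, W)
    rel_gaps = [(g0 - b, g1 - b) for g0, g1 in gaps]
    try:
        ideal_vals = _corrected_values(dist, W, rel_gaps, read_len)
    except FCDDegenerateError:
        return None
    return float(np.abs(obs.values - ideal_vals).sum() / mean_insert)


def fcd_error_track(
    assembly: Assembly,
    tracks: PerBaseTracks,
    lib: "LibraryStats",
    proper_fragments: Optional[Dict[str, Tuple[np.ndarray, np.ndarray]]] = None,
) -> None:
    """Fill ``tracks.fcd_error`` and ``tracks.fcd_status`` for every reference.

    Per base: bases inside a gap longer than half the mean insert (it is
    impossible to tell whether such scaffolding is correct), in such a gap's
    read-length shadow, or within one curve half-width of a sequence end are
    NOT_ANALYZED; bases with zero fragment coverage are ZERO_FRAG; otherwise
    the error uses the gap-corrected ideal whenever a gap lies within one
    mean insert of the base and the plain ideal elsewhere.

    Also fills ``tracks.fcd_error_std``, the depth-standardised error
    ``err * sqrt(cov / mean_cov)``: the raw L1 error of a clean base shrinks
    as 1/sqrt(fragment depth), so thresholds on the raw value conflate
    coverage fluctuations with structural signal; the standardised value has
    a depth-independent null level and is the quantity calibrated against
    and thresholded downstream.
    """
    dist: FragmentLengthDist = lib.frag_len_dist
    mean_insert = lib.mean_insert
    read_len = lib.read_len
    W = lib.fcd_width
    big_gap = mean_insert / 2.0
    ideal_vals = ideal_fcd(dist, W).values[W:]  # symmetric: offsets 0..W

    fragments = proper_fragments if proper_fragments is not None else tracks.fragments
    cov_by_ref: Dict[str, np.ndarray] = {}
    for ref, n in tracks.lengths.items():
        starts, ends = fragments.get(ref, (np.empty(0, np.int64), np.empty(0, np.int64)))
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        status = tracks.metric("fcd_status")[ref]
        err_out = tracks.metric("fcd_error")[ref]
        status[:] = FCD_OK
        if starts.size:
            err, cov = _fast_fcd_error(starts, ends, n, ideal_vals, mean_insert, W)
        else:
            err = np.zeros(n)
            cov = np.zeros(n)
        gaps = assembly.gaps.get(ref, [])
        # slow path: gap-corrected ideal near every gap
        near = np.zeros(n, dtype=bool)
        for g0, g1 in gaps:
            near[max(0, g0 - int(mean_insert)) : min(n, g1 + int(mean_insert))] = True
        for b in np.flatnonzero(near & (cov > 0)):
            b = int(b)
            reach = [
                (g0, g1)
                for g0, g1 in gaps
                if g0 - b <= W + dist.max_length and b - g1 <= W + dist.max_length
            ]
            v = _slow_fcd_error(
                b, starts, ends, dist, W, reach, read_len, mean_insert
            )
            if v is not None:
                err[b] = v
        status[cov == 0] = FCD_ZERO_FRAG
        # undecidable spans
        for g0, g1 in gaps:
            if g1 - g0 > big_gap:
                status[max(0, g0 - read_len) : min(n, g1 + read_len)] = (
                    FCD_NOT_ANALYZED
                )
        edge = min(W, n)
        status[:edge] = FCD_NOT_ANALYZED
        status[n - edge :] = FCD_NOT_ANALYZED
        err[status != FCD_OK] = 0.0
        err_out[:] = err
        cov_by_ref[ref] = cov
        tracks.metric("analyzable")[ref][:] = (status != FCD_NOT_ANALYZED).astype(
            np.int8
        )

    # depth-standardised error, scaled against the genome-wide mean fragment
    # coverage of analyzable bases
    total = 0.0
    count = 0
    for ref in tracks.lengths:
        ok = tracks.metric("fcd_status")[ref] == FCD_OK
        total += cov_by_ref[ref][ok].sum()
        count += int(ok.sum())
    mean_cov = total / count if count else 1.0
    lib.mean_outer_frag_cov = mean_cov
    for ref in tracks.lengths:
        std = tracks.metric("fcd_error")[ref] * np.sqrt(
            cov_by_ref[ref] / max(mean_cov, 1e-9)
        )
        std[tracks.metric("fcd_status")[ref] != FCD_OK] = 0.0
        tracks.metric("fcd_error_std")[ref][:] = std


def default_fcd_width(dist: FragmentLengthDist) -> int:
    """Curve half-width: ceiling of the 99th percentile fragment length."""
    return int(math.ceil(dist.quantile(0.99)))
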