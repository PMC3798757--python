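"""Single pass over sorted alignments producing every per-base metric track.

Tracks (all arrays of length = sequence length, one set per reference):

* ``read_depth_fwd`` / ``read_depth_rev`` — reads covering each base per strand
  (CIGAR D consumes reference, I does not);
* ``prop_{proper,orphan,wrong_orient,wrong_dist}_{fwd,rev}`` — per-base,
  per-strand proportions of read coverage by pair class;
* ``clip_count`` — alignment ends clipped at each base;
* ``frag_cov`` / ``inner_frag_cov`` — outer and inner fragment coverage from
  properly paired reads;
* ``perfect_unique_depth`` — depth of perfectly and uniquely mapped reads;
* ``fcd_error`` / ``fcd_status`` — filled by the FCD engine;
* ``frag_cov_ratio`` — GC-corrected relative inner fragment coverage;
* ``score`` / ``analyzable`` — filled by the scorer.

Duplicate and secondary records are excluded from every track.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np

from .formats_io import AlignmentRecord, Assembly
from .fragment_model import (
    FragmentInterval,
    PairClass,
    classify_pair,
    fragment_interval,
    is_perfect_unique,
)

logger = logging.getLogger(__name__)

#: fcd_status codes
FCD_OK = 0
FCD_ZERO_FRAG = 1
FCD_NOT_ANALYZED = 2

_PROP_METRICS = {
    PairClass.PROPER: "prop_proper",
    PairClass.ORPHAN: "prop_orphan",
    PairClass.WRONG_ORIENTATION: "prop_wrong_orient",
    PairClass.WRONG_DISTANCE: "prop_wrong_dist",
}

_DEPTH_METRICS = [
    "read_depth_fwd",
    "read_depth_rev",
    "prop_proper_fwd",
    "prop_proper_rev",
    "prop_orphan_fwd",
    "prop_orphan_rev",
    "prop_wrong_orient_fwd",
    "prop_wrong_orient_rev",
    "prop_wrong_dist_fwd",
    "prop_wrong_dist_rev",
    "clip_count",
    "frag_cov",
    "inner_frag_cov",
    "perfect_unique_depth",
]


class PerBaseTracks:
    """Container of per-reference metric arrays plus the proper fragments."""

    def __init__(self, assembly: Assembly):
        self.lengths = assembly.lengths()
        self._data: Dict[str, Dict[str, np.ndarray]] = {}
        for metric in _DEPTH_METRICS + [
            "fcd_error",
            "fcd_error_std",
            "frag_cov_ratio",
            "read_depth_ratio",
            "score",
        ]:
            self._data[metric] = {
                ref: np.zeros(n, dtype=np.float64) for ref, n in self.lengths.items()
            }
        self._data["fcd_status"] = {
            ref: np.zeros(n, dtype=np.int8) for ref, n in self.lengths.items()
        }
        self._data["analyzable"] = {
            ref: np.ones(n, dtype=np.int8) for ref, n in self.lengths.items()
        }
        #: proper-pair outer fragments per reference, as (starts, ends) arrays
        self.fragments: Dict[str, Tuple[np.ndarray, np.ndarray]] = {
            ref: (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
            for ref in self.lengths
        }
        #: matching inner spans, same order as ``fragments``
        self.inner_fragments: Dict[str, Tuple[np.ndarray, np.ndarray]] = {
            ref: (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
            for ref in self.lengths
        }
        self.total_aligned_bases: float = 0.0

    def metric_names(self) -> List[str]:
        return list(self._data)

    def metric(self, name: str) -> Dict[str, np.ndarray]:
        return self._data[name]

    def get(self, name: str, ref: str) -> np.ndarray:
        return self._data[name][ref]

    def __getattr__(self, name: str):
        data = self.__dict__.get("_data")
        if data is not None and name in data:
            return data[name]
        raise AttributeError(name)


def iter_pairs(
    records: Iterable[AlignmentRecord],
) -> Iterator[Tuple[AlignmentRecord, Optional[AlignmentRecord]]]:
    """Group a record stream into (record, mate-or-None) pairs by query name.

    Mapped paired records whose mate is mapped to the same reference are held
    until the mate arrives; everything else is yielded immediately with mate
    ``None``.  Leftovers whose mate never arrived are yielded alone at the
    end.
    """
    pending: Dict[str, AlignmentRecord] = {}
    for r in records:
        if (
            r.is_paired
            and r.is_mapped
            and r.mate_mapped
            and r.mate_ref_name == r.ref_name
            and not r.is_secondary
        ):
            mate = pending.pop(r.query_name, None)
            if mate is None:
                pending[r.query_name] = r
            else:
                yield mate, r
        else:
            yield r, None
    for r in pending.values():
        yield r, None


def _add_span(diff: np.ndarray, start: int, end: int, value: float = 1.0) -> None:
    diff[start] += value
    diff[end] -= value


def accumulate_tracks(
    assembly: Assembly,
    alignments: Iterable[AlignmentRecord],
    lib: "LibraryStats",
    perfect_alignments: Optional[Iterable[AlignmentRecord]] = None,
) -> PerBaseTracks:
    """Fill every alignment-derived track in one pass.

    ``lib`` supplies the acceptable proper-pair insert range and the
    mapq/read-length parameters of the perfect+unique rule.  When
    ``perfect_alignments`` (a second, short-insert library) is given it is
    the sole source of ``perfect_unique_depth``; otherwise the main
    alignments feed it.
    """
    tracks = PerBaseTracks(assembly)
    nref = tracks.lengths
    diffs: Dict[str, Dict[str, np.ndarray]] = {
        m: {ref: np.zeros(n + 1) for ref, n in nref.items()}
        for m in _DEPTH_METRICS
        if m != "clip_count"
    }
    clip = {ref: np.zeros(n) for ref, n in nref.items()}
    frag_lists: Dict[str, List[Tuple[int, int, int, int]]] = {ref: [] for ref in nref}
    insert_range = lib.insert_range
    rejected = 0
    perfect_from_main = perfect_alignments is None

    def accept(r: AlignmentRecord) -> bool:
        nonlocal rejected
        if not r.is_mapped or r.is_secondary or r.is_duplicate:
            return False
        if r.ref_name not in nref or r.ref_end > nref[r.ref_name]:
            rejected += 1
            return False
        return True

    def add_read(r: AlignmentRecord) -> None:
        strand = "fwd" if r.strand == "+" else "rev"
        _add_span(diffs[f"read_depth_{strand}"][r.ref_name], r.ref_start, r.ref_end)
        tracks.total_aligned_bases += r.ref_end - r.ref_start
        if r.left_soft_clip:
            clip[r.ref_name][r.ref_start] += 1
        if r.right_soft_clip:
            clip[r.ref_name][r.ref_end - 1] += 1
        if perfect_from_main and is_perfect_unique(
            r, min_mapq=lib.min_mapq, read_len=lib.read_len
        ):
            _add_span(
                diffs["perfect_unique_depth"][r.ref_name], r.ref_start, r.ref_end
            )

    def add_class(r: AlignmentRecord, cls: PairClass) -> None:
        metric = _PROP_METRICS.get(cls)
        if metric is None:
            return
        strand = "fwd" if r.strand == "+" else "rev"
        _add_span(diffs[f"{metric}_{strand}"][r.ref_name], r.ref_start, r.ref_end)

    for r, mate in iter_pairs(alignments):
        if mate is None:
            if not accept(r):
                continue
            add_read(r)
            if r.is_paired:
                # unmatched but same-ref-mate-flagged records degrade to orphan
                add_class(r, PairClass.ORPHAN)
            continue
        cls = classify_pair(r, mate, insert_range)
        for rec in (r, mate):
            if accept(rec):
                add_read(rec)
                add_class(rec, cls)
        if cls is PairClass.PROPER and accept(r) and accept(mate):
            frag = fragment_interval(r, mate)
            frag_lists[frag.ref_name].append(
                (frag.start, frag.end, frag.inner_start, frag.inner_end)
            )
            _add_span(diffs["frag_cov"][frag.ref_name], frag.start, frag.end)
            if frag.inner_end > frag.inner_start:
                _add_span(
                    diffs["inner_frag_cov"][frag.ref_name],
                    frag.inner_start,
                    frag.inner_end,
                )

    if perfect_alignments is not None:
        for r in perfect_alignments:
            if accept(r) and is_perfect_unique(
                r, min_mapq=lib.min_mapq, read_len=lib.read_len
            ):
                _add_span(
                    diffs["perfect_unique_depth"][r.ref_name], r.ref_start, r.ref_end
                )

    if rejected:
        logger.warning("rejected %d records outside assembly bounds", rejected)

    for metric, per_ref in diffs.items():
        for ref, diff in per_ref.items():
            tracks.metric(metric)[ref][:] = np.cumsum(diff[:-1])
    for ref in nref:
        tracks.metric("clip_count")[ref][:] = clip[ref]

    # class-depth -> proportions of per-strand read depth
    for strand in ("fwd", "rev"):
        for ref in nref:
            depth = tracks.get(f"read_depth_{strand}", ref)
            with np.errstate(invalid="ignore", divide="ignore"):
                for metric in _PROP_METRICS.values():
                    arr = tracks.get(f"{metric}_{strand}", ref)
                    np.divide(arr, depth, out=arr, where=depth > 0)

    for ref, frags in frag_lists.items():
        if frags:
            a = np.array(frags, dtype=np.int64)
            order = np.argsort(a[:, 0], kind="stable")
            a = a[order]
            tracks.fragments[ref] = (a[:, 0].copy(), a[:, 1].copy())
            tracks.inner_fragments[ref] = (a[:, 2].copy(), a[:, 3].copy())
    return tracks


def per_base_gc(
    assembly: Assembly, ref: str, window: int = 100
) -> np.ndarray:
    """GC fraction of the ``window`` bases centred on each base.

    N bases are ignored in both numerator and denominator; windows with no
    informative base fall back to the sequence-wide GC.
    """
    seq = np.frombuffer(assembly.sequences[ref].encode(), dtype=np.uint8)
    is_gc = ((seq == ord("G")) | (seq == ord("C"))).astype(np.float64)
    informative = (seq != ord("N")).astype(np.float64)
    kernel = np.ones(window)
    gc_sum = np.convolve(is_gc, kernel, mode="same")
    n_sum = np.convolve(informative, kernel, mode="same")
    global_gc = is_gc.sum() / max(informative.sum(), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        gc = np.where(n_sum > 0, gc_sum / np.maximum(n_sum, 1.0), global_gc)
    return gc


def relative_frag_cov_error(
    tracks: PerBaseTracks,
    assembly: Assembly,
    lib: "LibraryStats",
    gc_window: int = 100,
) -> Dict[str, np.ndarray]:
    """Observed inner fragment coverage over the GC-expected coverage.

    The expectation comes from the calibrated GC-bias curve evaluated at the
    local GC fraction; the curve itself is floored during fitting so the
    ratio never divides by ~0.  Results are also stored in
    ``tracks.frag_cov_ratio``.
    """
    out: Dict[str, np.ndarray] = {}
    for ref in tracks.lengths:
        gc = per_base_gc(assembly, ref, window=gc_window)
        expected = lib.gc_curve.expected(gc)
        ratio = tracks.get("inner_frag_cov", ref) / expected
        tracks.metric("frag_cov_ratio")[ref][:] = ratio
        out[ref] = ratio
    return out


def relative_read_depth_error(
    tracks: PerBaseTracks,
    assembly: Assembly,
    lib: "LibraryStats",
    gc_window: int = 100,
) -> Dict[str, np.ndarray]:
    """Observed read depth over the GC-expected read depth.

    Read depth degrades more gracefully than fragment coverage across a
    collapsed tandem repeat — pairs straddling the copy junction lose their
    fragment but their reads still align (clipped), so the depth ratio holds
    the full copy-number signal.  Requires ``lib.gc_curve_depth``; stored in
    ``tracks.read_depth_ratio``.
    """
    out: Dict[str, np.ndarray] = {}
    for ref in tracks.lengths:
        gc = per_base_gc(assembly, ref, window=gc_window)
        expected = lib.gc_curve_depth.expected(gc)
        depth = tracks.get("read_depth_fwd", ref) + tracks.get("read_depth_rev", ref)
        ratio = depth / expected
        tracks.metric("read_depth_ratio")[ref][:] = ratio
        out[ref] = ratio
    return out
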