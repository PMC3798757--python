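"""Read-pair classification, fragment intervals and the perfect+unique rule.

A *fragment* is the genomic interval between the outermost ends of a properly
paired read pair; the *inner fragment* is the interval between the two inner
read ends.  Pairs are classified into mutually exclusive classes; the class
proportions per strand are the basis of several per-base tracks.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Tuple

from .formats_io import AlignmentRecord


class PairClass(enum.Enum):
    PROPER = "proper"
    ORPHAN = "orphan"
    WRONG_ORIENTATION = "wrong_orientation"
    WRONG_DISTANCE = "wrong_distance"
    UNMAPPED = "unmapped"
    DUPLICATE = "duplicate"
    UNPAIRED = "unpaired"


@dataclass(frozen=True)
class FragmentInterval:
    """Outer fragment span of a proper pair plus its inner mate-pair span."""

    ref_name: str
    start: int
    end: int
    inner_start: int
    inner_end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def inner_length(self) -> int:
        return self.inner_end - self.inner_start


def classify_pair(
    r1: AlignmentRecord,
    r2: AlignmentRecord,
    insert_range: Tuple[float, float],
) -> PairClass:
    """Classify a mate pair into exactly one :class:`PairClass`.

    ``insert_range`` is the acceptable (low, high) outer fragment length of a
    proper pair, inclusive at both ends.  Duplicate takes precedence over
    everything; a pair with exactly one mapped mate, or mates on different
    references, is an orphan; same-strand or outward-facing pairs are
    wrong-orientation; inward-facing pairs outside the range are
    wrong-distance.
    """
    if r1.query_name != r2.query_name:
        raise ValueError(
            f"mismatched query names: {r1.query_name!r} vs {r2.query_name!r}"
        )
    if r1.is_duplicate or r2.is_duplicate:
        return PairClass.DUPLICATE
    if not (r1.is_paired and r2.is_paired):
        return PairClass.UNPAIRED
    if not r1.is_mapped and not r2.is_mapped:
        return PairClass.UNMAPPED
    if not (r1.is_mapped and r2.is_mapped) or r1.ref_name != r2.ref_name:
        return PairClass.ORPHAN
    if r1.strand == r2.strand:
        return PairClass.WRONG_ORIENTATION
    fwd, rev = (r1, r2) if r1.strand == "+" else (r2, r1)
    # innie: the forward read is leftmost, the reverse read rightmost
    if fwd.ref_start > rev.ref_start or fwd.ref_end > rev.ref_end:
        return PairClass.WRONG_ORIENTATION
    outer = max(r1.ref_end, r2.ref_end) - min(r1.ref_start, r2.ref_start)
    if insert_range[0] <= outer <= insert_range[1]:
        return PairClass.PROPER
    return PairClass.WRONG_DISTANCE


def fragment_interval(r1: AlignmentRecord, r2: AlignmentRecord) -> FragmentInterval:
    """Outer/inner fragment interval of a proper pair.

    The inner span is clamped to empty when the reads overlap.
    """
    if not (r1.is_mapped and r2.is_mapped and r1.ref_name == r2.ref_name):
        raise ValueError("fragment_interval requires a proper pair")
    start = min(r1.ref_start, r2.ref_start)
    end = max(r1.ref_end, r2.ref_end)
    inner_start = min(r1.ref_end, r2.ref_end)
    inner_end = max(r1.ref_start, r2.ref_start)
    if inner_end < inner_start:  # overlapping reads
        inner_start = inner_end = min(r1.ref_end, r2.ref_end)
    return FragmentInterval(
        ref_name=r1.ref_name,
        start=start,
        end=end,
        inner_start=inner_start,
        inner_end=inner_end,
    )


def is_perfect_unique(
    r: AlignmentRecord, min_mapq: int = 10, read_len: int | None = None
) -> bool:
    """True iff the read maps uniquely with its entire length matching.

    Perfect: edit distance 0, no soft/hard clips, aligned length equal to the
    read length.  Unique: mapping quality at least ``min_mapq`` (independent
    mapping assigns low mapq to ambiguously placed reads).  Secondary and
    duplicate records never qualify.
    """
    if not r.is_mapped or r.is_secondary or r.is_duplicate:
        return False
    if r.nm != 0 or r.is_clipped:
        return False
    expected = read_len if read_len is not None else r.query_length
    if expected and r.aligned_length != expected:
        return False
    return r.mapq >= min_mapq
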