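"""Self-contained test-input generation: truth genome, mis-assembled
"assembly", simulated read pairs as sorted SAM, and a truth GFF of expected
calls.

The simulator emulates the evidence the evaluator consumes: fragments are
drawn with uniform starts on the truth genome and near-normal lengths, each
terminal read is projected through the truth-to-assembly coordinate map, and
a read maps only where its footprint lies within one mapped piece and
outside every N-gap — reads straddling a piece boundary are soft-clipped at
the boundary, reads placed inside collapsed-repeat copies get mapping
quality 0, everything else maps perfectly (NM 0, MAPQ 60).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam
from scipy import stats

from .error_calling import Category, RegionCall, Severity
from .formats_io import Assembly

_COMP = str.maketrans("ACGTN", "TGCAN")


class ErrorType(enum.Enum):
    FALSE_JOIN_OVER_GAP = "false_join_over_gap"
    FALSE_JOIN_NO_GAP = "false_join_no_gap"
    DELETION = "deletion"
    INSERTION = "insertion"
    COLLAPSED_REPEAT = "collapsed_repeat"


@dataclass
class ErrorSpec:
    """One structural error to inject at a truth-genome position.

    ``size`` is the skipped truth span for joins and deletions, the inserted
    length for insertions, and the repeat unit length for collapsed repeats.
    """

    type: ErrorType
    position: int
    size: int
    true_copies: int = 2
    assembled_copies: int = 1

    @property
    def truth_span(self) -> int:
        """Bases of truth genome consumed by this edit."""
        if self.type is ErrorType.INSERTION:
            return 0
        if self.type is ErrorType.COLLAPSED_REPEAT:
            return self.size * self.true_copies
        return self.size


@dataclass(frozen=True)
class MapPiece:
    truth_start: int
    truth_end: int
    asm_start: int
    repeat: bool = False

    @property
    def asm_end(self) -> int:
        return self.asm_start + (self.truth_end - self.truth_start)


@dataclass
class CoordinateMap:
    """Piecewise monotone truth -> assembly mapping.

    Pieces are disjoint in truth coordinates; collapsed-repeat pieces may
    share assembly coordinates (marked ``repeat``).  Truth intervals with no
    piece are absent from the assembly.  ``truth`` holds the final truth
    sequence (collapsed-repeat injection rewrites the repeat locus to be
    tandem-repetitive).
    """

    pieces: List[MapPiece]
    truth: str = ""
    assembly_length: int = 0

    def __post_init__(self) -> None:
        for a, b in zip(self.pieces, self.pieces[1:]):
            if b.truth_start < a.truth_end:
                raise ValueError("map pieces overlap in truth coordinates")

    def pieces_overlapping(self, start: int, end: int) -> List[MapPiece]:
        return [
            p
            for p in self.pieces
            if p.truth_start < end and p.truth_end > start
        ]


def simulate_reference(length: int, gc_target: float, seed: int) -> str:
    """I.i.d. random sequence with P(G or C) = ``gc_target``; reproducible."""
    if not 0 <= gc_target <= 1:
        raise ValueError("gc_target must be within [0, 1]")
    rng = np.random.default_rng(seed)
    at, gc = (1.0 - gc_target) / 2.0, gc_target / 2.0
    bases = rng.choice(
        np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=[at, gc, gc, at]
    )
    return bases.tobytes().decode()


def inject_misassemblies(
    truth: str,
    specs: Sequence[ErrorSpec],
    gap_len: int = 100,
    benign_gaps: Optional[Sequence[Tuple[int, int]]] = None,
    min_spacing: int = 600,
    seed: int = 0,
) -> Tuple[str, CoordinateMap, List[RegionCall]]:
    """Build the mis-assembled sequence, its coordinate map and a truth GFF.

    Returns (assembly sequence, coordinate map, expected region calls in
    assembly coordinates).  ``benign_gaps`` are (truth position, length)
    scaffold gaps with correct flanking sequence: the assembly carries Ns of
    the same length, so spanning read pairs still map consistently.
    Injected intervals must be disjoint and at least ``min_spacing`` apart
    and from the sequence ends.
    """
    rng = np.random.default_rng(seed)
    events: List[Tuple[int, str, object]] = [
        (s.position, "error", s) for s in specs
    ]
    events += [(p, "benign_gap", ln) for p, ln in (benign_gaps or [])]
    events.sort(key=lambda e: e[0])
    prev_end = min_spacing  # also enforce distance from the left end
    for pos, kind, payload in events:
        span = payload.truth_span if kind == "error" else int(payload)  # type: ignore[union-attr]
        if pos - prev_end < 0:
            raise ValueError("injected intervals overlap or are too close")
        prev_end = pos + span + min_spacing
    if events and prev_end - min_spacing > len(truth) - min_spacing:
        raise ValueError("injected intervals too close to the sequence end")

    chunks: List[str] = []
    pieces: List[MapPiece] = []
    calls: List[RegionCall] = []
    asm_len = 0
    t = 0
    piece_t0 = 0
    piece_a0 = 0

    def emit(seq: str) -> None:
        nonlocal asm_len
        chunks.append(seq)
        asm_len += len(seq)

    def close_piece(at: int) -> None:
        if at > piece_t0:
            pieces.append(MapPiece(piece_t0, at, piece_a0))

    for pos, kind, payload in events:
        emit(truth[t:pos])
        t = pos
        if kind == "benign_gap":
            ln = int(payload)  # type: ignore[arg-type]
            emit("N" * ln)
            t = pos + ln
            continue
        spec: ErrorSpec = payload  # type: ignore[assignment]
        if spec.type in (
            ErrorType.FALSE_JOIN_OVER_GAP,
            ErrorType.FALSE_JOIN_NO_GAP,
            ErrorType.DELETION,
        ):
            close_piece(pos)
            gl = gap_len if spec.type is ErrorType.FALSE_JOIN_OVER_GAP else 0
            emit("N" * gl)
            t = pos + spec.size
            piece_t0, piece_a0 = t, asm_len
            if spec.type is ErrorType.FALSE_JOIN_OVER_GAP:
                calls.append(
                    RegionCall(
                        "asm",
                        asm_len - gl,
                        asm_len,
                        Category.FCD_ERROR_OVER_GAP,
                        Severity.ERROR,
                    )
                )
            else:
                calls.append(
                    RegionCall(
                        "asm",
                        asm_len - 1,
                        asm_len + 1,
                        Category.FCD_ERROR_CONTIG,
                        Severity.ERROR,
                    )
                )
                if spec.type is ErrorType.DELETION:
                    calls.append(
                        RegionCall(
                            "asm",
                            asm_len - 1,
                            asm_len + 1,
                            Category.ORPHAN_EXCESS,
                            Severity.WARNING,
                        )
                    )
        elif spec.type is ErrorType.INSERTION:
            close_piece(pos)
            ins = simulate_reference(spec.size, 0.5, int(rng.integers(2**31)))
            emit(ins)
            piece_t0, piece_a0 = pos, asm_len
            calls.append(
                RegionCall(
                    "asm",
                    asm_len - spec.size,
                    asm_len,
                    Category.ZERO_FRAGMENT_COVERAGE,
                    Severity.ERROR,
                )
            )
            calls.append(
                RegionCall(
                    "asm",
                    asm_len - spec.size - 1,
                    asm_len + 1,
                    Category.SOFT_CLIP_EXCESS,
                    Severity.WARNING,
                )
            )
        elif spec.type is ErrorType.COLLAPSED_REPEAT:
            unit, ct, ca = spec.size, spec.true_copies, spec.assembled_copies
            if ca < 1 or ct <= ca:
                raise ValueError("collapsed repeat needs true_copies > assembled_copies >= 1")
            truth = truth[:pos] + truth[pos : pos + unit] * ct + truth[pos + unit * ct :]
            close_piece(pos)
            rep_a0 = asm_len
            emit(truth[pos : pos + unit] * ca)
            for k in range(ct):
                pieces.append(
                    MapPiece(
                        pos + k * unit,
                        pos + (k + 1) * unit,
                        rep_a0 + (k % ca) * unit,
                        repeat=True,
                    )
                )
            t = pos + unit * ct
            piece_t0, piece_a0 = t, asm_len
            calls.append(
                RegionCall(
                    "asm",
                    rep_a0,
                    rep_a0 + unit * ca,
                    Category.COLLAPSED_REPEAT,
                    Severity.WARNING,
                )
            )
    emit(truth[t:])
    close_piece(len(truth))
    return "".join(chunks), CoordinateMap(pieces, truth=truth, assembly_length=asm_len), calls


# ---------------------------------------------------------------------------
# Read-pair simulation
# ---------------------------------------------------------------------------


@dataclass
class LibraryParams:
    """Fragment library the simulator draws from."""

    mean: float = 300.0
    sd: float = 30.0
    read_len: int = 100
    depth: float = 30.0

    @property
    def insert_range(self) -> Tuple[float, float]:
        """Central 99% of the generating normal, the calibrated proper range."""
        lo = stats.norm.ppf(0.005, loc=self.mean, scale=self.sd)
        hi = stats.norm.ppf(0.995, loc=self.mean, scale=self.sd)
        return (lo, hi)


@dataclass
class _SimRead:
    start: int  # assembly coords; -1 if unmapped
    end: int
    strand: str
    left_clip: int
    right_clip: int
    mapq: int
    truth_start: int
    truth_end: int


def _project_read(
    s: int,
    e: int,
    cmap: CoordinateMap,
    asm_gaps: List[Tuple[int, int]],
    min_anchor: int,
) -> Optional[Tuple[int, int, int, int, int]]:
    """Project truth footprint [s, e) onto the assembly.

    Returns (asm_start, asm_end, left_clip, right_clip, mapq) or None when
    unmapped.  A read anchored with >= ``min_anchor`` bases in one piece is
    soft-clipped at the piece boundary; a footprint overlapping an assembly
    N-gap does not map.
    """
    best: Optional[MapPiece] = None
    best_ol = 0
    for p in cmap.pieces_overlapping(s, e):
        ol = min(e, p.truth_end) - max(s, p.truth_start)
        if ol > best_ol:
            best, best_ol = p, ol
    if best is None or best_ol < min_anchor:
        return None
    ts = max(s, best.truth_start)
    te = min(e, best.truth_end)
    a0 = best.asm_start + (ts - best.truth_start)
    a1 = a0 + (te - ts)
    for g0, g1 in asm_gaps:
        if a0 < g1 and a1 > g0:
            return None
    return a0, a1, ts - s, e - te, 0 if best.repeat else 60


def simulate_pairs_to_sam(
    truth: str,
    assembly_seq: str,
    cmap: CoordinateMap,
    lib_params: LibraryParams,
    seed: int,
    out_path: str,
    ref_name: str = "asm",
    min_anchor: int = 10,
    dup_fraction: float = 0.0,
) -> Dict[str, int]:
    """Simulate read pairs from the truth genome and write a coordinate-
    sorted SAM against the assembly.

    Fragment starts are uniform on the truth sequence and lengths are
    normal(mean, sd) truncated at twice the read length.  Returns the
    expected pair-class census (counts keyed by class name).
    """
    rl = lib_params.read_len
    rng = np.random.default_rng(seed)
    n_pairs = int(round(lib_params.depth * len(truth) / (2 * rl)))
    lengths = np.maximum(
        np.rint(rng.normal(lib_params.mean, lib_params.sd, size=n_pairs)).astype(
            np.int64
        ),
        2 * rl,
    )
    lengths = np.minimum(lengths, len(truth))
    starts = rng.integers(0, len(truth) - lengths + 1)
    dup_mask = (
        rng.random(n_pairs) < dup_fraction
        if dup_fraction > 0
        else np.zeros(n_pairs, dtype=bool)
    )

    asm_gaps = Assembly.from_sequences({ref_name: assembly_seq}).gaps[ref_name]
    lo, hi = lib_params.insert_range
    census: Dict[str, int] = {
        "proper": 0,
        "orphan": 0,
        "wrong_orientation": 0,
        "wrong_distance": 0,
        "unmapped": 0,
        "duplicate": 0,
    }

    records: List[Tuple[int, str, int, object]] = []  # (sort pos, qname, mate idx, seg)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": ref_name, "LN": len(assembly_seq)}],
        }
    )

    def make_segment(
        qname: str,
        read: _SimRead,
        mate: _SimRead,
        first: bool,
        duplicate: bool,
    ) -> "pysam.AlignedSegment":
        a = pysam.AlignedSegment(header)
        a.query_name = qname
        mapped = read.start >= 0
        mate_mapped = mate.start >= 0
        flag = 0x1 | (0x40 if first else 0x80)
        if not mapped:
            flag |= 0x4
        if not mate_mapped:
            flag |= 0x8
        if mapped and read.strand == "-":
            flag |= 0x10
        if mate_mapped and mate.strand == "-":
            flag |= 0x20
        if duplicate:
            flag |= 0x400
        a.flag = flag
        # SAM stores the forward-strand representation, which is the truth
        # slice itself for both mates
        seq = truth[read.truth_start : read.truth_end]
        a.query_sequence = seq
        a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
        a.reference_id = 0
        if mapped:
            a.reference_start = read.start
            a.mapping_quality = read.mapq
            cig = []
            if read.left_clip:
                cig.append((4, read.left_clip))
            cig.append((0, read.end - read.start))
            if read.right_clip:
                cig.append((4, read.right_clip))
            a.cigartuples = cig
            a.set_tag("NM", 0)
        else:
            a.reference_start = mate.start if mate_mapped else 0
            a.mapping_quality = 0
        a.next_reference_id = 0
        a.next_reference_start = (
            mate.start if mate_mapped else (read.start if mapped else 0)
        )
        return a

    for i in range(n_pairs):
        p, L = int(starts[i]), int(lengths[i])
        r1_span = (p, p + rl)
        r2_span = (p + L - rl, p + L)
        proj1 = _project_read(*r1_span, cmap, asm_gaps, min_anchor)
        proj2 = _project_read(*r2_span, cmap, asm_gaps, min_anchor)
        if proj1 is None and proj2 is None:
            census["unmapped"] += 1
            continue
        reads: List[_SimRead] = []
        for span, proj, strand in ((r1_span, proj1, "+"), (r2_span, proj2, "-")):
            if proj is None:
                reads.append(_SimRead(-1, -1, strand, 0, 0, 0, span[0], span[1]))
            else:
                a0, a1, lc, rc, mapq = proj
                reads.append(_SimRead(a0, a1, strand, lc, rc, mapq, span[0], span[1]))
        r1, r2 = reads
        if dup_mask[i]:
            census["duplicate"] += 1
        elif proj1 is None or proj2 is None:
            census["orphan"] += 1
        else:
            outer = max(r1.end, r2.end) - min(r1.start, r2.start)
            fwd, rev = (r1, r2) if r1.strand == "+" else (r2, r1)
            if fwd.start > rev.start or fwd.end > rev.end:
                census["wrong_orientation"] += 1
            elif lo <= outer <= hi:
                census["proper"] += 1
            else:
                census["wrong_distance"] += 1
        qname = f"frag{i:08d}"
        seg1 = make_segment(qname, r1, r2, True, bool(dup_mask[i]))
        seg2 = make_segment(qname, r2, r1, False, bool(dup_mask[i]))
        records.append((seg1.reference_start, qname, 0, seg1))
        records.append((seg2.reference_start, qname, 1, seg2))

    records.sort(key=lambda r: (r[0], r[1], r[2]))
    with pysam.AlignmentFile(out_path, "w", header=header) as out:
        for _, _, _, seg in records:
            out.write(seg)
    census["n_pairs"] = n_pairs
    return census


# ---------------------------------------------------------------------------
# Canonical study scenarios (shared by the test suite and the acceptance
# script, so the conditions are defined exactly once)
# ---------------------------------------------------------------------------

#: assembly size of the standard fixtures, bases
STANDARD_LENGTH = 500_000
#: benign scaffold gap length, bases.  A correct scaffold join must be
#: spannable by the library: with fragments of ~300 +- 30 and two 100-base
#: terminal reads, gaps much beyond insert - 2*read_len (~100) cannot be
#: crossed by any pair, so 40 bases is a comfortably supported gap.
BENIGN_GAP_LEN = 40
#: N-run placed at an injected false join, bases
JOIN_GAP_LEN = 100

STANDARD_LIB = LibraryParams(mean=300.0, sd=30.0, read_len=100, depth=30.0)


def standard_clean_scenario(
    seed: int, length: int = STANDARD_LENGTH, n_benign_gaps: int = 6
) -> Tuple[str, str, CoordinateMap, List[RegionCall]]:
    """Error-free scaffold with a few benign gaps: the negative control.

    Returns (truth, assembly, map, expected calls == [])."""
    truth = simulate_reference(length, 0.45, seed)
    gap_positions = np.linspace(
        length * 0.12, length * 0.88, n_benign_gaps
    ).astype(int)
    benign = [(int(p), BENIGN_GAP_LEN) for p in gap_positions]
    asm, cmap, calls = inject_misassemblies(
        truth, [], benign_gaps=benign, seed=seed
    )
    return truth, asm, cmap, calls


def standard_error_scenario(
    seed: int, length: int = STANDARD_LENGTH
) -> Tuple[str, str, CoordinateMap, List[RegionCall]]:
    """The injected-error recovery scenario: 10 false joins over gaps, two
    2 kb deletions and one collapsed repeat (2 -> 1 copies of 500 bp).

    The truth genome is long enough that the assembly, after the joins skip
    10 kb each and the deletions 2 kb each, is ~``length`` bases.  Returns
    (truth, assembly, map, truth calls)."""
    skip = 10_000
    n_joins = 10
    del_size = 2_000
    truth_len = length + n_joins * skip + 2 * del_size + 500
    truth = simulate_reference(truth_len, 0.45, seed)
    anchors = np.linspace(truth_len * 0.05, truth_len * 0.95, 13).astype(int)
    specs = [
        ErrorSpec(ErrorType.FALSE_JOIN_OVER_GAP, int(anchors[k]), skip)
        for k in range(5)
    ]
    specs.append(ErrorSpec(ErrorType.DELETION, int(anchors[5]), del_size))
    specs.append(ErrorSpec(ErrorType.COLLAPSED_REPEAT, int(anchors[6]), 500))
    specs.append(ErrorSpec(ErrorType.DELETION, int(anchors[7]), del_size))
    specs += [
        ErrorSpec(ErrorType.FALSE_JOIN_OVER_GAP, int(anchors[k]), skip)
        for k in range(8, 13)
    ]
    benign = [
        (int(p), BENIGN_GAP_LEN)
        for p in ((anchors[:-1] + anchors[1:]) // 2)[::3]
    ]
    asm, cmap, calls = inject_misassemblies(
        truth, specs, gap_len=JOIN_GAP_LEN, benign_gaps=benign, seed=seed
    )
    return truth, asm, cmap, calls
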