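"""Reading and writing of the standard formats the pipeline touches.

All in-memory coordinates are 0-based, half-open.  Conversion to the 1-based
inclusive conventions of SAM and GFF3 happens only inside this module, at the
format boundary.
"""

from __future__ import annotations

import gzip as gzip_mod
import os
import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import pysam

GFF_SOURCE = "asmcritic"

# Every IUPAC code that is not a concrete A/C/G/T becomes an N and thereby may
# extend a gap run: mapped reads cannot be expected to match ambiguity codes.
_NORMALIZE = str.maketrans(
    "acgtnRYSWKMBDHVryswkmbdhvUu",
    "ACGTN" + "N" * 20 + "TT",
)
_VALID = set("ACGTN")

_N_RUN = re.compile("N+")


class AssemblyFormatError(ValueError):
    """Raised for malformed or empty FASTA input."""


class AlignmentInputError(ValueError):
    """Raised for alignment input violating the sorted/consistent contract."""


@dataclass
class Assembly:
    """Named sequences plus a registry of gap (N-run) intervals.

    ``sequences`` maps name -> uppercase nucleotide string over {A,C,G,T,N};
    ``gaps`` maps name -> sorted, disjoint, maximal N-run intervals
    (0-based, half-open).
    """

    sequences: Dict[str, str] = field(default_factory=dict)
    gaps: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    @property
    def gap_count(self) -> int:
        return sum(len(g) for g in self.gaps.values())

    @property
    def total_gap_length(self) -> int:
        return sum(e - s for g in self.gaps.values() for s, e in g)

    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @classmethod
    def from_sequences(cls, sequences: Dict[str, str]) -> "Assembly":
        """Normalize case/ambiguity codes and build the gap registry."""
        norm: Dict[str, str] = {}
        gaps: Dict[str, List[Tuple[int, int]]] = {}
        for name, seq in sequences.items():
            if len(seq) == 0:
                raise AssemblyFormatError(f"zero-length sequence: {name!r}")
            s = seq.translate(_NORMALIZE)
            bad = set(s) - _VALID
            if bad:
                raise AssemblyFormatError(
                    f"sequence {name!r} contains invalid characters: {sorted(bad)}"
                )
            norm[name] = s
            gaps[name] = [m.span() for m in _N_RUN.finditer(s)]
        return cls(sequences=norm, gaps=gaps)


def read_assembly(fasta_path: str) -> Assembly:
    """Read a FASTA assembly, uppercase it, map ambiguity codes to N and
    register maximal N-runs as gaps.

    Raises :class:`AssemblyFormatError` on an empty file, duplicate names or
    zero-length sequences.
    """
    sequences: Dict[str, str] = {}
    name: Optional[str] = None
    chunks: List[str] = []

    def flush() -> None:
        if name is not None:
            if name in sequences:
                raise AssemblyFormatError(f"duplicate sequence name: {name!r}")
            sequences[name] = "".join(chunks)

    opener = gzip_mod.open if str(fasta_path).endswith(".gz") else open
    with opener(fasta_path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise AssemblyFormatError("empty sequence name in FASTA header")
                chunks = []
            else:
                if name is None:
                    raise AssemblyFormatError("sequence data before first FASTA header")
                chunks.append(line.strip())
        flush()
    if not sequences:
        raise AssemblyFormatError(f"no sequences found in {fasta_path!r}")
    return Assembly.from_sequences(sequences)


def write_assembly(assembly: Assembly, path: str, width: int = 60) -> None:
    """Write an assembly as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for name, seq in assembly.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Alignment records
# ---------------------------------------------------------------------------

_CLIP_OPS = {4, 5}  # soft, hard: both signal a mismatching read end


@dataclass
class AlignmentRecord:
    """One mapped (or unmapped) read, in 0-based half-open coordinates."""

    query_name: str
    ref_name: Optional[str]
    ref_start: int
    ref_end: int
    strand: str  # '+' or '-'
    mapq: int
    nm: int
    cigar: Tuple[Tuple[int, int], ...]  # pysam (op, length) pairs
    is_paired: bool
    is_mapped: bool
    mate_mapped: bool
    mate_ref_name: Optional[str]
    mate_ref_start: int
    is_duplicate: bool
    is_secondary: bool
    is_read1: bool
    left_soft_clip: int
    right_soft_clip: int
    query_length: int

    @property
    def aligned_length(self) -> int:
        """Read bases consumed by M/=/X/I operations (excludes clips)."""
        return sum(n for op, n in self.cigar if op in (0, 1, 7, 8))

    @property
    def is_clipped(self) -> bool:
        return self.left_soft_clip > 0 or self.right_soft_clip > 0


def _record_from_pysam(a: "pysam.AlignedSegment") -> AlignmentRecord:
    cig = tuple(a.cigartuples) if a.cigartuples else ()
    left = cig[0][1] if cig and cig[0][0] in _CLIP_OPS else 0
    right = cig[-1][1] if cig and cig[-1][0] in _CLIP_OPS else 0
    mapped = not a.is_unmapped
    qlen = a.infer_read_length() or (len(a.query_sequence) if a.query_sequence else 0)
    return AlignmentRecord(
        query_name=a.query_name,
        ref_name=a.reference_name if mapped else None,
        ref_start=a.reference_start if mapped else -1,
        ref_end=a.reference_end if mapped else -1,
        strand="-" if a.is_reverse else "+",
        mapq=a.mapping_quality,
        nm=int(a.get_tag("NM")) if a.has_tag("NM") else 0,
        cigar=cig,
        is_paired=a.is_paired,
        is_mapped=mapped,
        mate_mapped=a.is_paired and not a.mate_is_unmapped,
        mate_ref_name=(
            a.next_reference_name
            if a.is_paired and a.next_reference_id >= 0
            else None
        ),
        mate_ref_start=a.next_reference_start if a.is_paired else -1,
        is_duplicate=a.is_duplicate,
        is_secondary=a.is_secondary or a.is_supplementary,
        is_read1=a.is_read1,
        left_soft_clip=left,
        right_soft_clip=right,
        query_length=qlen,
    )


def stream_alignments(
    sam_or_bam_path: str, assembly: Optional[Assembly] = None
) -> Iterator[AlignmentRecord]:
    """Yield :class:`AlignmentRecord` from a coordinate-sorted SAM/BAM.

    Secondary and duplicate records are yielded but flagged.  Raises
    :class:`AlignmentInputError` on unsorted input or reference names absent
    from the assembly.
    """
    with pysam.AlignmentFile(sam_or_bam_path, check_sq=False) as fh:
        if assembly is not None:
            for ref in fh.references:
                if ref not in assembly.sequences:
                    raise AlignmentInputError(
                        f"alignment reference {ref!r} absent from assembly"
                    )
        last: Tuple[int, int] = (-1, -1)
        for a in fh:
            if a.is_unmapped:
                yield _record_from_pysam(a)
                continue
            key = (a.reference_id, a.reference_start)
            if key < last:
                raise AlignmentInputError(
                    f"input not coordinate-sorted at {a.query_name!r}"
                )
            last = key
            yield _record_from_pysam(a)


# ---------------------------------------------------------------------------
# GFF3 output of region calls
# ---------------------------------------------------------------------------


def write_gff(calls: List["RegionCall"], path: str) -> None:
    """Write error/warning region calls as GFF3 (1-based inclusive).

    Lines are sorted by seqid then start; score column carries the supporting
    statistic and the Note attribute the severity.
    """
    from .error_calling import RegionCall  # noqa: F401  (type only)

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for call in sorted(calls, key=lambda c: (c.ref_name, c.start, c.end)):
            score = "." if call.statistic is None else f"{call.statistic:g}"
            sev = call.severity.name.capitalize()
            fh.write(
                f"{call.ref_name}\t{GFF_SOURCE}\t{call.category.value}\t"
                f"{call.start + 1}\t{call.end}\t{score}\t.\t.\t"
                f"Note={sev}: {call.description}\n"
            )


def read_gff(path: str) -> List["RegionCall"]:
    """Re-parse a GFF3 written by :func:`write_gff` back into RegionCalls."""
    from .error_calling import Category, RegionCall, Severity

    calls: List[RegionCall] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            seqid, _src, ftype, start, end, score, _strand, _frame, attrs = (
                line.rstrip("\n").split("\t")
            )
            note = attrs.split("Note=", 1)[1] if "Note=" in attrs else ""
            sev_word, _, desc = note.partition(": ")
            calls.append(
                RegionCall(
                    ref_name=seqid,
                    start=int(start) - 1,
                    end=int(end),
                    category=Category(ftype),
                    severity=Severity[sev_word.upper()],
                    statistic=None if score == "." else float(score),
                    description=desc,
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Per-base plot tracks (Artemis userplot style: one value per line)
# ---------------------------------------------------------------------------

#: tracks always emitted even when ``metrics`` is restricted
CORE_TRACKS = ("score", "fcd_error")


def write_tracks(
    tracks: "PerBaseTracks",
    out_dir: str,
    metrics: Optional[List[str]] = None,
    gzip: bool = False,
) -> List[str]:
    """Write one plain-text plot file per (reference, metric).

    Each file has exactly one fixed-decimal value per assembly base, in the
    one-value-per-line userplot dialect genome browsers accept.  Returns the
    written paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    names = list(metrics) if metrics is not None else list(tracks.metric_names())
    for core in CORE_TRACKS:
        if core in tracks.metric_names() and core not in names:
            names.append(core)
    written: List[str] = []
    for metric in names:
        per_ref = tracks.metric(metric)
        for ref, values in per_ref.items():
            fname = f"{ref}.{metric}.plot" + (".gz" if gzip else "")
            fpath = os.path.join(out_dir, fname)
            opener = gzip_mod.open if gzip else open
            with opener(fpath, "wt") as fh:
                fh.write("\n".join(f"{v:.4f}" for v in values))
                fh.write("\n")
            written.append(fpath)
    return written


def write_summary(summary: "AssemblySummary", path: str) -> None:
    """Write the per-reference + TOTAL summary spreadsheet as TSV."""
    rows = summary.as_rows()
    with open(path, "w") as fh:
        fh.write("\t".join(rows[0]) + "\n")
        for row in rows[1:]:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_break_log(log: List[Tuple[str, str, int, int]], path: str) -> None:
    """TSV of (original name, part name, original interval) for each piece."""
    with open(path, "w") as fh:
        fh.write("original\tpart\tstart\tend\n")
        for orig, part, start, end in log:
            fh.write(f"{orig}\t{part}\t{start}\t{end}\n")


def write_stats_report(pairs: List[Tuple[str, object]], path: str) -> None:
    """Two-column TSV (stat name, value) calibration report."""
    with open(path, "w") as fh:
        for name, value in pairs:
            fh.write(f"{name}\t{value}\n")
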