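"""Shared fixtures: an alignment-record factory, tiny SAM writers, and
session-scoped full pipeline runs on the two standard synthetic scenarios."""

from __future__ import annotations

import os
from dataclasses import replace
from typing import List, Optional, Tuple

import numpy as np
import pytest

from asmcritic import formats_io, pipeline
from asmcritic.formats_io import AlignmentRecord, Assembly
from asmcritic.pipeline import RunConfig
from asmcritic.synthetic_fixtures import (
    STANDARD_LIB,
    simulate_pairs_to_sam,
    standard_clean_scenario,
    standard_error_scenario,
)


def make_record(
    query_name: str = "q",
    ref_name: Optional[str] = "s1",
    ref_start: int = 0,
    ref_end: int = 100,
    strand: str = "+",
    mapq: int = 60,
    nm: int = 0,
    cigar: Tuple[Tuple[int, int], ...] = ((0, 100),),
    is_paired: bool = True,
    is_mapped: bool = True,
    mate_mapped: bool = True,
    mate_ref_name: Optional[str] = "s1",
    mate_ref_start: int = 0,
    is_duplicate: bool = False,
    is_secondary: bool = False,
    is_read1: bool = True,
    left_soft_clip: int = 0,
    right_soft_clip: int = 0,
    query_length: int = 100,
) -> AlignmentRecord:
    return AlignmentRecord(
        query_name=query_name,
        ref_name=ref_name,
        ref_start=ref_start,
        ref_end=ref_end,
        strand=strand,
        mapq=mapq,
        nm=nm,
        cigar=cigar,
        is_paired=is_paired,
        is_mapped=is_mapped,
        mate_mapped=mate_mapped,
        mate_ref_name=mate_ref_name,
        mate_ref_start=mate_ref_start,
        is_duplicate=is_duplicate,
        is_secondary=is_secondary,
        is_read1=is_read1,
        left_soft_clip=left_soft_clip,
        right_soft_clip=right_soft_clip,
        query_length=query_length,
    )


def make_pair(
    start1: int,
    end1: int,
    start2: int,
    end2: int,
    name: str = "p",
    ref: str = "s1",
    **kw,
) -> Tuple[AlignmentRecord, AlignmentRecord]:
    """An inward-facing pair: forward read at [start1, end1), reverse mate at
    [start2, end2)."""
    r1 = make_record(
        query_name=name,
        ref_name=ref,
        ref_start=start1,
        ref_end=end1,
        strand="+",
        mate_ref_name=ref,
        mate_ref_start=start2,
        cigar=((0, end1 - start1),),
        query_length=end1 - start1,
        is_read1=True,
        **kw,
    )
    r2 = make_record(
        query_name=name,
        ref_name=ref,
        ref_start=start2,
        ref_end=end2,
        strand="-",
        mate_ref_name=ref,
        mate_ref_start=start1,
        cigar=((0, end2 - start2),),
        query_length=end2 - start2,
        is_read1=False,
        **kw,
    )
    return r1, r2


@pytest.fixture
def tiny_assembly() -> Assembly:
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    return Assembly.from_sequences({"s1": seq})


def _run_scenario(tmpdir: str, scenario, seed: int):
    truth, asm, cmap, truth_calls = scenario(seed)
    fasta = os.path.join(tmpdir, "assembly.fa")
    sam = os.path.join(tmpdir, "reads.sam")
    formats_io.write_assembly(Assembly.from_sequences({"asm": asm}), fasta)
    census = simulate_pairs_to_sam(cmap.truth, asm, cmap, STANDARD_LIB, seed, sam)
    config = RunConfig(
        assembly=fasta, alignments=sam, outdir=os.path.join(tmpdir, "out"), seed=seed
    )
    result = pipeline.run_pipeline(config)
    return {
        "result": result,
        "truth_calls": truth_calls,
        "census": census,
        "config": config,
        "fasta": fasta,
        "sam": sam,
    }


@pytest.fixture(scope="session")
def clean_run(tmp_path_factory):
    """Full pipeline on the error-free 500 kb scenario at 30x (seed 1)."""
    tmpdir = tmp_path_factory.mktemp("clean_run")
    return _run_scenario(str(tmpdir), standard_clean_scenario, seed=1)


@pytest.fixture(scope="session")
def error_run(tmp_path_factory):
    """Full pipeline on the injected-error 500 kb scenario at 30x (seed 1)."""
    tmpdir = tmp_path_factory.mktemp("error_run")
    return _run_scenario(str(tmpdir), standard_error_scenario, seed=1)
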