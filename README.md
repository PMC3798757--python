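# asmcritic

Reference-free evaluation of genome assemblies from mapped paired reads.

Draft genome assemblies routinely contain mis-joined scaffolds, collapsed
repeats, deletions and insertions that summary statistics such as the N50
cannot see — an incorrectly joined scaffold *raises* the N50 while lowering
the accuracy of the sequence. `asmcritic` scores **every base** of an
assembly for accuracy using only reads mapped back to that assembly (no
reference genome needed), pinpoints mis-assemblies, and emits a corrected
assembly whose recomputed ("corrected") N50 reflects real contiguity.

It is aimed at genome-project teams comparing candidate assemblies from
different assemblers or parameter sweeps, and at anyone who needs a per-base
confidence track for a draft reference.

## The method

Each mate of a read pair must be mapped independently. A **fragment** is the
interval between the outermost ends of a properly paired read pair (correct
orientation, outer distance within the calibrated insert range); the **inner
fragment** is the interval between the two inner read ends.

At every base *b* the **fragment coverage distribution** (FCD) is the
fraction of *b*-covering fragments that also cover each offset *x*:

```
observed_b(x) = #{fragments covering both b and b+x} / #{fragments covering b}
```

Under uniform placement of fragments with length distribution *P(L)* the
ideal curve is the length-weighted expectation of `max(0, L − |x|)/L`. The
**FCD error** at *b* is the L1 area between observed and ideal curves,
divided by the mean insert size. Structural errors — false scaffold joins,
deletions, insertions — distort the local fragment landscape and produce a
run of high FCD errors, while single-base errors leave it untouched. Because
no read can map onto an N-gap, the ideal curve near a gap is recomputed by
enumerating only fragment placements whose two terminal read footprints
avoid every gap; a gap longer than half the mean insert cannot be validated
at all and is excluded from analysis.

The FCD-error cutoff is calibrated automatically: windows sampled across the
genome each yield the error value at which 80% of their bases would fail,
and the cutoff is chosen from the window-failure curve (turning-point
derivative rule), floored at a Monte-Carlo estimate of what pure sampling
noise can reach (see `docs/methods.md`). Regions where at least 80% of at
least half-an-insert of bases exceed the cutoff — or that have no fragment
coverage at all — are reported as **errors**: over a gap, a *scaffolding
error*; otherwise a *contig error*. Excess soft-clipping, orphaned or
wrongly oriented reads, low perfect coverage, depth outliers and
collapsed repeats (GC-corrected coverage ≥ 2× expectation over ≥ 100 bp)
are reported as **warnings**.

Every base gets a score in [0, 1]: **1** iff it is covered by ≥ 5 perfect,
uniquely mapped reads *and* passes the FCD test; otherwise the fraction of
an eight-test battery it passes. Scaffolds are broken at every gap inside a
scaffolding-error region and contig-error regions are masked with Ns,
giving the corrected assembly and corrected N50.

## Worked example

Generate a 500 kb synthetic assembly carrying ten false joins over gaps,
two 2 kb deletions and a collapsed repeat, with 30× simulated read pairs
(insert 300 ± 30), then evaluate it:

```bash
asmcritic simulate --outdir fixture --seed 1 --scenario errors
asmcritic all fixture/assembly.fa fixture/reads.sam --outdir run --seed 1
```

which prints:

```
wrote fixture (90675 pairs) to fixture/
errors+warnings: 104  n50: 501000  corrected_n50: 35338  error_free: 99.58%
```

`run/errors.gff` then contains one feature per call, e.g. a scaffolding
error spanning the first injected false join:

```
asm	asmcritic	FCD_error_over_gap	30208	30341	0.505269	.	.	Note=Error: FCD failure over gap (scaffolding error)
```

All ten joins are called as errors over their gaps, the deletions appear as
contig errors flanked by `orphan_excess` warnings, and the collapsed repeat
is flagged with a coverage ratio of ~2.1. The drop from N50 501 kb to a
corrected N50 of 35 kb is the contiguity the assembly actually supports;
99.58% of analyzable bases away from the injected errors score 1. On the
matching error-free scenario the same pipeline reports zero error regions
and leaves the N50 untouched.

Outputs per run: `errors.gff` (calls), `summary.tsv` (per-scaffold counts,
N50/corrected N50, error-free fraction), `broken_assembly.fa`,
`break_log.tsv`, `calibration.tsv`, `gc_curve.tsv` and per-base plot files
(`plots/<ref>.score.plot`, `plots/<ref>.fcd_error.plot`, one value per
base, loadable as genome-browser user plots).

Evaluating a real assembly is the same command with your FASTA and a
coordinate-sorted SAM/BAM of *independently* mapped mates (duplicates
marked); an optional short-insert library can be supplied with
`--perfect-alignments` to source the perfect+unique depth.

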