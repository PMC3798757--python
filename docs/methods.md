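# Methods

## Model

The evaluator treats an assembly as correct wherever the mapped read-pair
evidence looks the way a correct sequence would make it look. Two signals
carry almost all of the information:

**Local accuracy.** A base is locally supported when enough reads map over
it uniquely and with their entire length matching (edit distance 0, no
clipping, mapping quality ≥ `min_mapq`). The default requirement is five
such reads. Independent mapping of the two mates is assumed; a mapper that
rescues a mate next to its pair would hide exactly the errors being looked
for.

**Structural consistency.** For a properly paired read pair (same
reference, inward orientation, outer distance inside the calibrated insert
range) the *fragment* is the interval between the outermost read ends. At
each base the observed fragment coverage distribution (FCD) — the fraction
of base-covering fragments also covering each offset in ±W — is compared
with the ideal curve under uniform placement:

    ideal(x) = Σ_L P(L) · max(0, L − |x|) / Σ_L P(L) · L ,

the length weighting arising because a longer fragment is more likely to
cover the focal base. The FCD error is the discrete L1 area between the two
curves divided by the mean insert size (1-base bins; depth normalisation is
inherent in the observed curve being a fraction). W defaults to the 99th
percentile of fragment length — beyond it both curves are ~0.

Near an N-gap no read can map inside the gap, so the ideal curve is
recomputed constructively: enumerate every (length, placement) pair whose
fragment covers the focal base and whose two terminal read footprints
(`read_len` bases at each fragment end) avoid every gap, and count
coverage per offset over the admissible set only. With no gaps in reach
this reduces exactly to the closed form above (oracle-tested by exhaustive
enumeration). The correction is applied whenever a gap lies within one mean
insert of the base.

### Undecidable bases

Three zones are excluded from analysis (`NOT_ANALYZED`) rather than
scored: gaps longer than half the mean insert (no pair of this library can
span them, so the join is unverifiable either way) plus a read-length
shadow on each side; and one curve half-width W at each sequence terminus,
where the coverage ramp of a correct sequence is indistinguishable from an
error signal. These bases are left out of every region call and out of the
error-free denominator.

## Calibration

Library statistics come from the alignments themselves: candidate
inward-facing pairs with outer distance below 4× the median define the
empirical fragment-length histogram; the acceptable "proper" range is its
central 99%. GC bias is handled by a LOWESS line through (window GC, mean
coverage) over gap-free 100 bp windows, binned into 50 GC bins (thin bins
inherit their nearest populated neighbour; the curve is floored at 5% of
the global mean so ratios never divide by ~0). Two curves are kept: one on
inner-fragment coverage (for the relative fragment-coverage track) and one
on read depth (for the collapsed-repeat test, below).

### Depth-standardised FCD error

The raw L1 error of a *correct* base is pure sampling noise and shrinks as
1/√(fragment depth); thresholding the raw value therefore conflates
coverage fluctuations with structural signal. All calibration and calling
operate on the standardised error

    err_std(b) = err(b) · sqrt(cov(b) / mean_cov) ,

whose null level is depth-independent; the raw error is still computed,
plotted and exposed (and tends to 0 with depth, as it should). Structural
errors are O(1) distortions of the curve, so standardisation *increases*
their separation from noise at above-average coverage (e.g. over collapsed
repeats, where it prevents the doubled depth from simulating an FCD
failure).

### Automatic cutoff

Windows of half a mean insert, stepped by half their length (capped at
100,000, seeded uniform subsample beyond), each yield the error value at
which 80% of their bases would fail — the 20th percentile with lower
interpolation, so a constant window yields its constant. The proportion of
failing windows as a function of cutoff is evaluated on a 100-point grid up
to the 99.9th percentile of window cutoffs; the cutoff is the first grid
point, scanning from the largest, where the first and second
finite-difference derivatives (each normalised to maximum magnitude 1)
both have magnitude ≥ 0.05. If the condition is never met the 99th
percentile of window cutoffs is used, with a warning.

This turning-point rule locates the right edge of the *bulk* of the noise
distribution. At moderate fragment depth (tens of fragments per base,
as in the standard scenarios at 30× read coverage) the rule's landing
point sits ~2.5σ into the noise upper tail and would mislabel the top ~1%
of clean windows. The operational cutoff is therefore floored at a
Monte-Carlo null threshold: after calibration the no-error model is fully
specified (uniform fragment starts at the observed rate, fitted length
mixture), so the null distribution of window fail-cutoffs is simulated
directly on gap-free strips (~6,000 windows) and its exponential upper
tail is extrapolated to a survival probability of `alpha / n_windows`
(`alpha = 0.1`) — the level that a genome's worth of clean windows
exceeds with probability ~10%. Unlike any quantile of the real genome's
window cutoffs, the simulated null cannot be contaminated by true errors.
Its main simplification is uniform coverage: genomes with strong
systematic coverage structure (e.g. amplified DNA) will exceed it more
often, which matches the intended reading of such excursions as suspect.

## Calling and scoring

A metric region is reported when an interval of at least the metric's
minimum window length has at least 80% failing bases (inclusive — integer
arithmetic keeps the boundary exact); overlapping qualifying intervals are
merged and the result is trimmed to failing endpoints. The implementation
reduces "every interval" to a prefix-sum/prefix-min scan; an O(n²)
enumeration oracle pins its semantics in the tests. Regions are computed
separately within each maximal analyzable run, so calls never overlap
excluded spans.

Errors: FCD-failure regions (minimum window = mean insert / 2; a region
containing a gap base is a scaffolding error, otherwise a contig error) and
zero-fragment-coverage runs ≥ 10 bases (shorter dropouts at modest depth
are sampling noise). Warnings: orphan or wrong-orientation proportion
> 0.5 on either strand (window 100), clip count > 0.5× depth (single-base
windows — clipping piles up at breakpoints), perfect depth < 5 (window
100), read depth outside [0.25×, 4×] of the mean (window 100), and
collapsed repeats: GC-corrected **read-depth** ratio ≥ 2 for 80% of
≥ 100 bp. Read depth, not fragment coverage, carries the repeat test
because pairs straddling a collapsed tandem-copy junction become
discordant and vanish from fragment coverage (capping its ratio below 2
for units comparable to the insert size), while their reads still align,
clipped, at the copy boundaries.

Score: 1 iff perfect+unique depth ≥ 5 *and* the base passes the FCD test;
otherwise the passing fraction of the eight-test battery (perfect depth,
FCD, depth range, proper/orphan/orientation proportions, clipping, nonzero
inner-fragment coverage). In the pipeline the FCD test fails exactly
inside called FCD/zero-coverage error regions, keeping the score track
consistent with the reported calls; the standalone scorer falls back to
the per-base cutoff comparison. `NOT_ANALYZED` bases are emitted as 0 and
flagged, and are excluded from error-free denominators.

Breaking: every gap inside a scaffolding-error region becomes a split
point (each such join is unsupported); the gap bases are dropped and parts
are named `<name>.1`, `<name>.2`, … left to right. Contig-error regions
(including gapless zero-coverage regions) are replaced by Ns of equal
length for local reassembly by a gap closer. N50 is recomputed on the
pieces.

## The synthetic-data generator

The generator emulates exactly the evidence the evaluator consumes. A truth
genome is i.i.d. sequence at a target GC (default 0.45). Structural edits —
false joins over 100 bp gaps (skipping 10 kb of truth), gapless joins,
deletions, insertions, collapsed tandem repeats — are applied through a
piecewise coordinate map, alongside benign 40 bp scaffold gaps whose
flanking sequence is correct. Benign gaps are deliberately shorter than the
join gaps: with 300 ± 30 fragments and two 100-base reads, a gap needs
fragment ≥ gap + 2·read_len to be spanned, so a 100 bp "correct" gap would
be unspannable by construction and indistinguishable from a false join; at
40 bp the spanning fragment coverage is ~9×.

Pairs are drawn with uniform starts on the truth and normal(300, 30)
lengths truncated at twice the read length; each terminal read maps iff
its footprint lies within one mapped piece and outside every N-gap,
straddles a piece boundary with ≥ 10 anchored bases as a soft-clipped
alignment, and carries MAPQ 60 (0 inside repeat copies, exercising the
uniqueness filter) and NM 0. Output is coordinate-sorted SAM plus a truth
GFF of expected calls and a pair-class census; identical seeds give
byte-identical files.

What the generator does **not** emulate: sequencing errors and
base-quality structure (the signal here is positional), mapper-specific
clip/mismatch idiosyncrasies, optical duplicates, GC-dependent or
amplification-driven coverage unevenness, and diploid heterozygosity.
Passing tests therefore demonstrate correct recovery of positional
structural signals under the stated library geometry, not robustness to
every artifact of real sequencing.

Standard scenarios (used by the tests and the acceptance script): an
error-free 500 kb scaffold with six benign gaps, and a ~500 kb scaffold
with ten false joins over gaps, two 2 kb deletions and one collapsed
repeat (2 → 1 copies of 500 bp), both at 30× read coverage. At this scale
the full pipeline runs in well under a minute; the FCD scan is vectorised
per offset (the count of fragments covering b and b+x is the coverage of
right-truncated fragments, one cumulative sum per offset), with a slow
exact path only near gaps.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_perfect_depth` | 5 | perfect+unique reads for a locally error-free base |
| `min_mapq` | 10 | uniqueness proxy for independent mapping |
| proper insert range | central 99% | acceptable outer distance quantiles |
| `fail_fraction` | 0.8 | failing-base density that reports a region |
| FCD min window | mean insert / 2 | shortest reportable FCD region |
| `min_zero_window` | 10 bases | shortest reportable zero-coverage run |
| `repeat_ratio`, `repeat_window` | 2, 100 bp | collapsed-repeat rule |
| depth range | [0.25×, 4×] mean | read-depth outlier limits |
| `deriv_threshold` | 0.05 | turning-point rule on normalised derivatives |
| W (curve half-width) | 99th pct fragment length | FCD curve support |
| null `alpha` | 0.1 | expected clean-genome false windows at the floor |

All thresholds live in `RunConfig.thresholds` / `LibraryStats.thresholds`
and are overridable.

## Numerical notes and edge cases

- Internal coordinates are 0-based half-open everywhere; SAM and GFF are
  converted at the format boundary only.
- IUPAC ambiguity codes become N on input and may extend gap runs; hard
  clips count as clip events exactly like soft clips.
- The 80% region boundary and the 20th-percentile window statistic use
  integer/lower-interpolation arithmetic so ties behave deterministically;
  the derivative rule carries a 1e-9 relative slack so exact-ratio ties at
  0.05 are inclusive regardless of floating-point path, and derivative
  magnitudes below the smallest value a single window step could produce
  are treated as cancellation noise (a constant failure curve falls back
  to the percentile path).
- Zero-fragment bases inside otherwise analyzable sequence are a distinct
  sentinel: they fail the FCD test for scoring, and only runs ≥ 10 bases
  are reported as errors.
- Degenerate inputs: an empty fragment set marks everything zero-coverage;
  an assembly with a single GC value yields a constant GC curve; a
  constant window yields itself as its fail-cutoff; sequences shorter than
  2W are entirely unanalyzable and scored 0 with the flag cleared.

## Known limitations

- Error classes invisible to a given library geometry stay invisible:
  gaps longer than half the insert are unverifiable, and errors within W
  of sequence ends are excluded by construction.
- The Monte-Carlo null assumes uniform coverage; strongly structured real
  coverage raises the false-warning rate (and is itself reported by the
  depth-outlier warning).
- One evaluation library at a time; a second, short-insert library
  contributes only perfect+unique depth.
- Inward-facing (innie) libraries are first-class; outward mate-pair
  chemistry would need the orientation convention flipped before
  classification.
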