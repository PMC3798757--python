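"""Region calling from per-base tracks and the per-base score."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asmcritic.calibration import LibraryStats
from asmcritic.error_calling import (
    Category,
    RegionCall,
    Severity,
    call_fcd_and_coverage_errors,
    call_metric_regions,
    score_bases,
)
from asmcritic.fcd_engine import FragmentLengthDist
from asmcritic.formats_io import Assembly
from asmcritic.pileup_stats import FCD_NOT_ANALYZED, FCD_ZERO_FRAG, PerBaseTracks


def brute_force_regions(fail, min_window, fail_fraction=0.8):
    """Oracle: for every left end, the union of all qualifying intervals
    sharing it is [i, max qualifying j); merge the union, then trim each
    component to failing endpoints."""
    from fractions import Fraction

    fail = np.asarray(fail, dtype=bool)
    n = fail.size
    frac = Fraction(fail_fraction).limit_denominator(10**6)
    S = np.concatenate(([0], np.cumsum(np.where(fail, 1, 0)))).astype(np.int64)
    covered = np.zeros(n, dtype=bool)
    for i in range(n - min_window + 1):
        js = np.arange(i + min_window, n + 1)
        # integer arithmetic keeps the inclusive boundary exact
        ok = (S[js] - S[i]) * frac.denominator >= frac.numerator * (js - i)
        if ok.any():
            covered[i : int(js[np.flatnonzero(ok)[-1]])] = True
    regions = []
    b = 0
    while b < n:
        if covered[b]:
            e = b
            while e < n and covered[e]:
                e += 1
            idx = np.flatnonzero(fail[b:e])
            if idx.size:
                regions.append((b + int(idx[0]), b + int(idx[-1]) + 1))
            b = e
        else:
            b += 1
    return regions


class TestCallMetricRegions:
    def test_saturated_window(self):
        fail = np.zeros(300, dtype=bool)
        fail[100:200] = True
        assert call_metric_regions(fail, 100) == [(100, 200)]

    def test_density_below_threshold_gives_nothing(self):
        rng = np.random.default_rng(0)
        fail = np.zeros(100, dtype=bool)
        fail[rng.choice(100, size=79, replace=False)] = True
        # 79 fails in a 100-base window: density 0.79 < 0.8
        assert call_metric_regions(fail, 100) == []

    def test_exact_eighty_percent_is_inclusive(self):
        fail = np.zeros(100, dtype=bool)
        fail[:40] = True
        fail[50:90] = True  # exactly 80 of 100, endpoints failing via trim
        regions = call_metric_regions(fail, 100)
        assert regions == [(0, 90)]

    def test_empty_and_allpass(self):
        assert call_metric_regions(np.zeros(500, dtype=bool), 100) == []
        assert call_metric_regions(np.ones(100, dtype=bool), 100) == [(0, 100)]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(100, 1200))
        fail = rng.random(n) < rng.uniform(0.4, 0.95)
        w = int(rng.integers(5, 150))
        assert call_metric_regions(fail, w) == brute_force_regions(fail, w)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(data=st.data())
    def test_matches_brute_force_hypothesis(self, data):
        n = data.draw(st.integers(20, 400))
        p = data.draw(st.floats(0.3, 0.95))
        seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(seed)
        fail = rng.random(n) < p
        w = data.draw(st.integers(2, max(3, n // 2)))
        assert call_metric_regions(fail, w) == brute_force_regions(fail, w)


def make_lib(**kw):
    dist = FragmentLengthDist.from_lengths([300] * 10)
    lib = LibraryStats(
        frag_len_dist=dist,
        mean_insert=300.0,
        insert_range=(250.0, 350.0),
        read_len=100,
        mean_read_depth=30.0,
    )
    lib.fcd_cutoff = kw.pop("fcd_cutoff", 0.3)
    return lib


class TestRegionCallInvariants:
    def test_error_severity_enforced(self):
        with pytest.raises(ValueError):
            RegionCall("s1", 0, 10, Category.FCD_ERROR_CONTIG, Severity.WARNING)
        with pytest.raises(ValueError):
            RegionCall("s1", 0, 10, Category.ORPHAN_EXCESS, Severity.ERROR)

    def test_fcd_region_classification_by_gap_content(self):
        seq = "A" * 2000 + "N" * 40 + "A" * 2000
        assembly = Assembly.from_sequences({"s1": seq})
        tracks = PerBaseTracks(assembly)
        lib = make_lib()
        err = tracks.metric("fcd_error_std")["s1"]
        err[1900:2200] = 1.0  # spans the gap
        err[500:700] = 1.0  # contig interior
        calls = call_fcd_and_coverage_errors(tracks, assembly, lib)
        cats = {(c.start, c.end): c.category for c in calls}
        assert cats[(1900, 2200)] is Category.FCD_ERROR_OVER_GAP
        assert cats[(500, 700)] is Category.FCD_ERROR_CONTIG

    def test_zero_frag_runs_reported_and_short_runs_ignored(self):
        assembly = Assembly.from_sequences({"s1": "A" * 1000})
        tracks = PerBaseTracks(assembly)
        lib = make_lib()
        status = tracks.metric("fcd_status")["s1"]
        status[100:150] = FCD_ZERO_FRAG
        status[300:305] = FCD_ZERO_FRAG  # below the 10-base minimum
        calls = call_fcd_and_coverage_errors(tracks, assembly, lib)
        zero = [c for c in calls if c.category is Category.ZERO_FRAGMENT_COVERAGE]
        assert [(c.start, c.end) for c in zero] == [(100, 150)]

    def test_regions_never_overlap_not_analyzed(self):
        assembly = Assembly.from_sequences({"s1": "A" * 1000})
        tracks = PerBaseTracks(assembly)
        lib = make_lib()
        err = tracks.metric("fcd_error_std")["s1"]
        status = tracks.metric("fcd_status")["s1"]
        err[:] = 1.0
        status[400:600] = FCD_NOT_ANALYZED
        calls = call_fcd_and_coverage_errors(tracks, assembly, lib)
        for c in calls:
            assert c.end <= 400 or c.start >= 600


class TestScoreBases:
    def _tracks(self, n=400):
        assembly = Assembly.from_sequences({"s1": "A" * n})
        tracks = PerBaseTracks(assembly)
        # a healthy default state: depth 30, all proper, perfect depth 10
        for name, value in [
            ("read_depth_fwd", 15.0),
            ("read_depth_rev", 15.0),
            ("prop_proper_fwd", 1.0),
            ("prop_proper_rev", 1.0),
            ("perfect_unique_depth", 10.0),
            ("inner_frag_cov", 12.0),
        ]:
            tracks.metric(name)["s1"][:] = value
        return tracks

    def test_perfect_and_fcd_give_one(self):
        tracks = self._tracks()
        lib = make_lib()
        tracks.metric("perfect_unique_depth")["s1"][:] = 5.0  # exactly at limit
        score_bases(tracks, lib)
        assert np.all(tracks.get("score", "s1") == 1.0)

    def test_every_test_failing_gives_zero(self):
        assembly = Assembly.from_sequences({"s1": "A" * 100})
        tracks = PerBaseTracks(assembly)
        lib = make_lib()
        tracks.metric("fcd_status")["s1"][:] = FCD_ZERO_FRAG  # T2, T8 fail
        tracks.metric("prop_orphan_fwd")["s1"][:] = 1.0  # T4, T5 fail
        tracks.metric("prop_wrong_orient_rev")["s1"][:] = 1.0  # T6 fails
        tracks.metric("read_depth_fwd")["s1"][:] = 500.0  # T3 fails (outlier)
        tracks.metric("clip_count")["s1"][:] = 400.0  # T7 fails
        score_bases(tracks, lib)  # T1 fails: perfect depth 0
        assert np.all(tracks.get("score", "s1") == 0.0)

    def test_seven_of_eight(self):
        tracks = self._tracks()
        lib = make_lib()
        tracks.metric("perfect_unique_depth")["s1"][:] = 4.0  # only T1 fails
        score_bases(tracks, lib)
        assert np.all(tracks.get("score", "s1") == pytest.approx(7 / 8))

    def test_not_analyzed_scores_zero_with_flag(self):
        tracks = self._tracks()
        lib = make_lib()
        tracks.metric("fcd_status")["s1"][50:80] = FCD_NOT_ANALYZED
        score_bases(tracks, lib)
        assert np.all(tracks.get("score", "s1")[50:80] == 0.0)
        assert np.all(tracks.get("score", "s1")[:50] == 1.0)

    def test_region_based_fcd_test(self):
        tracks = self._tracks()
        lib = make_lib()
        tracks.metric("fcd_error_std")["s1"][:] = 10.0  # everywhere above cutoff
        regions = [RegionCall("s1", 100, 200, Category.FCD_ERROR_CONTIG,
                              Severity.ERROR)]
        score_bases(tracks, lib, fcd_fail_regions=regions)
        score = tracks.get("score", "s1")
        assert np.all(score[100:200] == pytest.approx(7 / 8))
        assert np.all(score[:100] == 1.0)  # outside regions T2 passes

    def test_score_one_implies_first_two_tests(self):
        rng = np.random.default_rng(9)
        tracks = self._tracks()
        lib = make_lib()
        tracks.metric("perfect_unique_depth")["s1"][:] = rng.integers(0, 10, 400)
        tracks.metric("fcd_error_std")["s1"][:] = rng.uniform(0, 0.6, 400)
        score_bases(tracks, lib)
        score = tracks.get("score", "s1")
        ones = score == 1.0
        assert np.all(tracks.get("perfect_unique_depth", "s1")[ones] >= 5)
        assert np.all(tracks.get("fcd_error_std", "s1")[ones] <= lib.fcd_cutoff)
        assert score.min() >= 0 and score.max() <= 1
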