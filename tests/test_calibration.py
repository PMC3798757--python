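"""Library statistics, GC-bias fitting and the automatic FCD-error cutoff."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asmcritic import calibration
from asmcritic.calibration import (
    CalibrationError,
    GCBiasCurve,
    choose_fcd_cutoff,
    estimate_library_stats,
    fit_gc_bias,
    window_fail_cutoff,
)
from asmcritic.fcd_engine import FragmentLengthDist
from asmcritic.formats_io import Assembly
from asmcritic.pileup_stats import PerBaseTracks

from conftest import make_pair, make_record


def normal_pairs(n, mean=300.0, sd=30.0, read_len=100, seed=0, genome=1_000_000):
    rng = np.random.default_rng(seed)
    lengths = np.maximum(np.rint(rng.normal(mean, sd, n)).astype(int), 2 * read_len)
    starts = rng.integers(0, genome - lengths.max(), n)
    out = []
    for i, (s, L) in enumerate(zip(starts, lengths)):
        out.extend(make_pair(int(s), int(s) + read_len,
                             int(s) + int(L) - read_len, int(s) + int(L),
                             name=f"p{i}"))
    return out


class TestEstimateLibraryStats:
    def test_normal_insert_recovery(self):
        asm = Assembly.from_sequences({"s1": "A" * 100})
        lib = estimate_library_stats(normal_pairs(50_000), asm, min_pairs=10_000)
        assert lib.mean_insert == pytest.approx(300, abs=2)
        assert 200 < lib.insert_range[0] < 250 < 350 < lib.insert_range[1] < 400
        assert lib.read_len == 100

    def test_degenerate_constant_insert(self):
        asm = Assembly.from_sequences({"s1": "A" * 100})
        pairs = []
        for i in range(300):
            pairs.extend(make_pair(i, i + 100, i + 150, i + 250, name=f"p{i}"))
        lib = estimate_library_stats(pairs, asm, min_pairs=100)
        assert lib.insert_range == (250.0, 250.0)
        assert lib.mean_insert == 250.0

    def test_orphans_only_rejected(self):
        asm = Assembly.from_sequences({"s1": "A" * 100})
        orphans = [
            make_record(query_name=f"o{i}", ref_start=i, ref_end=i + 100,
                        mate_mapped=False)
            for i in range(200)
        ]
        with pytest.raises(CalibrationError):
            estimate_library_stats(orphans, asm, min_pairs=100)


def tracks_with_cov(assembly, cov_fn):
    tracks = PerBaseTracks(assembly)
    for ref, n in tracks.lengths.items():
        tracks.metric("inner_frag_cov")[ref][:] = cov_fn(np.arange(n))
    return tracks


class TestFitGcBias:
    def _assembly(self, seed=0, n=200_000):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=n))
        return Assembly.from_sequences({"s1": seq})

    def test_unbiased_coverage_gives_flat_curve(self):
        assembly = self._assembly()
        rng = np.random.default_rng(1)
        tracks = tracks_with_cov(assembly, lambda x: rng.poisson(30, x.size))
        curve = fit_gc_bias(tracks, assembly)
        populated = (curve.values > 1.6) & (curve.values < 100)
        assert np.all(np.abs(curve.values[populated] - 30) < 3)

    def test_linear_bias_recovery(self):
        """cov = 10 + 40*GC recovered within 10% across populated bins."""
        assembly = self._assembly(seed=2)
        from asmcritic.pileup_stats import per_base_gc

        gc = per_base_gc(assembly, "s1", window=100)
        tracks = tracks_with_cov(assembly, lambda x: 10 + 40 * gc)
        curve = fit_gc_bias(tracks, assembly)
        mids = 0.5 * (curve.bin_edges[:-1] + curve.bin_edges[1:])
        # only judge bins the genome actually populates densely
        idx = (mids > 0.35) & (mids < 0.65)
        expected = 10 + 40 * mids[idx]
        assert np.all(np.abs(curve.values[idx] - expected) / expected < 0.10)

    def test_empty_bins_inherit_nearest(self):
        assembly = self._assembly(seed=3)
        tracks = tracks_with_cov(assembly, lambda x: np.full(x.size, 25.0))
        curve = fit_gc_bias(tracks, assembly)
        # extreme-GC bins are unpopulated in a 50%-GC genome yet defined
        assert curve.expected(np.array([0.0]))[0] > 0
        assert curve.expected(np.array([0.98]))[0] > 0

    def test_single_gc_value_gives_constant_curve(self):
        assembly = Assembly.from_sequences({"s1": "AT" * 50_000})
        tracks = tracks_with_cov(assembly, lambda x: np.full(x.size, 12.0))
        curve = fit_gc_bias(tracks, assembly)
        assert np.allclose(curve.values, 12.0)

    def test_floor_at_five_percent_of_mean(self):
        curve = GCBiasCurve.constant(30.0)
        assert curve.expected(np.array([0.5]))[0] == 30.0


class TestWindowFailCutoff:
    def test_decile_example(self):
        values = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
        assert window_fail_cutoff(values) == pytest.approx(0.2)

    def test_constant_window_yields_constant(self):
        assert window_fail_cutoff([0.5] * 7) == 0.5

    def test_sparse_tail_example(self):
        assert window_fail_cutoff([0, 0, 0, 0, 1]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            window_fail_cutoff([])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(values=st.lists(st.floats(0, 10, allow_nan=False), min_size=1,
                           max_size=50),
           shift=st.floats(0, 5))
    def test_permutation_invariant_and_monotone(self, values, shift):
        base = window_fail_cutoff(values)
        assert window_fail_cutoff(list(reversed(values))) == base
        assert window_fail_cutoff([v + shift for v in values]) >= base


def brute_force_cutoff(window_cutoffs, grid_size=100, thr=0.05,
                       grid_quantile=0.999):
    """Independent transcription of the derivative scan with plain loops."""
    arr = sorted(float(x) for x in window_cutoffs)
    n = len(arr)
    upper = float(np.percentile(arr, 100 * grid_quantile))
    if upper <= 0:
        return float(np.percentile(arr, 99))
    t = [upper * i / (grid_size - 1) for i in range(grid_size)]
    p = []
    for ti in t:
        p.append(sum(1 for v in arr if v >= ti) / n)

    def grad(y):
        g = [0.0] * len(y)
        for i in range(len(y)):
            if i == 0:
                g[i] = (y[1] - y[0]) / (t[1] - t[0])
            elif i == len(y) - 1:
                g[i] = (y[-1] - y[-2]) / (t[-1] - t[-2])
            else:
                g[i] = (y[i + 1] - y[i - 1]) / (t[i + 1] - t[i - 1])
        return g

    def normalize(g, floor):
        g = [0.0 if abs(x) < 1e-3 * floor else x for x in g]
        m = max(abs(x) for x in g)
        return [x / m for x in g] if m > 0 else g

    h = t[1] - t[0]
    d1 = normalize(grad(p), 1.0 / n / (2 * h))
    d2 = normalize(grad(grad(p)), 1.0 / n / h**2)
    eps = 1e-9 * thr  # inclusive at exact-ratio threshold ties
    for i in range(grid_size - 1, -1, -1):
        if abs(d1[i]) >= thr - eps and abs(d2[i]) >= thr - eps:
            return t[i]
    return float(np.percentile(arr, 99))


class TestChooseFcdCutoff:
    def test_matches_brute_force_on_random_samples(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            kind = rng.integers(0, 3)
            n = int(rng.integers(1000, 3000))
            if kind == 0:
                cuts = rng.uniform(0, 0.2, n)
            elif kind == 1:
                cuts = np.concatenate(
                    [rng.uniform(0, 0.2, n // 2), rng.uniform(0, 0.05, n - n // 2)]
                )
            else:
                cuts = np.abs(rng.normal(0.1, 0.03, n))
            got = choose_fcd_cutoff(cuts, min_windows=100)
            want = brute_force_cutoff(cuts)
            assert got == pytest.approx(want, abs=1e-12)

    def test_step_distribution_selects_near_step(self):
        cuts = np.full(2000, 0.3)
        got = choose_fcd_cutoff(cuts, min_windows=100)
        # grid resolution around the step of P(t) at 0.3
        assert got == pytest.approx(0.3, abs=0.3 / 99 + 1e-12)

    def test_flat_distribution_falls_back_to_percentile(self):
        cuts = np.zeros(2000)
        got = choose_fcd_cutoff(cuts, min_windows=100)
        assert got == 0.0

    def test_too_few_windows_rejected(self):
        with pytest.raises(CalibrationError):
            choose_fcd_cutoff([0.1] * 10, min_windows=1000)


class TestNullThreshold:
    def test_clears_clean_noise(self, clean_run):
        """The Monte-Carlo null threshold sits above every window cutoff
        sampled from genuinely error-free data."""
        res = clean_run["result"]
        cuts = calibration.sample_window_cutoffs(res.tracks, res.lib, seed=0)
        floor = calibration.null_window_cutoff_threshold(
            res.lib, len(cuts), seed=0
        )
        assert floor > float(cuts.max())
        assert res.lib.fcd_cutoff > float(cuts.max())

    def test_separates_junction_windows(self, error_run):
        """Windows over injected junctions exceed the chosen cutoff."""
        res = error_run["result"]
        err = res.tracks.get("fcd_error_std", "asm")
        status = res.tracks.get("fcd_status", "asm")
        joins = [c for c in error_run["truth_calls"]
                 if c.category.value == "FCD_error_over_gap"]
        exceed = 0
        for tc in joins:
            lo, hi = tc.start - 150, tc.end + 150
            window = err[lo:hi][status[lo:hi] == 0]
            if window.size and window.max() > res.lib.fcd_cutoff:
                exceed += 1
        assert exceed >= 9
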