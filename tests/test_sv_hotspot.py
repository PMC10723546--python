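"""Binning, background GLM, PCF and hotspot-calling tests with independent oracles."""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from tumourevo.cohort_io import InvalidInputError
from tumourevo.sv_hotspot import (
    BinnedTrack,
    bin_breakpoints,
    call_hotspots,
    empty_track,
    exclude_fragile,
    fit_background,
    flag_fragile,
    pcf_segment,
    pcf_segment_values,
)
from tumourevo.sv_hotspot.pcf import ConstantSegment

from conftest import make_sv

GENOME = [("chr1", 2_000_000, 900_000), ("chr2", 1_000_000, 400_000)]


class TestBinning:
    def test_deletion_both_ends_one_bin(self):
        svs = [make_sv(pos1=10_000, pos2=20_000)]
        track = bin_breakpoints(svs, GENOME, bin_width=100_000)
        assert track.values["chr1"][0] == 2

    def test_translocation_two_chromosomes(self):
        svs = [make_sv(pos1=150_000, chrom2="chr2", pos2=250_000, sv_class="translocation")]
        track = bin_breakpoints(svs, GENOME, bin_width=100_000)
        assert track.values["chr1"][1] == 1
        assert track.values["chr2"][2] == 1

    def test_total_conservation(self):
        rng = np.random.default_rng(0)
        svs = []
        for _ in range(200):
            c1, c2 = rng.choice(["chr1", "chr2"], size=2)
            lengths = dict((c, l) for c, l, _ in GENOME)
            p1 = int(rng.integers(1, lengths[c1] + 1))
            p2 = int(rng.integers(1, lengths[c2] + 1))
            cls = "translocation" if c1 != c2 else "deletion"
            svs.append(make_sv(chrom1=c1, pos1=p1, chrom2=c2, pos2=p2, sv_class=cls))
        track = bin_breakpoints(svs, GENOME, bin_width=50_000)
        assert track.total == 2 * len(svs)

    def test_out_of_range_breakpoint(self):
        with pytest.raises(InvalidInputError):
            bin_breakpoints([make_sv(pos1=10, pos2=3_000_000)], GENOME)


class TestBackgroundFit:
    def test_intercept_only_mean(self):
        track = empty_track(GENOME, bin_width=100_000)
        track.values["chr1"][:] = [3, 1, 4, 1, 5, 9, 2, 6, 5, 3, 5, 8, 9, 7, 9, 3, 2, 3, 8, 4]
        track.values["chr2"][:] = 2
        expected, _ = fit_background(track)
        assert np.allclose(expected.concat(), track.concat().mean())

    def test_total_preserved(self):
        rng = np.random.default_rng(1)
        counts = empty_track(GENOME, bin_width=100_000)
        cov = empty_track(GENOME, bin_width=100_000)
        for chrom in counts.values:
            cov.values[chrom] = rng.standard_normal(cov.values[chrom].size)
            counts.values[chrom] = rng.poisson(3.0, counts.values[chrom].size).astype(float)
        expected, _ = fit_background(counts, [cov])
        assert expected.total == pytest.approx(counts.total, rel=1e-6)

    def test_beta_recovery(self):
        # counts from one covariate with known effect 0.7 over 30,000 bins
        rng = np.random.default_rng(2)
        n = 30_000
        z = rng.standard_normal(n)
        lam = np.exp(np.log(2.0) + 0.7 * z)
        counts = BinnedTrack(1000, {"chr1": rng.poisson(lam).astype(float)})
        cov = BinnedTrack(1000, {"chr1": z})
        _, beta = fit_background(counts, [cov])
        assert beta[1] == pytest.approx(0.7, abs=0.05)

    def test_constant_covariate_is_inert(self):
        rng = np.random.default_rng(3)
        counts = empty_track(GENOME, bin_width=100_000)
        for chrom in counts.values:
            counts.values[chrom] = rng.poisson(4.0, counts.values[chrom].size).astype(float)
        flat = empty_track(GENOME, bin_width=100_000)
        for chrom in flat.values:
            flat.values[chrom][:] = 7.0
        base, _ = fit_background(counts)
        with_flat, _ = fit_background(counts, [flat])
        assert np.allclose(base.concat(), with_flat.concat(), atol=1e-6)

    def test_grid_mismatch_rejected(self):
        counts = empty_track(GENOME, bin_width=100_000)
        cov = empty_track(GENOME, bin_width=50_000)
        with pytest.raises(InvalidInputError):
            fit_background(counts, [cov])


def dp_oracle(x, gamma, min_bins):
    """Independent recursive-memoized DP over changepoints."""
    x = np.asarray(x, dtype=float)
    n = x.size

    def seg_cost(i, j):
        seg = x[i:j]
        return float(np.sum((seg - seg.mean()) ** 2))

    @lru_cache(maxsize=None)
    def solve(i):
        if i == n:
            return 0.0, ()
        best = (np.inf, ())
        for j in range(i + min_bins, n + 1):
            tail_cost, tail_cuts = solve(j)
            total = seg_cost(i, j) + gamma + tail_cost
            if total < best[0]:
                best = (total, ((i, j),) + tail_cuts)
        return best

    cost, cuts = solve(0)
    return cost, list(cuts)


def brute_force_oracle(x, gamma, min_bins):
    """Exhaustive enumeration of all segmentations (tiny n only)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    best = (np.inf, None)
    for k in range(n):  # k interior cut points
        for cuts in combinations(range(1, n), k):
            bounds = [0, *cuts, n]
            if any(b - a < min_bins for a, b in zip(bounds, bounds[1:])):
                continue
            cost = sum(
                float(np.sum((x[a:b] - x[a:b].mean()) ** 2)) for a, b in zip(bounds, bounds[1:])
            ) + gamma * (len(bounds) - 1)
            if cost < best[0]:
                best = (cost, bounds)
    return best


def segmentation_cost(x, segments, gamma):
    return sum(
        float(np.sum((np.asarray(x[a:b]) - np.mean(x[a:b])) ** 2)) for a, b, _ in segments
    ) + gamma * len(segments)


class TestPCF:
    def test_constant_input_single_segment(self):
        segs = pcf_segment_values(np.full(100, 2.5), gamma=1.0)
        assert len(segs) == 1
        assert segs[0] == (0, 100, 2.5)

    def test_step_signal_changepoint_recovered(self):
        x = np.concatenate([np.zeros(100), np.full(100, 5.0)])
        segs = pcf_segment_values(x, gamma=1.0)
        assert [(a, b) for a, b, _ in segs] == [(0, 100), (100, 200)]
        assert segs[0][2] == 0.0 and segs[1][2] == 5.0

    def test_gamma_limits(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(50)
        assert len(pcf_segment_values(x, gamma=1e9)) == 1
        assert len(pcf_segment_values(x, gamma=1e-9, min_bins=1)) == 50

    def test_matches_recursive_dp_oracle(self):
        rng = np.random.default_rng(5)
        for trial in range(10):
            n = int(rng.integers(20, 200))
            x = np.repeat(rng.normal(0, 3, size=4), n // 4 + 1)[:n] + rng.standard_normal(n) * 0.3
            gamma = float(rng.uniform(0.5, 10))
            segs = pcf_segment_values(x, gamma, min_bins=2)
            cost = segmentation_cost(x, segs, gamma)
            oracle_cost, _ = dp_oracle(tuple(x), gamma, 2)
            assert cost == pytest.approx(oracle_cost, abs=1e-8)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(6)
        for trial in range(5):
            x = rng.normal(0, 2, size=10)
            gamma = float(rng.uniform(0.5, 5))
            segs = pcf_segment_values(x, gamma, min_bins=2)
            cost = segmentation_cost(x, segs, gamma)
            brute_cost, _ = brute_force_oracle(x, gamma, 2)
            assert cost == pytest.approx(brute_cost, abs=1e-8)

    def test_chromosome_order_invariance(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal(40)
        b = rng.standard_normal(30)
        t1 = BinnedTrack(1000, {"chr1": a, "chr2": b})
        t2 = BinnedTrack(1000, {"chr2": b, "chr1": a})
        s1 = pcf_segment(t1, gamma=2.0)
        s2 = pcf_segment(t2, gamma=2.0)
        assert sorted((s.chrom, s.start_bin, s.end_bin) for s in s1) == sorted(
            (s.chrom, s.start_bin, s.end_bin) for s in s2
        )


class TestHotspotCalling:
    @staticmethod
    def _tracks(obs, exp):
        return (
            BinnedTrack(100_000, {"chr1": np.asarray(obs, dtype=float)}),
            BinnedTrack(100_000, {"chr1": np.asarray(exp, dtype=float)}),
        )

    def test_null_landscape_no_hotspots(self):
        counts, expected = self._tracks([3.0] * 50, [3.0] * 50)
        segs = [ConstantSegment("chr1", 0, 50, 1.0)]
        assert call_hotspots(segs, counts, expected) == []

    def test_poisson_tail_matches_series_sum(self):
        counts, expected = self._tracks([30.0], [3.0])
        segs = [ConstantSegment("chr1", 0, 1, 10.0)]
        (hotspot,) = call_hotspots(segs, counts, expected)
        # direct summation oracle for P(X >= 30 | 3)
        from math import factorial

        k = np.arange(0, 30)
        oracle = 1.0 - float(np.sum(np.exp(-3.0) * 3.0**k / [factorial(int(i)) for i in k]))
        assert hotspot.p_value == pytest.approx(oracle, rel=1e-10)

    def test_monotone_in_fdr(self):
        rng = np.random.default_rng(8)
        exp = np.full(100, 2.0)
        obs = rng.poisson(2.0, 100).astype(float)
        obs[10:13] = 20.0
        counts, expected = self._tracks(obs, exp)
        segs = [ConstantSegment("chr1", i, i + 1, obs[i] / 2.0) for i in range(100)]
        n_called = [
            len(call_hotspots(segs, counts, expected, fdr=f)) for f in (0.25, 0.05, 0.01, 0.001)
        ]
        assert n_called == sorted(n_called, reverse=True)

    def test_rate_ratio_threshold(self):
        counts, expected = self._tracks([40.0], [25.0])
        segs = [ConstantSegment("chr1", 0, 1, 40 / 25)]
        assert call_hotspots(segs, counts, expected, min_rate_ratio=2.0) == []


class TestFragileFlagging:
    def _hotspot(self, chrom="chr1", start=0, end=1_000_000):
        from tumourevo.sv_hotspot import HotspotSegment

        return HotspotSegment(
            chrom=chrom, start=start, end=end, n_bins=10,
            observed_breakpoints=50, expected_breakpoints=5.0,
            rate_ratio=10.0, p_value=1e-10, q_value=1e-8,
        )

    def test_requires_a_source(self):
        with pytest.raises(InvalidInputError):
            flag_fragile([self._hotspot()])

    def test_empty_resources_no_flags(self):
        flagged = flag_fragile([self._hotspot()], fragile_intervals=[])
        assert not flagged[0].fragile_flag

    def test_listed_site_flagged(self):
        flagged = flag_fragile(
            [self._hotspot()], fragile_intervals=[("chr1", 500_000, 700_000)]
        )
        assert flagged[0].fragile_flag and flagged[0].flag_reason == "listed-site"

    def test_large_late_gene_flagged(self):
        values = np.full(20, 10.0)
        values[1:8] = 0.0  # latest-replicating stretch hosting the gene
        rep = BinnedTrack(100_000, {"chr1": values})
        genes = [("FHIT-like", "chr1", 100_000, 800_000)]
        flagged = flag_fragile(
            [self._hotspot()], fragile_intervals=[], large_genes=genes, replication_track=rep
        )
        assert flagged[0].fragile_flag
        assert "large-late-gene" in flagged[0].flag_reason

    def test_exclusion_arithmetic(self):
        hotspots = [self._hotspot(start=i * 2_000_000, end=i * 2_000_000 + 1_000_000)
                    for i in range(37)]
        fragile = [("chr1", i * 2_000_000, i * 2_000_000 + 500_000) for i in range(10)]
        flagged = flag_fragile(hotspots, fragile_intervals=fragile)
        assert sum(h.fragile_flag for h in flagged) == 10
        assert len(exclude_fragile(flagged)) == 27
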