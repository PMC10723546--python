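"""Multiplicity, molecular/chronological timing and ordering tests."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from tumourevo.cohort_io import CopyNumberSegment, InvalidInputError
from tumourevo.event_timing import (
    RateModel,
    UntimeableError,
    assign_multiplicity,
    chronological_lead_time,
    clonality_odds_ratio,
    driver_clonality_or,
    expected_vaf,
    molecular_time_gain,
    molecular_time_of_lead,
    relative_event_ordering,
    time_wgd,
)
from tumourevo.synthetic_cohort import GainSpec, SimulationConfig, simulate_sample

from conftest import make_sample, make_variant


def seg(major, minor, chrom="chr1", start=1, end=1_000_000):
    return CopyNumberSegment(chrom, start, end, major, minor)


class TestAssignMultiplicity:
    def test_likelihood_grid_oracle(self):
        # rho=1, state (2,1), VAF=2/3 at depth 300: oracle over the full grid
        v = make_variant(pos=100, ref_depth=100, alt_depth=200)
        segment = seg(2, 1)
        call = assign_multiplicity(v, segment, purity=1.0)
        # oracle: evaluate binomial likelihood for every candidate m directly
        best = max(
            range(1, 3),
            key=lambda m: stats.binom.logpmf(200, 300, expected_vaf(m, 1.0, 3)),
        )
        assert call.best_multiplicity == best == 2
        assert call.clonal

    def test_diploid_half_vaf(self):
        v = make_variant(pos=100, ref_depth=150, alt_depth=150)
        call = assign_multiplicity(v, seg(1, 1), purity=1.0)
        assert call.best_multiplicity == 1
        assert call.ccf_estimate == pytest.approx(1.0)
        assert call.clonal

    def test_subclonal_detected(self):
        # rho=0.5, (1,1), VAF=0.05 at depth 500 -> ccf ~= 0.2, CI excludes 1
        v = make_variant(pos=100, ref_depth=475, alt_depth=25)
        call = assign_multiplicity(v, seg(1, 1), purity=0.5)
        assert not call.clonal
        assert call.ccf_estimate == pytest.approx(0.2, abs=0.02)
        # oracle: exact binomial CI scaled to CCF space
        lo, hi = stats.beta.ppf([0.025, 0.975], [25, 26], [476, 475])
        factor = (0.5 * 2 + 2 * 0.5) / (0.5 * 1)
        assert call.ccf_ci == pytest.approx((lo * factor, hi * factor), rel=1e-6)
        assert hi * factor < 1

    def test_variant_outside_segment_rejected(self):
        v = make_variant(chrom="chr2", pos=100)
        with pytest.raises(InvalidInputError):
            assign_multiplicity(v, seg(1, 1), purity=1.0)

    def test_zero_copy_segment_untimeable(self):
        v = make_variant(pos=100)
        with pytest.raises(UntimeableError):
            assign_multiplicity(v, seg(0, 0), purity=1.0)


class TestMolecularTime:
    def test_no_mult2_time_zero(self):
        res = molecular_time_gain(50, 0, "2+1", rng=0)
        assert res.molecular_time == 0.0

    def test_all_pre_event_2plus0(self):
        res = molecular_time_gain(0, 40, "2+0", rng=0)
        assert res.molecular_time == 1.0

    def test_point_estimate_formulas(self):
        assert molecular_time_gain(30, 10, "2+1", rng=0).molecular_time == pytest.approx(0.6)
        assert molecular_time_gain(30, 10, "2+0", rng=0).molecular_time == pytest.approx(0.4)
        assert molecular_time_gain(30, 10, "2+2", rng=0).molecular_time == pytest.approx(0.4)

    def test_insufficient_mutations_not_guessed(self):
        with pytest.raises(UntimeableError):
            molecular_time_gain(5, 5, "2+1")

    def test_simulation_recovery_2plus1(self):
        # forward simulate count pairs at t=0.6 and check the estimator mean
        rng = np.random.default_rng(0)
        mu, t = 100.0, 0.6
        t_hats = []
        for _ in range(500):
            n2 = rng.poisson(mu * t)
            n1 = rng.poisson(mu * (3 - 2 * t))
            t_hats.append(molecular_time_gain(n1, n2, "2+1", rng=1).molecular_time)
        assert 0.58 <= np.mean(t_hats) <= 0.62

    def test_scale_invariance_in_mu(self):
        rng = np.random.default_rng(1)
        means = {}
        for mu in (50.0, 100.0):
            t_hats = []
            for _ in range(400):
                n2 = rng.poisson(mu * 0.5)
                n1 = rng.poisson(2 * mu * 0.5)
                t_hats.append(molecular_time_gain(n1, n2, "2+0", rng=2).molecular_time)
            means[mu] = np.mean(t_hats)
        assert means[50.0] == pytest.approx(means[100.0], abs=0.02)

    def test_bootstrap_ci_brackets_estimate(self):
        res = molecular_time_gain(120, 60, "2+1", rng=3)
        assert res.ci_low <= res.molecular_time <= res.ci_high


class TestTimeWgd:
    def _wgd_sample(self, seed=0, t=0.7):
        config = SimulationConfig(
            n_samples=1,
            genome=[("chr1", 10_000_000, 4_000_000)],
            purity_range=(1.0, 1.0),
            subclonal_fraction=0.0,
            sv_background_rate=0.0,
            context_rates={"ACA:C>T": 5e-6},  # mu = 50/copy over 10 Mb
            wgd_fraction=1.0,
            wgd_time=t,
            depth_mean=120.0,
            seed=seed,
        )
        return simulate_sample(config, 0)[0]

    def test_non_wgd_rejected(self):
        sample = make_sample(segments=[seg(1, 1, end=10_000_000)])
        with pytest.raises(InvalidInputError):
            time_wgd(sample)

    def test_all_mult2_time_one(self):
        variants = [
            make_variant(pos=1000 + i, ref_depth=50, alt_depth=50) for i in range(30)
        ]  # VAF 0.5 at (2,2), rho=1 -> m=2
        sample = make_sample(segments=[seg(2, 2, end=10_000_000)], variants=variants)
        res = time_wgd(sample, rng=0)
        assert res.molecular_time == 1.0

    def test_recovery_and_coverage(self):
        hits = 0
        errors = []
        n_seeds = 40
        for s in range(n_seeds):
            sample = self._wgd_sample(seed=s)
            res = time_wgd(sample, rng=s)
            errors.append(abs(res.molecular_time - 0.7))
            if res.ci_low - 0.02 <= 0.7 <= res.ci_high + 0.02:
                hits += 1
        assert np.mean(errors) <= 0.06
        assert hits / n_seeds >= 0.85

    def test_pooling_matches_weighted_combination(self):
        # two (2,2) segments: pooled estimate equals estimate from summed counts
        variants = []
        pos = 0
        for n, vaf in ((30, 0.5), (20, 0.25)):  # m=2 and m=1 at rho=1, (2,2)
            for _ in range(n):
                pos += 1
                variants.append(
                    make_variant(pos=pos, ref_depth=int(400 * (1 - vaf)), alt_depth=int(400 * vaf))
                )
        sample = make_sample(segments=[seg(2, 2, end=10_000_000)], variants=variants)
        res = time_wgd(sample, rng=0)
        assert res.n1 == 20 and res.n2 == 30
        assert res.molecular_time == pytest.approx(2 * 30 / (20 + 2 * 30))


class TestChronology:
    def test_constant_rate_closed_form(self):
        model = RateModel(clock_rate=0.1, acceleration=1.0, initiation_lead=0.0)
        assert chronological_lead_time(0.5, 60.0, model) == pytest.approx(30.0)

    def test_t_one_lead_zero(self):
        model = RateModel()
        assert chronological_lead_time(1.0, 60.0, model) == pytest.approx(0.0)

    def test_numeric_inversion_oracle(self):
        # A=60, tau=10, a=5, r0=0.1, t=0.8: invert the cumulative-rate function numerically
        from scipy.optimize import brentq

        model = RateModel(clock_rate=0.1, acceleration=5.0, initiation_lead=10.0)
        age, t = 60.0, 0.8

        def cumulative(g):
            if g <= age - 10.0:
                return 0.1 * g
            return 0.1 * (age - 10.0) + 5.0 * 0.1 * (g - (age - 10.0))

        B = cumulative(age)
        g = brentq(lambda x: cumulative(x) - t * B, 0, age)
        assert chronological_lead_time(t, age, model) == pytest.approx(age - g, abs=1e-9)

    def test_inverse_round_trip(self):
        model = RateModel(clock_rate=0.05, acceleration=5.0, initiation_lead=12.0)
        for lead in (0.0, 5.0, 10.0, 30.0, 59.0):
            t = molecular_time_of_lead(lead, 60.0, model)
            assert chronological_lead_time(t, 60.0, model) == pytest.approx(lead, abs=1e-9)

    def test_burden_rescaling(self):
        model = RateModel(clock_rate=0.05, acceleration=1.0, initiation_lead=0.0)
        # burden twice the model-implied value: clock rescales, constant-rate
        # answer unchanged because t is burden-relative
        lead = chronological_lead_time(0.5, 60.0, model, burden_per_mb=6.0)
        assert lead == pytest.approx(30.0)


class TestClonalityOR:
    def test_background_split_or_one(self):
        odds, _ = clonality_odds_ratio(50, 50, 200, 200)
        assert odds == pytest.approx(1.0, abs=0.01)

    def test_haldane_correction_arithmetic(self):
        odds, _ = clonality_odds_ratio(10, 0, 100, 100)
        assert odds == pytest.approx((10.5 / 0.5) / (100.5 / 100.5))

    def test_label_swap_inverts(self):
        o1, _ = clonality_odds_ratio(30, 10, 100, 150)
        o2, _ = clonality_odds_ratio(10, 30, 150, 100)
        assert o1 == pytest.approx(1 / o2)

    def test_cohort_wrapper(self):
        samples = [
            make_sample(
                sample_id=f"S{i}",
                variants=[
                    make_variant(pos=1, gene="VHL", clonal=True),
                    make_variant(pos=2, gene="OTHER", clonal=(i % 2 == 0)),
                ],
            )
            for i in range(10)
        ]
        odds, ci = driver_clonality_or(samples, "VHL")
        assert odds > 1
        assert ci[0] < odds < ci[1]

    def test_absent_gene(self):
        from tumourevo.event_timing import AbsentGeneError

        with pytest.raises(AbsentGeneError):
            driver_clonality_or([make_sample()], "NOPE")


class TestOrdering:
    def test_unanimous_winner_first(self):
        pairs = [("A", "B")] * 20
        ranking = relative_event_ordering(pairs)
        assert ranking[0][0] == "A"

    def test_cyclic_evidence_equal_strengths(self):
        pairs = [("A", "B")] * 5 + [("B", "C")] * 5 + [("C", "A")] * 5
        ranking = relative_event_ordering(pairs)
        strengths = [s for _, s, _ in ranking]
        assert max(strengths) - min(strengths) < 1e-6

    def test_duplication_invariance(self):
        pairs = [("A", "B"), ("B", "C"), ("A", "C"), ("A", "B")]
        r1 = relative_event_ordering(pairs)
        r2 = relative_event_ordering(pairs * 2)
        assert [e for e, _, _ in r1] == [e for e, _, _ in r2]

    def test_disconnected_components_warn(self):
        with pytest.warns(UserWarning, match="disconnected"):
            ranking = relative_event_ordering([("A", "B"), ("C", "D")])
        assert {c for _, _, c in ranking} == {0, 1}

    def test_transitive_chain_ordered(self):
        pairs = [("A", "B")] * 8 + [("B", "C")] * 8 + [("A", "C")] * 8
        ranking = relative_event_ordering(pairs)
        assert [e for e, _, _ in ranking] == ["A", "B", "C"]
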