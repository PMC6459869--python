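import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyspread.io_formats import GenomicInterval, Peak
from polyspread.regions import TargetRegion
from polyspread.spreading_stats import (
    compare_densities,
    promoter_enrichment_score,
    ratio_correlation,
    records_frame,
    region_density,
    spreading_table,
    top_fraction,
    SpreadingRecord,
)
from polyspread.tracks import CoverageTrack


def _track(values, binsize=50, length=None):
    values = np.asarray(values, dtype=float)
    length = length or len(values) * binsize
    return CoverageTrack(binsize, {"chrA": values}, {"chrA": length}, scaled=True)


class TestRegionDensity:
    def test_constant_track(self):
        track = _track(np.full(100, 2.0))
        iv = GenomicInterval("chrA", 123, 4567)
        assert region_density(track, iv) == pytest.approx(2.0)

    def test_partial_bin_weighting(self):
        # half of a bin valued 4, half of a bin valued 0 -> 2
        track = _track([4.0, 0.0])
        assert region_density(track, GenomicInterval("chrA", 25, 75)) == pytest.approx(2.0)

    def test_matches_per_bp_oracle(self):
        rng = np.random.default_rng(99)
        track = _track(rng.random(200), binsize=37)
        per_bp = np.repeat(track.values["chrA"], 37)
        for _ in range(500):
            a = int(rng.integers(0, 200 * 37 - 1))
            b = int(rng.integers(a + 1, 200 * 37 + 1))
            oracle = per_bp[a:b].mean()
            got = region_density(track, GenomicInterval("chrA", a, b))
            assert got == pytest.approx(oracle, abs=1e-9)

    def test_off_chromosome_is_error(self):
        track = _track(np.ones(10))
        with pytest.raises(ValueError):
            region_density(track, GenomicInterval("chrA", 400, 600))


class TestSpreadingTable:
    def _region(self, start, end, name="s1"):
        p = Peak(GenomicInterval("chrA", start, end), name, 0.0, 2.0)
        return TargetRegion(p, p)

    def test_confined_signal_gives_small_ratio(self):
        # signal only inside the region: ratio is the pseudocount floor effect
        values = np.zeros(200)
        values[40:60] = 10.0  # [2000, 3000)
        track = _track(values)
        (rec,) = spreading_table(track, [self._region(2000, 3000)], flank_bp=1200)
        assert rec.density_in == pytest.approx(10.0)
        assert rec.ratio5 < 0.01 and rec.ratio3 < 0.01

    def test_flat_track_ratio_one(self):
        track = _track(np.full(200, 3.0))
        (rec,) = spreading_table(track, [self._region(2000, 3000)])
        assert rec.ratio5 == pytest.approx(1.0) and rec.ratio3 == pytest.approx(1.0)

    def test_clipped_flank_flagged(self):
        track = _track(np.ones(200))
        (rec,) = spreading_table(track, [self._region(500, 2000)])
        assert rec.clipped

    def test_pseudocount_stability(self, tiny_tracks, tiny_regions):
        # halving/doubling epsilon moves the WT median ratio by < 1%
        track = tiny_tracks["WT"]
        medians = {}
        for eps in (0.005, 0.01, 0.02):
            recs = spreading_table(track, tiny_regions, 1200, pseudocount=eps)
            frame = records_frame(recs)
            medians[eps] = frame[~frame.clipped].ratio5.median()
        base = medians[0.01]
        assert abs(medians[0.005] - base) / base < 0.01
        assert abs(medians[0.02] - base) / base < 0.01


class TestCompareDensities:
    def test_identical_samples_t_is_zero(self):
        res = compare_densities([1, 2, 3], [1, 2, 3], "student_t")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_pooled_variance_t_closed_form(self):
        # classical two-sample pooled-variance t: t = -1.2247, df = 4
        res = compare_densities([1, 2, 3], [2, 3, 4], "student_t")
        assert res.statistic == pytest.approx(-math.sqrt(1.5), abs=1e-4)
        assert res.p_value == pytest.approx(0.2879, abs=1e-3)

    def test_rank_sum_matches_exact_enumeration(self):
        rng = np.random.default_rng(5)
        for n_a, n_b in [(2, 2), (3, 4), (4, 4)]:
            a = rng.normal(size=n_a)
            b = rng.normal(size=n_b) + 1.0
            res = compare_densities(a, b, "wilcoxon")
            # enumerate all assignments of the pooled ranks to group A
            pooled = np.concatenate([a, b])
            ranks = stats.rankdata(pooled)
            u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
            count = total = 0
            mu = n_a * n_b / 2
            for combo in itertools.combinations(range(n_a + n_b), n_a):
                u = ranks[list(combo)].sum() - n_a * (n_a + 1) / 2
                total += 1
                if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                    count += 1
            assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_all_identical_wilcoxon_p_one(self):
        res = compare_densities([2.0, 2.0], [2.0, 2.0, 2.0], "wilcoxon")
        assert res.p_value == 1.0

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            compare_densities([1.0], [1.0, 2.0])


class TestRatioCorrelation:
    def test_identity_pairs(self):
        a = np.array([0.1, 0.5, 0.9, 1.2])
        res = ratio_correlation(a, a)
        assert res.slope == pytest.approx(1.0)
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        a = np.array([0.0, 1.0, 2.0])
        res = ratio_correlation(a, -a + 5)
        assert res.r == pytest.approx(-1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(17)
        a = rng.random(50)
        b = 0.7 * a + 0.1 + rng.normal(0, 0.05, 50)
        res = ratio_correlation(a, b)
        X = np.column_stack([a, np.ones(50)])
        slope, intercept = np.linalg.solve(X.T @ X, X.T @ b)
        r = np.corrcoef(a, b)[0, 1]
        assert res.slope == pytest.approx(slope, abs=1e-9)
        assert res.intercept == pytest.approx(intercept, abs=1e-9)
        assert res.r == pytest.approx(r, abs=1e-9)
        assert res.r_squared == pytest.approx(r * r, abs=1e-12)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            ratio_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _records(n):
    return [
        SpreadingRecord(f"r{i:03d}", "chrA", i * 100, i * 100 + 50,
                        1.0, 0.5, 0.5, 0.5, 0.5, False)
        for i in range(n)
    ]


class TestTopFraction:
    def test_count_is_ceil(self):
        recs = _records(10)
        assert len(top_fraction(recs, list(range(10)), 0.2)) == 2
        assert len(top_fraction(recs, list(range(10)), 0.25)) == 3

    def test_q_one_is_identity(self):
        recs = _records(5)
        got = top_fraction(recs, [3, 1, 4, 1, 5], 1.0)
        assert {r.region_id for r in got} == {r.region_id for r in recs}

    def test_empty_input(self):
        assert top_fraction([], [], 0.5) == []

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(8)
        recs = _records(200)
        scores = rng.random(200)
        got = [r.region_id for r in top_fraction(recs, scores, 0.2)]
        oracle = [
            recs[i].region_id
            for i in sorted(range(200), key=lambda i: (-scores[i], recs[i].region_id))[:40]
        ]
        assert got == oracle


class TestPromoterEnrichmentScore:
    def _count_track(self, counts, binsize, fragment):
        # bin value = fragment-bp / binsize for `counts` fragments per bin
        values = np.asarray(counts, dtype=float) * fragment / binsize
        return CoverageTrack(
            binsize, {"chrA": values}, {"chrA": len(counts) * binsize}
        )

    def test_observed_equals_expectation(self):
        # upper tail including the observed count at lambda = 10 is 0.542
        ip = self._count_track([10], 200, 200)
        inp = self._count_track([10], 200, 200)
        score = promoter_enrichment_score(ip, inp, GenomicInterval("chrA", 0, 200))
        assert 10 ** -score == pytest.approx(stats.poisson.sf(9, 10), rel=1e-9)

    def test_zero_observed_full_tail(self):
        ip = self._count_track([0], 200, 200)
        inp = self._count_track([1], 200, 200)
        score = promoter_enrichment_score(ip, inp, GenomicInterval("chrA", 0, 200))
        assert score == pytest.approx(0.0)  # p = 1

    def test_matches_pmf_summation(self):
        # 25 observed fragments against an input expectation of 5; genome-wide
        # totals equalized with padding mass so no depth rescaling applies
        ip = self._count_track([25, 0], 200, 200)
        inp = self._count_track([5, 20], 200, 200)
        score = promoter_enrichment_score(ip, inp, GenomicInterval("chrA", 0, 200))
        oracle = sum(stats.poisson.pmf(k, 5.0) for k in range(25, 200))
        assert 10 ** -score == pytest.approx(oracle, abs=1e-10)

    def test_expectation_floor(self):
        # tiny input expectation floored at lambda = 1
        ip = self._count_track([3, 0], 200, 200)
        inp = self._count_track([0, 3], 200, 200)
        score = promoter_enrichment_score(ip, inp, GenomicInterval("chrA", 0, 200))
        assert 10 ** -score == pytest.approx(stats.poisson.sf(2, 1.0), rel=1e-9)
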