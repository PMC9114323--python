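import itertools
import math

import numpy as np
import pytest

from fusloc import peaks
from fusloc.io import PeakRecord, PeakSet
from fusloc.peaks import ScoredTranscript


class TestPeakScore:
    @pytest.mark.parametrize(
        "raw,total,expected",
        [
            (0, 191_404_803, 0.0),
            (5, 10_000_000, 5.0),
            (20, 200_000_000, 1.0),
        ],
    )
    def test_normalization_to_ten_million(self, raw, total, expected):
        assert peaks.compute_peak_score(raw, total) == pytest.approx(expected)

    def test_invalid_total_rejected(self):
        with pytest.raises(ValueError):
            peaks.compute_peak_score(5, 0)

    def test_depth_invariance(self):
        """Scaling counts and depth together leaves scores unchanged."""
        rng = np.random.default_rng(0)
        raws = rng.integers(1, 1000, 50)
        for factor in (2, 10, 7):
            for raw in raws:
                assert peaks.compute_peak_score(raw * factor, 10_000_000 * factor) == (
                    pytest.approx(peaks.compute_peak_score(raw, 10_000_000)))


class TestBindingSurfaceScore:
    @pytest.mark.parametrize(
        "score,length,expected",
        [(1.0, 1, 0.0), (0.1, 10, 0.0), (2.0, 1024, 11.0)],
    )
    def test_log2_of_product(self, score, length, expected):
        assert peaks.binding_surface_score(score, length) == pytest.approx(expected, abs=1e-12)

    def test_zero_score_undefined(self):
        with pytest.raises(ValueError):
            peaks.binding_surface_score(0.0, 100)

    def test_doubling_length_adds_one(self, scored_transcripts):
        ts = scored_transcripts([(0.5, 200), (3.0, 1000), (0.1, 7)])
        for t in ts:
            assert peaks.binding_surface_score(t.peak_score, 2 * t.length) == (
                pytest.approx(t.binding_surface_score + 1.0, abs=1e-12))

    def test_stored_scores_recomputable(self):
        """score_peaks output satisfies bss == log2(score*length) to 1e-9."""
        rng = np.random.default_rng(5)
        records = [
            PeakRecord(f"p{i}", f"g{i}", "chr1", i * 10_000, i * 10_000 + int(rng.integers(1, 5000)),
                       "+", float(rng.integers(1, 10_000)))
            for i in range(100)
        ]
        ps = PeakSet("s", 37_000_000, records)
        for t in peaks.score_peaks(ps):
            assert t.binding_surface_score == pytest.approx(
                math.log2(t.peak_score * t.length), abs=1e-9)


class TestFilterPeaks:
    def test_boundary_exactly_at_threshold_retained(self, scored_transcripts):
        ts = scored_transcripts([(0.05, 10), (0.1, 10), (0.2, 10)])
        kept = peaks.filter_peaks(ts, min_score=0.1)
        assert [t.peak_score for t in kept] == [0.1, 0.2]

    def test_empty_and_identity(self, scored_transcripts):
        assert peaks.filter_peaks([]) == []
        ts = scored_transcripts([(1.0, 10), (2.0, 20)])
        assert peaks.filter_peaks(ts) == ts

    def test_idempotent(self, scored_transcripts):
        ts = scored_transcripts([(0.01, 5), (0.1, 5), (5.0, 5), (0.09, 5)])
        once = peaks.filter_peaks(ts)
        assert peaks.filter_peaks(once) == once

    def test_negative_threshold_rejected(self, scored_transcripts):
        with pytest.raises(ValueError):
            peaks.filter_peaks(scored_transcripts([(1.0, 1)]), min_score=-0.1)


class TestSubsetByTargets:
    def test_intersection_preserves_order_and_flags(self, scored_transcripts):
        ts = scored_transcripts([(1, 10)] * 5)
        subset = peaks.subset_by_targets(ts, {"g1", "g3"})
        assert [t.gene_id for t in subset] == ["g1", "g3"]
        assert all(t.is_target for t in subset)

    def test_empty_targets_and_superset(self, scored_transcripts):
        ts = scored_transcripts([(1, 10), (2, 10)])
        assert peaks.subset_by_targets(ts, set()) == []
        allofit = peaks.subset_by_targets(ts, {"g0", "g1", "extra"})
        assert [t.gene_id for t in allofit] == ["g0", "g1"]
        assert all(t.is_target for t in allofit)

    def test_matching_is_case_sensitive(self, scored_transcripts):
        ts = scored_transcripts([(1, 10)])
        assert peaks.subset_by_targets(ts, {"G0"}) == []


class TestCumulativeDistribution:
    def test_single_and_uniform_steps(self):
        xs, fr = peaks.cumulative_distribution([7.0])
        assert xs.tolist() == [7.0] and fr.tolist() == [1.0]
        xs, fr = peaks.cumulative_distribution([3, 1, 4, 2])
        assert xs.tolist() == [1, 2, 3, 4]
        assert fr.tolist() == [0.25, 0.5, 0.75, 1.0]

    def test_duplicates_reflected_in_step_height(self):
        # brute-force ECDF on a 6-element multiset
        values = [2.0, 1.0, 2.0, 3.0, 2.0, 5.0]
        xs, fr = peaks.cumulative_distribution(values)
        brute = [(v, sum(u <= v for u in values) / len(values)) for v in sorted(values)]
        assert list(zip(xs.tolist(), fr.tolist()))[-1] == brute[-1]
        # fraction evaluated at each distinct value matches the brute count
        for v in sorted(set(values)):
            assert fr[xs == v].max() == pytest.approx(
                sum(u <= v for u in values) / len(values))

    def test_fractions_monotone_ending_at_one(self):
        rng = np.random.default_rng(2)
        xs, fr = peaks.cumulative_distribution(rng.normal(size=101))
        assert np.all(np.diff(fr) >= 0) and fr[0] > 0 and fr[-1] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            peaks.cumulative_distribution([])


def brute_force_rank_sum(a, b, alternative):
    """Independent oracle: enumerate all C(n_a+n_b, n_a) rank assignments."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na = len(a)
    u_obs = sum((x > y) for x in a for y in b)
    pooled = np.sort(np.concatenate([a, b]))
    us = []
    for comb in itertools.combinations(range(len(pooled)), na):
        aa = pooled[list(comb)]
        bb = np.delete(pooled, list(comb))
        us.append(sum((x > y) for x in aa for y in bb))
    us = np.array(us)
    if alternative == "less":
        p = (us <= u_obs).mean()
    elif alternative == "greater":
        p = (us >= u_obs).mean()
    else:
        p = min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
    return u_obs, p


class TestRankSumTest:
    def test_separated_samples_one_sided(self):
        res = peaks.rank_sum_test([1, 2, 3], [4, 5, 6], alternative="less")
        assert res.u_statistic == 0
        assert res.p_value == pytest.approx(1 / 20)  # enumeration of C(6,3)=20
        assert res.method == "exact"

    def test_identical_multisets_p_one(self):
        res = peaks.rank_sum_test([1, 2], [1, 2])
        assert res.p_value == pytest.approx(1.0)

    def test_percent_reduction_uses_reference_mean(self):
        res = peaks.rank_sum_test([100.0, 100.0], [90.0, 90.0])
        assert res.percent_reduction == pytest.approx(10.0)

    def test_u_bounded_by_product(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 30))
            b = rng.normal(size=rng.integers(2, 30))
            res = peaks.rank_sum_test(a, b)
            assert 0 <= res.u_statistic <= len(a) * len(b)

    def test_matches_enumeration_on_small_tie_free_samples(self):
        rng = np.random.default_rng(10)
        for k in range(40):
            na = int(rng.integers(2, 6))
            nb = int(rng.integers(2, 10 - na + 1))
            vals = rng.normal(size=na + nb)
            alt = ["two-sided", "less", "greater"][k % 3]
            u, p = brute_force_rank_sum(vals[:na], vals[na:], alt)
            res = peaks.rank_sum_test(vals[:na], vals[na:], alternative=alt)
            assert res.u_statistic == pytest.approx(u)
            assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            peaks.rank_sum_test([], [1.0])


class TestSummarizeSample:
    def test_total_binding_surface_of_worked_scores(self, scored_transcripts):
        ts = scored_transcripts([(1.0, 1), (2.0, 1024)])  # scores 0 and 11
        s = peaks.summarize_sample(ts)
        assert s.n_peaks == 2
        assert s.total_binding_surface == pytest.approx(11.0)

    def test_empty_flagged(self):
        s = peaks.summarize_sample([])
        assert s.n_peaks == 0 and not s.defined and math.isnan(s.mean_peak_score)

    def test_single_transcript_mean_is_its_score(self, scored_transcripts):
        ts = scored_transcripts([(4.0, 32)])
        s = peaks.summarize_sample(ts)
        assert s.mean_binding_surface == pytest.approx(ts[0].binding_surface_score)


class TestAggregateByGene:
    def test_sums_scores_and_takes_max_length(self):
        ts = [
            ScoredTranscript("gA", 1.0, 100, math.log2(100)),
            ScoredTranscript("gA", 3.0, 50, math.log2(150)),
            ScoredTranscript("gB", 2.0, 10, math.log2(20)),
        ]
        agg = peaks.aggregate_by_gene(ts)
        assert [t.gene_id for t in agg] == ["gA", "gB"]
        assert agg[0].peak_score == pytest.approx(4.0)
        assert agg[0].length == 100
        assert agg[0].binding_surface_score == pytest.approx(math.log2(400))
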