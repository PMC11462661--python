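"""ATAC peak post-processing, fragment comparison and promoter-overlap
enrichment."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylrelease import (
    build_consensus,
    compare_fragment_lengths,
    extend_and_filter_peaks,
    generate_fragment_lengths,
    promoter_overlap_enrichment,
    score_per_million,
)

CHROM_SIZES = {"chr1": 1_000_000, "chr2": 500_000}


def make_peaks(rows, sample="s1"):
    """rows: (chrom, summit, score)."""
    df = pd.DataFrame(rows, columns=["chrom", "summit", "score"])
    df["start"] = df["summit"]
    df["end"] = df["summit"] + 1
    df["name"] = [f"peak{i}" for i in range(len(df))]
    df["strand"] = "."
    df["sample_id"] = sample
    return df


class TestExtendAndFilter:
    def test_width_is_501(self):
        out = extend_and_filter_peaks(
            make_peaks([("chr1", 10_000, 5.0)]), CHROM_SIZES
        )
        assert len(out) == 1
        assert (out.end - out.start).iloc[0] == 501
        assert out.start.iloc[0] == 10_000 - 250

    def test_summit_near_chromosome_start_removed(self):
        out = extend_and_filter_peaks(make_peaks([("chr1", 100, 5.0)]), CHROM_SIZES)
        assert len(out) == 0

    def test_summit_near_chromosome_end_removed(self):
        out = extend_and_filter_peaks(
            make_peaks([("chr2", 499_900, 5.0)]), CHROM_SIZES
        )
        assert len(out) == 0

    def test_blacklist_and_bounds_vs_sweep_oracle(self):
        rng = np.random.default_rng(0)
        summits = rng.integers(0, 1_000_000, size=10)
        peaks = make_peaks([("chr1", int(s), 1.0) for s in summits])
        blacklist = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [100_000, 600_000],
             "end": [105_000, 600_500]}
        )
        out = extend_and_filter_peaks(peaks, CHROM_SIZES, blacklist)
        # brute-force interval sweep
        survivors = []
        for s in summits:
            lo, hi = s - 250, s + 251
            if lo < 0 or hi > CHROM_SIZES["chr1"]:
                continue
            if any(lo < be and bs < hi for bs, be in
                   zip(blacklist.start, blacklist.end)):
                continue
            survivors.append(s)
        assert len(out) == len(survivors)
        assert (out.end - out.start == 501).all()

    def test_unknown_chromosome_error(self):
        with pytest.raises(ValueError, match="chrUn"):
            extend_and_filter_peaks(make_peaks([("chrUn", 5000, 1.0)]), CHROM_SIZES)


class TestScorePerMillion:
    def test_single_peak_gets_million(self):
        out = score_per_million(make_peaks([("chr1", 1000, 7.0)]))
        assert out.score.iloc[0] == pytest.approx(1e6)

    def test_hand_computed_normalization(self):
        peaks = make_peaks(
            [("chr1", 1000, 1.0), ("chr1", 2000, 2.0),
             ("chr1", 3000, 3.0), ("chr1", 4000, 4.0)]
        )
        out = score_per_million(peaks)
        np.testing.assert_allclose(out.score, [1e5, 2e5, 3e5, 4e5])
        assert out.score.sum() == pytest.approx(1e6, rel=1e-6)

    def test_idempotent_fixed_point_and_rank_order(self):
        rng = np.random.default_rng(1)
        peaks = make_peaks(
            [("chr1", 1000 * i, float(s)) for i, s in
             enumerate(rng.integers(1, 100, 8), start=1)]
        )
        once = score_per_million(peaks)
        twice = score_per_million(once)
        np.testing.assert_allclose(once.score, twice.score)
        assert list(np.argsort(once.score)) == list(np.argsort(peaks.score))

    def test_zero_total_error(self):
        with pytest.raises(ValueError):
            score_per_million(make_peaks([("chr1", 1000, 0.0)]))


def greedy_consensus_oracle(intervals):
    """Independent oracle: repeatedly keep the highest-scoring interval and
    drop everything overlapping it."""
    remaining = sorted(intervals, key=lambda t: (-t[3], t[0], t[1]))
    kept = []
    while remaining:
        top = remaining.pop(0)
        kept.append(top)
        remaining = [
            iv for iv in remaining
            if iv[0] != top[0] or not (iv[1] < top[2] and top[1] < iv[2])
        ]
    return sorted(kept)


def df_from_intervals(intervals, sample="s1"):
    df = pd.DataFrame(intervals, columns=["chrom", "start", "end", "score"])
    df["summit"] = (df.start + df.end) // 2
    df["sample_id"] = sample
    return df


class TestBuildConsensus:
    def test_disjoint_peaks_both_kept(self):
        out = build_consensus(
            [df_from_intervals([("chr1", 0, 100, 5.0), ("chr1", 200, 300, 3.0)])]
        )
        assert len(out) == 2

    def test_mutually_overlapping_keep_highest(self):
        out = build_consensus(
            [df_from_intervals(
                [("chr1", 0, 100, 5.0), ("chr1", 50, 150, 9.0), ("chr1", 90, 190, 7.0)]
            )]
        )
        assert len(out) == 1
        assert out.score.iloc[0] == 9.0

    def test_chain_resolution_trace(self):
        # A-B overlap, B-C overlap, A-C disjoint: A (10) and C (9) survive
        out = build_consensus(
            [df_from_intervals(
                [("chr1", 0, 100, 10.0), ("chr1", 90, 200, 8.0),
                 ("chr1", 150, 250, 9.0)]
            )]
        )
        assert sorted(out.score) == [9.0, 10.0]

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_greedy_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        intervals = []
        for _ in range(10):
            start = int(rng.integers(0, 500))
            intervals.append(
                ("chr1", start, start + int(rng.integers(10, 120)),
                 float(rng.integers(1, 1000)))
            )
        out = build_consensus([df_from_intervals(intervals)])
        oracle = greedy_consensus_oracle(intervals)
        got = sorted(zip(out.chrom, out.start, out.end, out.score))
        assert got == oracle

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_output_pairwise_non_overlapping(self, seed):
        rng = np.random.default_rng(seed)
        intervals = []
        for _ in range(12):
            start = int(rng.integers(0, 300))
            intervals.append(
                ("chr1", start, start + int(rng.integers(5, 80)),
                 float(rng.random()))
            )
        out = build_consensus([df_from_intervals(intervals)])
        for (_, a), (_, b) in combinations(out.iterrows(), 2):
            assert a.end <= b.start or b.end <= a.start


class TestCompareFragmentLengths:
    def test_identical_multisets_p_one(self):
        a = np.array([100, 150, 200, 250])
        res = compare_fragment_lengths(a, a.copy())
        assert res.p_value == pytest.approx(1.0)

    def test_planted_shorter_distribution_significant(self):
        a, b = generate_fragment_lengths(500, 20, seed=0)
        res = compare_fragment_lengths(a, b, alternative="less")
        assert res.p_value < 1e-4
        assert "shorter" in res.direction

    def test_exact_p_matches_enumeration_4v4(self):
        a = np.array([100, 140, 180, 220])
        b = np.array([90, 130, 170, 210])

        def u_stat(first, second):
            return sum(x > y for x in first for y in second)

        pooled = np.concatenate([a, b])
        observed = u_stat(b, a)
        count = total = 0
        for idx in combinations(range(8), 4):
            mask = np.zeros(8, dtype=bool)
            mask[list(idx)] = True
            u = u_stat(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - 8) >= abs(observed - 8):
                count += 1
        assert total == 70
        res = compare_fragment_lengths(a, b)
        assert res.p_value == pytest.approx(count / total)

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            compare_fragment_lengths(np.array([]), np.array([100]))


class TestPromoterOverlapEnrichment:
    def test_accessible_equals_universe(self):
        genes = [f"g{i}" for i in range(30)]
        res = promoter_overlap_enrichment(genes, genes[:10], genes, seed=0)
        assert res.observed_pct == 100.0
        assert res.null_mean_pct == 100.0

    def test_null_mean_matches_hypergeometric_expectation(self):
        universe = [f"g{i}" for i in range(100)]
        up = universe[:20]
        acc = universe[40:70]
        res = promoter_overlap_enrichment(universe, up, acc,
                                          n_iterations=10_000, seed=1)
        assert res.expected_pct == pytest.approx(30.0)
        assert abs(res.null_mean_pct - res.expected_pct) <= 3 * res.null_se_pct

    def test_enriched_toy_detected(self):
        universe = [f"g{i}" for i in range(500)]
        up = universe[:50]
        acc = universe[:40] + universe[400:420]  # heavy overlap with up
        res = promoter_overlap_enrichment(universe, up, acc,
                                          n_iterations=200, seed=2)
        assert res.observed_pct > res.null_mean_pct + 2 * res.null_sd_pct
        assert res.enriched

    def test_deterministic_given_seed(self):
        universe = [f"g{i}" for i in range(50)]
        r1 = promoter_overlap_enrichment(universe, universe[:10], universe[20:35],
                                         n_iterations=10, seed=3)
        r2 = promoter_overlap_enrichment(universe, universe[:10], universe[20:35],
                                         n_iterations=10, seed=3)
        assert r1 == r2

    def test_empty_upregulated_error(self):
        with pytest.raises(ValueError):
            promoter_overlap_enrichment(["g1"], [], ["g1"], seed=0)
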