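import time

import numpy as np
import pytest

from ascnseg.counts_io import ChromCounts, compute_totals
from ascnseg.mixture_model import fit_segment
from ascnseg.segmentation import (ChangePointSet, SegmentationConfig,
                                  best_split, mbic_penalty, mbic_score,
                                  recursive_segment, segment_chromosome,
                                  segment_genome)
from ascnseg.spikein_sim import (SimConfig, simulate_pair, six_event_layout,
                                 spike_for_type)

from conftest import make_counts, simulate_mixture


def free_loglik(cc_slice):
    """Unconstrained mixture loglik (the segmentation scan objective)."""
    return fit_segment(cc_slice, separation_test=False).loglik


def em_gain_oracle(cc, lo, hi, s):
    """Split gain computed directly from three independent EM fits."""
    return (free_loglik(cc.subset(slice(lo, s)))
            + free_loglik(cc.subset(slice(s, hi)))
            - free_loglik(cc.subset(slice(lo, hi))))


def two_level_counts(T, change_at, ratios_left, ratios_right, coverage, seed):
    """Mixture counts with one change in (p_a, p_b) at a known index."""
    left = simulate_mixture(change_at, *ratios_left, coverage=coverage, seed=seed)
    right = simulate_mixture(T - change_at, *ratios_right, coverage=coverage,
                             seed=seed + 1)
    return make_counts(
        np.concatenate([left.xA, right.xA]), np.concatenate([left.xB, right.xB]),
        np.concatenate([left.yA, right.yA]), np.concatenate([left.yB, right.yB]))


class TestBestSplit:
    def test_matches_exhaustive_scan(self):
        cc = two_level_counts(60, 30, (0.5, 0.5), (0.25, 0.5), 40, seed=4)
        min_seg = 5
        s, gain = best_split(cc, 0, 60, min_seg)
        gains = {c: em_gain_oracle(cc, 0, 60, c) for c in range(5, 56)}
        s_oracle = max(gains, key=lambda c: (gains[c], -c))
        assert s == s_oracle
        assert gain == pytest.approx(gains[s_oracle], abs=1e-3)

    def test_localizes_strong_change(self):
        # minor ratio 1 -> 0.5 at full purity, coverage 40
        p_left = 0.5
        p_right_lo = 0.5 * 1 / (0.5 + 1)  # ratio 0.5 at M = N
        cc = two_level_counts(400, 200, (p_left, p_left),
                              (p_right_lo, 0.5), 40, seed=12)
        s, gain = best_split(cc, 0, 400, 5)
        assert abs(s - 200) <= 10
        assert gain > 50

    def test_interval_too_short(self, null_chromosome):
        with pytest.raises(ValueError, match="no admissible split"):
            best_split(null_chromosome, 0, 9, 5)


class TestRecursiveSegment:
    def test_candidates_are_nested(self):
        cc = two_level_counts(300, 150, (0.5, 0.5), (0.35, 0.5), 40, seed=6)
        cands = recursive_segment(cc, min_seg=5, max_K=4,
                                  config=SegmentationConfig(stop_gain_factor=0.0,
                                                            max_K=4))
        for (cp1, ll1), (cp2, ll2) in zip(cands, cands[1:]):
            assert set(cp1.tau) <= set(cp2.tau)
            assert ll2 >= ll1 - 1e-6  # loglik non-decreasing in K

    def test_constant_data_yields_base_candidate(self, null_chromosome):
        cands = recursive_segment(null_chromosome, min_seg=5, max_K=3)
        assert cands[0][0].K == 0

    def test_two_changes_recovered_in_first_two_splits(self):
        left = simulate_mixture(150, 0.5, 0.5, 40, seed=31)
        mid = simulate_mixture(150, 0.25, 0.6, 40, seed=32)
        right = simulate_mixture(150, 0.5, 0.5, 40, seed=33)
        cc = make_counts(
            np.concatenate([left.xA, mid.xA, right.xA]),
            np.concatenate([left.xB, mid.xB, right.xB]),
            np.concatenate([left.yA, mid.yA, right.yA]),
            np.concatenate([left.yB, mid.yB, right.yB]))
        cands = recursive_segment(cc, min_seg=5, max_K=2)
        tau = cands[-1][0].tau
        assert len(tau) == 2
        assert abs(tau[0] - 150) <= 10 and abs(tau[1] - 300) <= 10

    def test_greedy_matches_exact_dp_on_clear_signal(self):
        # exact dynamic program over per-interval EM logliks, T small
        left = simulate_mixture(30, 0.5, 0.5, 40, seed=41)
        mid = simulate_mixture(30, 0.2, 0.65, 40, seed=42)
        right = simulate_mixture(30, 0.5, 0.5, 40, seed=43)
        cc = make_counts(
            np.concatenate([left.xA, mid.xA, right.xA]),
            np.concatenate([left.xB, mid.xB, right.xB]),
            np.concatenate([left.yA, mid.yA, right.yA]),
            np.concatenate([left.yB, mid.yB, right.yB]))
        T, min_seg, K = 90, 5, 2
        ll = {}
        for i in range(T):
            for j in range(i + min_seg, T + 1):
                ll[(i, j)] = free_loglik(cc.subset(slice(i, j)))
        # DP for exactly K change-points
        best = {(0, j): ll[(0, j)] for j in range(min_seg, T + 1)}
        argmax = {}
        for k in range(1, K + 1):
            new = {}
            for j in range((k + 1) * min_seg, T + 1):
                options = [
                    (best[(k - 1, s)] + ll[(s, j)], s)
                    for s in range(k * min_seg, j - min_seg + 1)
                ]
                val, s = max(options)
                new[(k, j)] = val
                argmax[(k, j)] = s
            best.update(new)
        # backtrack DP change-points
        tau_dp = []
        j, k = T, K
        while k > 0:
            s = argmax[(k, j)]
            tau_dp.append(s)
            j, k = s, k - 1
        tau_dp = sorted(tau_dp)
        cands = recursive_segment(cc, min_seg=min_seg, max_K=K)
        assert list(cands[-1][0].tau) == tau_dp


class TestMbic:
    def test_no_changepoints_score_is_loglik(self):
        cp = ChangePointSet(tau=(), T=500)
        assert mbic_score(cp, -1234.5, 500) == -1234.5

    def test_zero_gain_changepoint_decreases_score(self):
        T = 500
        base = mbic_score(ChangePointSet(tau=(), T=T), -100.0, T)
        with_cp = mbic_score(ChangePointSet(tau=(250,), T=T), -100.0, T)
        assert with_cp < base

    def test_penalty_floor_applies_to_short_segments(self):
        T = 1000
        edge = mbic_penalty(ChangePointSet(tau=(5,), T=T), T)
        assert edge >= np.log(T)

    def test_null_calibration_sample(self):
        # small preview of the 200-replicate null study in the acceptance suite
        k_hat = []
        for seed in range(20):
            cc, _ = simulate_pair(SimConfig(T=1000, mean_cov=40, seed=900 + seed), [])
            totals = compute_totals({cc.chrom: cc})
            k_hat.append(segment_chromosome(cc, totals).K)
        assert sum(k == 0 for k in k_hat) >= 19


class TestSegmentChromosome:
    def test_null_chromosome_single_normal_segment(self, null_chromosome):
        totals = compute_totals({"c": null_chromosome})
        res = segment_chromosome(null_chromosome, totals)
        assert res.K == 0 and len(res.segments) == 1
        seg = res.segments[0]
        assert seg.ratios.minor == pytest.approx(1.0, abs=0.15)
        assert seg.ratios.major == pytest.approx(1.0, abs=0.15)

    def test_segments_partition_all_loci(self):
        cc, _ = simulate_pair(
            SimConfig(T=4000, seed=55),
            [spike_for_type("normal/loss", 0.6, 1000, 1600),
             spike_for_type("gain/gain", 0.6, 2500, 3100)])
        totals = compute_totals({cc.chrom: cc})
        res = segment_chromosome(cc, totals)
        assert res.segments[0].start_idx == 0
        assert res.segments[-1].end_idx == len(cc)
        for a, b in zip(res.segments, res.segments[1:]):
            assert a.end_idx == b.start_idx
        assert res.total_loglik == pytest.approx(
            sum(s.fit.loglik for s in res.segments))

    def test_six_spiked_events_recovered_at_full_purity(self):
        spikes = six_event_layout(1.0, T=9500)
        cc, truth = simulate_pair(SimConfig(T=9500, seed=77), spikes)
        totals = compute_totals({cc.chrom: cc})
        res = segment_chromosome(cc, totals)
        from ascnseg.event_calling import call_events

        # with six simultaneous aberrations the at-loci totals compress all
        # ratios by the aberrant coverage fraction (~5% here), so allow a
        # correspondingly wider balance tolerance when typing events
        events = call_events(res, delta=0.1, balance_tol=0.15)
        for _, row in truth.iterrows():
            matches = [
                e for e in events
                if e.type == row["type"]
                and min(e.end_idx, row["end_idx"]) - max(e.start_idx, row["start_idx"])
                >= 0.5 * (row["end_idx"] - row["start_idx"])
            ]
            assert matches, f"missing {row['type']}"

    def test_deterministic(self):
        cc, _ = simulate_pair(SimConfig(T=2000, seed=13),
                              [spike_for_type("normal/loss", 0.5, 800, 1300)])
        totals = compute_totals({cc.chrom: cc})
        r1 = segment_chromosome(cc, totals)
        r2 = segment_chromosome(cc, totals)
        assert [s.start_idx for s in r1.segments] == [s.start_idx for s in r2.segments]
        assert r1.total_loglik == r2.total_loglik

    def test_global_label_swap_invariance(self):
        cc, _ = simulate_pair(SimConfig(T=2000, seed=14),
                              [spike_for_type("balanced gain/loss", 0.5, 800, 1300)])
        swapped = ChromCounts(cc.chrom, cc.pos, cc.xB, cc.xA, cc.yB, cc.yA)
        t1 = compute_totals({"c": cc})
        t2 = compute_totals({"c": swapped})
        r1 = segment_chromosome(cc, t1)
        r2 = segment_chromosome(swapped, t2)
        assert [s.start_idx for s in r1.segments] == [s.start_idx for s in r2.segments]
        for s1, s2 in zip(r1.segments, r2.segments):
            assert s1.ratios == s2.ratios

    def test_tiny_chromosome_kept_whole(self, caplog):
        cc = make_counts([10] * 6, [10] * 6, [10] * 6, [10] * 6)
        totals = compute_totals({"c": cc})
        with caplog.at_level("WARNING"):
            res = segment_chromosome(cc, totals,
                                     SegmentationConfig(min_seg=5))
        assert len(res.segments) == 1

    def test_segment_genome_processes_chromosomes_independently(self):
        c1, _ = simulate_pair(SimConfig(T=500, seed=1, chrom="c1"), [])
        c2, _ = simulate_pair(SimConfig(T=500, seed=2, chrom="c2"),
                              [spike_for_type("normal/loss", 1.0, 100, 300)])
        chroms = {"c1": c1, "c2": c2}
        totals = compute_totals(chroms)
        results = segment_genome(chroms, totals)
        assert results["c1"].K == 0
        assert results["c2"].K == 2


def test_runtime_scales_subquadratically():
    """Doubling the number of loci should far less than triple the runtime."""
    def run(T, seed):
        cc, _ = simulate_pair(SimConfig(T=T, seed=seed),
                              [spike_for_type("normal/loss", 0.8,
                                              T // 2, T // 2 + T // 10)])
        totals = compute_totals({cc.chrom: cc})
        best = np.inf
        for _ in range(3):
            t0 = time.perf_counter()
            segment_chromosome(cc, totals)
            best = min(best, time.perf_counter() - t0)
        return best

    run(500, 0)  # warm-up (JIT-free, but caches/allocator)
    t_small = run(2000, 1)
    t_large = run(4000, 2)
    assert t_large < 3.0 * t_small
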