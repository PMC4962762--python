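"""Tests for recombination-fraction estimation and map construction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import simulate_chromosome_codes, simulate_marker_pair
from peppermap.mapping import (F2Matrix, GeneticMap, _class_counts, _loglik,
                               assemble_segments, build_map, collapse_bins,
                               double_crossover_scan, estimate_rf,
                               group_markers, inverse_kosambi, kosambi_cM,
                               map_correlation, map_positions, order_markers,
                               pairwise_rf, rf_heatmap, sarf)


def grid_search_rf(gi, gj, step=1e-4):
    """Independent grid-search oracle for the rf MLE."""
    n0, n1, n2, nc, _ = _class_counts(gi, gj)
    grid = np.arange(0.0, 0.5 + step / 2, step)
    lls = np.array([_ll_closed(r, n0, n1, n2, nc) for r in grid])
    return float(grid[int(np.argmax(lls))])


def _ll_closed(r, n0, n1, n2, nc):
    # written independently of mapping._loglik (plain closed form)
    s = 1.0 - r
    with np.errstate(divide="ignore"):
        terms = [n0 * np.log(s * s / 4) if n0 else 0.0,
                 n1 * np.log(r * s / 2) if n1 else 0.0,
                 n2 * np.log(r * r / 4) if n2 else 0.0,
                 nc * np.log((s * s + r * r) / 2) if nc else 0.0]
    return float(sum(terms))


class TestKosambi:
    def test_closed_form_values(self):
        assert kosambi_cM(0.0) == 0.0
        assert kosambi_cM(0.1) == pytest.approx(10.14, abs=0.005)

    def test_round_trip_identity(self):
        for d in (0.1, 1.0, 10.0, 37.2, 90.0):
            assert kosambi_cM(inverse_kosambi(d)) == pytest.approx(d, abs=1e-10)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            kosambi_cM(0.5)
        with pytest.raises(ValueError):
            inverse_kosambi(-1.0)


class TestEstimateRf:
    def test_identical_markers_give_zero_r_positive_lod(self):
        rng = np.random.default_rng(1)
        g = (rng.random(50) < 0.5).astype(np.int8) * 2  # no double hets
        pair = estimate_rf(g, g)
        assert pair.r_hat == 0.0 and pair.lod > 0

    def test_independent_markers_near_half(self):
        rng = np.random.default_rng(2)
        gi, _ = simulate_marker_pair(0.5, 1000, rng)
        gj, _ = simulate_marker_pair(0.5, 1000, rng)
        pair = estimate_rf(gi, gj)
        assert abs(pair.r_hat - 0.5) < 0.05
        assert pair.lod < 2

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            r = rng.uniform(0.01, 0.45)
            gi, gj = simulate_marker_pair(r, 200, rng)
            mle = estimate_rf(gi, gj).r_hat
            assert abs(mle - grid_search_rf(gi, gj)) < 1e-3

    def test_no_shared_individuals_rejected(self):
        gi = np.array([0, -1], dtype=np.int8)
        gj = np.array([-1, 0], dtype=np.int8)
        with pytest.raises(ValueError):
            estimate_rf(gi, gj)

    def test_pairwise_em_agrees_with_scalar_mle(self):
        rng = np.random.default_rng(4)
        codes = np.vstack([simulate_chromosome_codes([0, 8, 20, 45], 150, rng)
                           .T])
        R, LOD, N = pairwise_rf(codes)
        for i, j in itertools.combinations(range(4), 2):
            pair = estimate_rf(codes[i], codes[j])
            assert R[i, j] == pytest.approx(pair.r_hat, abs=1e-6)
            assert LOD[i, j] == pytest.approx(pair.lod, abs=1e-4)
            assert N[i, j] == pair.n_informative


class TestGrouping:
    def test_two_chromosomes_recovered(self, two_chromosome_f2):
        truth, f2 = two_chromosome_f2
        R, LOD, _ = pairwise_rf(f2.codes)
        groups = group_markers(R, LOD, f2.markers)
        assert len(groups) == 2
        chroms = truth.f2_map.set_index("marker")["chrom"]
        for g in groups:
            assert len(set(chroms[m] for m in g)) == 1

    def test_all_missing_marker_is_singleton(self):
        rng = np.random.default_rng(5)
        codes = simulate_chromosome_codes([0, 5, 10], 100, rng).T
        codes = np.vstack([codes, np.full(100, -1, dtype=np.int8)])
        R, LOD, _ = pairwise_rf(codes)
        groups = group_markers(R, LOD, ["a", "b", "c", "empty"])
        assert ["empty"] in groups

    def test_lowering_lod_threshold_never_splits_groups(self, two_chromosome_f2):
        _, f2 = two_chromosome_f2
        R, LOD, _ = pairwise_rf(f2.codes)
        strict = group_markers(R, LOD, f2.markers, lod_min=6.0)
        loose = group_markers(R, LOD, f2.markers, lod_min=3.0)
        loose_sets = [set(g) for g in loose]
        for g in strict:
            assert any(set(g) <= ls for ls in loose_sets)

    def test_pvalue_mode_runs(self, two_chromosome_f2):
        _, f2 = two_chromosome_f2
        R, LOD, _ = pairwise_rf(f2.codes)
        groups = group_markers(R, LOD, f2.markers, criterion="pvalue",
                               alpha=1e-6)
        assert len(groups) == 2


class TestOrdering:
    def brute_force(self, R):
        D = np.where(np.isnan(R), 0.5, R)
        n = R.shape[0]
        return min(sarf(p, D) for p in itertools.permutations(range(n)))

    def test_small_groups_match_brute_force(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            pos = np.sort(rng.uniform(0, 50, n))
            codes = simulate_chromosome_codes(pos, 90, rng).T
            R, _, _ = pairwise_rf(codes)
            ids = [f"m{i}" for i in range(n)]
            idx = {m: i for i, m in enumerate(ids)}
            best = self.brute_force(R)
            for limit in (8, 2):  # exhaustive path and heuristic path
                got = order_markers(ids, R, exhaustive_limit=limit)
                val = sarf([idx[m] for m in got], np.where(np.isnan(R), 0.5, R))
                assert val == pytest.approx(best, abs=1e-9)

    def test_recovers_simulated_order(self):
        from scipy.stats import kendalltau
        rng = np.random.default_rng(7)
        pos = np.sort(rng.uniform(0, 100, 50))
        codes = simulate_chromosome_codes(pos, 200, rng).T
        R, _, _ = pairwise_rf(codes)
        ids = [f"m{i:02d}" for i in range(50)]
        got = order_markers(ids, R)
        tau, _ = kendalltau([int(m[1:]) for m in got], range(50))
        assert abs(tau) >= 0.95

    def test_reversal_invariance_of_sarf(self):
        rng = np.random.default_rng(8)
        R = rng.uniform(0, 0.5, (6, 6))
        R = (R + R.T) / 2
        order = list(range(6))
        assert sarf(order, R) == pytest.approx(sarf(order[::-1], R))


class TestBins:
    def test_duplicated_marker_shares_bin(self):
        rng = np.random.default_rng(9)
        codes = simulate_chromosome_codes([0.0, 0.0, 12.0], 90, rng).T
        bins = collapse_bins(codes)
        assert bins[0] == bins[1] != bins[2]

    def test_one_informative_difference_splits_bins(self):
        codes = np.array([[0, 0, 1, 2], [0, 1, 1, 2]], dtype=np.int8)
        assert collapse_bins(codes)[1] == 1

    def test_three_planted_clusters_recovered(self):
        rng = np.random.default_rng(10)
        pos = [0.0, 0.0, 0.0, 25.0, 25.0, 25.0, 60.0, 60.0, 60.0, 60.0]
        codes = simulate_chromosome_codes(pos, 300, rng).T
        bins = collapse_bins(codes)
        assert len(set(bins)) == 3
        assert list(bins) == sorted(bins)

    def test_bin_count_bounded_by_marker_count(self, two_chromosome_f2):
        _, f2 = two_chromosome_f2
        bins = collapse_bins(f2.codes[:15])
        assert len(set(bins)) <= 15


class TestDoubleCrossovers:
    def test_clean_dense_map_has_near_zero_dcos(self):
        rng = np.random.default_rng(11)
        codes = simulate_chromosome_codes(np.linspace(0, 10, 20), 200, rng).T
        counts, flags = double_crossover_scan(codes)
        assert counts.sum() <= 2
        assert not flags.any()

    def test_noisy_marker_flagged_and_monotone(self):
        rng = np.random.default_rng(12)
        codes = simulate_chromosome_codes(np.linspace(0, 20, 30), 300, rng).T
        noisy = codes.copy()
        bad = rng.random(300) < 0.05
        noisy[15, bad] = (noisy[15, bad] + 1) % 3
        c0, _ = double_crossover_scan(codes)
        c1, flags = double_crossover_scan(noisy)
        assert flags[15]
        assert c1[15] >= c0[15]

    def test_flagged_marker_removal_does_not_grow_map(self):
        rng = np.random.default_rng(13)
        codes = simulate_chromosome_codes(np.linspace(0, 40, 25), 200, rng).T
        noisy = codes.copy()
        bad = rng.random(200) < 0.08
        noisy[12, bad] = 2 - noisy[12, bad]
        _, flags = double_crossover_scan(noisy)
        assert flags[12]
        R, _, _ = pairwise_rf(noisy)
        ids = [f"m{i}" for i in range(25)]
        idx = {m: i for i, m in enumerate(ids)}
        full = map_positions(ids, R, idx)
        kept = [m for i, m in enumerate(ids) if not flags[i]]
        Rk, _, _ = pairwise_rf(noisy[[idx[m] for m in kept]])
        sub = map_positions(kept, Rk, {m: i for i, m in enumerate(kept)})
        assert max(sub.values()) <= max(full.values())


class TestHeatmap:
    def test_correct_order_scores_high_permuted_scores_lower(self):
        rng = np.random.default_rng(14)
        codes = simulate_chromosome_codes(np.linspace(0, 90, 25), 200, rng).T
        R, _, _ = pairwise_rf(codes)
        ids = [f"m{i:02d}" for i in range(25)]
        idx = {m: i for i, m in enumerate(ids)}
        mat, good = rf_heatmap(ids, R, idx)
        assert good > 0.9
        perm = [ids[i] for i in rng.permutation(25)]
        _, bad = rf_heatmap(perm, R, idx)
        assert bad < good
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)
        assert np.allclose(np.diag(mat.to_numpy()), 0.0)


class TestSegments:
    def make_f2(self, rng, pos, n=200):
        codes = simulate_chromosome_codes(pos, n, rng).T
        ids = [f"m{i:02d}" for i in range(len(pos))]
        return F2Matrix(ids, [f"i{j}" for j in range(n)], codes)

    def test_single_segment_is_identity(self):
        rng = np.random.default_rng(15)
        f2 = self.make_f2(rng, np.linspace(0, 30, 8))
        order, pos = assemble_segments([f2.markers], f2)
        assert order == f2.markers
        R, _, _ = pairwise_rf(f2.codes)
        direct = map_positions(f2.markers, R,
                               {m: i for i, m in enumerate(f2.markers)})
        for m in order:
            assert pos[m] == pytest.approx(direct[m], abs=1e-6)

    def test_junction_distance_is_pairwise_estimate(self):
        rng = np.random.default_rng(16)
        f2 = self.make_f2(rng, np.linspace(0, 40, 10))
        seg1, seg2 = f2.markers[:5], f2.markers[5:]
        _, pos = assemble_segments([seg1, seg2], f2)
        pair = estimate_rf(f2.codes[4], f2.codes[5])
        gap = pos[seg2[0]] - pos[seg1[-1]]
        assert gap == pytest.approx(kosambi_cM(pair.r_hat), abs=1e-6)

    def test_split_and_reassemble_length_close_to_unsplit(self):
        rng = np.random.default_rng(17)
        f2 = self.make_f2(rng, np.sort(rng.uniform(0, 100, 30)), n=300)
        whole, wpos = assemble_segments([f2.markers], f2)
        _, spos = assemble_segments([f2.markers[:15], f2.markers[15:]], f2)
        assert max(spos.values()) == pytest.approx(max(wpos.values()),
                                                   rel=0.10)

    def test_overlapping_segments_rejected(self):
        rng = np.random.default_rng(18)
        f2 = self.make_f2(rng, np.linspace(0, 10, 4))
        with pytest.raises(ValueError):
            assemble_segments([f2.markers[:3], f2.markers[2:]], f2)


class TestMapCorrelation:
    def simple_map(self, positions, scale=1.0):
        groups = [list(positions)]
        return GeneticMap(groups, {m: p * scale for m, p in positions.items()},
                          {m: i for i, m in enumerate(positions)})

    def test_self_correlation_is_one(self):
        pos = {f"m{i}": float(i * 3) for i in range(10)}
        m = self.simple_map(pos)
        assert map_correlation(m, m) == pytest.approx(1.0)

    def test_scale_invariance(self):
        pos = {f"m{i}": float(i * 3) for i in range(10)}
        assert map_correlation(self.simple_map(pos),
                               self.simple_map(pos, scale=7.3)) \
            == pytest.approx(1.0)

    def test_too_few_shared_markers_rejected(self):
        a = self.simple_map({"m1": 0.0, "m2": 1.0})
        b = self.simple_map({"m1": 0.0, "x": 1.0})
        with pytest.raises(ValueError):
            map_correlation(a, b)

    def test_independent_f2_draws_correlate(self):
        from peppermap import SimConfig, make_f2_truth, simulate_f2
        truth = make_f2_truth(2, 25, chrom_cM=90.0, seed=30)
        maps = []
        for seed in (31, 32):
            f2 = simulate_f2(truth, 200, SimConfig(seed=seed, missing_rate=0.0))
            maps.append(build_map(f2, lod_min=6.0).gmap)
        assert map_correlation(*maps) >= 0.95


def test_build_map_partitions_bins_within_groups(two_chromosome_f2):
    _, f2 = two_chromosome_f2
    build = build_map(f2, lod_min=6.0)
    gmap = build.gmap
    assert len(gmap.groups) == 2
    assert set(gmap.bins) == set(f2.markers)
    # bins are contiguous runs within each ordered group
    for g in gmap.groups:
        ids = [gmap.bins[m] for m in g]
        seen = set()
        for prev, cur in zip(ids, ids[1:]):
            if cur != prev:
                assert cur not in seen
                seen.add(prev)
    # positions non-decreasing along each group
    for g in gmap.groups:
        pos = [gmap.positions[m] for m in g]
        assert pos == sorted(pos)
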