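import math

import numpy as np
import pytest

from kdcnv.features import FeaturePoint
from kdcnv.rkdos import (
    compute_neighbor_sets,
    extended_set,
    knn,
    lkd,
    rkdos_scores,
    rnn,
    silverman_sigma,
    snn,
)
from oracles import brute_knn, brute_rkdos, brute_rnn, brute_snn, brute_union


def _points(xy):
    return [FeaturePoint(segment_id=i, x=float(x), y=float(y)) for i, (x, y) in enumerate(xy)]


def _random_points(rng, n):
    return _points(rng.normal(size=(n, 2)))


class TestKnn:
    def test_collinear_middle_point(self):
        pts = _points([(0, 0), (1, 0), (3, 0)])
        lists = knn(pts, k=1)
        assert lists[1] == [0]  # nearer endpoint

    def test_duplicate_coordinates_tie_break_by_id(self):
        pts = _points([(0, 0), (1, 0), (1, 0), (1, 0)])
        lists = knn(pts, k=2)
        assert lists[0] == [1, 2]

    def test_k_clamped(self):
        pts = _points([(0, 0), (1, 0), (2, 0)])
        lists = knn(pts, k=10)
        assert all(len(l) == 2 for l in lists)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            knn(_points([(0, 0)]), k=1)

    def test_matches_exhaustive_oracle(self, rng):
        # [DERIVED] all-pairs distance sort
        pts = _random_points(rng, 200)
        xy = np.array([[p.x, p.y] for p in pts])
        assert knn(pts, k=60) == brute_knn(xy, 60)


class TestRnn:
    def test_symmetric_pair(self):
        pts = _points([(0, 0), (1, 0), (10, 0)])
        lists = knn(pts, k=1)
        r = rnn(lists)
        assert 0 in r[1] and 1 in r[0]

    def test_remote_outlier_has_empty_rnn(self):
        pts = _points([(0, 0), (0.1, 0), (0, 0.1), (0.1, 0.1), (100, 100)])
        r = rnn(knn(pts, k=2))
        assert r[4] == []

    def test_matches_transpose_oracle(self, rng):
        pts = _random_points(rng, 100)
        lists = knn(pts, k=10)
        assert [sorted(v) for v in rnn(lists)] == [sorted(v) for v in brute_rnn(lists)]


class TestSnn:
    def test_shared_neighbor_mutual(self):
        pts = _points([(0, 0), (1, 0), (0.5, 0.1)])
        lists = knn(pts, k=1)
        s = snn(lists, pts)
        # 0 and 1 both have 2 as their nearest neighbor => mutual SNN
        assert lists[0] == [2] and lists[1] == [2]
        assert 1 in s[0] and 0 in s[1]

    def test_disjoint_knn_gives_empty_snn(self):
        # with k=1, mutual nearest pairs have knn lists {1},{0},... which
        # are pairwise disjoint, so nobody shares a neighbor with anybody
        pts = _points([(0, 0), (0.1, 0), (100, 0), (100.1, 0)])
        lists = knn(pts, k=1)
        assert snn(lists, pts) == [[], [], [], []]

    def test_matches_pairwise_intersection_oracle(self, rng):
        pts = _random_points(rng, 120)
        lists = knn(pts, k=15)
        xy = np.array([[p.x, p.y] for p in pts])
        assert snn(lists, pts) == brute_snn(lists, xy, 15)


class TestExtendedSet:
    def test_union_falls_back_to_knn(self):
        k = [[1], [0]]
        r = [[], []]
        s = [[], []]
        assert extended_set(k, r, s) == [[1], [0]]

    def test_overlapping_sets_dedup(self):
        k = [[1, 2], [0, 2], [0, 1]]
        assert extended_set(k, k, k) == [[1, 2], [0, 2], [0, 1]]

    def test_self_excluded(self, rng):
        pts = _random_points(rng, 50)
        nsets = compute_neighbor_sets(pts, k=5)
        for i, u in enumerate(nsets.union):
            assert i not in u
            assert len(u) >= 5  # union at least as big as knn

    def test_matches_set_union_oracle(self, rng):
        pts = _random_points(rng, 80)
        nsets = compute_neighbor_sets(pts, k=10)
        assert nsets.union == brute_union(nsets.knn, nsets.rnn, nsets.snn)


class TestLkd:
    def test_single_neighbor_at_distance_zero(self):
        p = FeaturePoint(0, 1.0, 1.0)
        q = FeaturePoint(1, 1.0, 1.0)
        assert lkd(p, [q], sigma=1.0) == pytest.approx(1.0 / (2 * math.pi))

    def test_far_neighbors_vanish(self):
        p = FeaturePoint(0, 0.0, 0.0)
        q = FeaturePoint(1, 1e6, 1e6)
        assert lkd(p, [q], sigma=1.0) == pytest.approx(0.0, abs=1e-300)

    def test_requires_positive_sigma(self):
        p = FeaturePoint(0, 0, 0)
        with pytest.raises(ValueError):
            lkd(p, [p], sigma=0.0)

    def test_matches_summation_oracle(self, rng):
        # [DERIVED] direct re-summation of the kernel formula
        pts = _random_points(rng, 61)
        target, neighbors = pts[0], pts[1:]
        sigma = 0.7
        expected = np.mean(
            [
                (1 / sigma**2)
                * (1 / (2 * math.pi))
                * math.exp(-((n.x - target.x) ** 2 + (n.y - target.y) ** 2) / (2 * sigma**2))
                for n in neighbors
            ]
        )
        assert lkd(target, neighbors, sigma) == pytest.approx(expected, abs=1e-12)


class TestRkdosScores:
    def test_uniform_grid_interior_near_one(self):
        pts = _points([(i, j) for i in range(12) for j in range(12)])
        nsets = compute_neighbor_sets(pts, k=8)
        scored = rkdos_scores(pts, nsets, sigma=1.0)
        interior = [
            s.rkdos
            for s, p in zip(scored, pts)
            if 3 <= p.x <= 8 and 3 <= p.y <= 8
        ]
        assert np.median(interior) == pytest.approx(1.0, abs=0.05)

    def test_far_outlier_scores_highest(self):
        rng = np.random.default_rng(3)
        xy = rng.normal(size=(60, 2)) * 0.1
        xy[0] = [5.0, 5.0]
        pts = _points(xy)
        nsets = compute_neighbor_sets(pts, k=10)
        scored = rkdos_scores(pts, nsets)
        assert max(scored, key=lambda s: s.rkdos).id == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_end_to_end_brute_force(self, seed):
        # [DERIVED] naive O(n^2) reimplementation of the whole scoring chain
        rng = np.random.default_rng(seed)
        xy = np.vstack(
            [rng.normal(size=(150, 2)), rng.normal(loc=4.0, size=(150, 2))]
        )
        pts = _points(xy)
        k, sigma = 60, 0.5
        nsets = compute_neighbor_sets(pts, k=k)
        scored = rkdos_scores(pts, nsets, sigma=sigma)
        knn_o, rnn_o, snn_o, union_o, f_o, scores_o = brute_rkdos(xy, k, sigma)
        assert nsets.knn == knn_o
        assert [sorted(v) for v in nsets.rnn] == [sorted(v) for v in rnn_o]
        assert nsets.snn == snn_o
        assert nsets.union == union_o
        np.testing.assert_allclose([s.lkd for s in scored], f_o, atol=1e-12)
        np.testing.assert_allclose([s.rkdos for s in scored], scores_o, atol=1e-10)

    def test_median_score_near_one_for_gaussian_cloud(self):
        medians = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pts = _points(rng.normal(size=(500, 2)))
            nsets = compute_neighbor_sets(pts, k=60)
            scored = rkdos_scores(pts, nsets)
            medians.append(np.median([s.rkdos for s in scored]))
        assert all(0.9 <= m <= 1.1 for m in medians)

    def test_translation_and_rotation_invariance(self, rng):
        xy = rng.normal(size=(100, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = xy @ rot.T + np.array([5.0, -3.0])
        s1 = rkdos_scores(_points(xy), compute_neighbor_sets(_points(xy), k=20), sigma=0.5)
        s2 = rkdos_scores(
            _points(moved), compute_neighbor_sets(_points(moved), k=20), sigma=0.5
        )
        np.testing.assert_allclose(
            [s.rkdos for s in s1], [s.rkdos for s in s2], rtol=1e-8
        )

    def test_scaling_invariance_with_scaled_sigma(self, rng):
        xy = rng.normal(size=(80, 2))
        c = 3.5
        pts1, pts2 = _points(xy), _points(c * xy)
        s1 = rkdos_scores(pts1, compute_neighbor_sets(pts1, k=15), sigma=0.4)
        s2 = rkdos_scores(pts2, compute_neighbor_sets(pts2, k=15), sigma=0.4 * c)
        np.testing.assert_allclose(
            [s.rkdos for s in s1], [s.rkdos for s in s2], rtol=1e-8
        )

    def test_planted_outliers_rank_top(self):
        # 10 displaced points (>= 6 sd) among a 500-point cluster should be
        # the 10 largest scores in nearly every seed
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            cloud = rng.normal(size=(500, 2))
            # spread angles so displaced points don't collide with each other
            angle = 2 * np.pi * (np.arange(10) + rng.uniform(0, 0.5, 10)) / 10
            radius = rng.uniform(8.0, 12.0, size=10)
            outliers = np.c_[radius * np.cos(angle), radius * np.sin(angle)]
            pts = _points(np.vstack([cloud, outliers]))
            nsets = compute_neighbor_sets(pts, k=60)
            scored = rkdos_scores(pts, nsets)
            top10 = {s.id for s in sorted(scored, key=lambda s: -s.rkdos)[:10]}
            if top10 == set(range(500, 510)):
                hits += 1
        assert hits >= 0.95 * n_seeds


class TestSilverman:
    def test_formula(self, rng):
        pts = _random_points(rng, 100)
        xy = np.array([[p.x, p.y] for p in pts])
        s_hat = np.mean([xy[:, 0].std(ddof=1), xy[:, 1].std(ddof=1)])
        assert silverman_sigma(pts) == pytest.approx(1.06 * s_hat * 100 ** (-0.2))

    def test_degenerate_cloud_rejected(self):
        pts = _points([(1, 1), (1, 1), (1, 1)])
        with pytest.raises(ValueError):
            silverman_sigma(pts)
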