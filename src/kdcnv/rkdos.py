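"""Relative kernel-density outlier scoring.

Each 2-D feature point gets an extended neighbor set — the union of its
k-nearest neighbors, reverse-nearest neighbors (points whose KNN list
contains it) and shared-nearest neighbors (points whose KNN list intersects
its own, capped at the k nearest) — a local kernel density estimated with a
Gaussian kernel over that union, and finally the ratio between the mean
neighbor density and its own density.  Scores near 1 indicate homogeneous
surroundings; scores well above 1 indicate outliers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .features import FeaturePoint

log = logging.getLogger(__name__)


@dataclass
class NeighborSets:
    """Per-point neighbor id lists (indices into the point list)."""

    knn: list[list[int]]
    rnn: list[list[int]]
    snn: list[list[int]]
    union: list[list[int]]


@dataclass(frozen=True)
class ScoredPoint:
    id: int
    lkd: float
    rkdos: float


def _xy(points: list[FeaturePoint]) -> np.ndarray:
    return np.array([[p.x, p.y] for p in points], dtype=float)


def _distance_matrix(xy: np.ndarray) -> np.ndarray:
    d = cdist(xy, xy)
    np.fill_diagonal(d, np.inf)  # self is never a neighbor
    return d


def _clamp_k(k: int, n: int) -> int:
    if k >= n:
        log.warning("k=%d >= n=%d points; clamping to %d", k, n, n - 1)
        return n - 1
    return k


def knn(points: list[FeaturePoint], k: int = 60) -> list[list[int]]:
    """Ids of the *k* Euclidean-nearest points; ties break on smaller id."""
    n = len(points)
    if n < 2:
        raise ValueError("need at least 2 points")
    if k < 1:
        raise ValueError("k must be >= 1")
    k = _clamp_k(k, n)
    d = _distance_matrix(_xy(points))
    # stable argsort on distance => equal distances ordered by id
    order = np.argsort(d, axis=1, kind="stable")
    return [list(map(int, order[i, :k])) for i in range(n)]


def rnn(knn_lists: list[list[int]]) -> list[list[int]]:
    """Reverse nearest neighbors: ``rnn(O) = {q : O in knn(q)}``; may be empty."""
    out: list[list[int]] = [[] for _ in knn_lists]
    for q, neighbors in enumerate(knn_lists):
        for o in neighbors:
            out[o].append(q)
    return out


def snn(
    knn_lists: list[list[int]],
    points: list[FeaturePoint],
    k: int | None = None,
) -> list[list[int]]:
    """Shared nearest neighbors, capped at the *k* nearest qualifying points.

    ``q`` qualifies for ``O`` when their KNN lists intersect.  The cap
    (default: the KNN list length) keeps the extended set O(k)-sized.
    """
    n = len(knn_lists)
    if k is None:
        k = len(knn_lists[0]) if n else 0
    member = np.zeros((n, n), dtype=bool)
    for i, neighbors in enumerate(knn_lists):
        member[i, neighbors] = True
    shares = member @ member.T  # shares[i, q] != 0 iff knn(i) & knn(q) != {}
    d = _distance_matrix(_xy(points))
    out: list[list[int]] = []
    for i in range(n):
        cands = np.flatnonzero(shares[i])
        cands = cands[cands != i]
        if cands.size > k:
            # nearest first; stable sort keeps id order on distance ties
            order = np.argsort(d[i, cands], kind="stable")
            cands = cands[order[:k]]
        out.append(sorted(int(c) for c in cands))
    return out


def extended_set(
    knn_lists: list[list[int]],
    rnn_lists: list[list[int]],
    snn_lists: list[list[int]],
) -> list[list[int]]:
    """Deduplicated union of the three neighbor lists, self excluded."""
    out: list[list[int]] = []
    for i, (a, b, c) in enumerate(zip(knn_lists, rnn_lists, snn_lists)):
        u = set(a) | set(b) | set(c)
        u.discard(i)
        out.append(sorted(u))
    return out


def compute_neighbor_sets(points: list[FeaturePoint], k: int = 60) -> NeighborSets:
    knn_lists = knn(points, k=k)
    rnn_lists = rnn(knn_lists)
    snn_lists = snn(knn_lists, points)
    return NeighborSets(
        knn=knn_lists,
        rnn=rnn_lists,
        snn=snn_lists,
        union=extended_set(knn_lists, rnn_lists, snn_lists),
    )


def silverman_sigma(points: list[FeaturePoint]) -> float:
    """Single scalar KDE bandwidth: ``1.06 * s_hat * n^(-1/5)``.

    ``s_hat`` is the mean of the two coordinate-wise sample standard
    deviations.
    """
    xy = _xy(points)
    n = xy.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points for a bandwidth")
    s_hat = float(np.mean(xy.std(axis=0, ddof=1)))
    sigma = 1.06 * s_hat * n ** (-1 / 5)
    if sigma <= 0:
        raise ValueError("degenerate point cloud: zero bandwidth")
    return sigma


def lkd(point: FeaturePoint, neighbors: list[FeaturePoint], sigma: float) -> float:
    """Gaussian-kernel local density of *point* over its neighbor set (d = 2)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if not neighbors:
        raise ValueError("empty neighbor set")
    xy = _xy(neighbors)
    dx = xy[:, 0] - point.x
    dy = xy[:, 1] - point.y
    sq = dx * dx + dy * dy
    kern = np.exp(-sq / (2.0 * sigma * sigma)) / (2.0 * math.pi)
    return float(np.mean(kern / (sigma * sigma)))


def rkdos_scores(
    points: list[FeaturePoint],
    neighbor_sets: NeighborSets,
    sigma: float | None = None,
) -> list[ScoredPoint]:
    """Score every point: mean neighbor density over own density.

    A zero own-density yields an infinite score (flagged in the log).
    """
    if sigma is None:
        sigma = silverman_sigma(points)
    densities = np.array(
        [
            lkd(p, [points[j] for j in neighbor_sets.union[i]], sigma)
            for i, p in enumerate(points)
        ]
    )
    scored: list[ScoredPoint] = []
    for i in range(len(points)):
        f_o = densities[i]
        mean_neighbor = float(np.mean(densities[neighbor_sets.union[i]]))
        if f_o == 0:
            log.warning("point %d has zero local density; score set to inf", i)
            score = math.inf
        else:
            score = mean_neighbor / f_o
        scored.append(ScoredPoint(id=i, lkd=float(f_o), rkdos=score))
    return scored


def score_points(
    points: list[FeaturePoint],
    k: int = 60,
    sigma: float | None = None,
) -> tuple[NeighborSets, list[ScoredPoint], float]:
    """Convenience wrapper: neighbor sets + scores; returns the sigma used."""
    nsets = compute_neighbor_sets(points, k=k)
    if sigma is None:
        sigma = silverman_sigma(points)
    return nsets, rkdos_scores(points, nsets, sigma=sigma), sigma
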