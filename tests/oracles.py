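"""Independent brute-force oracles used to validate the package.

Everything here is deliberately naive (pure-Python loops, generic convex
solvers) and shares no code with the package implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import lsq_linear


# ---------------------------------------------------------------- intervals
def stab_counts(reads: list[tuple[int, int]], length: int) -> np.ndarray:
    """Per-position coverage by checking every read against every position.

    *reads* are (start, end) 1-based inclusive reference spans.
    """
    counts = np.zeros(length, dtype=int)
    for pos in range(1, length + 1):
        counts[pos - 1] = sum(1 for s, e in reads if s <= pos <= e)
    return counts


# --------------------------------------------------------------- TV denoise
def tv_denoise_dual(y: np.ndarray, lam: float) -> np.ndarray:
    """Exact TV denoising via the box-constrained least-squares dual.

    The minimizer of ``0.5||x - y||^2 + lam * sum|x[i+1]-x[i]|`` is
    ``x = y - D^T z`` where ``z`` solves ``min 0.5||D^T z - y||^2`` subject
    to ``|z_i| <= lam`` (D the forward-difference operator).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n <= 1 or lam == 0:
        return y.copy()
    d = np.zeros((n - 1, n))
    for i in range(n - 1):
        d[i, i] = -1.0
        d[i, i + 1] = 1.0
    res = lsq_linear(d.T, y, bounds=(-lam, lam), tol=1e-14, max_iter=5000)
    return y - d.T @ res.x


def tv_objective(x: np.ndarray, y: np.ndarray, lam: float) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return 0.5 * float(np.sum((x - y) ** 2)) + lam * float(np.sum(np.abs(np.diff(x))))


# ------------------------------------------------------- windowed contrast
def windowed_contrast(x: np.ndarray, m: int) -> np.ndarray:
    """Literal five-regime windowed mean-absolute-difference (1-based)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    out = np.zeros(n)
    for i in range(1, n + 1):
        total = 0.0
        count = 0
        if i == 1:
            lo, hi = i + 1, min(i + m, n)
            for j in range(lo, hi + 1):
                total += abs(x[i - 1] - x[j - 1])
                count += 1
        elif 1 < i <= m:
            for j in range(1, i):
                total += abs(x[i - 1] - x[j - 1])
                count += 1
            for j in range(i + 1, min(i + m, n) + 1):
                total += abs(x[i - 1] - x[j - 1])
                count += 1
        elif m < i <= n - m:
            for j in range(i - m, i):
                total += abs(x[i - 1] - x[j - 1])
                count += 1
            for j in range(i + 1, i + m + 1):
                total += abs(x[i - 1] - x[j - 1])
                count += 1
        elif n - m < i <= n - 1:
            for j in range(i - m, i):
                total += abs(x[i - 1] - x[j - 1])
                count += 1
            for j in range(i + 1, n):  # the last index is excluded here
                total += abs(x[i - 1] - x[j - 1])
                count += 1
        else:  # i == n
            for j in range(i - m, i):
                total += abs(x[i - 1] - x[j - 1])
                count += 1
        out[i - 1] = total / count if count else 0.0
    return out


# ------------------------------------------------------------ neighborhoods
def brute_knn(xy: np.ndarray, k: int) -> list[list[int]]:
    n = len(xy)
    out = []
    for i in range(n):
        ranked = sorted(
            (math.dist(xy[i], xy[j]), j) for j in range(n) if j != i
        )
        out.append([j for _, j in ranked[:k]])
    return out


def brute_rnn(knn_lists: list[list[int]]) -> list[list[int]]:
    return [
        [q for q, neigh in enumerate(knn_lists) if o in neigh]
        for o in range(len(knn_lists))
    ]


def brute_snn(knn_lists: list[list[int]], xy: np.ndarray, k: int) -> list[list[int]]:
    n = len(knn_lists)
    out = []
    for i in range(n):
        shared = [
            q
            for q in range(n)
            if q != i and set(knn_lists[q]) & set(knn_lists[i])
        ]
        if len(shared) > k:
            shared = [
                q
                for _, q in sorted((math.dist(xy[i], xy[q]), q) for q in shared)[:k]
            ]
        out.append(sorted(shared))
    return out


def brute_union(knn_l, rnn_l, snn_l) -> list[list[int]]:
    return [
        sorted((set(a) | set(b) | set(c)) - {i})
        for i, (a, b, c) in enumerate(zip(knn_l, rnn_l, snn_l))
    ]


def brute_lkd(xy: np.ndarray, i: int, union: list[int], sigma: float) -> float:
    total = 0.0
    for j in union:
        sq = (xy[j][0] - xy[i][0]) ** 2 + (xy[j][1] - xy[i][1]) ** 2
        total += (1.0 / sigma**2) * (1.0 / (2 * math.pi)) * math.exp(
            -sq / (2 * sigma**2)
        )
    return total / len(union)


def brute_rkdos(xy: np.ndarray, k: int, sigma: float):
    """Full naive pipeline: neighbor sets, densities and scores."""
    knn_l = brute_knn(xy, k)
    rnn_l = brute_rnn(knn_l)
    snn_l = brute_snn(knn_l, xy, k)
    union = brute_union(knn_l, rnn_l, snn_l)
    f = [brute_lkd(xy, i, union[i], sigma) for i in range(len(xy))]
    scores = []
    for i in range(len(xy)):
        mean_nb = sum(f[j] for j in union[i]) / len(union[i])
        scores.append(math.inf if f[i] == 0 else mean_nb / f[i])
    return knn_l, rnn_l, snn_l, union, f, scores


# ------------------------------------------------------------------ strings
def brute_lcs_substring(a: str, b: str) -> int:
    """Longest common substring by extending every start pair."""
    best = 0
    for i in range(len(a)):
        for j in range(len(b)):
            length = 0
            while (
                i + length < len(a)
                and j + length < len(b)
                and a[i + length] == b[j + length]
            ):
                length += 1
            best = max(best, length)
    return best
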