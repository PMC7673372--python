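"""Segment-level features for outlier scoring.

Two steps: a symmetrization that re-centers segment depths on the modal
(normal-state) value so gains and losses deviate comparably, and the
conversion of the 1-D segment track into 2-D points: a copy-ratio-like
coordinate ``x`` and a local mean-absolute-contrast coordinate ``y``
computed over an exploration window of ``m`` segments on each side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .preprocess import Segment

log = logging.getLogger(__name__)


class FlatProfileError(ValueError):
    """All segment values are identical: nothing can be called."""


@dataclass
class BalancedProfile:
    """Mode-centered, symmetrized segment values."""

    values: np.ndarray = field(repr=False)  # one value per segment
    rds_min: float
    rds_max: float
    rds_mode: float


@dataclass(frozen=True)
class FeaturePoint:
    segment_id: int
    x: float
    y: float


def balance(segments: list[Segment]) -> BalancedProfile:
    """Symmetrize segment depths: ``v' = |min/max| * (v - mode)``.

    The mode is the depth value whose segments cover the largest total
    number of bins; on a genome dominated by the normal state this is the
    normal-depth plateau, which maps to 0.
    """
    if not segments:
        raise ValueError("no segments")
    vals = np.array([s.value for s in segments], dtype=float)
    weights = np.array([s.n_bins for s in segments], dtype=float)
    if np.all(np.abs(vals - vals[0]) <= 1e-12 * max(1.0, abs(vals[0]))):
        raise FlatProfileError("flat profile, nothing to call")
    rds_min = float(vals.min())
    rds_max = float(vals.max())
    if rds_max == 0:
        raise ValueError("maximum segment value is zero; cannot balance")
    uniq, inverse = np.unique(vals, return_inverse=True)
    covered = np.bincount(inverse, weights=weights)
    rds_mode = float(uniq[int(np.argmax(covered))])
    scale = abs(rds_min / rds_max)
    return BalancedProfile(
        values=scale * (vals - rds_mode),
        rds_min=rds_min,
        rds_max=rds_max,
        rds_mode=rds_mode,
    )


def local_contrast(x: np.ndarray, m: int) -> np.ndarray:
    """Mean absolute difference of ``x[i]`` against its window of neighbors.

    The window covers up to *m* indices on each side with five positional
    regimes: the first index uses only the right window, indices up to *m*
    use a truncated left window, interior indices use *m* on each side,
    indices within *m* of the end use a right window truncated at the
    second-to-last index, and the last index uses only the left window.
    Each value is normalized by the number of terms actually summed.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    y = np.zeros(n, dtype=float)
    if n < 2:
        return y
    if m >= n:
        log.warning("local_contrast: m=%d >= n=%d; clamping to %d", m, n, n - 1)
        m = n - 1
    if m < 1:
        raise ValueError("m must be >= 1")
    for i in range(1, n + 1):  # 1-based to mirror the positional regimes
        if i == 1:
            js = range(2, min(1 + m, n) + 1)
        elif i <= m:
            js = list(range(1, i)) + list(range(i + 1, min(i + m, n) + 1))
        elif i <= n - m:
            js = list(range(i - m, i)) + list(range(i + 1, i + m + 1))
        elif i <= n - 1:
            js = list(range(i - m, i)) + list(range(i + 1, n))
        else:  # i == n
            js = range(i - m, i)
        js = list(js)
        if js:
            y[i - 1] = sum(abs(x[i - 1] - x[j - 1]) for j in js) / len(js)
    return y


def to_2d(
    segments: list[Segment],
    balanced: BalancedProfile,
    m: int = 10,
    x_mode: str = "anchored",
) -> list[FeaturePoint]:
    """Build one 2-D feature point per segment.

    ``x`` is a copy-ratio-like coordinate: with ``x_mode="anchored"`` it is
    ``1 + balanced_value / mean(raw segment values)`` so the modal (normal)
    state sits at x = 1, gains above and losses below; ``x_mode="literal"``
    uses the plain ratio ``value / mean(values)`` without symmetrization.
    ``y`` is the local contrast of ``x`` over a window of *m* segments.
    """
    if len(segments) < 2:
        raise ValueError("need at least 2 segments")
    raw = np.array([s.value for s in segments], dtype=float)
    raw_mean = float(raw.mean())
    if raw_mean == 0:
        raise ValueError("mean segment value is zero")
    if x_mode == "anchored":
        x = 1.0 + balanced.values / raw_mean
    elif x_mode == "literal":
        x = raw / raw_mean
    else:
        raise ValueError(f"unknown x_mode {x_mode!r}")
    y = local_contrast(x, m)
    return [
        FeaturePoint(segment_id=s.id, x=float(x[i]), y=float(y[i]))
        for i, s in enumerate(segments)
    ]
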