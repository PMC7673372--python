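"""Benchmarking of call sets against planted or published truth.

Implements reciprocal-overlap matching with one-to-one greedy assignment,
recall/precision/F1, the loss-detection power score, exact boundary
correctness, and the overlapping-density score used to compare call sets
across methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

log = logging.getLogger(__name__)


def _interval(obj) -> tuple[int, int]:
    return int(obj.start), int(obj.end)


def _call_type(obj) -> str:
    t = getattr(obj, "type")
    if t in ("hemi-loss", "homo-loss"):
        return "loss"
    return t


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def match_calls(
    calls: list,
    truth: list,
    min_overlap: float = 0.5,
) -> list[tuple[int, int, int]]:
    """Greedy one-to-one matching of calls to truth intervals.

    A (truth, call) pair is eligible when the call's type agrees with the
    truth's (hemi-/homo-losses count as losses) and they overlap
    reciprocally by at least *min_overlap* of each length.  Pairs are
    assigned largest-overlap first; returns ``(truth_idx, call_idx,
    overlap_bp)`` triples.
    """
    candidates = []
    for ti, t in enumerate(truth):
        for ci, c in enumerate(calls):
            if _call_type(c) != _call_type(t):
                continue
            ti_iv, ci_iv = _interval(t), _interval(c)
            ov = _overlap(ti_iv, ci_iv)
            len_t = ti_iv[1] - ti_iv[0] + 1
            len_c = ci_iv[1] - ci_iv[0] + 1
            if ov >= min_overlap * len_t and ov >= min_overlap * len_c:
                candidates.append((ov, ti, ci))
    candidates.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_t: set[int] = set()
    used_c: set[int] = set()
    matches = []
    for ov, ti, ci in candidates:
        if ti in used_t or ci in used_c:
            continue
        used_t.add(ti)
        used_c.add(ci)
        matches.append((ti, ci, ov))
    return matches


def prf(
    calls: list,
    truth: list,
    min_overlap: float = 0.5,
) -> tuple[float | None, float, float]:
    """Recall, precision and F1 under reciprocal-overlap matching.

    With empty truth, recall is undefined and reported as ``None``; with no
    calls, precision is reported as 0.
    """
    matches = match_calls(calls, truth, min_overlap=min_overlap)
    n_matched = len(matches)
    recall = n_matched / len(truth) if truth else None
    precision = n_matched / len(calls) if calls else 0.0
    if recall is None:
        return None, precision, 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return recall, precision, f1


def p_score(l_n: int, l_fp: int) -> float:
    """Loss-detection power: ``L_n * L_n / (L_n + L_fp)``; 0 when L_n = 0."""
    if l_n < 0 or l_fp < 0:
        raise ValueError("counts must be non-negative")
    if l_n == 0:
        return 0.0
    return l_n * l_n / (l_n + l_fp)


def loss_p_score(
    calls: list,
    truth: list,
    subtype: str | None = None,
    min_overlap: float = 0.5,
) -> float:
    """Power score over loss regions.

    ``L_n`` counts correctly detected truth losses (restricted to *subtype*
    — ``"hemi-loss"`` or ``"homo-loss"`` — when given); ``L_fp`` counts
    loss-typed calls matching no truth loss of any subtype.
    """
    loss_truth = [t for t in truth if t.type in ("hemi-loss", "homo-loss")]
    loss_calls = [c for c in calls if _call_type(c) == "loss"]
    matches = match_calls(loss_calls, loss_truth, min_overlap=min_overlap)
    if subtype is None:
        l_n = len(matches)
    else:
        l_n = sum(1 for ti, _, _ in matches if loss_truth[ti].type == subtype)
    matched_calls = {ci for _, ci, _ in matches}
    l_fp = len(loss_calls) - len(matched_calls)
    return p_score(l_n, l_fp)


def cob(calls: list, truth: list, min_overlap: float = 0.5) -> int:
    """Count exactly-correct boundaries among correctly detected CNVs.

    Start and end coordinates are counted separately, so a perfectly
    refined call contributes 2.
    """
    matches = match_calls(calls, truth, min_overlap=min_overlap)
    n = 0
    for ti, ci, _ in matches:
        t_iv = _interval(truth[ti])
        c_iv = _interval(calls[ci])
        n += int(t_iv[0] == c_iv[0]) + int(t_iv[1] == c_iv[1])
    return n


def ods(my_calls: list, other_call_sets: list[list]) -> float:
    """Overlapping-density score against other methods' call sets.

    ``M_o`` is the mean, over the other sets, of how many of my calls
    overlap (by >= 1 bp) at least one event in that set; ``M_p`` is
    ``M_o`` over my total call count; the score is their product.
    """
    if not other_call_sets:
        raise ValueError("need at least one other call set")
    if not my_calls:
        return 0.0
    per_set = []
    for other in other_call_sets:
        ivs = [_interval(o) for o in other]
        n_ov = sum(
            1 for c in my_calls if any(_overlap(_interval(c), iv) > 0 for iv in ivs)
        )
        per_set.append(n_ov)
    m_o = sum(per_set) / len(per_set)
    m_p = m_o / len(my_calls)
    return m_o * m_p


@dataclass
class Metrics:
    recall: float | None
    precision: float
    f1: float
    p_score_hemi: float
    p_score_homo: float
    cob: int

    def as_dict(self) -> dict:
        return {
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "p_score_hemi": self.p_score_hemi,
            "p_score_homo": self.p_score_homo,
            "cob": self.cob,
        }


def score_sample(calls: list, truth: list, min_overlap: float = 0.5) -> Metrics:
    """All per-sample metrics in one report."""
    recall, precision, f1 = prf(calls, truth, min_overlap=min_overlap)
    return Metrics(
        recall=recall,
        precision=precision,
        f1=f1,
        p_score_hemi=loss_p_score(calls, truth, "hemi-loss", min_overlap=min_overlap),
        p_score_homo=loss_p_score(calls, truth, "homo-loss", min_overlap=min_overlap),
        cob=cob(calls, truth, min_overlap=min_overlap),
    )


def read_bed_calls(path) -> list:
    """Read BED4(+) intervals back as simple call records."""

    @dataclass
    class _BedCall:
        contig: str
        start: int
        end: int
        type: str

    calls = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith(("#", "track", "browser")):
                continue
            calls.append(
                _BedCall(
                    contig=parts[0],
                    start=int(parts[1]) + 1,
                    end=int(parts[2]),
                    type=parts[3] if len(parts) > 3 else ".",
                )
            )
    return calls
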