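"""Split-read boundary refinement of candidate CNV regions.

Split reads falling into windows of half-width ``L`` around each candidate
boundary supply base-precise breakpoints: tandem gains are corrected with
clip-then-match (SM) reads whose clipped sequence re-matches inside the
expanded region; losses are corrected with (match-then-clip, clip-then-
match) read pairs whose clipped sequences overlap enough to witness the
same breakpoint pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .alignment_io import SplitRead
from .calling import CandidateRegion

log = logging.getLogger(__name__)

STATUS_REFINED = "refined"
STATUS_NO_SRS = "no_SRs"
STATUS_LOW_SUPPORT = "low_support"
STATUS_NO_S_MATCH = "no_S_match"


@dataclass
class RefinedCall:
    """A candidate region with (possibly) corrected boundaries."""

    region: CandidateRegion
    start: int  # refined if status == "refined", else the candidate boundary
    end: int
    status: str
    support: int  # qualifying SRs (gain) or SR pairs (loss)

    @property
    def contig(self) -> str:
        return self.region.contig

    @property
    def type(self) -> str | None:
        return self.region.type


def collect_window_srs(
    region: CandidateRegion,
    srs: list[SplitRead],
    L: int,
) -> tuple[list[SplitRead], list[SplitRead]]:
    """Split reads whose POS lies within L of the start / end boundary."""
    if L <= 0:
        raise ValueError("L must be > 0")
    start_win = [sr for sr in srs if region.start - L <= sr.pos <= region.start + L]
    end_win = [sr for sr in srs if region.end - L <= sr.pos <= region.end + L]
    return start_win, end_win


def _find_all(haystack: str, needle: str) -> list[int]:
    """All 0-based occurrence offsets of *needle* in *haystack*."""
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def refine_gain(
    region: CandidateRegion,
    windows: tuple[list[SplitRead], list[SplitRead]],
    ref_seq: str,
    L: int,
    min_support: int = 2,
) -> RefinedCall:
    """Correct a gain region with SM-type split reads.

    A read spanning a tandem-duplication junction maps its suffix at the
    duplicated span's start (the M block, giving the corrected start) while
    its clipped prefix re-occurs at the span's end; the clipped sequence's
    exact match inside the expanded region gives the corrected end
    ``POS_S + n - 1``.  Requires at least *min_support* qualifying reads and
    uses the one with the longest clip.
    """
    if region.type != "gain":
        raise ValueError("refine_gain requires a gain region")
    sm = sorted(
        {sr for sr in windows[0] + windows[1] if sr.cigar_type == "SM"},
        key=lambda sr: (sr.pos, sr.m, sr.seq),
    )
    unrefined = lambda status, support: RefinedCall(  # noqa: E731
        region=region, start=region.start, end=region.end, status=status, support=support
    )
    if not sm:
        return unrefined(STATUS_NO_SRS, 0)

    lo = max(1, region.start - L)  # expanded region, 1-based inclusive
    hi = min(len(ref_seq), region.end + L)
    expanded = ref_seq[lo - 1 : hi]

    qualifying: list[tuple[SplitRead, int]] = []  # (read, POS_S)
    for sr in sm:
        hits = _find_all(expanded, sr.clip_seq)
        if not hits:
            continue
        # several hits: keep the one closest to the uncorrected end boundary
        pos_s = min(
            (lo + h for h in hits), key=lambda p: (abs(p - region.end), p)
        )
        qualifying.append((sr, pos_s))
    if not qualifying:
        return unrefined(STATUS_NO_S_MATCH, 0)
    if len(qualifying) < min_support:
        return unrefined(STATUS_LOW_SUPPORT, len(qualifying))

    # largest clip wins; ties go to the read implying the smallest boundary shift
    sr, pos_s = min(
        qualifying,
        key=lambda t: (-t[0].n, abs(t[0].pos - region.start), t[0].pos),
    )
    new_start = sr.pos  # POS of the M block
    new_end = pos_s + sr.n - 1
    if not (region.start - L <= new_start <= new_end <= region.end + L):
        log.info(
            "refine_gain: implied boundaries %d-%d outside window; leaving unrefined",
            new_start,
            new_end,
        )
        return unrefined(STATUS_NO_S_MATCH, len(qualifying))
    return RefinedCall(
        region=region,
        start=new_start,
        end=new_end,
        status=STATUS_REFINED,
        support=len(qualifying),
    )


def longest_common_substring(a: str, b: str) -> int:
    """Length of the longest common substring (dynamic programming)."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    best = 0
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, 1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def overlap_ratio(sr_a: SplitRead, sr_b: SplitRead) -> float:
    """Clipped-sequence overlap between an MS-type and an SM-type read.

    The longest common substring between either read's clipped block and
    the other read's full sequence, normalized by the shorter clip length
    and capped at 1.  Reads witnessing the same breakpoint share junction
    context, driving the ratio toward 1.
    """
    if sr_a.cigar_type != "MS" or sr_b.cigar_type != "SM":
        raise ValueError("overlap_ratio expects (MS-type, SM-type)")
    if sr_a.n == 0 or sr_b.n == 0:
        return 0.0
    lcs = max(
        longest_common_substring(sr_a.clip_seq, sr_b.seq),
        longest_common_substring(sr_b.clip_seq, sr_a.seq),
    )
    return min(1.0, lcs / min(sr_a.n, sr_b.n))


def refine_loss(
    region: CandidateRegion,
    windows: tuple[list[SplitRead], list[SplitRead]],
    L: int,
    min_support_pairs: int = 2,
    min_overlap: float = 0.6,
) -> RefinedCall:
    """Correct a loss region with (MS, SM) split-read pairs.

    An MS read crossing the left breakpoint gives the corrected start
    ``POS + m``; an SM read mapping just past the deleted span gives the
    corrected end ``POS' - 1``.  Pairs qualify when their clipped sequences
    overlap by more than *min_overlap*; at least *min_support_pairs* pairs
    are required, and the pair with the longest clip wins.
    """
    if region.type != "loss":
        raise ValueError("refine_loss requires a loss region")
    ms_reads = sorted(
        {sr for sr in windows[0] if sr.cigar_type == "MS"},
        key=lambda sr: (sr.pos, sr.m, sr.seq),
    )
    sm_reads = sorted(
        {sr for sr in windows[1] if sr.cigar_type == "SM"},
        key=lambda sr: (sr.pos, sr.m, sr.seq),
    )
    unrefined = lambda status, support: RefinedCall(  # noqa: E731
        region=region, start=region.start, end=region.end, status=status, support=support
    )
    if not ms_reads or not sm_reads:
        return unrefined(STATUS_NO_SRS, 0)

    pairs = [
        (a, b)
        for a in ms_reads
        for b in sm_reads
        if overlap_ratio(a, b) > min_overlap
    ]
    if not pairs:
        return unrefined(STATUS_NO_S_MATCH, 0)
    if len(pairs) < min_support_pairs:
        return unrefined(STATUS_LOW_SUPPORT, len(pairs))

    def rank(pair):
        a, b = pair
        implied_start = a.pos + a.m
        implied_end = b.pos - 1
        return (
            -max(a.n, b.n),
            -(a.n + b.n),
            abs(implied_start - region.start) + abs(implied_end - region.end),
        )

    a, b = min(pairs, key=rank)
    new_start = a.pos + a.m
    new_end = b.pos - 1
    if not (region.start - L <= new_start <= new_end <= region.end + L):
        log.info(
            "refine_loss: implied boundaries %d-%d outside window; leaving unrefined",
            new_start,
            new_end,
        )
        return unrefined(STATUS_NO_S_MATCH, len(pairs))
    return RefinedCall(
        region=region,
        start=new_start,
        end=new_end,
        status=STATUS_REFINED,
        support=len(pairs),
    )


def refine_regions(
    regions: list[CandidateRegion],
    srs: list[SplitRead],
    ref_seq: str,
    L: int,
    min_support: int = 2,
    min_overlap: float = 0.6,
) -> list[RefinedCall]:
    """Refine every typed candidate region with the appropriate strategy."""
    out = []
    for region in regions:
        windows = collect_window_srs(region, srs, L)
        if region.type == "gain":
            out.append(refine_gain(region, windows, ref_seq, L, min_support=min_support))
        elif region.type == "loss":
            out.append(
                refine_loss(
                    region,
                    windows,
                    L,
                    min_support_pairs=min_support,
                    min_overlap=min_overlap,
                )
            )
        else:
            raise ValueError(f"region {region.start}-{region.end} is untyped")
    return out
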