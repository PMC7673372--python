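"""Candidate CNV declaration from outlier scores.

Segments whose score exceeds a threshold are candidates; genomically
adjacent candidates (no intervening non-candidate segment and no assembly
gap) merge into one region, which is typed gain or loss by its bin-weighted
mean copy-ratio coordinate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .features import FeaturePoint
from .preprocess import Segment
from .rkdos import ScoredPoint

log = logging.getLogger(__name__)


@dataclass
class CandidateRegion:
    contig: str
    start: int  # 1-based inclusive
    end: int
    segment_ids: list[int] = field(default_factory=list)
    type: str | None = None  # "gain" | "loss"
    mean_x: float | None = None
    max_rkdos: float = 0.0


def call_candidates(
    scored: list[ScoredPoint],
    segments: list[Segment],
    theta: float = 1.1,
    points: list[FeaturePoint] | None = None,
    contig: str = "",
    merge_gap: int = 0,
    baseline_x: float = 1.0,
) -> list[CandidateRegion]:
    """Declare and merge candidate regions where ``rkdos > theta``.

    Adjacency requires consecutive segment ids with abutting genomic
    coordinates; ``merge_gap`` allows bridging up to that many intervening
    non-candidate segments (still requiring genomic contiguity).  When
    *points* is given each region is typed via :func:`classify_region`.
    """
    if len(scored) != len(segments):
        raise ValueError("scored and segments must be parallel")
    score_by_id = {s.id: s.rkdos for s in scored}
    is_cand = [score_by_id[seg.id] > theta for seg in segments]
    x_by_id = {p.segment_id: p.x for p in points} if points is not None else {}

    regions: list[CandidateRegion] = []
    i = 0
    n = len(segments)
    while i < n:
        if not is_cand[i]:
            i += 1
            continue
        members = [i]
        j = i
        while j + 1 < n:
            # try to extend: directly adjacent candidate, or bridge a short
            # genomically contiguous run of non-candidates
            nxt = j + 1
            bridged = 0
            contiguous = True
            while (
                nxt < n
                and not is_cand[nxt]
                and bridged < merge_gap
            ):
                if segments[nxt].start != segments[nxt - 1].end + 1:
                    contiguous = False
                    break
                bridged += 1
                nxt += 1
            if (
                contiguous
                and nxt < n
                and is_cand[nxt]
                and segments[nxt].start == segments[nxt - 1].end + 1
                and all(
                    segments[t].start == segments[t - 1].end + 1
                    for t in range(j + 1, nxt)
                )
            ):
                members.extend(range(j + 1, nxt + 1))
                j = nxt
            else:
                break
        member_segs = [segments[t] for t in members]
        region = CandidateRegion(
            contig=contig,
            start=member_segs[0].start,
            end=member_segs[-1].end,
            segment_ids=[s.id for s in member_segs],
            max_rkdos=max(score_by_id[s.id] for s in member_segs),
        )
        if points is not None:
            weights = np.array([s.n_bins for s in member_segs], dtype=float)
            xs = np.array([x_by_id[s.id] for s in member_segs], dtype=float)
            region.mean_x = float(np.average(xs, weights=weights))
            region.type = classify_region(region, baseline_x=baseline_x)
        regions.append(region)
        i = j + 1
    if not regions:
        log.info("call_candidates: no segment exceeded theta=%.3g", theta)
    return regions


def classify_region(region: CandidateRegion, baseline_x: float = 1.0) -> str:
    """Type a region: gain if its mean copy-ratio coordinate exceeds baseline."""
    if region.mean_x is None:
        raise ValueError("region has no mean_x; pass feature points when calling")
    if region.mean_x == baseline_x:
        log.warning(
            "region %s:%d-%d sits exactly at baseline; classified as loss",
            region.contig,
            region.start,
            region.end,
        )
        return "loss"
    return "gain" if region.mean_x > baseline_x else "loss"


def extract_cores(
    regions: list[CandidateRegion],
    segments: list[Segment],
    points: list[FeaturePoint],
    scored: list[ScoredPoint] | None = None,
    baseline_x: float = 1.0,
    core_frac: float = 0.5,
    mad_z: float = 3.0,
    min_bins: int = 3,
) -> list[CandidateRegion]:
    """Trim merged candidate regions down to their deviating cores.

    Outlier scoring flags not only CNV segments but also their flanking
    normal segments (whose local-contrast coordinate is inflated by nearby
    CNV values), so merged regions can over-extend past the true event or
    swallow several events.  This pass keeps, within each region, the
    maximal genomically contiguous runs of segments that deviate from
    ``baseline_x`` on one side by at least ``core_frac`` of the region's
    peak deviation on that side — with an absolute floor of ``mad_z``
    robust standard deviations of the genome-wide ``x`` distribution — and
    drops runs shorter than ``min_bins`` bins.  Each surviving run becomes
    its own typed region.
    """
    if not regions:
        return []
    xs_all = np.array([p.x for p in points], dtype=float)
    mad = float(np.median(np.abs(xs_all - np.median(xs_all))))
    floor = mad_z * 1.4826 * mad
    seg_by_id = {s.id: s for s in segments}
    x_by_id = {p.segment_id: p.x for p in points}
    score_by_id = {s.id: s.rkdos for s in scored} if scored is not None else {}

    out: list[CandidateRegion] = []
    for reg in regions:
        members = reg.segment_ids
        devs = {sid: x_by_id[sid] - baseline_x for sid in members}
        for side in (1.0, -1.0):
            side_devs = [side * devs[sid] for sid in members]
            dev_max = max((d for d in side_devs if d > 0), default=0.0)
            if dev_max <= 0:
                continue
            thr = max(core_frac * dev_max, floor)
            keep = [side * devs[sid] >= thr for sid in members]
            i = 0
            while i < len(members):
                if not keep[i]:
                    i += 1
                    continue
                j = i
                while (
                    j + 1 < len(members)
                    and keep[j + 1]
                    and seg_by_id[members[j + 1]].start
                    == seg_by_id[members[j]].end + 1
                ):
                    j += 1
                run = members[i : j + 1]
                run_segs = [seg_by_id[sid] for sid in run]
                if sum(s.n_bins for s in run_segs) >= min_bins:
                    weights = np.array([s.n_bins for s in run_segs], dtype=float)
                    xs = np.array([x_by_id[sid] for sid in run], dtype=float)
                    out.append(
                        CandidateRegion(
                            contig=reg.contig,
                            start=run_segs[0].start,
                            end=run_segs[-1].end,
                            segment_ids=list(run),
                            type="gain" if side > 0 else "loss",
                            mean_x=float(np.average(xs, weights=weights)),
                            max_rkdos=max(
                                (score_by_id.get(sid, reg.max_rkdos) for sid in run),
                                default=reg.max_rkdos,
                            ),
                        )
                    )
                i = j + 1
    out.sort(key=lambda r: r.start)
    return out


def write_bed(regions, path, contig: str | None = None) -> None:
    """Write regions as BED4 (0-based half-open, name = gain/loss)."""
    with open(path, "w") as fh:
        for r in regions:
            chrom = getattr(r, "contig", None) or contig or "."
            name = getattr(r, "type", None) or "."
            fh.write(f"{chrom}\t{r.start - 1}\t{r.end}\t{name}\n")
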