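"""Read-depth preprocessing.

Bins the per-position read-count profile, drops bins overlapping assembly
gaps (reference 'N' runs), calibrates GC bias against per-stratum depth
means, denoises the depth track with an exact 1-D total-variation solver,
and merges the resulting plateaus into read-depth segments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .alignment_io import ReadCountProfile

log = logging.getLogger(__name__)


class NoUsableBinsError(ValueError):
    """Every bin was filtered out (e.g. all overlap 'N' runs)."""


@dataclass(frozen=True)
class Bin:
    """One fixed-width genomic window with its depth and composition."""

    index: int
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    rd: float  # mean read count over the window
    gc: float  # G+C fraction of the reference window
    has_n: bool


@dataclass
class BinProfile:
    """Ordered fixed-width bins for one contig (stored as parallel arrays)."""

    contig: str
    bin_size: int
    start: np.ndarray = field(repr=False)  # 1-based inclusive
    end: np.ndarray = field(repr=False)
    rd: np.ndarray = field(repr=False)
    gc: np.ndarray = field(repr=False)
    has_n: np.ndarray = field(repr=False)

    @property
    def n_bins(self) -> int:
        return int(self.start.size)

    def __len__(self) -> int:
        return self.n_bins

    @property
    def mean_rd(self) -> float:
        return float(self.rd.mean()) if self.n_bins else float("nan")

    def bin(self, i: int) -> Bin:
        return Bin(
            index=i,
            start=int(self.start[i]),
            end=int(self.end[i]),
            rd=float(self.rd[i]),
            gc=float(self.gc[i]),
            has_n=bool(self.has_n[i]),
        )

    def subset(self, mask: np.ndarray) -> "BinProfile":
        return BinProfile(
            contig=self.contig,
            bin_size=self.bin_size,
            start=self.start[mask],
            end=self.end[mask],
            rd=self.rd[mask],
            gc=self.gc[mask],
            has_n=self.has_n[mask],
        )


@dataclass(frozen=True)
class Segment:
    """A maximal run of genomically adjacent bins sharing one denoised value."""

    id: int
    bin_start: int  # index into the filtered bin arrays, inclusive
    bin_end: int  # inclusive
    start: int  # genomic, 1-based inclusive
    end: int
    value: float
    n_bins: int


def make_bins(rc: ReadCountProfile, ref_seq: str, bin_size: int = 2000) -> BinProfile:
    """Partition the contig into non-overlapping ``bin_size`` windows.

    Trailing bases that do not fill a whole bin are dropped.  Each bin
    carries the mean read count, the reference GC fraction and a flag for
    reference 'N' bases.
    """
    length = len(ref_seq)
    if length < bin_size:
        raise ValueError(
            f"contig length {length} shorter than one bin ({bin_size} bp)"
        )
    counts = np.asarray(rc.counts, dtype=float)
    if counts.size < length:
        log.info(
            "make_bins: count profile (%d) shorter than contig (%d); zero-padding",
            counts.size,
            length,
        )
        counts = np.pad(counts, (0, length - counts.size))
    elif counts.size > length:
        raise ValueError("count profile longer than reference contig")

    n_bins = length // bin_size
    used = n_bins * bin_size
    rd = counts[:used].reshape(n_bins, bin_size).mean(axis=1)

    seq_codes = np.frombuffer(ref_seq[:used].upper().encode("ascii"), dtype=np.uint8)
    seq_codes = seq_codes.reshape(n_bins, bin_size)
    is_gc = (seq_codes == ord("G")) | (seq_codes == ord("C"))
    is_n = ~(
        is_gc | (seq_codes == ord("A")) | (seq_codes == ord("T"))
    )
    gc = is_gc.sum(axis=1) / bin_size
    has_n = is_n.any(axis=1)

    starts = np.arange(n_bins, dtype=np.int64) * bin_size + 1
    return BinProfile(
        contig=rc.contig,
        bin_size=bin_size,
        start=starts,
        end=starts + bin_size - 1,
        rd=rd,
        gc=gc,
        has_n=has_n,
    )


def filter_n_bins(profile: BinProfile) -> BinProfile:
    """Drop every bin flagged ``has_n``; genomic coordinates are retained."""
    keep = ~profile.has_n
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("filter_n_bins: dropped %d/%d bins containing 'N'", n_dropped, len(profile))
    if not keep.any():
        raise NoUsableBinsError("no usable bins: every bin contains 'N'")
    return profile.subset(keep)


def gc_correct(profile: BinProfile, gc_bin_width: float = 0.01) -> BinProfile:
    """Rescale each bin's depth by its GC stratum: ``rd' = RDbar * rd / RD_gc``.

    Strata are GC fractions rounded to ``gc_bin_width``.  A stratum whose
    mean depth is zero cannot be rescaled and is left uncorrected.
    """
    if profile.n_bins == 0:
        raise NoUsableBinsError("empty bin profile")
    strata = np.rint(profile.gc / gc_bin_width).astype(np.int64)
    rd_bar = profile.mean_rd
    corrected = profile.rd.astype(float).copy()
    n_zero = 0
    for stratum in np.unique(strata):
        members = strata == stratum
        rd_gc = profile.rd[members].mean()
        if rd_gc == 0:
            n_zero += 1
            continue
        corrected[members] = rd_bar * profile.rd[members] / rd_gc
    if n_zero:
        log.warning("gc_correct: %d strata with zero mean depth left uncorrected", n_zero)
    out = profile.subset(np.ones(profile.n_bins, dtype=bool))
    out.rd = corrected
    return out


def default_tv_lambda(rd: np.ndarray) -> float:
    """Data-driven TV regularization weight.

    Scales the median absolute first difference (a robust noise estimate)
    by ``sqrt(log N)`` so longer profiles are smoothed harder.
    """
    rd = np.asarray(rd, dtype=float)
    if rd.size < 2:
        return 0.0
    med = float(np.median(np.abs(np.diff(rd))))
    return 1.5 * med * math.sqrt(max(math.log(rd.size), 1.0))


def tv_denoise(rd: np.ndarray, lam: float) -> np.ndarray:
    """Exact minimizer of ``0.5*||x - rd||^2 + lam * sum |x[i+1] - x[i]|``.

    Direct non-iterative 1-D total-variation solver; the output is exactly
    piecewise constant, so plateaus can be detected by equality.
    """
    y = np.asarray(rd, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("tv_denoise: input must be finite")
    if lam < 0:
        raise ValueError("tv_denoise: lam must be >= 0")
    n = y.size
    if n == 0:
        return y.copy()
    if lam == 0 or n == 1:
        return y.copy()

    x = np.empty(n, dtype=float)
    k = k0 = km = kp = 0
    vmin = y[0] - lam
    vmax = y[0] + lam
    umin = lam
    umax = -lam

    while True:
        if k == n - 1:  # last sample reached with a pending jump
            x[k] = vmin + umin
            return x
        if y[k + 1] + umin < vmin - lam:  # negative jump is certain
            x[k0 : km + 1] = vmin
            k = k0 = km = kp = km + 1
            vmin = y[k]
            vmax = y[k] + 2 * lam
            umin = lam
            umax = -lam
        elif y[k + 1] + umax > vmax + lam:  # positive jump is certain
            x[k0 : kp + 1] = vmax
            k = k0 = km = kp = kp + 1
            vmin = y[k] - 2 * lam
            vmax = y[k]
            umin = lam
            umax = -lam
        else:  # no jump yet: extend the current plateau
            k += 1
            umin += y[k] - vmin
            umax += y[k] - vmax
            if umin >= lam:
                vmin += (umin - lam) / (k - k0 + 1)
                umin = lam
                km = k
            if umax <= -lam:
                vmax += (umax + lam) / (k - k0 + 1)
                umax = -lam
                kp = k
        if k < n - 1:
            continue
        # end of signal: resolve the pending plateau
        if umin < 0:
            x[k0 : km + 1] = vmin
            k = k0 = km = km + 1
            vmin = y[k]
            umin = lam
            umax = y[k] + lam - vmax
        elif umax > 0:
            x[k0 : kp + 1] = vmax
            k = k0 = kp = kp + 1
            vmax = y[k]
            umax = -lam
            umin = y[k] - lam - vmin
        else:
            x[k0:] = vmin + umin / (k - k0 + 1)
            return x


def to_segments(
    denoised: np.ndarray,
    bins: BinProfile,
    tol: float = 1e-9,
    merge: bool = True,
) -> list[Segment]:
    """Merge runs of equal-valued, genomically adjacent bins into segments.

    A run breaks on a value change (beyond *tol*) or on a coordinate gap
    left by N-bin filtering, so no segment spans an assembly gap.  With
    ``merge=False`` every bin becomes its own segment.
    """
    denoised = np.asarray(denoised, dtype=float)
    if denoised.size != bins.n_bins:
        raise ValueError("denoised length must equal the number of bins")
    segments: list[Segment] = []
    if denoised.size == 0:
        return segments

    run_start = 0
    for i in range(1, denoised.size + 1):
        end_run = i == denoised.size
        if not end_run:
            adjacent = bins.start[i] == bins.end[i - 1] + 1
            same = abs(denoised[i] - denoised[run_start]) <= tol
            if merge and adjacent and same:
                continue
        segments.append(
            Segment(
                id=len(segments),
                bin_start=run_start,
                bin_end=i - 1,
                start=int(bins.start[run_start]),
                end=int(bins.end[i - 1]),
                value=float(denoised[run_start:i].mean()),
                n_bins=i - run_start,
            )
        )
        run_start = i
    return segments
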