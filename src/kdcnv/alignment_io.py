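"""Alignment-file and read-count-table input.

Extracts two things from a coordinate-sorted SAM/BAM file: the per-position
read-count profile used for depth-based calling, and the soft-clipped split
reads used for boundary refinement.  A plain TSV read-count table is
supported as a desk-scale alternative to an alignment file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pysam

log = logging.getLogger(__name__)

_OP_M = 0  # pysam CIGAR op codes
_OP_S = 4


class ContigNotFoundError(KeyError):
    """The requested contig is absent from the alignment header."""


@dataclass
class ReadCountProfile:
    """Per-position read counts for one contig.

    ``counts[i]`` is the number of usable aligned reads whose reference span
    covers 1-based position ``i + 1``.
    """

    contig: str
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-D array")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("read counts must be non-negative")

    def __len__(self) -> int:
        return int(self.counts.size)


@dataclass(frozen=True)
class SplitRead:
    """A read aligned with one matched block and one soft-clipped block.

    ``pos`` is the 1-based leftmost mapped coordinate (SAM POS), i.e. the
    position of the first base of the M block.  ``cigar_type`` is ``"MS"``
    for match-then-clip (``mMnS``) and ``"SM"`` for clip-then-match
    (``nSmM``).
    """

    pos: int
    cigar_type: str
    m: int
    n: int
    seq: str

    def __post_init__(self) -> None:
        if self.cigar_type not in ("MS", "SM"):
            raise ValueError(f"bad cigar_type {self.cigar_type!r}")
        if self.m <= 0 or self.n <= 0:
            raise ValueError("M and S lengths must be positive")

    @property
    def clip_seq(self) -> str:
        """Bases of the soft-clipped (S) block."""
        return self.seq[self.m:] if self.cigar_type == "MS" else self.seq[: self.n]

    @property
    def match_seq(self) -> str:
        """Bases of the matched (M) block."""
        return self.seq[: self.m] if self.cigar_type == "MS" else self.seq[self.n:]

    def cigar(self) -> str:
        if self.cigar_type == "MS":
            return f"{self.m}M{self.n}S"
        return f"{self.n}S{self.m}M"


def _usable(read: "pysam.AlignedSegment") -> bool:
    # mapq 0 / secondary / supplementary / duplicate records are excluded
    # from both depth counting and split-read extraction.
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
        or read.mapping_quality == 0
    )


def read_rc_profile(path, contig: str) -> ReadCountProfile:
    """Count, for every position of *contig*, the usable reads covering it."""
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        if contig not in af.references:
            raise ContigNotFoundError(
                f"contig {contig!r} not in alignment header of {path}"
            )
        length = af.get_reference_length(contig)
        diff = np.zeros(length + 1, dtype=np.int64)
        n_used = 0
        for read in af:
            if not _usable(read) or read.reference_name != contig:
                continue
            start = read.reference_start  # 0-based
            end = read.reference_end  # exclusive
            if end is None or end <= start:
                continue
            diff[min(start, length)] += 1
            diff[min(end, length)] -= 1
            n_used += 1
    counts = np.cumsum(diff[:length])
    log.info("read_rc_profile: %d reads used on %s (%d bp)", n_used, contig, length)
    return ReadCountProfile(contig=contig, counts=counts)


def extract_split_reads(
    path,
    contig: str,
    min_clip: int = 11,
    read_len: int = 100,
) -> list[SplitRead]:
    """Collect reads whose CIGAR is exactly ``mMnS`` or ``nSmM``.

    Only records with ``m + n == read_len`` and clip length ``n >= min_clip``
    qualify; everything else is silently skipped (the skip count is logged).
    """
    srs: list[SplitRead] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        if contig not in af.references:
            raise ContigNotFoundError(
                f"contig {contig!r} not in alignment header of {path}"
            )
        for read in af:
            if not _usable(read) or read.reference_name != contig:
                continue
            ct = read.cigartuples
            if not ct or len(ct) != 2:
                skipped += 1
                continue
            (op1, len1), (op2, len2) = ct
            if (op1, op2) == (_OP_M, _OP_S):
                ctype, m, n = "MS", len1, len2
            elif (op1, op2) == (_OP_S, _OP_M):
                ctype, n, m = "SM", len1, len2
            else:
                skipped += 1
                continue
            seq = read.query_sequence
            if (
                m <= 0
                or n < min_clip
                or m + n != read_len
                or seq is None
                or len(seq) != read_len
            ):
                skipped += 1
                continue
            srs.append(
                SplitRead(pos=read.reference_start + 1, cigar_type=ctype, m=m, n=n, seq=seq)
            )
    log.info(
        "extract_split_reads: %d split reads kept, %d records skipped", len(srs), skipped
    )
    return srs


def read_rc_table(path, contig: str = "rc") -> ReadCountProfile:
    """Read a per-position count table.

    Accepts either one count per line (positions implied 1..N) or two
    whitespace-separated columns ``position<TAB>count``.  A single leading
    non-numeric header row is skipped.  Positions must be strictly
    increasing; unlisted positions get count 0.
    """
    rows: list[tuple[int, int]] = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            try:
                values = [int(p) for p in parts]
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ValueError(f"{path}:{lineno}: non-integer field in {line!r}")
            if len(values) not in (1, 2):
                raise ValueError(f"{path}:{lineno}: expected 1 or 2 columns")
            if ncols is None:
                ncols = len(values)
            elif len(values) != ncols:
                raise ValueError(f"{path}:{lineno}: inconsistent column count")
            if ncols == 1:
                rows.append((len(rows) + 1, values[0]))
            else:
                rows.append((values[0], values[1]))
    if not rows:
        return ReadCountProfile(contig=contig, counts=np.zeros(0, dtype=np.int64))
    positions = np.array([r[0] for r in rows], dtype=np.int64)
    values = np.array([r[1] for r in rows], dtype=np.int64)
    if positions[0] < 1 or np.any(np.diff(positions) <= 0):
        raise ValueError(f"{path}: positions must be strictly increasing and >= 1")
    if np.any(values < 0):
        raise ValueError(f"{path}: negative count")
    counts = np.zeros(int(positions[-1]), dtype=np.int64)
    counts[positions - 1] = values
    return ReadCountProfile(contig=contig, counts=counts)


def write_rc_table(profile: ReadCountProfile, path) -> None:
    """Write a two-column position/count TSV readable by :func:`read_rc_table`."""
    import pandas as pd  # deferred: only needed on the write path

    pd.DataFrame(
        {
            "pos": np.arange(1, len(profile) + 1, dtype=np.int64),
            "count": profile.counts.astype(np.int64),
        }
    ).to_csv(path, sep="\t", header=False, index=False)
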