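"""Self-contained tumor-sample simulator.

Generates everything the pipeline consumes — a random reference contig, a
set of planted CNVs (gains, hemizygous and homozygous losses), a per-
position read-count profile with tumor-purity mixing, GC bias and Poisson
noise, and a SAM file of breakpoint-spanning soft-clipped reads — so each
stage and the end-to-end pipeline can be tested without external data.
All outputs are deterministic functions of the configuration seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .alignment_io import ReadCountProfile, write_rc_table

log = logging.getLogger(__name__)

GAIN = "gain"
HEMI = "hemi-loss"
HOMO = "homo-loss"

_CN = {HEMI: 1, HOMO: 0}  # gains draw their CN per event


@dataclass(frozen=True)
class TruthCNV:
    start: int  # 1-based inclusive
    end: int
    type: str  # gain | hemi-loss | homo-loss
    cn: int

    def __post_init__(self):
        if self.type not in (GAIN, HEMI, HOMO):
            raise ValueError(f"bad CNV type {self.type!r}")
        if self.start > self.end:
            raise ValueError("start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SimConfig:
    contig: str = "sim0"
    contig_length: int = 5_000_000
    bin_size: int = 2000
    tumor_purity: float = 0.2
    coverage: float = 30.0
    read_len: int = 100
    seed: int = 1
    gc_bias_amp: float = 0.3
    gc_gradient: bool = True
    noise: str = "poisson"  # or "nb"
    nb_dispersion: float = 10.0  # NB size parameter when noise == "nb"
    n_gains: int = 6
    n_hemi: int = 4
    n_homo: int = 4
    cnv_min_len: int = 10_000
    cnv_max_len: int = 100_000
    min_sep_bins: int = 5
    sr_per_breakpoint: int = 4
    n_background_reads: int = 200
    n_runs: tuple = ()  # ((start, length), ...) of planted reference N runs

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        data = json.loads(text)
        data["n_runs"] = tuple(tuple(r) for r in data.get("n_runs", ()))
        return cls(**data)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def make_reference(
    length: int,
    seed: int,
    gc_gradient: bool = True,
    n_runs: tuple = (),
    gc_period: int = 1_000_000,
) -> str:
    """Random A/C/G/T contig with optional sinusoidal GC drift and N runs."""
    if length < 10**5:
        raise ValueError("reference length must be >= 1e5")
    rng = _rng(seed, 0)
    pos = np.arange(length)
    p_gc = np.full(length, 0.5)
    if gc_gradient:
        # large-scale drift plus fine-scale (2 kb block) composition noise,
        # so equal-GC windows are scattered across the contig as in a real
        # genome rather than pinned to a few loci
        p_gc = p_gc + 0.08 * np.sin(2 * np.pi * pos / gc_period)
        block = np.repeat(rng.normal(0.0, 0.05, size=length // 2000 + 1), 2000)[:length]
        p_gc = np.clip(p_gc + block, 0.25, 0.75)
    is_gc = rng.random(length) < p_gc
    second = rng.random(length) < 0.5
    codes = np.where(
        is_gc,
        np.where(second, ord("G"), ord("C")),
        np.where(second, ord("A"), ord("T")),
    ).astype(np.uint8)
    for start, run_len in n_runs:
        if start < 1 or start + run_len - 1 > length:
            raise ValueError(f"N run ({start}, {run_len}) outside contig")
        codes[start - 1 : start - 1 + run_len] = ord("N")
    return codes.tobytes().decode("ascii")


def plant_cnvs(
    length: int,
    seed: int,
    n_gains: int = 6,
    n_hemi: int = 4,
    n_homo: int = 4,
    min_len: int = 10_000,
    max_len: int = 100_000,
    bin_size: int = 2000,
    min_sep_bins: int = 5,
    edge_margin: int = 50_000,
    max_attempts: int = 10_000,
) -> list[TruthCNV]:
    """Plant disjoint CNVs by rejection sampling, sorted by position.

    Events are separated by at least ``min_sep_bins`` bins and stay
    ``edge_margin`` away from the contig ends (so breakpoint-spanning reads
    always fit on the contig).
    """
    rng = _rng(seed, 1)
    types = [GAIN] * n_gains + [HEMI] * n_hemi + [HOMO] * n_homo
    if len(types) * max_len >= 0.3 * length:
        raise ValueError("requested CNVs could span >= 30% of the contig")
    placed: list[TruthCNV] = []
    min_sep = min_sep_bins * bin_size
    for cnv_type in types:
        ok = False
        for _ in range(max_attempts):
            size = int(rng.integers(min_len, max_len + 1))
            start = int(rng.integers(edge_margin, length - edge_margin - size + 1))
            end = start + size - 1
            if all(
                end + min_sep < p.start or start - min_sep > p.end for p in placed
            ):
                cn = int(rng.integers(3, 7)) if cnv_type == GAIN else _CN[cnv_type]
                placed.append(TruthCNV(start=start, end=end, type=cnv_type, cn=cn))
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place a {cnv_type} after {max_attempts} attempts"
            )
    placed.sort(key=lambda c: c.start)
    return placed


def _copy_number(length: int, truth: list[TruthCNV]) -> np.ndarray:
    cn = np.full(length, 2.0)
    for t in truth:
        cn[t.start - 1 : t.end] = t.cn
    return cn


def _bin_gc(ref: str, bin_size: int) -> np.ndarray:
    """Per-position GC fraction, constant within each bin-sized window."""
    codes = np.frombuffer(ref.upper().encode("ascii"), dtype=np.uint8)
    is_gc = (codes == ord("G")) | (codes == ord("C"))
    length = codes.size
    n_bins = (length + bin_size - 1) // bin_size
    gc_pos = np.empty(length)
    for b in range(n_bins):
        lo, hi = b * bin_size, min((b + 1) * bin_size, length)
        gc_pos[lo:hi] = is_gc[lo:hi].mean()
    return gc_pos


def simulate_rc(ref: str, truth: list[TruthCNV], cfg: SimConfig) -> ReadCountProfile:
    """Per-position counts ``~ Poisson(SC * g(GC) * [TP*CN/2 + (1-TP)])``.

    ``g`` is a mild concave multiplicative GC-bias curve equal to 1 at 50%
    GC.  Positions inside reference N runs get zero counts.
    """
    length = len(ref)
    rng = _rng(cfg.seed, 2)
    mix = cfg.tumor_purity * _copy_number(length, truth) / 2.0 + (1.0 - cfg.tumor_purity)
    gc_pos = _bin_gc(ref, cfg.bin_size)
    g = 1.0 - cfg.gc_bias_amp * (2.0 * gc_pos - 1.0) ** 2
    lam = cfg.coverage * g * mix
    codes = np.frombuffer(ref.upper().encode("ascii"), dtype=np.uint8)
    is_n = ~np.isin(codes, [ord(c) for c in "ACGT"])
    lam[is_n] = 0.0
    if cfg.noise == "poisson":
        counts = rng.poisson(lam)
    elif cfg.noise == "nb":
        size = cfg.nb_dispersion
        # NB as Poisson with Gamma-distributed rate (mean lam, shape size)
        rates = rng.gamma(shape=size, scale=np.maximum(lam, 1e-12) / size)
        counts = rng.poisson(rates)
        counts[lam == 0] = 0
    else:
        raise ValueError(f"unknown noise model {cfg.noise!r}")
    return ReadCountProfile(contig=cfg.contig, counts=counts.astype(np.int64))


@dataclass(frozen=True)
class _SamRecord:
    qname: str
    pos: int
    cigar: str
    seq: str

    def line(self, contig: str) -> str:
        return (
            f"{self.qname}\t0\t{contig}\t{self.pos}\t60\t{self.cigar}\t*\t0\t0\t"
            f"{self.seq}\t*\n"
        )


def simulate_split_reads(ref: str, truth: list[TruthCNV], cfg: SimConfig, path) -> None:
    """Write a coordinate-sorted SAM with breakpoint-spanning reads.

    Deletions get MS reads at the left breakpoint and SM reads at the
    right; tandem gains get SM reads at the duplication junction whose
    clipped prefix matches the end of the duplicated span.  Clip lengths
    are uniform in [11, 60].  Fully matched background reads are added at
    random positions.
    """
    rng = _rng(cfg.seed, 3)
    rl = cfg.read_len
    records: list[_SamRecord] = []

    def clip_len() -> int:
        return int(rng.integers(11, 61))

    for t in truth:
        s, e = t.start, t.end
        for _ in range(cfg.sr_per_breakpoint):
            if t.type == GAIN:
                # junction read: suffix maps at s (M), clipped prefix is the
                # last n bases of the duplicated span
                n = clip_len()
                m = rl - n
                seq = ref[e - n : e] + ref[s - 1 : s - 1 + m]
                records.append(_SamRecord(qname="", pos=s, cigar=f"{n}S{m}M", seq=seq))
            else:  # deletion breakpoints
                n = clip_len()
                m = rl - n
                seq = ref[s - m - 1 : s - 1] + ref[e : e + n]
                records.append(
                    _SamRecord(qname="", pos=s - m, cigar=f"{m}M{n}S", seq=seq)
                )
                n2 = clip_len()
                m2 = rl - n2
                seq2 = ref[s - 1 - n2 : s - 1] + ref[e : e + m2]
                records.append(
                    _SamRecord(qname="", pos=e + 1, cigar=f"{n2}S{m2}M", seq=seq2)
                )

    length = len(ref)
    n_bg = 0
    while n_bg < cfg.n_background_reads:
        pos = int(rng.integers(1, length - rl + 1))
        seq = ref[pos - 1 : pos - 1 + rl]
        if "N" in seq:
            continue
        records.append(_SamRecord(qname="", pos=pos, cigar=f"{rl}M", seq=seq))
        n_bg += 1

    records.sort(key=lambda r: (r.pos, r.cigar, r.seq))
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{cfg.contig}\tLN:{length}\n")
        for i, rec in enumerate(records):
            fh.write(
                _SamRecord(qname=f"r{i:06d}", pos=rec.pos, cigar=rec.cigar, seq=rec.seq).line(
                    cfg.contig
                )
            )
    log.info("simulate_split_reads: wrote %d records to %s", len(records), path)


def write_fasta(seq: str, contig: str, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width])
            fh.write("\n")


def write_truth_bed(truth: list[TruthCNV], contig: str, path) -> None:
    """BED with name = CNV type and score column = copy number."""
    with open(path, "w") as fh:
        for t in truth:
            fh.write(f"{contig}\t{t.start - 1}\t{t.end}\t{t.type}\t{t.cn}\n")


def read_truth_bed(path) -> list[TruthCNV]:
    truth = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            truth.append(
                TruthCNV(
                    start=int(parts[1]) + 1,
                    end=int(parts[2]),
                    type=parts[3],
                    cn=int(parts[4]),
                )
            )
    return truth


@dataclass
class SimulatedSample:
    cfg: SimConfig
    ref: str
    truth: list[TruthCNV]
    rc: ReadCountProfile
    sam_path: Path | None = None


def simulate_sample(cfg: SimConfig, out_dir=None) -> SimulatedSample:
    """Generate a full sample; optionally persist all artifacts to *out_dir*."""
    ref = make_reference(
        cfg.contig_length, cfg.seed, gc_gradient=cfg.gc_gradient, n_runs=cfg.n_runs
    )
    truth = plant_cnvs(
        cfg.contig_length,
        cfg.seed,
        n_gains=cfg.n_gains,
        n_hemi=cfg.n_hemi,
        n_homo=cfg.n_homo,
        min_len=cfg.cnv_min_len,
        max_len=cfg.cnv_max_len,
        bin_size=cfg.bin_size,
        min_sep_bins=cfg.min_sep_bins,
    )
    rc = simulate_rc(ref, truth, cfg)
    sample = SimulatedSample(cfg=cfg, ref=ref, truth=truth, rc=rc)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(ref, cfg.contig, out_dir / "ref.fa")
        write_rc_table(rc, out_dir / "rc.tsv")
        write_truth_bed(truth, cfg.contig, out_dir / "truth.bed")
        sam_path = out_dir / "reads.sam"
        simulate_split_reads(ref, truth, cfg, sam_path)
        (out_dir / "config.json").write_text(cfg.to_json() + "\n")
        sample.sam_path = sam_path
    return sample
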