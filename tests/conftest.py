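import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from kdcnv import simulate


def write_sam(path, records, contig="sim0", length=100_000):
    """Write a minimal SAM file.

    *records* are (qname, flag, pos, mapq, cigar, seq) tuples.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{contig}\tLN:{length}\n")
        for qname, flag, pos, mapq, cigar, seq in records:
            fh.write(
                f"{qname}\t{flag}\t{contig}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t*\n"
            )
    return path


@pytest.fixture
def sam_writer(tmp_path):
    def _write(records, name="test.sam", **kwargs):
        return write_sam(tmp_path / name, records, **kwargs)

    return _write


@pytest.fixture(scope="session")
def small_sample():
    """A 1.5 Mb simulated tumor sample shared across tests (read-only)."""
    cfg = simulate.SimConfig(
        contig_length=1_500_000,
        n_gains=2,
        n_hemi=1,
        n_homo=1,
        cnv_min_len=20_000,
        cnv_max_len=60_000,
        seed=7,
        tumor_purity=0.2,
    )
    return simulate.simulate_sample(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
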