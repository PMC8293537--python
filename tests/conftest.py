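import numpy as np
import pandas as pd
import pytest

from mccnv import CountMatrix, SimulationConfig, simulate_pool


SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:100000\n@SQ\tSN:chr2\tLN:100000\n"


def sam_pair(qname, chrom, pos1, pos2, mapq1=60, mapq2=60, dup=False, proper=True,
             read_len=50):
    """Two SAM records for one read pair (1-based positions)."""
    f1, f2 = 0x1 | 0x40 | 0x20, 0x1 | 0x80 | 0x10
    if proper:
        f1 |= 0x2
        f2 |= 0x2
    if dup:
        f1 |= 0x400
        f2 |= 0x400
    tlen = pos2 + read_len - pos1
    r1 = (f"{qname}\t{f1}\t{chrom}\t{pos1}\t{mapq1}\t{read_len}M\t=\t{pos2}\t{tlen}\t"
          + "A" * read_len + "\t" + "I" * read_len)
    r2 = (f"{qname}\t{f2}\t{chrom}\t{pos2}\t{mapq2}\t{read_len}M\t=\t{pos1}\t{-tlen}\t"
          + "A" * read_len + "\t" + "I" * read_len)
    return [(pos1, r1), (pos2, r2)]


def write_sam(path, pairs):
    """Write records coordinate-sorted, as the counter requires."""
    recs = []
    for p in pairs:
        recs.extend(p)
    recs.sort(key=lambda t: t[0])
    with open(path, "w") as fh:
        fh.write(SAM_HEADER)
        for _, line in recs:
            fh.write(line + "\n")
    return path


@pytest.fixture
def small_counts():
    """Tiny deterministic count matrix: 3 subjects x 4 targets."""
    targets = pd.DataFrame(
        {
            "chrom": ["chr1"] * 4,
            "start": [100, 500, 900, 1300],
            "end": [250, 650, 1050, 1450],
            "target_id": ["T1", "T2", "T3", "T4"],
        }
    )
    counts = pd.DataFrame(
        [[100, 200, 300, 400], [110, 190, 310, 390], [90, 210, 290, 410]],
        index=["A", "B", "C"],
        columns=["T1", "T2", "T3", "T4"],
    )
    return CountMatrix(counts, targets)


@pytest.fixture(scope="session")
def medium_pool():
    """One simulated pool at recommended depth, reused across tests."""
    cfg = SimulationConfig(
        n_subjects=16, n_targets=2000, depth=225 * 2000, variant_prob=1e-3, seed=42
    )
    return simulate_pool(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
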