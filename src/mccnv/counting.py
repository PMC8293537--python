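"""Per-target molecule (read-pair) counting from paired-end alignments.

A molecule is the physical DNA fragment represented by a read pair; its
reference span runs from the leftmost mapped base of either mate to the
rightmost, half-open. A molecule is counted toward every target its span
overlaps by at least one base, and at most once per target. Inclusion
filters: the pair is flagged properly paired, both mates map to the same
chromosome with mapping quality >= ``min_mapq`` (default 20), and no
contributing record is a duplicate, secondary, or supplementary
alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .matrix import CountMatrix, read_counts, write_counts

__all__ = [
    "TargetSet",
    "read_bed",
    "count_molecules",
    "CountMatrix",
    "read_counts",
    "write_counts",
]


@dataclass
class TargetSet:
    """Sorted capture targets with unique ids (BED 0-based half-open)."""

    table: pd.DataFrame  # columns chrom, start, end, target_id

    def __post_init__(self):
        t = self.table
        if (t["end"] <= t["start"]).any():
            bad = t.loc[t["end"] <= t["start"]].iloc[0]
            raise ValueError(
                f"zero/negative-length target {bad['chrom']}:{bad['start']}-{bad['end']}"
            )
        if t["target_id"].duplicated().any():
            dup = t.loc[t["target_id"].duplicated(), "target_id"].iloc[0]
            raise ValueError(f"duplicate target id {dup!r}")
        self.table = t.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    def __len__(self):
        return len(self.table)

    @property
    def target_ids(self) -> list:
        return list(self.table["target_id"])

    def trees(self) -> dict:
        """Per-chromosome interval trees mapping spans to row indices."""
        out: dict[str, IntervalTree] = {}
        for idx, row in self.table.iterrows():
            out.setdefault(row["chrom"], IntervalTree()).addi(row["start"], row["end"], idx)
        return out


def read_bed(path) -> TargetSet:
    """Read BED3+ targets; column 4 supplies target ids when present."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            tid = parts[3] if len(parts) > 3 and parts[3] else f"{chrom}:{start}-{end}"
            rows.append((chrom, start, end, tid))
    if not rows:
        raise ValueError(f"{path}: no targets found")
    return TargetSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "target_id"]))


def _record_ok(rec: pysam.AlignedSegment, qc: dict) -> bool:
    """Record-level exclusion filters; increments failure tallies."""
    if rec.is_unmapped or rec.mate_is_unmapped:
        qc["failed_unmapped"] += 1
        return False
    if rec.is_secondary or rec.is_supplementary:
        qc["failed_secondary_supplementary"] += 1
        return False
    if rec.is_duplicate:
        qc["failed_duplicate"] += 1
        return False
    if not rec.is_proper_pair:
        qc["failed_not_proper_pair"] += 1
        return False
    if rec.reference_id != rec.next_reference_id:
        qc["failed_mate_other_chrom"] += 1
        return False
    return True


def count_molecules(alignments, targets: TargetSet, min_mapq: int = 20):
    """Count passing molecules overlapping each target.

    Parameters
    ----------
    alignments : str or pysam.AlignmentFile
        Coordinate-sorted SAM/BAM. BAM files additionally require an
        index only when opened for random access elsewhere; counting
        itself streams sequentially.
    targets : TargetSet
    min_mapq : int
        Both mates must have mapping quality >= this value.

    Returns
    -------
    counts : pandas.Series
        One non-negative integer per target id, in target order.
    qc : dict
        Molecules seen / passed and per-filter record failure tallies.
    """
    own = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments))
        own = True
    try:
        so = (alignments.header.to_dict().get("HD") or {}).get("SO")
        if so != "coordinate":
            raise ValueError(
                f"alignments must be coordinate-sorted (header SO={so!r})"
            )
        header_chroms = set(alignments.references or ())
        missing = sorted(set(targets.table["chrom"]) - header_chroms)
        if missing:
            warnings.warn(
                "target chromosome(s) absent from alignment header, counts "
                f"will be zero there: {', '.join(missing)}"
            )

        trees = targets.trees()
        counts = np.zeros(len(targets), dtype=np.int64)
        qc = {
            "molecules_seen": 0,
            "molecules_passed": 0,
            "failed_unmapped": 0,
            "failed_secondary_supplementary": 0,
            "failed_duplicate": 0,
            "failed_not_proper_pair": 0,
            "failed_mate_other_chrom": 0,
            "failed_mapq": 0,
        }
        pending: dict[str, tuple] = {}
        for rec in alignments:
            if not _record_ok(rec, qc):
                continue
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = (
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    rec.mapping_quality,
                )
                continue
            chrom, m_start, m_end, m_mapq = mate
            qc["molecules_seen"] += 1
            if rec.mapping_quality < min_mapq or m_mapq < min_mapq:
                qc["failed_mapq"] += 1
                continue
            span_start = min(m_start, rec.reference_start)
            span_end = max(m_end, rec.reference_end)
            qc["molecules_passed"] += 1
            tree = trees.get(chrom)
            if tree is None:
                continue
            for iv in tree.overlap(span_start, span_end):
                counts[iv.data] += 1
        return pd.Series(counts, index=targets.target_ids, name="count"), qc
    finally:
        if own:
            alignments.close()
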