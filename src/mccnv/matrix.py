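"""The subjects x targets count matrix and its TSV representation.

The count matrix is the universal interchange object of the package:
the counting step produces one, the simulator produces one, and the
caller and the Dirichlet profiler consume one. On disk it is a
tab-separated file with a version comment line, a header row naming the
target-metadata columns followed by the subject ids, and one row per
target::

    # mccnv counts v1
    chrom  start  end  target_id  S01  S02 ...
    chr1   1000   1150 T000001    231  198 ...

Copy-state matrices (simulated truth or estimated states) use the same
layout with float cells and a ``# mccnv states v1`` header.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COUNTS_MAGIC = "# mccnv counts v1"
STATES_MAGIC = "# mccnv states v1"

_META_COLS = ["chrom", "start", "end", "target_id"]


@dataclass
class CountMatrix:
    """Non-negative integer molecule counts for one pool.

    Parameters
    ----------
    counts : pandas.DataFrame
        Subjects (rows) x targets (columns); columns are target ids.
    targets : pandas.DataFrame
        One row per target with columns ``chrom``, ``start``, ``end``,
        ``target_id``; order matches the columns of ``counts``.
    """

    counts: pd.DataFrame
    targets: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.targets is None:
            ids = list(self.counts.columns)
            self.targets = pd.DataFrame(
                {
                    "chrom": "chrU",
                    "start": np.arange(len(ids)) * 1000,
                    "end": np.arange(len(ids)) * 1000 + 150,
                    "target_id": ids,
                }
            )
        self.validate()

    # -- contracts -------------------------------------------------------
    def validate(self) -> None:
        t = self.targets
        if list(t.columns[:4]) != _META_COLS:
            raise ValueError(f"target metadata must have columns {_META_COLS}")
        if t["target_id"].duplicated().any():
            dup = t.loc[t["target_id"].duplicated(), "target_id"].iloc[0]
            raise ValueError(f"duplicate target id: {dup!r}")
        if (t["end"] <= t["start"]).any():
            bad = t.loc[t["end"] <= t["start"], "target_id"].iloc[0]
            raise ValueError(f"target {bad!r} has end <= start")
        if list(self.counts.columns) != list(t["target_id"]):
            raise ValueError("counts columns do not match target metadata order")
        vals = self.counts.to_numpy()
        if vals.size and (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative count at subject {self.counts.index[i]!r}, "
                f"target {self.counts.columns[j]!r}"
            )

    # -- convenience -----------------------------------------------------
    @property
    def subjects(self) -> list:
        return list(self.counts.index)

    @property
    def target_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple:
        return self.counts.shape

    def to_numpy(self) -> np.ndarray:
        return self.counts.to_numpy()

    def subset_targets(self, target_ids) -> "CountMatrix":
        keep = list(target_ids)
        t = self.targets.set_index("target_id").loc[keep].reset_index()
        t = t[_META_COLS]
        return CountMatrix(self.counts[keep].copy(), t)


def _write_matrix(df: pd.DataFrame, targets: pd.DataFrame, path, magic: str) -> None:
    wide = targets[_META_COLS].copy()
    block = df.T
    block.columns = df.index
    wide = pd.concat([wide.reset_index(drop=True), block.reset_index(drop=True)], axis=1)
    buf = io.StringIO()
    buf.write(magic + "\n")
    wide.to_csv(buf, sep="\t", index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _read_matrix(path, magic: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != magic:
            raise ValueError(
                f"{path}: expected version line {magic!r}, found {first!r}"
            )
        body = pd.read_csv(fh, sep="\t")
    for col in _META_COLS:
        if col not in body.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    subjects = [c for c in body.columns if c not in _META_COLS]
    if not subjects:
        raise ValueError(f"{path}: no subject columns found")
    targets = body[_META_COLS].copy()
    values = body[subjects].T
    values.columns = targets["target_id"]
    values.columns.name = None
    return values, targets


def write_counts(cm: CountMatrix, path) -> None:
    """Write a count matrix to its TSV representation (lossless)."""
    _write_matrix(cm.counts, cm.targets, path, COUNTS_MAGIC)


def read_counts(path) -> CountMatrix:
    """Read a count matrix TSV, validating version line and cell types."""
    values, targets = _read_matrix(path, COUNTS_MAGIC)
    arr = values.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        flo = values.astype(float)
        if not np.all(np.mod(flo.to_numpy(), 1) == 0):
            bad = np.argwhere(np.mod(flo.to_numpy(), 1) != 0)[0]
            raise ValueError(
                f"{path}: non-integer count at subject {values.index[bad[0]]!r}, "
                f"target {values.columns[bad[1]]!r}"
            )
        values = flo.astype(np.int64)
    return CountMatrix(values, targets)


def write_states(states: pd.DataFrame, targets: pd.DataFrame, path) -> None:
    """Write a copy-state matrix (float multipliers, 1 = diploid)."""
    _write_matrix(states, targets, path, STATES_MAGIC)


def read_states(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a copy-state matrix; returns (states, target metadata)."""
    values, targets = _read_matrix(path, STATES_MAGIC)
    return values.astype(float), targets
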