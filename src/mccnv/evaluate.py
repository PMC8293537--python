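"""Exon-level benchmarking of call sets against known copy states.

The unit of evaluation is the (subject, exon) pair. A pair is a true
positive when it is flagged and the called direction (duplication:
state > 1; deletion: state < 1) matches the truth direction; a flagged
pair whose truth is diploid — or whose direction disagrees — is a false
positive. Metrics can be stratified to duplications or deletions only,
and a target exclusion mask (e.g. repetitive/low-complexity regions)
removes pairs from the tally entirely.

Zero-denominator conventions: FDR = 0 with no positives, TPR = NaN with
no true variants, MCC = 0 when any confusion-margin is empty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = ["ConfusionSummary", "confusion", "overlap_sets", "sweep_depths"]


@dataclass
class ConfusionSummary:
    """Confusion counts with the standard derived metrics."""

    tp: int
    fp: int
    tn: int
    fn: int
    stratum: str = "ALL"

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def tpr(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else math.nan

    @property
    def fdr(self) -> float:
        d = self.tp + self.fp
        return self.fp / d if d else 0.0

    @property
    def ppv(self) -> float:
        return 1.0 - self.fdr

    @property
    def tnr(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else math.nan

    @property
    def balanced_accuracy(self) -> float:
        return (self.tpr + self.tnr) / 2

    @property
    def mcc(self) -> float:
        tp, fp, tn, fn = self.tp, self.fp, self.tn, self.fn
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        if denom == 0:
            return 0.0
        return (tp * tn - fp * fn) / math.sqrt(denom)

    def as_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "TP": self.tp,
            "FP": self.fp,
            "TN": self.tn,
            "FN": self.fn,
            "MCC": self.mcc,
            "TPR": self.tpr,
            "FDR": self.fdr,
            "PPV": self.ppv,
            "BalAcc": self.balanced_accuracy,
        }


def _align(calls_states, called, truth):
    """Coerce the three matrices to aligned numpy arrays."""
    frames = [calls_states, called, truth]
    if all(isinstance(f, pd.DataFrame) for f in frames):
        base = calls_states
        for other, name in ((called, "called"), (truth, "truth")):
            if list(other.index) != list(base.index) or list(other.columns) != list(
                base.columns
            ):
                missing_r = sorted(set(base.index) ^ set(other.index))
                missing_c = sorted(set(base.columns) ^ set(other.columns))
                raise ValueError(
                    f"{name} matrix index mismatch; differing subjects "
                    f"{missing_r[:5]} / targets {missing_c[:5]}"
                )
        return (f.to_numpy() for f in frames)
    arrs = [np.asarray(f) for f in frames]
    if not (arrs[0].shape == arrs[1].shape == arrs[2].shape):
        raise ValueError("states, called and truth must share one shape")
    return arrs


def confusion(
    states,
    called,
    truth,
    stratum: str = "ALL",
    exclude=None,
) -> ConfusionSummary:
    """Score exon-level calls against truth for one stratum.

    Parameters
    ----------
    states : estimated copy-state matrix (subjects x targets)
    called : boolean matrix of flagged cells
    truth : true copy-state matrix, 1 = diploid
    stratum : {"ALL", "DUP", "DEL"}
    exclude : optional boolean target mask (True = omit that target)
    """
    stratum = stratum.upper()
    if stratum not in ("ALL", "DUP", "DEL"):
        raise ValueError("stratum must be ALL, DUP or DEL")
    s, flag, t = _align(states, called, truth)
    flag = flag.astype(bool)
    keep = np.ones(s.shape[1], dtype=bool)
    if exclude is not None:
        keep &= ~np.asarray(exclude, dtype=bool)
    s, flag, t = s[:, keep], flag[:, keep], t[:, keep]

    call_dup = flag & (s > 1)
    call_del = flag & (s < 1)
    true_dup = t > 1
    true_del = t < 1
    if stratum == "DUP":
        pos, true_pos = call_dup, true_dup
        good = pos & true_pos
    elif stratum == "DEL":
        pos, true_pos = call_del, true_del
        good = pos & true_pos
    else:
        pos = flag
        true_pos = true_dup | true_del
        good = (call_dup & true_dup) | (call_del & true_del)
    tp = int(good.sum())
    fp = int((pos & ~good).sum())
    # each pair gets exactly one label: a flagged direction-mismatch is an
    # FP, so only unflagged true variants count as FN
    fn = int((true_pos & ~pos).sum())
    tn = int(s.size - tp - fp - fn)
    return ConfusionSummary(tp, fp, tn, fn, stratum)


def overlap_sets(callsets: dict) -> pd.DataFrame:
    """Membership tallies for 2-3 labelled exon-level call collections.

    Each call set is an iterable of (subject, target_id, direction)
    tuples with direction in {"dup", "del"}. Returns one row per
    non-empty label combination and direction with the count of calls
    private to exactly that combination.
    """
    if not 2 <= len(callsets) <= 3:
        raise ValueError("overlap_sets takes 2 or 3 labelled call sets")
    sets = {k: set(map(tuple, v)) for k, v in callsets.items()}
    labels = list(sets)
    rows = []
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets[l] for l in combo))
            outside = set.union(set(), *(sets[l] for l in labels if l not in combo))
            exact = inside - outside
            for direction in ("dup", "del"):
                rows.append(
                    {
                        "region": "&".join(combo),
                        "direction": direction,
                        "count": sum(1 for c in exact if c[2] == direction),
                    }
                )
    return pd.DataFrame(rows)


def sweep_depths(
    depths,
    n_replicates: int = 5,
    seed: int = 0,
    n_subjects: int = 16,
    n_targets: int = 2000,
    variant_prob: float = 1e-3,
    alpha: float = 0.05,
    depth_is_per_target: bool = True,
):
    """Simulation study over sequencing depth.

    For each depth, simulate ``n_replicates`` pools, run the caller, and
    score exon-level calls against truth. ``depth_is_per_target`` reads
    the depth grid as mean molecules per target per subject (total
    depth = value * n_targets); otherwise values are totals.

    Returns a table with one row per (depth, replicate) plus a pooled
    row per depth (replicate = "pooled") computed on summed confusion
    counts.
    """
    from .core import CNVCaller
    from .simulate import SimulationConfig, simulate_pool

    # one seed per replicate, shared across depths: each replicate keeps
    # the same capture simplex and variant placements at every depth, so
    # the depth trend is not confounded by placement noise
    rep_seeds = [
        int(c.generate_state(1)[0] % (2**31))
        for c in np.random.SeedSequence(seed).spawn(n_replicates)
    ]
    rows = []
    for depth in depths:
        total = float(depth) * n_targets if depth_is_per_target else float(depth)
        agg = np.zeros(4, dtype=np.int64)
        for rep in range(n_replicates):
            cfg = SimulationConfig(
                n_subjects=n_subjects,
                n_targets=n_targets,
                depth=total,
                variant_prob=variant_prob,
                seed=rep_seeds[rep],
            )
            pool = simulate_pool(cfg)
            caller = CNVCaller(alpha=alpha).fit(pool.counts)
            cs = confusion(caller.states_, caller.called_, pool.states.to_numpy())
            agg += np.array([cs.tp, cs.fp, cs.tn, cs.fn])
            rows.append(
                {"depth_per_target": float(depth) if depth_is_per_target else total / n_targets,
                 "replicate": str(rep), **cs.as_dict()}
            )
        pooled = ConfusionSummary(*agg.tolist())
        rows.append(
            {"depth_per_target": float(depth) if depth_is_per_target else total / n_targets,
             "replicate": "pooled", **pooled.as_dict()}
        )
    return pd.DataFrame(rows)
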