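"""Multinomial capture simulator with known copy-number truth.

Hybridization capture of a pooled library is modelled as repeated
multinomial trials: every sequenced molecule falls on target j with
probability e_j, the pool's capture simplex. A subject's copy state s_ij
multiplies its capture probability at that target; renormalizing gives
the subject-specific simplex, and the subject's counts are one
multinomial draw of its total molecule count n_i from it. Row sums of
the simulated counts therefore equal the realized depths exactly.

Copy states use the multiplier convention: 1 is diploid, 0.5 a
heterozygous deletion, 0 a homozygous deletion, 1.5 and 2 duplications.
Variants are injected independently per (subject, target) with total
probability ``variant_prob`` split equally across the non-diploid
states, the prior used throughout the simulation study (1/1000 by
default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import CountMatrix

DEFAULT_STATES = (0.0, 0.5, 1.0, 1.5, 2.0)
#: symmetric-Dirichlet concentration giving an exome-like right-skewed
#: spread of per-target capture probability (median/mean ~ 0.85)
DEFAULT_CONCENTRATION = 2.0


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_simplex(n_targets: int, concentration: float = DEFAULT_CONCENTRATION, seed=None) -> np.ndarray:
    """Draw a baseline capture simplex from a symmetric Dirichlet.

    Returns a strictly positive vector summing to 1. ``concentration``
    controls spread: small values give a heavier right tail of capture
    probability, mimicking uneven bait efficiency.
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    if n_targets == 1:
        return np.array([1.0])
    rng = _rng(seed)
    g = rng.gamma(concentration, size=n_targets)
    g = np.maximum(g, np.finfo(float).tiny)
    return g / g.sum()


def draw_depths(n_subjects: int, depth: float, seed=None, window: float = 0.3) -> np.ndarray:
    """Per-subject total molecule counts, uniform on depth*(1 +/- window).

    Matches the observed spread of total molecules across real pools: a
    30% window on either side of the nominal depth. ``window=0`` gives
    every subject exactly ``depth`` molecules. Depths are rounded to the
    nearest integer.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not 0 <= window < 1:
        raise ValueError("window must be in [0, 1)")
    if window == 0:
        return np.full(n_subjects, int(round(depth)), dtype=np.int64)
    rng = _rng(seed)
    lo, hi = depth * (1 - window), depth * (1 + window)
    return np.rint(rng.uniform(lo, hi, size=n_subjects)).astype(np.int64)


def draw_states(
    n_subjects: int,
    n_targets: int,
    variant_prob: float,
    states=DEFAULT_STATES,
    seed=None,
) -> np.ndarray:
    """Independent copy states per (subject, target).

    Each cell is diploid (1) with probability ``1 - variant_prob``;
    otherwise one of the non-diploid states in ``states``, all equally
    likely.
    """
    if not 0 <= variant_prob <= 1:
        raise ValueError("variant_prob must be in [0, 1]")
    variant_states = np.array([s for s in states if s != 1], dtype=float)
    if variant_prob > 0 and variant_states.size == 0:
        raise ValueError("no non-diploid states available but variant_prob > 0")
    out = np.ones((n_subjects, n_targets))
    if variant_prob == 0:
        return out
    rng = _rng(seed)
    hit = rng.random((n_subjects, n_targets)) < variant_prob
    out[hit] = rng.choice(variant_states, size=int(hit.sum()))
    return out


@dataclass
class SimulationConfig:
    """Parameters of one simulated pool.

    depth is the nominal molecules per subject; with J targets the mean
    molecules per target per subject is depth / J.
    """

    n_subjects: int = 16
    n_targets: int = 20000
    depth: float = 5e6
    variant_prob: float = 1e-3
    states: tuple = DEFAULT_STATES
    depth_window: float = 0.3
    concentration: float = DEFAULT_CONCENTRATION
    simplex: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("a pool needs at least 2 subjects")
        if self.simplex is not None:
            self.simplex = np.asarray(self.simplex, dtype=float)
            if self.simplex.ndim != 1 or (self.simplex <= 0).any():
                raise ValueError("simplex must be a strictly positive vector")
            if abs(self.simplex.sum() - 1.0) > 1e-12:
                raise ValueError("simplex must sum to 1 within 1e-12")
            self.n_targets = self.simplex.size


@dataclass
class SimulatedPool:
    """Counts plus ground truth for one simulated pool."""

    counts: CountMatrix
    states: pd.DataFrame  # truth, same subjects x targets layout
    depths: np.ndarray
    simplex: np.ndarray
    config: SimulationConfig = field(repr=False)


def simulate_pool(config: SimulationConfig) -> SimulatedPool:
    """Run the three-step capture simulation for one pool.

    1. draw copy states per (subject, target);
    2. scale the baseline simplex by each subject's states, renormalize;
    3. draw each subject's counts multinomially with its realized depth.
    """
    ss = np.random.SeedSequence(config.seed)
    s_simplex, s_depth, s_states, s_counts = ss.spawn(4)
    simplex = (
        config.simplex
        if config.simplex is not None
        else random_simplex(config.n_targets, config.concentration, np.random.default_rng(s_simplex))
    )
    depths = draw_depths(
        config.n_subjects, config.depth, np.random.default_rng(s_depth), config.depth_window
    )
    states = draw_states(
        config.n_subjects,
        simplex.size,
        config.variant_prob,
        config.states,
        np.random.default_rng(s_states),
    )
    rng = np.random.default_rng(s_counts)
    counts = np.empty((config.n_subjects, simplex.size), dtype=np.int64)
    for i in range(config.n_subjects):
        adjusted = simplex * states[i]
        total = adjusted.sum()
        if total <= 0:
            raise ValueError(f"subject {i}: all copy states zero, capture simplex degenerate")
        counts[i] = rng.multinomial(depths[i], adjusted / total)

    subjects = [f"S{i + 1:02d}" for i in range(config.n_subjects)]
    tids = [f"T{j + 1:06d}" for j in range(simplex.size)]
    targets = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": np.arange(simplex.size) * 1000,
            "end": np.arange(simplex.size) * 1000 + 150,
            "target_id": tids,
        }
    )
    cm = CountMatrix(pd.DataFrame(counts, index=subjects, columns=tids), targets)
    truth = pd.DataFrame(states, index=subjects, columns=tids)
    return SimulatedPool(cm, truth, depths, simplex, config)
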