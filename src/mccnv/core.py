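"""Iterative copy-state estimation under a shared negative-binomial model.

Counts for subject i at target j are modelled as

    C_ij ~ NB(f_i * s_ij * mu_j,  phi_j / f_i)

with the mean/dispersion parameterization Var = m + phi * m^2, where f_i
is a median-of-ratios size factor, s_ij the copy-state multiplier
(1 = diploid), mu_j the diploid mean and phi_j a per-target dispersion
shrunken toward a common value to stabilize small-pool estimates. The
caller starts all-diploid, alternates (re-estimate f, mu, phi from
copy-adjusted counts) with (argmax of the NB likelihood over the state
grid {0.001, 0.5, 1, 1.5, 2}) until the states stop changing, then
reports an exact two-sided NB p-value for the diploid state per cell,
Benjamini-Hochberg adjusted across the pool.

There is no randomness anywhere in the caller: identical input gives
identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .matrix import CountMatrix

#: copy-state grid searched by the caller; 0.001 stands in for a
#: homozygous deletion so the NB mean stays positive
STATE_GRID = (0.001, 0.5, 1.0, 1.5, 2.0)

#: states at or below this are zero-equivalent for estimation purposes:
#: c / 0.001 is not a meaningful diploid-equivalent count, so cells
#: called as homozygous deletions are excluded like true zeros
ZERO_STATE_MAX = 0.1

_DISPERSION_EPS = 1e-12


# ---------------------------------------------------------------------------
# model steps
# ---------------------------------------------------------------------------

def adjusted_counts(counts: np.ndarray, states: np.ndarray) -> np.ndarray:
    """Copy-adjusted counts c' = c / s; NaN where the state is 0."""
    counts = np.asarray(counts, dtype=float)
    states = np.asarray(states, dtype=float)
    out = np.full(counts.shape, np.nan)
    ok = states > 0
    out[ok] = counts[ok] / states[ok]
    return out


def subset_counts(cprime: np.ndarray, min_count: float = 10) -> np.ndarray:
    """Estimation subset: keep cells with c' > min_count (NaN elsewhere).

    Masked cells (state 0) stay NaN. The subset feeds size-factor and
    dispersion estimation only; state updates and p-values always see
    every raw count.
    """
    cprime = np.asarray(cprime, dtype=float)
    return np.where(cprime > min_count, cprime, np.nan)


def size_factors(cprime: np.ndarray, min_count: float = 10) -> np.ndarray:
    """Median-of-ratios size factor per subject.

    Cells are first restricted to c' > min_count; g_j is the geometric
    mean of the surviving c' at target j, and f_i the median over that
    subject's surviving targets of c'_ij / g_j.
    """
    kept = subset_counts(cprime, min_count)
    with np.errstate(divide="ignore", invalid="ignore"):
        logc = np.log(kept)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            g = np.exp(np.nanmean(logc, axis=0))
        ratio = kept / g
    f = np.empty(kept.shape[0])
    for i in range(kept.shape[0]):
        vals = ratio[i, ~np.isnan(ratio[i])]
        if vals.size == 0:
            raise ValueError(
                f"subject index {i}: no targets with adjusted count > {min_count}; "
                "cannot estimate a size factor"
            )
        f[i] = np.median(vals)
    return f


def mom_dispersion(cprime: np.ndarray, f: np.ndarray):
    """Method-of-moments diploid mean and raw dispersion per target.

    mu_j and sigma^2_j are the sample mean and variance of c'_ij / f_i
    over unmasked subjects; phi_j = max(0, (sigma^2 - mu) / mu^2).
    Targets with fewer than two unmasked subjects or mu = 0 get phi = 0.
    """
    x = np.asarray(cprime, dtype=float) / np.asarray(f, dtype=float)[:, None]
    n = np.sum(~np.isnan(x), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(x, axis=0)
        var = np.nanvar(x, axis=0, ddof=1)
    mu = np.where(n >= 1, mu, 0.0)
    var = np.where(n >= 2, var, 0.0)
    phi = np.zeros_like(mu)
    pos = mu > 0
    phi[pos] = np.maximum(0.0, (var[pos] - mu[pos]) / mu[pos] ** 2)
    return mu, phi


def shrink_dispersion(phi_hat: np.ndarray, delta: float | None = None, xi: float | None = None):
    """Shrink raw dispersions toward a common value.

    phi~_j = (1 - delta) * phi^_j + delta * xi^ with xi^ the arithmetic
    mean of the raw dispersions (the stationary point of the squared-
    distance objective) and the shrinkage weight

        delta = [sum_j (phi^_j - mean)^2 / (J - 1)]
              / [sum_j (phi^_j - xi^)^2 / (J - 2)]

    clamped to [0, 1]; a zero denominator (all raw values equal the
    shrinkage target) gives delta = 1. Pass ``delta``/``xi`` to override
    the estimated values.
    """
    phi_hat = np.asarray(phi_hat, dtype=float)
    J = phi_hat.size
    if J < 3:
        raise ValueError("shrinkage needs at least 3 targets")
    if xi is None:
        xi = float(phi_hat.mean())
    if delta is None:
        center = phi_hat.mean()
        num = np.sum((phi_hat - center) ** 2) / (J - 1)
        den = np.sum((phi_hat - xi) ** 2) / (J - 2)
        delta = 1.0 if den == 0 else float(np.clip(num / den, 0.0, 1.0))
    phi_tilde = (1 - delta) * phi_hat + delta * xi
    return np.maximum(phi_tilde, 0.0), float(delta), float(xi)


def grid_search_xi(phi_hat: np.ndarray, n_grid: int = 2001) -> float:
    """Cross-check for the shrinkage target: minimize sum (phi^ - xi)^2
    over a grid spanning [min phi^, max phi^]."""
    phi_hat = np.asarray(phi_hat, dtype=float)
    grid = np.linspace(phi_hat.min(), phi_hat.max(), n_grid)
    obj = ((phi_hat[:, None] - grid[None, :]) ** 2).sum(axis=0)
    return float(grid[np.argmin(obj)])


def nb_loglik(c, mean, dispersion):
    """Log-pmf of the NB with Var = m + phi m^2; Poisson when phi = 0."""
    c = np.asarray(c)
    mean = np.broadcast_to(np.asarray(mean, dtype=float), np.broadcast_shapes(np.shape(c), np.shape(mean)))
    phi = np.broadcast_to(np.asarray(dispersion, dtype=float), mean.shape)
    c = np.broadcast_to(c, mean.shape)
    out = np.empty(mean.shape)
    pois = phi <= _DISPERSION_EPS
    if pois.any():
        out[pois] = stats.poisson.logpmf(c[pois], mean[pois])
    nb = ~pois
    if nb.any():
        r = 1.0 / phi[nb]
        p = r / (r + mean[nb])
        out[nb] = stats.nbinom.logpmf(c[nb], r, p)
    return out


def update_states(
    counts: np.ndarray,
    f: np.ndarray,
    mu: np.ndarray,
    phi_tilde: np.ndarray,
    grid=STATE_GRID,
):
    """Per-cell argmax of the NB likelihood over the copy-state grid.

    The candidate mean for state s is f_i * s * mu_j with dispersion
    phi~_j / f_i. Ties break toward s = 1, then toward the state nearest
    1 (smaller state first). Targets with mu_j = 0 come back NaN.

    Returns (states matrix, validity mask).
    """
    counts = np.asarray(counts)
    f = np.asarray(f, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi_tilde = np.asarray(phi_tilde, dtype=float)
    order = sorted(grid, key=lambda s: (abs(s - 1), s))
    valid = mu > 0
    ll = np.full((len(order),) + counts.shape, -np.inf)
    disp = phi_tilde[None, valid] / f[:, None]
    for k, s in enumerate(order):
        m = f[:, None] * s * mu[None, valid]
        ll[k][:, valid] = nb_loglik(counts[:, valid], m, disp)
    best = np.argmax(ll, axis=0)  # first max wins -> tie-break by order
    states = np.asarray(order, dtype=float)[best]
    states[:, ~valid] = np.nan
    return states, np.broadcast_to(valid, counts.shape).copy()


def diploid_pvalue(counts, f, mu, phi_tilde):
    """Exact two-sided NB p-value for the diploid state.

    pi = min(1, 2 * min(Pr(C <= c), Pr(C >= c))) under
    C ~ NB(f * mu, phi~ / f).
    """
    counts = np.asarray(counts)
    shape = np.broadcast_shapes(
        np.shape(counts), np.broadcast_shapes(np.shape(f), np.shape(mu))
    )
    c = np.broadcast_to(counts, shape)
    m = np.broadcast_to(np.asarray(f, dtype=float) * np.asarray(mu, dtype=float), shape)
    phi = np.broadcast_to(np.asarray(phi_tilde, dtype=float) / np.asarray(f, dtype=float), shape)
    lower = np.empty(shape)
    upper = np.empty(shape)
    pois = phi <= _DISPERSION_EPS
    if pois.any():
        lower[pois] = stats.poisson.cdf(c[pois], m[pois])
        upper[pois] = stats.poisson.sf(c[pois] - 1, m[pois])
    nb = ~pois
    if nb.any():
        r = 1.0 / phi[nb]
        p = r / (r + m[nb])
        lower[nb] = stats.nbinom.cdf(c[nb], r, p)
        upper[nb] = stats.nbinom.sf(c[nb] - 1, r, p)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def likelihood_pvalue(counts, f, mu, phi_tilde, grid=STATE_GRID):
    """Alternative Pr(s = 1): the diploid likelihood normalized over the
    state grid. Not a tail probability; exposed for sensitivity checks."""
    counts = np.asarray(counts)
    f = np.asarray(f, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi_tilde, dtype=float)
    ll = np.stack(
        [
            nb_loglik(counts, f[:, None] * s * mu[None, :], phi[None, :] / f[:, None])
            for s in grid
        ]
    )
    ll -= ll.max(axis=0, keepdims=True)
    lik = np.exp(ll)
    return lik[list(grid).index(1.0)] / lik.sum(axis=0)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(k) = min over r >= k of p_(r) * m / r, capped at 1; invariant
    to input order up to the matching permutation.
    """
    p = np.asarray(pvalues, dtype=float)
    flat = p.ravel()
    if flat.size == 0:
        return p.copy()
    if np.nanmin(flat) < 0 or np.nanmax(flat) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    ok = ~np.isnan(flat)
    vals = flat[ok]
    m = vals.size
    order = np.argsort(vals, kind="stable")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out_ok = np.empty(m)
    out_ok[order] = np.minimum(adj, 1.0)
    out = np.full(flat.shape, np.nan)
    out[ok] = out_ok
    return out.reshape(p.shape)


# ---------------------------------------------------------------------------
# fitted-state containers
# ---------------------------------------------------------------------------

@dataclass
class ModelState:
    """Per-iteration snapshot of the model parameters."""

    iteration: int
    size_factors: np.ndarray
    mu: np.ndarray
    phi_raw: np.ndarray
    phi_shrunk: np.ndarray
    delta: float
    xi: float
    n_changed: int


@dataclass
class CallSet:
    """Per-cell calls plus merged contiguous variant records."""

    table: pd.DataFrame  # subject, chrom, start, end, target_id, state, p, p_adj, called
    variants: pd.DataFrame = field(default=None)  # merged records
    alpha: float = 0.05

    def called(self) -> pd.DataFrame:
        return self.table[self.table["called"]]


def merge_variants(table: pd.DataFrame) -> pd.DataFrame:
    """Merge contiguous flagged exons of one direction into variant records.

    Exons adjacent in target sort order, for the same subject and the
    same direction (dup: state > 1, del: state < 1), collapse into one
    record with the exon count and mean state. Reporting convenience
    only; evaluation stays at the exon level.
    """
    called = table[table["called"]].copy()
    cols = ["subject", "chrom", "start", "end", "n_exons", "direction", "mean_state"]
    if called.empty:
        return pd.DataFrame(columns=cols)
    called["direction"] = np.where(called["state"] > 1, "dup", "del")
    called = called.sort_values(["subject", "exon_order"])
    rows = []
    prev = None
    for rec in called.itertuples():
        if (
            prev is not None
            and rec.subject == prev["subject"]
            and rec.direction == prev["direction"]
            and rec.chrom == prev["chrom"]
            and rec.exon_order == prev["order"] + 1
        ):
            prev["end"] = rec.end
            prev["order"] = rec.exon_order
            prev["states"].append(rec.state)
        else:
            if prev is not None:
                rows.append(prev)
            prev = {
                "subject": rec.subject,
                "chrom": rec.chrom,
                "start": rec.start,
                "end": rec.end,
                "direction": rec.direction,
                "order": rec.exon_order,
                "states": [rec.state],
            }
    rows.append(prev)
    return pd.DataFrame(
        [
            {
                "subject": r["subject"],
                "chrom": r["chrom"],
                "start": r["start"],
                "end": r["end"],
                "n_exons": len(r["states"]),
                "direction": r["direction"],
                "mean_state": float(np.mean(r["states"])),
            }
            for r in rows
        ],
        columns=cols,
    )


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class CNVCaller(BaseEstimator):
    """Copy-number caller for one multiplexed-capture pool.

    scikit-learn style estimator: ``fit`` takes the subjects x targets
    count matrix and estimates a copy state per cell; there is no
    separate predict step because the pool itself is the unit of
    analysis.

    Parameters
    ----------
    alpha : float
        BH-adjusted significance threshold for flagging a call.
    change_threshold : int
        Stop when no more than this many states change in an iteration.
    max_iter : int
        Iteration cap for the alternating estimation.
    state_grid : tuple of float
        Candidate copy states (0.001 stands in for homozygous deletion).
    min_count : float
        Copy-adjusted count floor for the size-factor subset.
    pvalue_method : {"tail", "likelihood"}
        Diploid p-value construction; "tail" is the exact doubled-tail
        NB test, "likelihood" the normalized diploid likelihood.

    Attributes
    ----------
    states_ : ndarray of shape (n_subjects, n_targets)
        Estimated copy-state multipliers (NaN where unestimable).
    pvalues_, pvalues_adjusted_ : ndarray
        Diploid p-values and their BH adjustment (pooled across cells).
    called_ : ndarray of bool
        adjusted p < alpha and state != 1.
    size_factors_, mu_, dispersion_raw_, dispersion_ : ndarray
        Final model parameters.
    n_iter_ : int, converged_ : bool, trace_ : list of ModelState
    """

    def __init__(
        self,
        alpha: float = 0.05,
        change_threshold: int = 0,
        max_iter: int = 40,
        state_grid=STATE_GRID,
        min_count: float = 10,
        pvalue_method: str = "tail",
    ):
        self.alpha = alpha
        self.change_threshold = change_threshold
        self.max_iter = max_iter
        self.state_grid = state_grid
        self.min_count = min_count
        self.pvalue_method = pvalue_method

    # -- internals -------------------------------------------------------
    def _validate_counts(self, X):
        if isinstance(X, CountMatrix):
            arr = X.to_numpy()
        elif isinstance(X, pd.DataFrame):
            arr = X.to_numpy()
        else:
            arr = np.asarray(X)
        if arr.ndim != 2:
            raise ValueError("count matrix must be 2-dimensional (subjects x targets)")
        if arr.shape[0] < 2:
            raise ValueError(
                "a single-subject pool carries no between-sample information; "
                "at least 2 subjects required"
            )
        if arr.size == 0:
            raise ValueError("empty count matrix")
        if (arr < 0).any() or not np.all(np.mod(arr, 1) == 0):
            raise ValueError("counts must be non-negative integers")
        return arr.astype(np.int64)

    def fit(self, X, y=None):
        """Estimate copy states for every (subject, target) cell of X."""
        if self.pvalue_method not in ("tail", "likelihood"):
            raise ValueError("pvalue_method must be 'tail' or 'likelihood'")
        counts = self._validate_counts(X)
        n_sub, n_tar = counts.shape

        keep = counts.sum(axis=0) > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} all-zero target(s) from calling"
            )
        work = counts[:, keep]
        if work.shape[1] < 3:
            raise ValueError("fewer than 3 non-empty targets; cannot fit the model")

        states = np.ones_like(work, dtype=float)
        trace: list[ModelState] = []
        converged = False
        grid = tuple(self.state_grid)
        for it in range(1, self.max_iter + 1):
            cp = adjusted_counts(work, states)
            # the c' > min_count, s > 0 subset governs estimation (size
            # factors and dispersion alike); the 0.001 grid state is a
            # stand-in for 0, so those cells are excluded like true zeros
            # rather than contributing c / 0.001
            cp_est = np.where(states > ZERO_STATE_MAX, cp, np.nan)
            est = subset_counts(cp_est, self.min_count)
            f = size_factors(est, self.min_count)
            mu, phi_raw = mom_dispersion(est, f)
            phi_shrunk, delta, xi = shrink_dispersion(phi_raw)
            new_states, valid = update_states(work, f, mu, phi_shrunk, grid)
            both = valid & ~np.isnan(states) & ~np.isnan(new_states)
            n_changed = int(np.sum(states[both] != new_states[both]))
            states = new_states
            trace.append(
                ModelState(it, f, mu, phi_raw, phi_shrunk, delta, xi, n_changed)
            )
            if n_changed <= self.change_threshold:
                converged = True
                break

        valid_cells = ~np.isnan(states)
        if self.pvalue_method == "tail":
            pv = diploid_pvalue(work, f[:, None], mu[None, :], phi_shrunk[None, :])
        else:
            pv = likelihood_pvalue(work, f, mu, phi_shrunk, grid)
        pv = np.where(valid_cells, pv, np.nan)
        padj = bh_adjust(pv)
        called = valid_cells & (padj < self.alpha) & (states != 1.0)

        # scatter back over dropped all-zero targets
        def expand(a, fill=np.nan):
            out = np.full((n_sub, n_tar), fill)
            out[:, keep] = a
            return out

        self.states_ = expand(states)
        self.pvalues_ = expand(pv)
        self.pvalues_adjusted_ = expand(padj)
        self.called_ = expand(called, fill=False).astype(bool)
        self.size_factors_ = f
        mu_full = np.full(n_tar, np.nan)
        mu_full[keep] = mu
        self.mu_ = mu_full
        pr = np.full(n_tar, np.nan)
        pr[keep] = phi_raw
        self.dispersion_raw_ = pr
        ps = np.full(n_tar, np.nan)
        ps[keep] = phi_shrunk
        self.dispersion_ = ps
        self.delta_ = trace[-1].delta
        self.xi_ = trace[-1].xi
        self.n_iter_ = len(trace)
        self.converged_ = converged
        self.trace_ = trace
        self.kept_targets_ = keep
        if not converged:
            warnings.warn(
                f"caller did not converge in {self.max_iter} iterations "
                f"({trace[-1].n_changed} states still changing)"
            )
        return self

    def fit_predict(self, X, y=None):
        """Fit and return the estimated copy-state matrix."""
        return self.fit(X).states_

    def callset(self, X: CountMatrix) -> CallSet:
        """Tabulate fitted calls against the count matrix's metadata."""
        if not hasattr(self, "states_"):
            raise ValueError("fit the caller before requesting a call set")
        t = X.targets
        n_sub, n_tar = self.states_.shape
        table = pd.DataFrame(
            {
                "subject": np.repeat(X.subjects, n_tar),
                "chrom": np.tile(t["chrom"].to_numpy(), n_sub),
                "start": np.tile(t["start"].to_numpy(), n_sub),
                "end": np.tile(t["end"].to_numpy(), n_sub),
                "target_id": np.tile(t["target_id"].to_numpy(), n_sub),
                "state": self.states_.ravel(),
                "p": self.pvalues_.ravel(),
                "p_adj": self.pvalues_adjusted_.ravel(),
                "called": self.called_.ravel(),
                "exon_order": np.tile(np.arange(n_tar), n_sub),
            }
        )
        variants = merge_variants(table)
        return CallSet(table.drop(columns="exon_order"), variants, self.alpha)


def run_mccnv(
    counts: CountMatrix,
    alpha: float = 0.05,
    change_threshold: int = 0,
    max_iter: int = 40,
    **kwargs,
):
    """Fit the caller on a count matrix; returns (CallSet, fitted caller)."""
    caller = CNVCaller(
        alpha=alpha, change_threshold=change_threshold, max_iter=max_iter, **kwargs
    )
    caller.fit(counts)
    return caller.callset(counts), caller
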