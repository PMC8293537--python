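# Methods

## Model

Molecule counts for subject *i* at target (exon) *j* are modelled as
negative binomial,

```
C_ij ~ NB( f_i · s_ij · μ_j ,  φ̃_j / f_i ),     Var = m + φ m²,
```

a copy-state extension of the shrunken-dispersion NB framework used for
small-sample RNA-seq differential expression. `s_ij` is a multiplier on
the diploid mean: 1 diploid, 0.5 heterozygous deletion, 1.5 and 2
duplications, and 0.001 as a numerical stand-in for a homozygous
deletion (a zero state would make the NB mean degenerate). The model
deliberately contains no GC-content or fragment-length terms: within a
multiplexed pool every sample sees the same capture chemistry, so those
biases cancel in the between-sample comparison; the trade-off is that
the method is blind to variants shared by the whole pool (common CNVs)
and does not estimate breakpoints — analysis is strictly per exon.

## The iterative caller

Initialize all states at 1, then repeat:

1. **Copy-adjust**: `c'_ij = c_ij / ŝ_ij` (cells with state 0 are
   masked).
2. **Estimation subset**: keep cells with `c'_ij > 10` and `ŝ_ij > 0`.
   The 0.001 stand-in is treated as zero here: `c / 0.001` is not a
   meaningful diploid-equivalent value, so cells called as homozygous
   deletions are excluded from estimation exactly like true zeros. This
   subset governs both of the next two steps; letting called deletions
   leak into the target mean produces a label-switching runaway in
   which the deflated mean flips the remaining diploid subjects to
   1.5/2 one by one (or, at weak targets, `c/0.001` values inflate the
   mean by orders of magnitude). State updates and p-values (steps 5–6)
   always use every raw count.
3. **Size factors**: `f_i = median_j ( c'_ij / g_j )` over the subject's
   surviving cells, with `g_j` the geometric mean of surviving `c'` at
   target *j* — the median-of-ratios normalization familiar from
   count-based expression analysis.
4. **Dispersion**: method-of-moments per target on `c'_ij / f_i`:
   `φ̂_j = max(0, (σ̂²_j − μ̂_j) / μ̂_j²)`, then shrink toward the pool
   mean: `φ̃_j = (1 − δ) φ̂_j + δ ξ̂` with `ξ̂ = mean(φ̂)` (the
   stationary point of the squared-distance criterion; a grid minimizer
   over `[min φ̂, max φ̂]` is exposed as a cross-check) and
   `δ = [Σ(φ̂_j − φ̄)²/(J−1)] / [Σ(φ̂_j − ξ̂)²/(J−2)]`, clamped to
   [0, 1], with δ = 1 when the denominator vanishes. With `ξ̂` at the
   mean this weight is ≈ (J−2)/(J−1), i.e. near-total shrinkage — the
   intended behaviour for capture data, whose within-pool counts are
   close to Poisson so a pooled dispersion is both stable and nearly
   correct.
5. **State update**: per cell, argmax of the NB log-likelihood over the
   grid `{0.001, 0.5, 1, 1.5, 2}` with mean `f_i·s·μ̂_j` and dispersion
   `φ̃_j / f_i`. Ties break toward s = 1, then toward the state nearest
   1 (smaller first) — a deterministic rule that favours the null.
   Targets with `μ̂_j = 0` or fewer than 2 usable subjects are reported
   missing, not called.
6. **Stop** when the number of changed states falls to the threshold
   (default 0) or after `max_iter` (default 40) iterations; then compute
   per-cell diploid p-values and BH-adjust them jointly across all
   (subject, target) cells of the pool. Calls are cells with adjusted
   p < α (default 0.05) and `ŝ ≠ 1`.

The caller contains no randomness; identical input yields identical
output.

**Diploid p-value.** The "probability of the diploid state" is
implemented as an exact doubled-tail NB test under the s = 1 model:
`π = min(1, 2·min(Pr(C ≤ c), Pr(C ≥ c)))` with `C ~ NB(f μ̂, φ̃/f)`.
An alternative — the diploid likelihood normalized over the state grid —
is available as `pvalue_method="likelihood"`; it is not a tail
probability and is provided for sensitivity analysis only. Both produce
identical state estimates; only the flagging threshold semantics differ.

**NB parameterization and Poisson limit.** All likelihoods use the
(mean m, dispersion φ) form with `Var = m + φ m²`; `φ ≤ 1e-12` switches
exactly to the Poisson pmf, so the φ → 0 limit is exact rather than
approximate.

**Merged variant records.** Flagged exons adjacent in target order for
the same subject and direction are merged into variant records (span,
exon count, mean state) for reporting; all evaluation remains at the
(subject, exon) level.

## Capture simulator

Capture of a pooled library is modelled as `n_i` independent multinomial
trials over the exon capture simplex `𝔼`; subject-specific simplexes are
`𝔼 ⊙ 𝕊_i` renormalized, so a deletion halves (and a duplication
multiplies) the relative capture probability of its exon. Consequences:
row sums of counts equal the realized depths exactly, and the expected
count fraction at target *j* is `e_j s_ij / Σ_k e_k s_ik`.

Defaults define the simulated study conditions:

- **Pool size 16**, the configuration used throughout the evaluation.
- **Depths** uniform on ±30% around the nominal per-subject total,
  rounded to integers, matching the spread seen in real pools.
- **Variant prior 1/1000** per (subject, target), split equally over
  the non-diploid states {0, 0.5, 1.5, 2}; injections are independent
  across cells, and simulated variants are single-exon. Note the
  simulator's state set uses a true 0 for homozygous deletions while
  the caller's grid uses 0.001 — the two sets are intentionally
  different.
- **Capture simplex**: symmetric Dirichlet with concentration 2.0,
  giving gamma(2)-like right-skewed per-exon capture probabilities
  whose median/mean ratio (~0.85) matches real exome pools. A real
  pool's empirical simplex can be passed in instead.

What the simulator does *not* emulate: GC/fragment-length bias,
correlated multi-exon variants, mappability artifacts, batch effects
between capture reactions, and read-level noise (no FASTQ). Passing
tests therefore demonstrate correctness of the statistical machinery
under the multinomial capture model, not robustness to every artifact
of real exome data.

## Dirichlet variance profiling

Per-sample proportion vectors (counts normalized over retained targets)
are fitted with a Dirichlet MLE; the precision `α₀ = Σα` is inversely
related to inter-sample variance
(`Var(p_k) = α_k(α₀−α_k) / (α₀²(α₀+1))`), so `α₀` ranks pools by how
tightly capture was balanced. Targets are pre-filtered to those with
**every** subject's count in [5, 2000] — the per-subject reading
guarantees strictly positive proportions for the log-likelihood; a
pool-sum reading of the same bounds is available via `mode="pool-sum"`.

The fit is Newton–Raphson on the log-likelihood with digamma gradients
and a trigamma Hessian whose diagonal-plus-rank-one structure is
inverted in closed form (Sherman–Morrison); initialization matches
first and second moments; steps are halved as needed to keep α
positive. Convergence: max |gradient per observation| < 1e-8 within
1000 iterations. Degenerate input (near-identical rows) drives α₀ to
infinity; because the flattening digamma gradient can then satisfy the
tolerance at an arbitrarily large iterate, fits with α₀ above 1e7 are
marked non-converged and provisional, with a warning.

## Molecule counting

A molecule is a properly-paired read pair; its span runs from the
leftmost to the rightmost mapped base of either mate (half-open,
0-based, BED convention throughout). A molecule counts once toward
every target its span overlaps by ≥ 1 bp (no largest-overlap
attribution: the model treats targets independently). Inclusion: both
mates MAPQ ≥ 20, same chromosome, and no duplicate, secondary or
supplementary records. Input must be coordinate-sorted (checked from
the header); molecules are paired by query name while streaming.

## Evaluation conventions

The evaluation unit is the (subject, exon) pair. A flagged pair is a
true positive only when the called direction matches the truth
direction; a flagged direction-mismatch is a false positive (each pair
receives exactly one label, so TP+FP+TN+FN equals the number of pairs).
Zero-denominator conventions: FDR = 0 with no positives, TPR = NaN with
no true variants, MCC = 0 when a margin is empty. Depth sweeps reuse
the same per-replicate seeds at every depth, so each replicate keeps
its capture simplex and variant placements as depth varies and the
depth trend is not confounded by placement noise; metrics are reported
per replicate and pooled over summed confusion counts.

## Problem sizes and numerical choices

The test suite exercises pools of 16 subjects at 300–2,000 targets; the
end-to-end sensitivity check and the acceptance script use ten pools of
16 × 20,000 targets at ~225 molecules/target/subject — the recommended
operating depth — with 5-replicate sweeps across {25, 100, 225}
molecules/target. These sizes give a few hundred true variants per
condition, enough for percent-level Monte-Carlo precision while keeping
a full run in minutes on one core.

Other numerical details: size-factor subset threshold `c' > 10`
(re-evaluated every iteration as states change); BH applied once per
pool over all cells jointly; p-values of missing cells excluded from
adjustment; all-zero targets dropped with a warning before fitting;
single-subject pools rejected (no between-sample information).

## Known limitations

- Common variants shared across the pool are invisible by design.
- No breakpoint estimation; multi-exon events appear as runs of
  adjacent exon calls and are only merged post hoc.
- Sensitivity degrades at weakly captured exons (expected counts below
  ~10 leave the estimation subset and may be reported missing).
- The doubled-tail p-value is discrete and slightly conservative at low
  counts.
- The Dirichlet profiler assumes exchangeable samples within a pool; it
  flags, but cannot correct, unbalanced pooling.
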