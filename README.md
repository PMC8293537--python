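# mccnv

Copy-number variant (CNV) detection from **multiplexed-capture exome
sequencing**, for groups doing rare-disease or clinical exome analysis who
want to call small (single-exon) CNVs from read depth without a reference
database of control samples and without priors on variant size or
prevalence.

## The idea

When barcoded sample libraries are pooled *before* hybridization capture,
every sample in the pool experiences identical capture conditions, so
per-exon coverage becomes directly comparable across samples. `mccnv`
exploits this with a shared negative-binomial model of molecule counts:

```
C_ij ~ NB( f_i · s_ij · μ_j ,  φ̃_j / f_i )        Var(C) = m + φ m²
```

where `C_ij` is the molecule (read-pair) count for subject *i* at exon *j*,
`f_i` a median-of-ratios size factor, `s_ij` the copy-state multiplier
(1 = diploid, 0.5 heterozygous deletion, 2 duplication, ...), `μ_j` the
diploid mean, and `φ̃_j` a per-exon dispersion shrunken toward the pool
mean to stabilize small-pool estimates. Starting all-diploid, the caller
alternates re-estimating `(f, μ, φ̃)` from copy-adjusted counts `c/s` with
a per-cell likelihood argmax over the state grid `{0.001, 0.5, 1, 1.5, 2}`
until the states stop changing, then reports an exact two-sided NB p-value
for the diploid state per cell, Benjamini–Hochberg adjusted across the
pool.

The package also ships:

- a **multinomial capture simulator** (`simulate_pool`): each captured
  molecule is one multinomial trial over the exon capture simplex, scaled
  per subject by its copy states — so simulated pools come with exact
  ground truth;
- a **Dirichlet variance profiler** (`DirichletMLE`): the precision
  `α₀ = Σα` of a Dirichlet MLE over the per-sample proportion vectors
  quantifies inter-sample capture variance (bigger `α₀` = tighter pool);
- **read-pair counting** from SAM/BAM over BED targets (properly-paired,
  MAPQ ≥ 20 on both mates, duplicates/secondary/supplementary excluded);
- **exon-level benchmarking** (confusion matrices with MCC/TPR/FDR/PPV/
  balanced accuracy, dup/del strata, call-set overlaps, depth sweeps).

## Worked example

```python
from mccnv import SimulationConfig, simulate_pool, run_mccnv, confusion

cfg = SimulationConfig(n_subjects=16, n_targets=2000, depth=450_000,
                       variant_prob=1e-3, seed=7)
pool = simulate_pool(cfg)                    # counts + known truth
calls, caller = run_mccnv(pool.counts, alpha=0.05)

print(f"converged in {caller.n_iter_} iterations "
      f"(shrinkage weight delta = {caller.delta_:.4f})")
print(f"flagged exons: {int(calls.table['called'].sum())}")
print(calls.variants.head(5).to_string(index=False))

cs = confusion(caller.states_, caller.called_, pool.states.to_numpy())
print(f"TPR = {cs.tpr:.3f}  FDR = {cs.fdr:.3f}  MCC = {cs.mcc:.3f}")
```

prints

```
converged in 7 iterations (shrinkage weight delta = 0.9995)
flagged exons: 33
subject chrom   start     end  n_exons direction  mean_state
    S01  chrS 1413000 1413150        1       dup       2.000
    S02  chrS  967000  967150        1       del       0.500
    S02  chrS 1169000 1169150        1       del       0.001
    S03  chrS   60000   60150        1       dup       1.500
    S03  chrS  389000  389150        1       dup       2.000
TPR = 0.914  FDR = 0.030  MCC = 0.942
```

The pool carries 16 subjects × 2,000 exons at ~225 molecules per exon per
subject (the recommended depth); variants were injected with probability
1/1000 per cell. The caller recovers 91% of them with a 3% false-discovery
rate; `delta ≈ 1` means the per-exon dispersions were shrunk essentially
all the way to the pool mean, as expected for multinomial (Poisson-like)
counts. Each merged record is one called variant: subject, span, exon
count, direction, and the mean estimated copy state (0.5 = het deletion,
0.001 = homozygous deletion, 1.5/2 = duplication).

The same pipeline is available from the shell:

```sh
mccnv simulate --subjects 16 --targets 2000 --depth 450000 --seed 7 --out-prefix pool
mccnv call --counts pool.counts.tsv --out calls.tsv
mccnv evaluate --calls calls.tsv --truth pool.truth.tsv --out metrics.json
mccnv dirichlet --counts pool.counts.tsv --out fit.json
mccnv count --bam sample.bam --targets exons.bed --out sample.counts.tsv
mccnv sweep --depths 25,100,225 --replicates 5 --seed 1 --out sweep.tsv
```

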