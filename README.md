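# elonglm

Inference of **local RNA polymerase II elongation rates** from nascent RNA
sequencing (NRS) data — PRO-seq, GRO-seq, NET-seq — where the 3′ end of
each aligned read marks the active site of an engaged polymerase.

## The problem

Read depth along a gene body is shaped by two things: how often the gene
initiates transcription, and how fast Pol II moves through each
nucleotide.  At steady state, slow positions accumulate polymerase and
therefore reads; fast positions are depleted.  Because the signal at any
single nucleotide is weak and the counts are extremely sparse, per-site
rate estimates are hopeless — but by tying the rate at every site to the
genomic and epigenomic features present there, information can be pooled
across millions of sites and thousands of genes.

## The model

The read count at nucleotide *i* of gene *j* is modeled as

```
X_ij ~ Poisson( chi_j / zeta_ij ),        zeta_ij = exp( kappa · Y_ij )
```

* `zeta_ij` — the **local elongation rate**, a unitless scale factor on the
  gene's average rate (< 1 = slowdown, > 1 = speedup), a log-linear
  function of the feature vector `Y_ij` (smoothed epigenomic tracks,
  DNA k-mer indicators, or both);
* `kappa` — feature coefficients shared by all sites and genes;
* `chi_j` — a per-gene nuisance parameter (read-depth-scaled
  initiation-to-elongation ratio) absorbing gene-level depth differences;
  it has a closed-form update `chi_j = s_j / U_j` given `kappa`.

The joint log likelihood reduces to
`sum_j [ s_j log chi_j − kappa·T_j − chi_j U_j ]` with sufficient
statistics `s_j = Σ_i X_ij`, `T_j = Σ_i X_ij Y_ij`,
`U_j = Σ_i exp(−kappa·Y_ij)`; it is maximized by gradient ascent on
`kappa` alternating with analytic `chi` updates.  High-dimensional k-mer
models add an L1 penalty `ν Σ|kappa_n|` with `ν` chosen by held-out AIC.
A sequence-bias variant reweights each position by the bulk frequency of
its 3′ base (`rho_b = 4 π_b`) to separate genuine rate effects from
protocol preferences.

The package also includes a stochastic simulator that tracks individual
polymerases (initiation, per-site movement probabilities, steric
exclusion) across thousands of cells, used to validate the model on data
it did *not* generate.

## Worked example

```python
import numpy as np
from elonglm import (generate_kmer_scenario, simulate_scenario_reads,
                     standardize, select_nu)
from elonglm.evaluate import r_squared

# 600 random 1-kb sequences; 100 5-mers truly modulate the rate
scen = generate_kmer_scenario(n_seqs=600, length=1000, n_active=100, seed=1)
genes, _ = simulate_scenario_reads(scen, n_cells=100, total_time=3.0,
                                   target_mean_depth=0.5, seed=2)
matrix = standardize(scen.matrix)
nu_star, result, table = select_nu(genes, matrix, seed=3)
print(f"selected nu = {nu_star:.0f}, "
      f"nonzero 5-mers = {len(result.nonzero_features)}")
r2 = r_squared(scen.kappa_true[1:], result.kappa_raw[1:])
print(f"coefficient recovery r2 = {r2:.2f}")
```

```
selected nu = 1655, nonzero 5-mers = 43
coefficient recovery r2 = 0.53
```

At this miniature scale only the stronger 5-mers are recoverable (43 of
100 survive the penalty, recovery r² = 0.53): with sparse counts,
statistical power comes from sequence volume.  At the study scale of
2,000 sequences the same pipeline recovers ~100 features with r² ≈ 0.9 —
run the acceptance script below to reproduce that.

A CLI mirrors the library (`elonglm simulate / fit / select-nu / predict /
evaluate / preprocess`, or `elonglm run --config run.yaml` for the whole
pipeline); outputs are plain text (CSV, JSON, bedGraph) with version and
seed headers.

## Layout

| module | contents |
|---|---|
| `elonglm.features` | smoothing filters, k-mer encoding, standardization, sparse/dense feature matrices |
| `elonglm.glm` | likelihood, gradients, chi updates, (penalized) fitting, penalty selection, sequence-bias variant, prediction |
| `elonglm.simulate` | polymerase simulator, covariate-block and 5-mer scenario generators |
| `elonglm.preprocess` | TSS refinement, gene-body definition, internal-TSS masking, metagene (U-shape) correction, pause windows |
| `elonglm.evaluate` | relative-depth ratios, metaplots, pause/window prediction scores, 5-mer clustering for logos |
| `elonglm.io`, `elonglm.cli` | bedGraph/bigWig/BED/config I/O and the command line |
| `elonglm.experiments` | the two end-to-end simulation studies |

See `docs/methods.md` for the model's assumptions, the simulator design,
and every numerical choice.
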