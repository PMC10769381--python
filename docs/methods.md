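# Methods

## Model

Nascent-RNA sequencing read 3′ ends mark the active sites of engaged
polymerases.  Under a continuous-time Markov description of Pol II
movement with position-specific rates, and assuming (1) collisions between
polymerases are rare and (2) premature termination is negligible, the
steady-state occupancy of nucleotide *i* in gene *j* is proportional to
`alpha_j / (zbar_j * zeta_ij)`: initiation rate over (gene-average rate ×
local scale factor).  Read counts are conditionally Poisson given that
occupancy, so

    X_ij ~ Poisson( chi_j / zeta_ij ),    zeta_ij = exp(kappa · Y_ij),

with `chi_j = lambda * alpha_j / zbar_j` a compound, per-gene parameter.
`lambda` (sequencing depth), `alpha_j`, and `zbar_j` are individually
non-identifiable from a single steady-state snapshot — the model estimates
only `chi_j` and the *relative* local rates, never absolute speeds.  The
feature vector `Y_ij` carries a constant 1 for the intercept; the
remaining entries are standardized covariates so coefficients are
mutually comparable.

Dropping parameter-free constants (including log X! terms), the joint log
likelihood is `sum_j [ s_j log chi_j − kappa·T_j − chi_j U_j ]`.  The
per-gene `s_j, T_j` are computed once; `U_j` (and the gradient ingredient
`V_j`) are recomputed whenever `kappa` moves.  Metagene-adjusted counts
are real-valued, so the Poisson likelihood is used as a quasi-likelihood;
nothing in the estimating equations requires integer counts.

Profiling `chi` out of the likelihood (`chi_j = s_j / U_j`, exact
stationarity) makes the intercept direction flat — `kappa_0` stays at its
initial 0 and gene-level scale lives entirely in `chi`.  Consequently all
between-gene depth information is discarded by design: the model learns
only from *within*-gene contrasts, which is what makes the per-gene
initiation rates nuisance-free.

## Fitting

Gradient ascent on `kappa` with a full analytic `chi` update every
iteration.  The default learning rate is 1e-7; by default
the step adapts (grow ×1.1 on improvement, halve and retry on any
decrease), which makes the objective trace monotone without tuning.  A
fixed-step mode exists for studying the raw dynamics.  Convergence is
declared after two consecutive relative objective changes below 1e-9 —
deliberately tighter than a casual 1e-6, because at the problem sizes
used here (1e5–2e6 positions) the objective is O(1e5) and a looser test
stops before coefficients are resolved to the ~1e-3 precision the
recovery experiments need.  `kappa·Y` is clipped at ±50 before
exponentiation (with a warning); with standardized features the guard
never binds in practice.

**L1 penalty.**  The penalized objective `l − nu Σ|kappa_n|` (intercept
excluded) is maximized by proximal gradient: soft-threshold after each
step.  The raw subgradient `−nu·sgn(kappa)` is retained behind
`l1_mode="subgradient"` but is ill-behaved at 0 and never produces exact
zeros; both share fixed points.  `nu` is selected on an 80/20 gene split
by AIC on the held-out genes, `AIC = 2k − 2·loglik_test` with `k` the
nonzero-coefficient count and held-out `chi` re-fit analytically with
`kappa` frozen (`chi` is gene-specific, so it cannot transfer).  The grid
is glmnet-style: 16 log-spaced values from `nu_max` (the smallest penalty
that zeroes everything, computed from the score at `kappa = 0`) down to
`nu_max/100`, fitted in decreasing order with warm starts; AIC ties go to
the larger `nu` (sparser model).  The final model is refit on all genes
at the selected `nu`.

**Sparse features.**  k-mer indicator columns are kept raw and sparse;
standardization is applied as an affine map inside every dot product
(`kappa·Y_std = (kappa/s)·Y_raw − kappa·(mu/s)`), which reproduces the
dense standardized computation to 1e-10 while preserving sparsity.

**Sequence-bias variant.**  Per-base scales `rho_b = 4*pi_b`
(pre-estimated from the bulk 3′-nucleotide distribution) enter as a
per-position offset `−log rho_i` on the linear predictor.  With
`rho ≡ 1` the code path is numerically identical to the base model,
bit for bit on identical iteration schedules.

## Feature engineering

* **Smoothing filters** `F_{r,sigma,delta}` redistribute a covariate over
  `[i+delta−r, i+delta+r]` with weights `F(k)` normalized to sum 1:
  Gaussian `(1/sigma) exp(−(k/sigma)²/2)` for ChIP-scale features
  (defaults r=400, sigma=100 nt; stem-loops r=500, sigma=200 nt), or a
  generalized filter whose 2r+1 nonnegative weights are either supplied
  or estimated as the mean relative read depth at each offset in a
  metaplot around the feature.  Boundary policy: zero-pad outside the
  track and renormalize over in-bounds taps — constants are preserved and
  no signal is invented beyond the gene body.
* **k-mers** (k ≤ 5): one indicator per k per position, for the k-mer
  whose window covers the active site.  Odd k centers on the site; even k
  puts the site at the left-of-center base, so the 2-mer "CA" reads "C at
  the active site followed by A" — consistent with how dinucleotide
  context is described.  Windows containing N or running off the sequence
  leave all indicators zero (coordinate frames stay aligned with the
  counts).  An anchor shift of ±5..25 nt probes context upstream or
  downstream of the active site.
* **Standardization** to mean 0, sd 1 (population sd) per column over the
  positions used for fitting; features defined on a subset of positions
  (e.g. methylation at CpGs) are standardized over defined positions and
  set exactly 0 elsewhere.  Statistics are pooled across genes — a single
  shared `kappa` implies a single scale.  Zero-variance columns error or
  drop by configuration, reported by name.

## Simulator

Discrete time slices of `dt = 1e-4` min, at most one movement per slice:
a polymerase at site *i* advances with probability `rate_i·dt` unless the
next polymerase is within the footprint (default 33 nt, the Pol II
footprint scale; studies run in the collision-free regime where the value
is immaterial); initiation occurs at site 1 with probability `alpha·dt`
while the initiation region is free; polymerases leaving the template are
removed.  Within a slice, downstream polymerases update first, so a move
can free space for a follower in the same slice.

The kernel does not loop over slices: Bernoulli-per-slice waiting times
are geometric and memoryless, so it jumps from event to event, and a
blocked attempt simply draws a fresh geometric wait — a process exactly
equal in distribution to the per-slice simulation, at ~30× less work.
The reported density is occupancy averaged over cells *and* over the
post-burn-in half of the run (per-site residence times are ~1e-3 min, so
time-averaging multiplies the effective sample size by orders of
magnitude compared with an end-point snapshot).  Each run asserts the
exact flux identity (initiations = terminations + resident) and reports
the minimum inter-polymerase gap ever realized (exclusion check).

Read sampling: `counts_i ~ Poisson(c · density_i)` with one global `c`
chosen so the expected mean count matches the target depth — per-gene
depth differences then reflect initiation rates, exactly as sequencing
works.  Default target depth 0.5 reads/nt, the sparsity regime of deeply
sequenced nascent-RNA libraries over robustly expressed gene bodies
(~60% of sites zero, most of the remainder one).

## Synthetic scenarios

**Epigenomic scenario.**  Six binary tracks emulate one point-like
DNA-binding factor (CTCF-like, density 0.02, runs ~25 nt), four broad
chromatin marks (densities 0.10–0.15, domains ~400 nt, latent
cross-correlation 0.5 among marks), and short stem-loops (density 0.08).
Tracks are thresholded latent Gaussian AR(1) processes, cut into 1-kb
blocks; TUs are tiled by sampling blocks jointly, preserving
cross-feature correlation.  Covariates are then Gaussian-smoothed (as
their real counterparts would be) and standardized; true log-rates are
`kappa_true·Y + N(0, noise_sd²)` with `noise_sd = 0.1` and coefficients
at the magnitudes of real-data estimates (−0.10 … +0.03).  These defaults
were calibrated once so that the noise contributes ≈25% of
`var(log zeta_true)` — the defining property of the noisy scenario — and
then frozen.  Per-TU initiation rates are log-normal with median
1 event/min (dispersion sigma_log = 1).

When the study is run on TUs shorter than the full-scale 10 kb, every
generator length scale (domain lengths, smoothing bandwidths) shrinks by
`tu_length/10000`, preserving the ratio of signal correlation length to
TU length; without this, 2-kb TUs carry essentially one signal value each
and held-out variance estimates are dominated by a handful of effective
draws.

**5-mer scenario.**  Sequences are i.i.d. draws matching mammalian base
composition (A/T 0.295, C/G 0.205) — no higher-order genomic structure is
emulated.  100 random 5-mers receive coefficients evenly spanning
[−0.3, 0.3]; all others are 0; rates are noise-free.  Each position
carries exactly the indicator of the 5-mer centered on it, so
`zeta_i = exp(kappa(5-mer at i))`.

**What passing these studies does and does not show.**  The simulator
violates the model in the directions real data would (steric exclusion,
occupancy noise, initiation-rate heterogeneity), so recovery demonstrates
robustness to those.  It does not emulate unannotated internal TSSs,
mappability artifacts, protocol sequence bias, or correlated noise along
the genome — real-data performance depends on the preprocessing steps
(masking, metagene correction) doing their job.

## Study sizes and headline quantities

The validation studies run at desk scale: epigenomic — 50 TUs × 2 kb,
500 cells, 5 simulated minutes, depth 0.5/nt; 5-mer — 2,000 sequences ×
1 kb, 100 cells, 3 simulated minutes (time-averaged occupancy makes
count overdispersion negligible already at 100 cells).  In the
epigenomic study the TUs rotate through 5 folds — each fold fits on 80%
of TUs and predicts its own held-out 20%, and the pooled held-out
predictions are scored once, so every TU is predicted by a model that
never saw it.

Predicted and true rates are compared on the **log scale** (squared
Pearson correlation of log rates).  On that scale the Gaussian-noise
variance decomposition is exact — with a perfectly recovered `kappa`,
unexplained variance equals the injected noise share (≈25%), giving the
r² ≈ 0.75 headline; on the raw rate scale the same comparison is
distorted by the skewness that exponentiation introduces.  Coefficient
recovery in the 5-mer study is scored on the raw indicator scale
(standardized-space estimates divided by the column sds), against the
generating coefficients, over all 1024 5-mers.

## Numerical choices and degenerate inputs

* `chi` update: `s_j/U_j`, the exact conditional maximizer; the depth
  scale `lambda` (mean count/nt) is reported separately for converting
  `chi` into interpretable initiation-to-elongation ratios.
* Genes with zero counts: `chi_j = 0` with a warning; they contribute
  nothing to the likelihood.
* Metagene (U-shape) correction: per-gene counts divided by the gene
  median (mean fallback when the median is 0, the rule rather than the
  exception for sparse data), pooled on a 1000-bin relative-position
  grid, LOESS-smoothed (span 0.3 default), curve rescaled to mean exactly
  1, counts divided by the curve.  Masked positions contribute to neither
  medians nor the pooled profile.
* Pause windows: non-overlapping 200-bp tiling from the body start,
  trailing partial window dropped (sums over unequal widths are not
  comparable), ties broken leftmost.
* TSS refinement: argmax of 5′-end signal in ±1500 bp, ties toward the
  annotation; all-zero windows keep the annotated TSS with a warning.
* Internal-TSS mask: union of regulatory-element intervals and 2-kb
  windows on capped-5′ peaks with count strictly > 10, clipped to the
  body and merged; the regulatory-element source can be disabled for data
  sets where it is unreliable.
* Pause-location agreement: top-5 windows from true and predicted counts
  are paired rank-wise and r² computed on paired start positions (the
  transparent, monotone choice), with a window-set Jaccard index reported
  alongside as a pairing-free secondary measure.
* 5-mer logos: per coefficient sign, top 50 by |kappa|, K-means (K=2,
  10 seeded restarts) on the scalar coefficients, each cluster summarized
  as a 4×5 position frequency matrix (columns sum to 1).

## Limitations

* Only relative local rates are identifiable; `alpha_j`, `zbar_j`, and
  absolute speeds are not, and promoter-proximal pause escape and
  termination are outside the model (gene bodies are defined to exclude
  them).
* The AIC-selected support size of the L1 fit is the least stable headline
  quantity at the reduced study scale: its realization varies by roughly
  ±20% around 100 across seeds, because held-out-likelihood differences
  per feature are O(1) at this data volume.
* Held-out rate r² in the epigenomic study inherits sampling noise from
  the ~100 independent covariate patches per fold; ±0.02 across seeds is
  typical.
* bigWig files are read but only bedGraph is written (binary output is
  optional, never required).
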