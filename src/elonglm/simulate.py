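"""Stochastic polymerase-occupancy simulator and synthetic-data scenarios.

The simulator tracks individual polymerases moving along a DNA template in
many independent cells, in discrete time slices of ``dt`` minutes with at
most one movement per slice: a polymerase at site i advances with
probability rate_i * dt unless another polymerase within the footprint
blocks it, and a new polymerase initiates at site 1 with probability
alpha * dt per slice while the initiation region is free.  Rather than
looping over every slice, the kernel exploits the memorylessness of the
per-slice Bernoulli trials and jumps between events with geometric waiting
times; a blocked attempt simply reschedules another geometric wait, which
reproduces the per-slice process exactly.  The reported density is the
occupancy averaged over cells *and* over the post-burn-in time window,
a lower-variance estimator of the steady-state density than a single
end-point snapshot.

In the low-collision steady state the occupancy of site i is
alpha / (mean_rate * zeta_i), i.e. inversely proportional to the local
elongation rate — the relationship the GLM inverts.

Two scenario generators reproduce the synthetic studies: correlated
epigenomic-like covariate blocks with Gaussian noise on the log-rate, and
DNA 5-mer-driven rates over random sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .features import BASES, FeatureMatrix, KmerEncoding, encode_kmers, standardize
from .glm import GeneData

__all__ = [
    "SimConfig",
    "SimResult",
    "SimScenario",
    "CovariateBlocks",
    "simulate_polymerases",
    "sample_reads",
    "synthetic_covariate_source",
    "generate_epigenomic_scenario",
    "generate_kmer_scenario",
    "simulate_scenario_reads",
    "DEFAULT_EPIGENOMIC_FEATURES",
    "DEFAULT_KAPPA_TRUE",
]

_NEVER = np.int64(1) << 60


@dataclass
class SimConfig:
    """Configuration for one transcription unit's polymerase simulation.

    ``site_rates`` are absolute movement rates per site (moves/min), i.e.
    the gene's mean elongation rate times the local scale factor zeta_i.
    ``initiation_rate`` is alpha in events/min per cell.
    """

    site_rates: np.ndarray
    initiation_rate: float
    n_cells: int = 5000
    dt: float = 1e-4
    total_time: float = 20.0
    burnin_time: float | None = None
    footprint: int = 33
    seed: int = 0

    def __post_init__(self) -> None:
        self.site_rates = np.asarray(self.site_rates, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if np.any(self.site_rates * self.dt > 1.0):
            raise ValueError("rate * dt must be <= 1 at every site")
        if np.any(self.site_rates <= 0):
            raise ValueError("site rates must be positive")
        if self.initiation_rate < 0 or self.initiation_rate * self.dt > 1.0:
            raise ValueError("initiation rate * dt must be in [0, 1]")
        if self.burnin_time is None:
            self.burnin_time = self.total_time / 2.0
        if not 0 <= self.burnin_time < self.total_time:
            raise ValueError("burn-in must lie within the simulated time")


@dataclass
class SimResult:
    """Output of a polymerase simulation (and optional read sampling)."""

    density: np.ndarray
    counts: np.ndarray | None = None
    realized_mean_depth: float | None = None
    n_initiations: int = 0
    n_terminations: int = 0
    n_resident: int = 0
    min_gap: int = 0


@njit(cache=False)
def _geom(p: float) -> np.int64:
    """Slices until the next success of a Bernoulli(p) process (>= 1)."""
    if p <= 0.0:
        return _NEVER
    if p >= 1.0:
        return np.int64(1)
    u = np.random.random()
    if u <= 0.0:
        return _NEVER
    g = np.floor(np.log(u) / np.log(1.0 - p))
    if g > 1e15:
        return _NEVER
    return np.int64(1 + g)


@njit(cache=False)
def _simulate_kernel(p_move, p_init, n_steps, burn_steps, n_cells, footprint,
                     seed, max_pols):
    np.random.seed(seed)
    L = p_move.size
    occ = np.zeros(L)
    pos = np.zeros(max_pols, dtype=np.int64)
    nxt = np.zeros(max_pols, dtype=np.int64)
    ent = np.zeros(max_pols, dtype=np.int64)
    n_init_tot = 0
    n_term = 0
    n_res = 0
    min_gap = np.int64(1) << 40
    for _cell in range(n_cells):
        npol = 0
        next_init = _geom(p_init)
        while True:
            # next event: smallest step; ties go to the most-downstream
            # polymerase, initiation (the most-upstream event) last
            best = next_init
            kind = -1
            for k in range(npol - 1, -1, -1):
                if nxt[k] <= best:
                    best = nxt[k]
                    kind = k
            if best > n_steps:
                break
            t = best
            if kind == -1:
                if npol < max_pols and (npol == 0 or pos[npol - 1] - 0 > footprint):
                    pos[npol] = 0
                    ent[npol] = t
                    nxt[npol] = t + _geom(p_move[0])
                    if npol > 0:
                        gap = pos[npol - 1] - pos[npol]
                        if gap < min_gap:
                            min_gap = gap
                    npol += 1
                    n_init_tot += 1
                next_init = t + _geom(p_init)
            else:
                k = kind
                if k == 0 or pos[k - 1] - pos[k] > footprint:
                    a = ent[k] if ent[k] > burn_steps else burn_steps
                    b = t if t < n_steps else n_steps
                    if b > a:
                        occ[pos[k]] += b - a
                    pos[k] += 1
                    ent[k] = t
                    if k > 0:
                        gap = pos[k - 1] - pos[k]
                        if gap < min_gap:
                            min_gap = gap
                    if pos[k] >= L:
                        n_term += 1
                        for m in range(k, npol - 1):
                            pos[m] = pos[m + 1]
                            nxt[m] = nxt[m + 1]
                            ent[m] = ent[m + 1]
                        npol -= 1
                    else:
                        nxt[k] = t + _geom(p_move[pos[k]])
                else:
                    nxt[k] = t + _geom(p_move[pos[k]])
        for k in range(npol):
            a = ent[k] if ent[k] > burn_steps else burn_steps
            if n_steps > a:
                occ[pos[k]] += n_steps - a
        n_res += npol
    density = occ / ((n_steps - burn_steps) * n_cells)
    return density, n_init_tot, n_term, n_res, min_gap


def simulate_polymerases(config: SimConfig) -> SimResult:
    """Simulate polymerase movement and return the mean occupancy per site.

    The density is averaged over cells and over the post-burn-in window;
    ``min_gap`` reports the smallest inter-polymerase distance ever
    realized (always >= footprint by construction — the exclusion check).
    """
    n_steps = int(round(config.total_time / config.dt))
    burn_steps = int(round(config.burnin_time / config.dt))
    if burn_steps >= n_steps:
        raise ValueError("burn-in leaves no averaging window")
    L = config.site_rates.size
    max_pols = L // (config.footprint + 1) + 2
    density, n_init, n_term, n_res, min_gap = _simulate_kernel(
        config.site_rates * config.dt,
        config.initiation_rate * config.dt,
        n_steps,
        burn_steps,
        config.n_cells,
        config.footprint,
        int(config.seed) % (2**32),
        max_pols,
    )
    if n_init != n_term + n_res:
        raise AssertionError("flux balance violated: initiations != terminations + resident")
    return SimResult(density=density, n_initiations=n_init, n_terminations=n_term,
                     n_resident=n_res, min_gap=int(min_gap))


def sample_reads(density: np.ndarray, target_mean_depth: float,
                 seed: int | np.random.Generator = 0) -> np.ndarray:
    """Poisson-sample read counts proportional to an occupancy density.

    counts_i ~ Poisson(c * density_i) with c chosen so that the expected
    mean count equals ``target_mean_depth`` — the sampling step that turns
    simulated Pol II density into realistically sparse read counts.
    """
    density = np.asarray(density, dtype=float)
    if np.any(density < 0):
        raise ValueError("density must be >= 0")
    mean = density.mean()
    if mean <= 0:
        if target_mean_depth > 0:
            raise ValueError("all-zero density cannot reach a positive target depth")
        return np.zeros(density.shape, dtype=np.int64)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c = target_mean_depth / mean
    return rng.poisson(c * density)


# ---------------------------------------------------------------------------
# synthetic covariates
# ---------------------------------------------------------------------------

@dataclass
class CovariateBlocks:
    """Library of jointly sampled covariate blocks (n_blocks, n_features, block)."""

    blocks: np.ndarray
    feature_names: list[str]

    @property
    def block_size(self) -> int:
        return self.blocks.shape[2]


# (name, genomic density, correlation length in nt) for the six features the
# epigenomic scenario emulates: a point-like DNA-binding factor, four broad
# chromatin marks, and short RNA stem-loops.
DEFAULT_EPIGENOMIC_FEATURES = [
    ("CTCF", 0.02, 25.0),
    ("H3K36me3", 0.15, 400.0),
    ("H3K9me1", 0.12, 400.0),
    ("H4K20me1", 0.10, 400.0),
    ("H3K79me2", 0.10, 400.0),
    ("stem_loop", 0.08, 40.0),
]

# Gaussian smoothing applied to each scenario covariate before it enters the
# model, matching how the corresponding real features are prepared:
# (radius, bandwidth) in nt — ChIP-derived features r=400, sigma=100;
# stem-loops r=500, sigma=200.
DEFAULT_FEATURE_FILTERS = {
    "CTCF": (400, 100.0),
    "H3K36me3": (400, 100.0),
    "H3K9me1": (400, 100.0),
    "H4K20me1": (400, 100.0),
    "H3K79me2": (400, 100.0),
    "stem_loop": (500, 200.0),
}

# True coefficients on the standardized covariates, at the magnitudes of the
# real-data estimates (strongest marks ~0.1, weakest ~0.03).  Together with
# the correlation structure below they put the Gaussian-noise share of
# var(log zeta) near 25% at noise_sd = 0.1.
DEFAULT_KAPPA_TRUE = {
    "CTCF": -0.025,
    "H3K36me3": -0.100,
    "H3K9me1": -0.080,
    "H4K20me1": -0.040,
    "H3K79me2": 0.030,
    "stem_loop": -0.050,
}

# latent correlation among the four histone marks (they co-occur in domains)
_MARK_CORR = 0.5
_BASE_CORR = 0.1


def _default_latent_correlation(names: Sequence[str]) -> np.ndarray:
    n = len(names)
    corr = np.full((n, n), _BASE_CORR)
    marks = [i for i, nm in enumerate(names) if nm.startswith(("H3", "H4"))]
    for i in marks:
        for j in marks:
            corr[i, j] = _MARK_CORR
    np.fill_diagonal(corr, 1.0)
    return corr


def synthetic_covariate_source(
    n_blocks: int,
    features: Sequence[tuple[str, float, float]] = tuple(DEFAULT_EPIGENOMIC_FEATURES),
    correlation: np.ndarray | None = None,
    block: int = 1000,
    length_scale: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> CovariateBlocks:
    """Generate a block library of correlated binary covariate tracks.

    Each feature is a thresholded latent Gaussian AR(1) process: the AR
    coefficient sets ChIP-like run lengths, the latent cross-correlation
    sets co-occurrence between features, and the threshold sets genomic
    density.  Blocks are cut from one long realization so that within-block
    cross-feature correlation matches the source process.
    """
    names = [f[0] for f in features]
    dens = np.array([f[1] for f in features])
    if np.any((dens <= 0) | (dens >= 1)):
        raise ValueError("densities must lie in (0, 1)")
    lengths = np.maximum(np.array([f[2] for f in features]) * length_scale, 2.0)
    if correlation is None:
        correlation = _default_latent_correlation(names)
    correlation = np.asarray(correlation, dtype=float)
    try:
        chol = np.linalg.cholesky(correlation)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix must be positive definite") from exc
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = n_blocks * block
    nf = len(features)
    eps = rng.standard_normal((n, nf)) @ chol.T
    a = np.exp(-1.0 / lengths)
    latent = np.empty((n, nf))
    latent[0] = eps[0]
    scale = np.sqrt(1.0 - a**2)
    for t in range(1, n):
        latent[t] = a * latent[t - 1] + scale * eps[t]
    from scipy.stats import norm

    thresh = norm.ppf(1.0 - dens)
    binary = (latent > thresh).astype(float)
    blocks = binary.T.reshape(nf, n_blocks, block).transpose(1, 0, 2)
    return CovariateBlocks(blocks=blocks, feature_names=names)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

@dataclass
class SimScenario:
    """Ground truth for a synthetic study: covariates, true coefficients,
    true per-nucleotide rates, and per-TU initiation rates.

    ``kappa_true`` lives in the same space as ``matrix`` (standardized for
    the epigenomic scenario, raw indicators for the k-mer scenario).  The
    gene-level initiation rate alpha and the mean elongation rate are kept
    here — at steady state the GLM can only recover their compound chi.
    """

    kind: str
    n_tus: int
    tu_length: int
    matrix: FeatureMatrix
    kappa_true: np.ndarray
    zeta_true: list[np.ndarray]
    initiation_rates: np.ndarray
    noise_sd: float
    seed: int
    feature_names: list[str] = field(default_factory=list)
    sequences: list[str] | None = None
    active_kmers: list[str] | None = None

    @property
    def log_rate_noise_share(self) -> float:
        """Share of var(log zeta_true) contributed by the Gaussian noise."""
        logz = np.concatenate([np.log(z) for z in self.zeta_true])
        total = logz.var()
        return float(self.noise_sd**2 / total) if total > 0 else 0.0


def _lognormal_initiation_rates(n: int, rng: np.random.Generator,
                                median: float = 1.0, sigma_log: float = 1.0) -> np.ndarray:
    """Per-TU initiation rates, log-normal with the given median (events/min)."""
    return median * np.exp(sigma_log * rng.standard_normal(n))


def generate_epigenomic_scenario(
    n_tus: int = 100,
    tu_length: int = 10_000,
    kappa_true: dict[str, float] | None = None,
    noise_sd: float = 0.1,
    block: int = 1000,
    source: CovariateBlocks | None = None,
    feature_filters: dict[str, tuple[int, float]] | None = None,
    length_scale: float | None = None,
    seed: int = 0,
) -> SimScenario:
    """Build the epigenomic-covariate simulation scenario.

    TUs are tiled with jointly drawn covariate blocks (preserving
    cross-feature correlation); each covariate is then Gaussian-smoothed
    within its TU (ChIP-style features enter the model as smoothed tracks)
    and standardized pooled across TUs.  The true local rate at position i
    is zeta_i = exp(kappa_true . Y_i + delta_i) with
    delta_i ~ N(0, noise_sd^2).  Per-TU initiation rates are log-normal
    with median 1 event/min.

    ``length_scale`` shrinks every genomic length scale of the generator
    (feature domain lengths and smoothing bandwidths) together; it defaults
    to tu_length / 10000 so that reduced-scale TUs preserve the ratio of
    signal correlation length to TU length of the full-scale study on
    10-kb TUs.
    """
    if kappa_true is None:
        kappa_true = dict(DEFAULT_KAPPA_TRUE)
    if length_scale is None:
        length_scale = tu_length / 10_000
    rng = np.random.default_rng(seed)
    if source is None:
        n_source_blocks = max(4 * n_tus * (tu_length // block), 200)
        source = synthetic_covariate_source(n_source_blocks, length_scale=length_scale,
                                            seed=rng)
    if block > tu_length:
        raise ValueError("block size exceeds TU length")
    names = source.feature_names
    missing = set(kappa_true) - set(names)
    if missing:
        raise ValueError(f"kappa_true names unknown to the covariate source: {missing}")
    per_tu = tu_length // block
    if per_tu * block != tu_length:
        raise ValueError("TU length must be a multiple of the block size")
    picks = rng.integers(0, source.blocks.shape[0], size=(n_tus, per_tu))
    covs = source.blocks[picks]                     # (n_tus, per_tu, nf, block)
    covs = covs.transpose(0, 1, 3, 2).reshape(n_tus * tu_length, len(names))
    if feature_filters is None:
        feature_filters = DEFAULT_FEATURE_FILTERS
    from .features import FeatureTrack, apply_filter, build_filter

    for c, nm in enumerate(names):
        if nm not in feature_filters:
            continue
        r, sig = feature_filters[nm]
        r = max(int(round(r * length_scale)), 1)
        sig = max(sig * length_scale, 1.0)
        filt = build_filter("gaussian", r, sigma=sig)
        col = covs[:, c].reshape(n_tus, tu_length)
        covs[:, c] = np.concatenate(
            [apply_filter(FeatureTrack(nm, row), filt).values for row in col]
        )
    matrix = standardize(FeatureMatrix(list(names), covs))
    kvec = np.concatenate([[0.0], [kappa_true.get(nm, 0.0) for nm in names]])
    log_rate = matrix.dot(kvec)
    if noise_sd > 0:
        log_rate = log_rate + rng.normal(0.0, noise_sd, size=log_rate.size)
    zeta = np.exp(log_rate)
    zeta_true = [zeta[i * tu_length : (i + 1) * tu_length] for i in range(n_tus)]
    alpha = _lognormal_initiation_rates(n_tus, rng)
    return SimScenario(
        kind="epigenomic", n_tus=n_tus, tu_length=tu_length, matrix=matrix,
        kappa_true=kvec, zeta_true=zeta_true, initiation_rates=alpha,
        noise_sd=noise_sd, seed=seed, feature_names=list(names),
    )


def generate_kmer_scenario(
    n_seqs: int = 20_000,
    length: int = 1000,
    n_active: int = 100,
    kappa_range: float = 0.3,
    base_composition: Sequence[float] = (0.295, 0.205, 0.205, 0.295),
    seed: int = 0,
) -> SimScenario:
    """Build the 5-mer simulation scenario.

    ``n_active`` randomly chosen 5-mers get coefficients spanning
    [-kappa_range, +kappa_range] (evenly spaced); all other 5-mers get 0.
    Sequences are i.i.d. draws matching a mammalian genomic base
    composition, and zeta_i = exp(kappa . Y_i) with no Gaussian noise —
    each position carries exactly one 5-mer indicator (the 5-mer centered
    on it), so zeta_i is the exponentiated coefficient of that 5-mer.
    """
    if n_active > 4**5:
        raise ValueError("cannot activate more than 1024 distinct 5-mers")
    rng = np.random.default_rng(seed)
    encoding = KmerEncoding(k_sizes=(5,), anchor_shift=0)
    kmer_names = encoding.column_names()
    kappa_kmers = np.zeros(4**5)
    active_idx = rng.choice(4**5, size=n_active, replace=False)
    if n_active > 0:
        kappa_kmers[active_idx] = (
            np.linspace(-kappa_range, kappa_range, n_active) if n_active > 1
            else np.array([kappa_range])
        )
    base_composition = np.asarray(base_composition, dtype=float)
    base_composition = base_composition / base_composition.sum()
    codes = rng.choice(4, size=(n_seqs, length), p=base_composition)
    letters = np.array(list(BASES))
    sequences = ["".join(letters[row]) for row in codes]
    mats = [encode_kmers(s, encoding) for s in sequences]
    import scipy.sparse as sp

    matrix = FeatureMatrix(kmer_names, sp.vstack(mats, format="csr"))
    kvec = np.concatenate([[0.0], kappa_kmers])
    zeta_all = np.exp(matrix.dot(kvec))
    zeta_true = [zeta_all[i * length : (i + 1) * length] for i in range(n_seqs)]
    alpha = _lognormal_initiation_rates(n_seqs, rng)
    return SimScenario(
        kind="kmer", n_tus=n_seqs, tu_length=length, matrix=matrix,
        kappa_true=kvec, zeta_true=zeta_true, initiation_rates=alpha,
        noise_sd=0.0, seed=seed, feature_names=kmer_names, sequences=sequences,
        active_kmers=[kmer_names[i] for i in sorted(active_idx)],
    )


def simulate_scenario_reads(
    scenario: SimScenario,
    n_cells: int = 5000,
    total_time: float = 20.0,
    burnin_time: float | None = None,
    dt: float = 1e-4,
    mean_elongation_rate: float = 2000.0,
    target_mean_depth: float = 0.5,
    footprint: int = 33,
    seed: int = 0,
) -> tuple[list[GeneData], list[np.ndarray]]:
    """Simulate occupancy for every TU of a scenario and sample read counts.

    Site rates are mean_elongation_rate * zeta_true (moves/min; 2 kb/min is
    the canonical mammalian Pol II speed).  Counts are sampled with one
    global depth scale so that per-TU depth differences reflect the
    initiation rates, exactly as sequencing depth works.  Returns the genes
    (all-True masks) and the per-TU densities.
    """
    ss = np.random.SeedSequence(seed)
    tu_seeds = ss.generate_state(scenario.n_tus)
    densities = []
    for j in range(scenario.n_tus):
        cfg = SimConfig(
            site_rates=mean_elongation_rate * scenario.zeta_true[j],
            initiation_rate=float(scenario.initiation_rates[j]),
            n_cells=n_cells, dt=dt, total_time=total_time,
            burnin_time=burnin_time, footprint=footprint,
            seed=int(tu_seeds[j]),
        )
        densities.append(simulate_polymerases(cfg).density)
    all_density = np.concatenate(densities)
    mean_density = all_density.mean()
    if mean_density <= 0:
        raise ValueError("simulation produced no occupancy; increase time or cells")
    c = target_mean_depth / mean_density
    rng = np.random.default_rng(ss.spawn(1)[0])
    genes = []
    for j, dens in enumerate(densities):
        counts = rng.poisson(c * dens)
        genes.append(GeneData(gene_id=f"TU{j:05d}", counts=counts.astype(float)))
    return genes, densities
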