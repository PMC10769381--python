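"""End-to-end simulation studies at desk scale.

Two pipelines validate the elongation-rate GLM against ground truth from
the polymerase simulator:

* :func:`run_epigenomic_recovery` — transcription units tiled with
  correlated epigenomic-like covariate blocks; true log-rates are a linear
  function of the standardized covariates plus Gaussian noise.  Fit on a
  training split, predict per-nucleotide rates on held-out TUs, and
  measure agreement with the truth.
* :func:`run_kmer_lasso` — random DNA sequences whose true rates are
  driven by 100 active 5-mers; the L1-penalized model over all 1024 5-mer
  indicators is fitted with the penalty chosen by held-out AIC, and the
  recovered coefficients, predicted rates, and support are compared with
  the truth.

Problem sizes default to the reduced scales these studies are run at on a
single CPU (epigenomic: 50 TUs x 2 kb, 500 cells, 5 simulated minutes;
5-mers: 2,000 sequences x 1 kb, 100 cells, 3 simulated minutes); all
randomness flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluate import r_squared
from .features import FeatureMatrix, standardize
from .glm import FitResult, fit, predict_rates, select_nu, split_genes, _subset
from .simulate import (
    SimScenario,
    generate_epigenomic_scenario,
    generate_kmer_scenario,
    simulate_scenario_reads,
)

__all__ = ["EpigenomicRecoveryResult", "KmerLassoResult",
           "run_epigenomic_recovery", "run_kmer_lasso"]


@dataclass
class EpigenomicRecoveryResult:
    scenario: SimScenario
    fit_result: FitResult            # fit of the first fold
    feature_names: list[str]
    kappa_true: np.ndarray           # non-intercept, standardized space
    kappa_hat: np.ndarray            # mean over folds, non-intercept
    kappa_hat_folds: np.ndarray      # (n_folds, P-1)
    r2_zeta_heldout: float
    noise_share: float
    n_heldout_positions: int
    n_train_tus: int


def run_epigenomic_recovery(
    n_tus: int = 50,
    tu_length: int = 2000,
    n_cells: int = 500,
    total_time: float = 5.0,
    noise_sd: float = 0.1,
    target_mean_depth: float = 0.5,
    n_folds: int = 5,
    seed: int = 1,
    **fit_kwargs,
) -> EpigenomicRecoveryResult:
    """Simulate the epigenomic scenario and score held-out rate recovery.

    TUs rotate through ``n_folds`` folds: each fold's model is fitted on
    the other 80% of TUs and predicts per-nucleotide rates for its own
    held-out 20%; held-out predictions are pooled across folds before
    computing r^2 against the truth (each TU is predicted exactly once, by
    a model that never saw it).  Rates are compared on the log scale,
    where the Gaussian-noise variance decomposition is exact (unexplained
    variance = noise share).
    """
    ss = np.random.SeedSequence(seed)
    s_scen, s_sim, s_split = (int(s.generate_state(1)[0]) for s in ss.spawn(3))
    scenario = generate_epigenomic_scenario(
        n_tus=n_tus, tu_length=tu_length, noise_sd=noise_sd, seed=s_scen
    )
    genes, _ = simulate_scenario_reads(
        scenario, n_cells=n_cells, total_time=total_time,
        target_mean_depth=target_mean_depth, seed=s_sim,
    )
    # standardization is refit on each fold's training TUs: held-out
    # covariates are transformed with training statistics, as for real data
    raw_vals = scenario.matrix.values * scenario.matrix.sigma + scenario.matrix.mu
    raw = FeatureMatrix(scenario.feature_names, raw_vals)
    perm = np.random.default_rng(s_split).permutation(n_tus)
    folds = np.array_split(perm, n_folds)
    log_true_all, log_hat_all = [], []
    kappa_folds = []
    first_fit = None
    for f, test_idx in enumerate(folds):
        train_idx = np.sort(np.setdiff1d(perm, test_idx))
        test_idx = np.sort(test_idx)
        genes_tr, raw_tr = _subset(genes, raw, train_idx)
        _, raw_te = _subset(genes, raw, test_idx)
        res = fit(genes_tr, standardize(raw_tr), **fit_kwargs)
        if first_fit is None:
            first_fit = res
        kappa_folds.append(res.params.kappa[1:])
        te_std = FeatureMatrix(res.columns[1:],
                               (np.asarray(raw_te.values) - res.mu) / res.sigma,
                               mu=res.mu, sigma=res.sigma, mode="dense")
        zeta_hat = predict_rates(res.params.kappa, te_std)
        zeta_true = np.concatenate([scenario.zeta_true[i] for i in test_idx])
        log_true_all.append(np.log(zeta_true))
        log_hat_all.append(np.log(zeta_hat))
    log_true = np.concatenate(log_true_all)
    log_hat = np.concatenate(log_hat_all)
    kappa_folds = np.array(kappa_folds)
    return EpigenomicRecoveryResult(
        scenario=scenario,
        fit_result=first_fit,
        feature_names=list(scenario.feature_names),
        kappa_true=scenario.kappa_true[1:],
        kappa_hat=kappa_folds.mean(axis=0),
        kappa_hat_folds=kappa_folds,
        r2_zeta_heldout=r_squared(log_true, log_hat),
        noise_share=scenario.log_rate_noise_share,
        n_heldout_positions=int(log_true.size),
        n_train_tus=n_tus - len(folds[0]),
    )


@dataclass
class KmerLassoResult:
    scenario: SimScenario
    fit_result: FitResult
    nu_star: float
    kappa_true_raw: np.ndarray   # 1024-vector over 5-mers
    kappa_hat_raw: np.ndarray
    r2_kappa: float
    r2_zeta: float
    n_nonzero: int
    true_positive: int           # selected 5-mers that are truly active
    nu_table: "object"
    n_positions: int


def run_kmer_lasso(
    n_seqs: int = 2000,
    length: int = 1000,
    n_active: int = 100,
    n_cells: int = 100,
    total_time: float = 3.0,
    target_mean_depth: float = 0.5,
    test_frac: float = 0.2,
    seed: int = 1,
    nu_grid=None,
    **fit_kwargs,
) -> KmerLassoResult:
    """Simulate the 5-mer scenario, fit the L1-penalized GLM with the
    penalty selected by held-out AIC, and score coefficient and rate
    recovery over all 1024 5-mers."""
    ss = np.random.SeedSequence(seed)
    s_scen, s_sim, s_split = (int(s.generate_state(1)[0]) for s in ss.spawn(3))
    scenario = generate_kmer_scenario(
        n_seqs=n_seqs, length=length, n_active=n_active, seed=s_scen
    )
    genes, _ = simulate_scenario_reads(
        scenario, n_cells=n_cells, total_time=total_time,
        target_mean_depth=target_mean_depth, seed=s_sim,
    )
    matrix = standardize(scenario.matrix)
    nu_star, res, table = select_nu(genes, matrix, nu_grid=nu_grid,
                                    test_frac=test_frac, seed=s_split,
                                    **fit_kwargs)
    kappa_hat_raw = res.kappa_raw[1:]
    kappa_true_raw = scenario.kappa_true[1:]
    zeta_hat = predict_rates(res.params.kappa, matrix)
    zeta_true = np.concatenate(scenario.zeta_true)
    selected = {c for c, k in zip(res.columns[1:], res.params.kappa[1:]) if k != 0.0}
    return KmerLassoResult(
        scenario=scenario,
        fit_result=res,
        nu_star=nu_star,
        kappa_true_raw=kappa_true_raw,
        kappa_hat_raw=kappa_hat_raw,
        r2_kappa=r_squared(kappa_true_raw, kappa_hat_raw),
        r2_zeta=r_squared(np.log(zeta_true), np.log(zeta_hat)),
        n_nonzero=len(selected),
        true_positive=len(selected & set(scenario.active_kmers)),
        nu_table=table,
        n_positions=int(zeta_true.size),
    )
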