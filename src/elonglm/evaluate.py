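"""Model-free validations and model assessments.

Because nascent-RNA counts are extremely sparse at single nucleotides,
model quality is judged through aggregated quantities: relative read
depth in feature-covered vs uncovered positions, metaplots around feature
anchors, agreement of predicted and observed pause-window locations, and
windowed read-count prediction on held-out genes.  A K-means clustering of
L1-selected 5-mer coefficients summarizes sequence preferences as position
frequency matrices suitable for logo rendering.

Relative read depth always means counts divided by their mean within each
gene body, which removes gene-level initiation/elongation differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import pause_windows

__all__ = [
    "RelativeDepthProfile",
    "PausePredictionResult",
    "KmerCluster",
    "r_squared",
    "covered_uncovered_ratio",
    "metaplot",
    "evaluate_pause_prediction",
    "evaluate_window_prediction",
    "cluster_kmers",
]


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Squared Pearson correlation (the r^2 of an agreement scatter).

    Returns 0.0 when either vector is constant (a constant prediction
    explains none of the variance).
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise ValueError("vectors must have equal length")
    st, sp = y_true.std(), y_pred.std()
    if st == 0 or sp == 0:
        return 0.0
    r = float(np.corrcoef(y_true, y_pred)[0, 1])
    return r * r


@dataclass
class RelativeDepthProfile:
    """Mean relative read depth around feature anchors."""

    anchor: str
    offsets: np.ndarray
    mean_relative_depth: np.ndarray
    n_anchors: int


def _relative_depth(counts: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mean = counts[mask].mean() if mask.any() else 0.0
    if mean <= 0:
        return np.zeros_like(counts)
    return counts / mean


def covered_uncovered_ratio(
    counts: list[np.ndarray],
    coverage: list[np.ndarray],
    masks: list[np.ndarray] | None = None,
) -> float:
    """Ratio of mean relative read depth in feature-covered positions to
    that in uncovered positions, pooled across genes.

    A ratio > 1 indicates elevated polymerase density (slower elongation)
    where the feature is present.  Raises if no position is covered.
    """
    if masks is None:
        masks = [np.ones(x.size, dtype=bool) for x in counts]
    cov_vals, unc_vals = [], []
    for x, c, m in zip(counts, coverage, masks):
        x = np.asarray(x, dtype=float)
        c = np.asarray(c, dtype=bool)
        m = np.asarray(m, dtype=bool)
        rel = _relative_depth(x, m)
        cov_vals.append(rel[m & c])
        unc_vals.append(rel[m & ~c])
    cov = np.concatenate(cov_vals)
    unc = np.concatenate(unc_vals)
    if cov.size == 0:
        raise ValueError("no covered positions: ratio undefined")
    if unc.size == 0 or unc.mean() <= 0:
        raise ValueError("no uncovered positions with signal: ratio undefined")
    return float(cov.mean() / unc.mean())


def metaplot(
    counts: list[np.ndarray],
    anchors: list[np.ndarray],
    flank: int = 500,
    masks: list[np.ndarray] | None = None,
    anchor_name: str = "feature",
) -> RelativeDepthProfile:
    """Mean relative read depth at each offset in [-flank, +flank] around
    feature anchors (a metagene profile; featureless data gives a flat
    profile at 1)."""
    if masks is None:
        masks = [np.ones(x.size, dtype=bool) for x in counts]
    total = np.zeros(2 * flank + 1)
    n = np.zeros(2 * flank + 1)
    n_anchors = 0
    for x, anc, m in zip(counts, anchors, masks):
        x = np.asarray(x, dtype=float)
        m = np.asarray(m, dtype=bool)
        rel = _relative_depth(x, m)
        for a in np.asarray(anc, dtype=int):
            lo, hi = a - flank, a + flank + 1
            olo, ohi = max(0, -lo), 2 * flank + 1 - max(0, hi - x.size)
            seg = slice(max(lo, 0), min(hi, x.size))
            use = m[seg]
            total[olo:ohi][use] += rel[seg][use]
            n[olo:ohi][use] += 1
            n_anchors += 1
    with np.errstate(invalid="ignore"):
        prof = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    return RelativeDepthProfile(anchor=anchor_name,
                                offsets=np.arange(-flank, flank + 1),
                                mean_relative_depth=prof, n_anchors=n_anchors)


@dataclass
class PausePredictionResult:
    r2: float
    jaccard: float
    n_genes: int


def evaluate_pause_prediction(
    true_counts: list[np.ndarray],
    predicted_counts: list[np.ndarray],
    width: int = 200,
    top: int = 5,
) -> PausePredictionResult:
    """Agreement between predicted and observed pausing locations.

    Per gene, the top-``top`` windows by summed counts are extracted from
    both tracks; windows are paired rank-wise (1st-ranked true with
    1st-ranked predicted, etc.) and r^2 is computed between the paired
    window start positions pooled over genes.  A window-set Jaccard index
    is reported as a secondary, pairing-free measure.  Genes shorter than
    ``width`` are skipped.
    """
    t_pos, p_pos = [], []
    jaccards = []
    n_genes = 0
    for xt, xp in zip(true_counts, predicted_counts):
        if np.asarray(xt).size < width:
            continue
        wt = pause_windows(np.asarray(xt), width=width, top=top)
        wp = pause_windows(np.asarray(xp), width=width, top=top)
        n_genes += 1
        for (a, _), (b, _) in zip(wt, wp):
            t_pos.append(a)
            p_pos.append(b)
        st, sp_ = set(wt), set(wp)
        jaccards.append(len(st & sp_) / len(st | sp_))
    if not t_pos:
        raise ValueError("no gene was long enough for pause windows")
    return PausePredictionResult(r2=r_squared(np.array(t_pos), np.array(p_pos)),
                                 jaccard=float(np.mean(jaccards)), n_genes=n_genes)


def evaluate_window_prediction(
    true_counts: list[np.ndarray],
    predicted_counts: list[np.ndarray],
    width: int = 1000,
    masks: list[np.ndarray] | None = None,
) -> float:
    """r^2 between mean true and mean predicted counts over fixed-width
    windows, pooled across (held-out) genes."""
    if masks is None:
        masks = [np.ones(np.asarray(x).size, dtype=bool) for x in true_counts]
    t_vals, p_vals = [], []
    for xt, xp, m in zip(true_counts, predicted_counts, masks):
        xt = np.asarray(xt, dtype=float)
        xp = np.asarray(xp, dtype=float)
        m = np.asarray(m, dtype=bool)
        n_win = xt.size // width
        for w in range(n_win):
            seg = slice(w * width, (w + 1) * width)
            use = m[seg]
            if use.sum() == 0:
                continue
            t_vals.append(xt[seg][use].mean())
            p_vals.append(xp[seg][use].mean())
    return r_squared(np.array(t_vals), np.array(p_vals))


@dataclass
class KmerCluster:
    """One cluster of 5-mers with its position frequency matrix (4 x k)."""

    sign: str
    members: list[str]
    kappas: np.ndarray
    pfm: np.ndarray  # rows A,C,G,T; columns sum to 1


def _pfm(kmers: list[str]) -> np.ndarray:
    k = len(kmers[0])
    pfm = np.zeros((4, k))
    order = {b: i for i, b in enumerate("ACGT")}
    for km in kmers:
        for j, b in enumerate(km):
            pfm[order[b], j] += 1
    return pfm / pfm.sum(axis=0, keepdims=True)


def cluster_kmers(
    kappa: dict[str, float],
    top: int = 50,
    n_clusters: int = 2,
    n_init: int = 10,
    seed: int = 0,
) -> list[KmerCluster]:
    """Cluster L1-selected 5-mers for logo rendering.

    5-mers are split by coefficient sign; within each sign group the top
    ``top`` candidates by |kappa| are clustered with K-means (K=2 by
    default, 10 seeded restarts) on the scalar kappa values, and each
    cluster is summarized by a position frequency matrix.  Groups with
    fewer than ``top`` nonzero 5-mers use all available with a warning;
    fewer than 2 distinct values fall back to a single cluster.
    """
    from sklearn.cluster import KMeans

    clusters: list[KmerCluster] = []
    for sign, keep in (("positive", lambda v: v > 0), ("negative", lambda v: v < 0)):
        items = [(k, v) for k, v in kappa.items() if keep(v)]
        if not items:
            continue
        if len(items) < top:
            warnings.warn(f"only {len(items)} {sign} 5-mers available (requested {top})")
        items.sort(key=lambda kv: -abs(kv[1]))
        items = items[:top]
        values = np.array([v for _, v in items])
        names = [k for k, _ in items]
        if np.unique(values).size < 2 or len(items) < n_clusters:
            labels = np.zeros(len(items), dtype=int)
            n_eff = 1
        else:
            km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed)
            labels = km.fit_predict(values.reshape(-1, 1))
            n_eff = n_clusters
        for c in range(n_eff):
            members = [n for n, l in zip(names, labels) if l == c]
            vals = values[labels == c]
            clusters.append(KmerCluster(sign=sign, members=members, kappas=vals,
                                        pfm=_pfm(members)))
    return clusters
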