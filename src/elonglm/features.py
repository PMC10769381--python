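"""Per-nucleotide feature engineering for the elongation-rate GLM.

The model relates the local elongation rate at nucleotide i to a feature
vector Y_i via zeta_i = exp(kappa . Y_i).  This module builds those feature
vectors: smoothing filters that distribute point-like annotations (splice
sites, ChIP peaks) over neighboring positions, sparse one-hot k-mer
indicator columns anchored at the polymerase active site (the read 3' end),
and column standardization to zero mean / unit standard deviation so that
coefficients are comparable across features.

Coordinates are 0-based half-open on the transcribed strand: position i is
the active site, negative offsets are upstream (5') of it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "FeatureTrack",
    "SmoothingFilter",
    "KmerEncoding",
    "FeatureMatrix",
    "build_filter",
    "apply_filter",
    "estimate_generalized_weights",
    "encode_kmers",
    "standardize",
    "stack_matrices",
]

BASES = "ACGT"
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


class FilterError(ValueError):
    """Invalid smoothing-filter specification."""


class EncodingError(ValueError):
    """Invalid sequence for k-mer encoding."""


@dataclass
class FeatureTrack:
    """One scalar covariate over a gene-body coordinate frame.

    ``defined_mask`` marks positions where the feature is meaningful (e.g.
    CpG positions for DNA methylation); undefined positions contribute
    exactly zero to the standardized feature matrix.
    """

    name: str
    values: np.ndarray
    defined_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.defined_mask is not None:
            self.defined_mask = np.asarray(self.defined_mask, dtype=bool)
            if self.defined_mask.shape != self.values.shape:
                raise ValueError("defined_mask and values must have equal length")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class SmoothingFilter:
    """Normalized kernel F_{r,sigma,delta} redistributing a covariate.

    ``kind`` is "gaussian" (F(k) = (1/sigma) exp(-(k/sigma)^2 / 2)) or
    "generalized" (F(k) = weights[k + r]).  ``delta`` offsets which input
    positions feed output position i: output i draws on inputs in
    [i + delta - r, i + delta + r].
    """

    kind: str
    radius: int
    sigma: float | None = None
    delta: int = 0
    weights: np.ndarray | None = None

    def kernel(self) -> np.ndarray:
        """Unnormalized taps F(k) for k = -r..r."""
        k = np.arange(-self.radius, self.radius + 1)
        if self.kind == "gaussian":
            return (1.0 / self.sigma) * np.exp(-0.5 * (k / self.sigma) ** 2)
        return np.asarray(self.weights, dtype=float)

    @property
    def normalizer(self) -> float:
        return float(self.kernel().sum())


def build_filter(
    kind: str,
    r: int,
    sigma: float | None = None,
    delta: int = 0,
    weights: Sequence[float] | None = None,
) -> SmoothingFilter:
    """Construct and validate a smoothing filter.

    Raises :class:`FilterError` for a negative radius, missing/invalid
    sigma on a Gaussian filter, or generalized weights that are negative,
    of the wrong length, or sum to zero.
    """
    if kind not in ("gaussian", "generalized"):
        raise FilterError(f"unknown filter kind {kind!r}")
    if r < 0:
        raise FilterError("radius must be >= 0")
    if kind == "gaussian":
        if sigma is None or sigma <= 0:
            raise FilterError("gaussian filter requires sigma > 0")
        filt = SmoothingFilter("gaussian", int(r), float(sigma), int(delta))
    else:
        if weights is None:
            raise FilterError("generalized filter requires weights")
        w = np.asarray(weights, dtype=float)
        if w.size != 2 * r + 1:
            raise FilterError(f"generalized filter needs 2r+1 = {2 * r + 1} weights, got {w.size}")
        if np.any(w < 0):
            raise FilterError("generalized filter weights must be nonnegative")
        filt = SmoothingFilter("generalized", int(r), None, int(delta), w)
    if filt.normalizer <= 0:
        raise FilterError("filter normalizer must be positive")
    return filt


def apply_filter(track: FeatureTrack, filt: SmoothingFilter) -> FeatureTrack:
    """Smooth a track: output_i = (1/Z_i) sum_k value(i+k+delta) F(k).

    Boundary policy: positions outside the track are zero-padded and the
    normalizer Z_i is recomputed over in-bounds taps only, so that a
    constant track maps to the same constant everywhere (no signal is
    invented beyond the gene body).
    """
    values = np.asarray(track.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"track {track.name!r} contains non-finite values")
    if track.defined_mask is not None:
        values = np.where(track.defined_mask, values, 0.0)
    n = values.size
    kern = filt.kernel()
    r, delta = filt.radius, filt.delta
    # output_i = sum_k values[i + k + delta] * kern[k + r]; np.correlate with the
    # kernel realises the sum over a window, the delta offset is an index shift.
    pad = r + abs(delta)
    padded = np.zeros(n + 2 * pad)
    padded[pad : pad + n] = values
    ones = np.zeros_like(padded)
    ones[pad : pad + n] = 1.0
    num = np.correlate(padded, kern, mode="same")
    den = np.correlate(ones, kern, mode="same")
    # window centered at padded index i covers padded[i-r .. i+r]; output position
    # i of the track reads the window centered at padded index i + pad + delta.
    idx = np.arange(n) + pad + delta
    out = np.zeros(n)
    valid = den[idx] > 0
    out[valid] = num[idx][valid] / den[idx][valid]
    return FeatureTrack(track.name, out)


def estimate_generalized_weights(
    counts: Sequence[np.ndarray],
    anchors: Sequence[np.ndarray],
    r: int,
) -> np.ndarray:
    """Estimate generalized-filter weights from a read-count metaplot.

    weights[k + r] is the mean relative read depth at offset k from the
    anchored feature (each gene's counts divided by its gene-body mean),
    clipped at zero.  Mirrors fitting filter scale factors to metaplots of
    nascent-RNA data centered on the feature of interest.
    """
    total = np.zeros(2 * r + 1)
    n = np.zeros(2 * r + 1)
    for x, anc in zip(counts, anchors):
        x = np.asarray(x, dtype=float)
        mean = x.mean()
        if mean <= 0:
            continue
        rel = x / mean
        for a in np.asarray(anc, dtype=int):
            lo, hi = a - r, a + r + 1
            klo, khi = max(0, -lo), 2 * r + 1 - max(0, hi - x.size)
            seg = rel[max(lo, 0) : min(hi, x.size)]
            total[klo:khi] += seg
            n[klo:khi] += 1
    with np.errstate(invalid="ignore"):
        w = np.where(n > 0, total / np.maximum(n, 1), 0.0)
    return np.clip(w, 0.0, None)


@dataclass(frozen=True)
class KmerEncoding:
    """One-hot k-mer indicators anchored at the active site.

    For odd k the window is centered on position i; for even k the active
    site is the left-of-center base, i.e. the window is
    [i - ceil(k/2) + 1, i + floor(k/2)] (so the 2-mer at i reads the base
    at i followed by the next base downstream).  ``anchor_shift`` moves the
    whole window by a signed offset (negative = upstream of the 3' end).
    """

    k_sizes: tuple[int, ...] = (5,)
    anchor_shift: int = 0

    def __post_init__(self) -> None:
        ks = tuple(sorted(set(int(k) for k in self.k_sizes)))
        if not ks or min(ks) < 1 or max(ks) > 5:
            raise ValueError("k sizes must be integers in 1..5")
        object.__setattr__(self, "k_sizes", ks)

    @property
    def n_columns(self) -> int:
        return sum(4**k for k in self.k_sizes)

    def column_names(self) -> list[str]:
        names = []
        for k in self.k_sizes:
            names.extend("".join(p) for p in itertools.product(BASES, repeat=k))
        return names

    def window_start(self, i: int, k: int) -> int:
        return i + self.anchor_shift - ((k + 1) // 2) + 1


def _sequence_codes(sequence: str) -> np.ndarray:
    if len(sequence) == 0:
        raise EncodingError("empty sequence")
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _BASE_CODE[raw].astype(np.int64)
    bad = (codes < 0) & ~np.isin(raw, [ord("N"), ord("n")])
    if bad.any():
        ch = chr(int(raw[np.argmax(bad)]))
        raise EncodingError(f"non-IUPAC character {ch!r} in sequence")
    return codes


def encode_kmers(sequence: str, encoding: KmerEncoding | None = None) -> sp.csr_matrix:
    """Encode a sequence as sparse k-mer indicator columns.

    Returns a CSR matrix of shape (len(sequence), sum_k 4^k): row i holds,
    for each k, the indicator of the k-mer whose (shifted) window covers
    the active site i.  Windows containing N or running off the sequence
    leave all indicators of that k at zero.  The sequence must already be
    on the transcribed strand.
    """
    if encoding is None:
        encoding = KmerEncoding()
    codes = _sequence_codes(sequence)
    n = codes.size
    rows, cols = [], []
    offset = 0
    positions = np.arange(n)
    for k in encoding.k_sizes:
        start = positions + encoding.anchor_shift - ((k + 1) // 2) + 1
        valid = (start >= 0) & (start + k <= n)
        idx = np.where(valid)[0]
        s = start[idx]
        code = np.zeros(idx.size, dtype=np.int64)
        ok = np.ones(idx.size, dtype=bool)
        for j in range(k):
            c = codes[s + j]
            ok &= c >= 0
            code = code * 4 + np.where(c >= 0, c, 0)
        idx, code = idx[ok], code[ok]
        rows.append(idx)
        cols.append(offset + code)
        offset += 4**k
    row = np.concatenate(rows) if rows else np.empty(0, dtype=int)
    col = np.concatenate(cols) if cols else np.empty(0, dtype=int)
    data = np.ones(row.size)
    return sp.csr_matrix((data, (row, col)), shape=(n, encoding.n_columns))


class ZeroVarianceError(ValueError):
    """A feature column has zero variance over its defined positions."""


@dataclass
class FeatureMatrix:
    """Per-position feature vectors Y_i with a leading implicit intercept.

    ``columns`` always starts with "intercept"; the stored ``values`` array
    (dense ndarray or CSR sparse, shape (N, P-1)) omits the intercept,
    which is identically 1 and never standardized.

    Standardization state:

    * mode "none"   — raw values, no mu/sigma.
    * mode "dense"  — values hold standardized columns in place.
    * mode "affine" — values stay raw (typically sparse indicators) and the
      affine map x -> (x - mu)/sigma is applied inside :meth:`dot` /
      :meth:`tdot`.  Because kappa.Y_std = (kappa/sigma).Y_raw -
      kappa.(mu/sigma), dot products with raw sparse columns plus a linear
      correction reproduce the dense standardized computation exactly; this
      keeps the k-mer indicator columns sparse.

    ``defined`` (dense mode only) marks, per column, the positions where
    the feature is meaningful; undefined positions are exactly 0 after
    standardization.
    """

    columns: list[str]
    values: np.ndarray | sp.spmatrix
    mu: np.ndarray | None = None
    sigma: np.ndarray | None = None
    mode: str = "none"
    defined: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.columns[0] != "intercept":
            self.columns = ["intercept"] + list(self.columns)
        if sp.issparse(self.values):
            self.values = self.values.tocsr()
        else:
            self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.columns) - 1:
            raise ValueError("values must have one column per non-intercept feature")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_tracks(cls, tracks: Sequence[FeatureTrack]) -> "FeatureMatrix":
        n = len(tracks[0])
        if any(len(t) != n for t in tracks):
            raise ValueError("all tracks must have equal length")
        vals = np.column_stack([t.values for t in tracks])
        defined = None
        if any(t.defined_mask is not None for t in tracks):
            defined = np.column_stack(
                [t.defined_mask if t.defined_mask is not None else np.ones(n, bool) for t in tracks]
            )
        return cls([t.name for t in tracks], vals, defined=defined)

    @classmethod
    def from_sparse(cls, columns: Iterable[str], values: sp.spmatrix) -> "FeatureMatrix":
        return cls(list(columns), values)

    # -- basic properties --------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        """Number of feature columns including the intercept."""
        return self.values.shape[1] + 1

    def subset_rows(self, idx: np.ndarray) -> "FeatureMatrix":
        vals = self.values[idx]
        defined = self.defined[idx] if self.defined is not None else None
        return replace(self, values=vals, defined=defined)

    # -- linear algebra in standardized space ------------------------------
    def dot(self, kappa: np.ndarray) -> np.ndarray:
        """kappa . Y_i for every row, in the standardized feature space."""
        kappa = np.asarray(kappa, dtype=float)
        if kappa.size != self.n_features:
            raise ValueError(
                f"kappa has {kappa.size} components, matrix has {self.n_features} features"
            )
        k0, k = kappa[0], kappa[1:]
        if self.mode == "affine":
            scaled = k / self.sigma
            out = np.asarray(self.values @ scaled).ravel()
            return out + (k0 - float(np.dot(k, self.mu / self.sigma)))
        out = np.asarray(self.values @ k).ravel()
        return out + k0

    def tdot(self, w: np.ndarray) -> np.ndarray:
        """Y^T w in standardized space, intercept component first."""
        w = np.asarray(w, dtype=float)
        total = float(w.sum())
        raw = np.asarray(self.values.T @ w).ravel()
        if self.mode == "affine":
            raw = (raw - self.mu * total) / self.sigma
        return np.concatenate([[total], raw])

    def to_dense_standardized(self) -> np.ndarray:
        """Dense standardized matrix including the intercept column (tests)."""
        if self.mode == "affine":
            dense = np.asarray(self.values.todense() if sp.issparse(self.values) else self.values)
            dense = (dense - self.mu) / self.sigma
        elif self.mode == "dense":
            dense = np.asarray(self.values)
        else:
            dense = np.asarray(self.values.todense() if sp.issparse(self.values) else self.values)
        return np.column_stack([np.ones(self.n_rows), dense])

    def kappa_raw(self, kappa: np.ndarray) -> np.ndarray:
        """Convert standardized-space coefficients to raw-feature scale.

        The raw-scale intercept absorbs the standardization shift:
        kappa.Y_std = kappa_raw.Y_raw + const.
        """
        kappa = np.asarray(kappa, dtype=float)
        if self.mode == "none" or self.sigma is None:
            return kappa.copy()
        out = np.empty_like(kappa)
        out[1:] = kappa[1:] / self.sigma
        out[0] = kappa[0] - float(np.dot(kappa[1:], self.mu / self.sigma))
        return out


def standardize(
    matrix: FeatureMatrix,
    rows: np.ndarray | None = None,
    on_zero_variance: str = "error",
) -> FeatureMatrix:
    """Standardize feature columns to mean 0, sd 1 (population sd).

    Statistics are computed over ``rows`` (boolean mask of positions used
    for fitting; default all) and, per column, only over its defined
    positions; undefined positions are assigned exactly 0 afterwards.
    Dense matrices are transformed in place ("dense" mode); sparse matrices
    keep their raw values and record the affine map ("affine" mode).
    Standardization is idempotent: applying it to a "dense"-mode matrix
    recomputes statistics that are already (0, 1).

    Zero-variance columns raise :class:`ZeroVarianceError` naming the
    column, or are dropped when ``on_zero_variance="drop"``.
    """
    if rows is None:
        rows = np.ones(matrix.n_rows, dtype=bool)
    rows = np.asarray(rows, dtype=bool)
    names = matrix.columns[1:]
    if sp.issparse(matrix.values):
        if matrix.defined is not None:
            raise ValueError("defined masks are not supported for sparse matrices")
        sub = matrix.values[rows]
        n = sub.shape[0]
        mu = np.asarray(sub.mean(axis=0)).ravel()
        sq = np.asarray(sub.multiply(sub).mean(axis=0)).ravel()
        var = sq - mu**2
        sigma = np.sqrt(np.clip(var, 0.0, None))
        keep = _check_zero_variance(sigma, names, on_zero_variance)
        vals = matrix.values[:, keep] if keep.size != sigma.size else matrix.values
        return FeatureMatrix(
            ["intercept"] + [names[i] for i in keep],
            vals,
            mu=mu[keep],
            sigma=sigma[keep],
            mode="affine",
        )
    vals = np.array(matrix.values, dtype=float)
    if matrix.mode == "dense":
        pass  # already-standardized columns re-standardize to themselves
    defined = matrix.defined
    p = vals.shape[1]
    mu = np.zeros(p)
    sigma = np.ones(p)
    out = np.zeros_like(vals)
    for c in range(p):
        dmask = rows if defined is None else (rows & defined[:, c])
        x = vals[dmask, c]
        mu[c] = x.mean() if x.size else 0.0
        sigma[c] = x.std() if x.size else 0.0
        if sigma[c] > 0:
            col_defined = slice(None) if defined is None else defined[:, c]
            if defined is None:
                out[:, c] = (vals[:, c] - mu[c]) / sigma[c]
            else:
                out[defined[:, c], c] = (vals[defined[:, c], c] - mu[c]) / sigma[c]
    keep = _check_zero_variance(sigma, names, on_zero_variance)
    return FeatureMatrix(
        ["intercept"] + [names[i] for i in keep],
        out[:, keep],
        mu=mu[keep],
        sigma=sigma[keep],
        mode="dense",
        defined=defined[:, keep] if defined is not None else None,
    )


def _check_zero_variance(sigma: np.ndarray, names: Sequence[str], policy: str) -> np.ndarray:
    bad = np.where(sigma <= 0)[0]
    if bad.size == 0:
        return np.arange(sigma.size)
    badnames = [names[i] for i in bad]
    if policy == "drop":
        import warnings

        warnings.warn(f"dropping zero-variance feature columns: {badnames}")
        return np.where(sigma > 0)[0]
    raise ZeroVarianceError(f"zero-variance feature columns: {badnames}")


def stack_matrices(matrices: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Vertically stack unstandardized per-gene matrices (same columns)."""
    cols = matrices[0].columns
    if any(m.columns != cols for m in matrices):
        raise ValueError("matrices must share identical columns")
    if any(m.mode != "none" for m in matrices):
        raise ValueError("stack matrices before standardization")
    if any(sp.issparse(m.values) for m in matrices):
        vals = sp.vstack([sp.csr_matrix(m.values) for m in matrices], format="csr")
        return FeatureMatrix(cols, vals)
    vals = np.vstack([m.values for m in matrices])
    defined = None
    if any(m.defined is not None for m in matrices):
        defined = np.vstack(
            [
                m.defined
                if m.defined is not None
                else np.ones((m.n_rows, m.values.shape[1]), bool)
                for m in matrices
            ]
        )
    return FeatureMatrix(cols, vals, defined=defined)
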