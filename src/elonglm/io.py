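"""File formats and configuration.

Signal tracks are read from bedGraph (text) or bigWig; rate predictions
are written as bedGraph with run-length merging of equal adjacent values.
Every output file carries a header comment with the package version, a
hash of the configuration, and the seed, so runs are traceable.
Coordinates are 0-based half-open throughout, matching BED/bedGraph.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__

__all__ = [
    "RunConfig",
    "read_signal",
    "read_bedgraph_region",
    "write_bedgraph",
    "write_rate_track",
    "read_bed",
    "save_fit_result",
    "load_fit_result",
]


class ChromosomeMismatchError(KeyError):
    """Requested region is absent from the signal file."""


@dataclass
class RunConfig:
    """One run's complete configuration; round-trips through YAML."""

    annotations: str | None = None
    signal_3p: str | None = None
    signal_5p: str | None = None
    covariates: dict[str, str] = field(default_factory=dict)
    sequence: str | None = None
    filters: list[dict] = field(default_factory=list)
    k_sizes: list[int] = field(default_factory=lambda: [5])
    anchor_shift: int = 0
    learning_rate: float = 1e-7
    tol: float = 1e-9
    max_iter: int = 50_000
    nu_grid: list[float] | None = None
    seed: int = 0
    simulator: dict = field(default_factory=dict)
    output_dir: str = "."

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def header_comment(seed: int | None = None, config: RunConfig | None = None) -> str:
    parts = [f"elonglm v{__version__}"]
    if config is not None:
        parts.append(f"config={config.digest()}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return "# " + " ".join(parts)


def build_filter_from_config(entry: dict):
    """Build a smoothing filter from a config entry.

    Keys: kind, r, sigma, delta, weights (inline list) or weights_file
    (whitespace-separated text, one value per tap).
    """
    from .features import build_filter

    weights = entry.get("weights")
    if weights is None and entry.get("weights_file"):
        weights = np.loadtxt(entry["weights_file"]).ravel()
    return build_filter(entry["kind"], int(entry["r"]),
                        sigma=entry.get("sigma"),
                        delta=int(entry.get("delta", 0)), weights=weights)


def read_abundance_table(path: str | Path) -> pd.DataFrame:
    """Gene expression table (gene_id, tpm) used for the optional
    expression filter (genes under 10 TPM are dropped when supplied)."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.lower() for c in df.columns]
    if not {"gene_id", "tpm"} <= set(df.columns):
        raise ValueError("abundance table needs gene_id and tpm columns")
    return df


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file (at least chrom/start/end; name/score/strand kept)."""
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = cols[: df.shape[1]]
    return df


def read_bedgraph_region(path: str | Path, chrom: str, start: int, end: int) -> np.ndarray:
    """Per-nucleotide values for [start, end) from a bedGraph file.

    Positions without data are 0.  Overlapping lines resolve last-wins
    (file order), with a warning — the documented dialect rule.
    """
    values = np.zeros(end - start)
    seen = np.zeros(end - start, dtype=bool)
    overlap = False
    found_chrom = False
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            c, a, b, v = line.split()[:4]
            if c != chrom:
                continue
            found_chrom = True
            a, b = int(a), int(b)
            lo, hi = max(a, start), min(b, end)
            if hi <= lo:
                continue
            if seen[lo - start : hi - start].any():
                overlap = True
            values[lo - start : hi - start] = float(v)
            seen[lo - start : hi - start] = True
    if not found_chrom:
        raise ChromosomeMismatchError(f"chromosome {chrom!r} not present in {path}")
    if overlap:
        import warnings

        warnings.warn(f"overlapping bedGraph intervals in {path}: last value wins")
    return values


def read_signal(path: str | Path, chrom: str, start: int, end: int,
                strand: str = "+") -> np.ndarray:
    """Per-nucleotide signal over a region, 5'->3' on the given strand.

    Dispatches on file extension: .bw/.bigwig via pyBigWig, anything else
    as bedGraph text.  Missing data maps to 0; minus-strand regions are
    reversed so index 0 is the transcribed-strand 5' end.
    """
    path = Path(path)
    if path.suffix.lower() in (".bw", ".bigwig"):
        import pyBigWig

        bw = pyBigWig.open(str(path))
        try:
            if chrom not in bw.chroms():
                raise ChromosomeMismatchError(f"chromosome {chrom!r} not in {path}")
            if end > bw.chroms()[chrom]:
                raise ValueError(f"region end {end} beyond contig {chrom}")
            vals = np.nan_to_num(np.array(bw.values(chrom, start, end), dtype=float))
        finally:
            bw.close()
    else:
        vals = read_bedgraph_region(path, chrom, start, end)
    if strand == "-":
        vals = vals[::-1].copy()
    return vals


def write_bedgraph(values: np.ndarray, chrom: str, start: int, path: str | Path,
                   seed: int | None = None, config: RunConfig | None = None,
                   decimals: int = 6) -> None:
    """Write per-nucleotide values as bedGraph, merging runs of equal values."""
    values = np.round(np.asarray(values, dtype=float), decimals)
    with open(path, "w") as fh:
        fh.write(header_comment(seed=seed, config=config) + "\n")
        if values.size == 0:
            return
        boundaries = np.flatnonzero(np.diff(values)) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [values.size]])
        for a, b in zip(starts, ends):
            fh.write(f"{chrom}\t{start + a}\t{start + b}\t{values[a]:g}\n")


def write_rate_track(zeta: np.ndarray, chrom: str, start: int, path: str | Path,
                     seed: int | None = None, config: RunConfig | None = None,
                     bigwig: bool = False, chrom_sizes: dict[str, int] | None = None) -> None:
    """Export predicted local elongation rates as a browser track.

    Always writes bedGraph; with ``bigwig=True`` (and chrom sizes) a
    companion .bw file is written via pyBigWig when available.
    """
    write_bedgraph(zeta, chrom, start, path, seed=seed, config=config)
    if bigwig:
        try:
            import pyBigWig
        except ImportError:  # pragma: no cover - environment-dependent
            import warnings

            warnings.warn("pyBigWig unavailable; bedGraph only")
            return
        if not chrom_sizes:
            raise ValueError("bigWig output requires chrom_sizes")
        bw = pyBigWig.open(str(path) + ".bw", "w")
        bw.addHeader(sorted(chrom_sizes.items()))
        bw.addEntries(chrom, int(start), values=np.asarray(zeta, dtype=float),
                      span=1, step=1)
        bw.close()


def save_fit_result(result, path: str | Path, seed: int | None = None,
                    config: RunConfig | None = None) -> None:
    """Serialize a FitResult as JSON (coefficients, scaling, chi, trace tail)."""
    payload = {
        "header": header_comment(seed=seed, config=config),
        "columns": result.columns,
        "kappa": result.params.kappa.tolist(),
        "kappa_raw": result.kappa_raw.tolist(),
        "mu": None if result.mu is None else result.mu.tolist(),
        "sigma": None if result.sigma is None else result.sigma.tolist(),
        "chi": result.params.chi.tolist(),
        "lambda": result.params.lam,
        "nu": result.params.nu,
        "rho": None if result.params.rho is None else result.params.rho.tolist(),
        "converged": bool(result.converged),
        "n_iter": int(result.n_iter),
        "aic": result.aic,
        "objective_final": float(result.objective_trace[-1]),
        "objective_trace_tail": result.objective_trace[-10:].tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_fit_result(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
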