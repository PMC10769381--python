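"""Turn annotations and raw 3'-end coverage into model-ready gene bodies.

Nascent-RNA read counts within annotated genes are contaminated by
promoter-proximal pausing, internal transcription starts, and a broad
"U-shaped" metagene trend (elevated depth near both gene ends).  The steps
here produce clean gene-body count vectors: TSS refinement from capped
5'-end signal, conservative gene-body definition (2250 bp downstream of
the refined TSS to 250 bp upstream of the TTS, dropping bodies under
6 kb), masking of putative internal TSSs, metagene (U-shape) correction,
and pause-window extraction.

All intervals are 0-based half-open in genomic coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneBodyDefinition",
    "refine_tss",
    "define_gene_body",
    "mask_internal_tss",
    "ushape_correct",
    "pause_windows",
]

BODY_OFFSET_TSS = 2250   # bp downstream of refined TSS; clears all pause peaks
BODY_OFFSET_TTS = 250    # bp upstream of annotated TTS
MIN_BODY_LENGTH = 6000   # shorter gene bodies are dropped
CAP_PEAK_HALFWIDTH = 1000  # masked interval is 2 kb centered on a cap peak
CAP_PEAK_MIN_COUNT = 10    # cap peaks must have read count strictly above this


@dataclass
class GeneBodyDefinition:
    """A gene body selected for analysis, with its mask intervals."""

    gene_id: str
    chrom: str
    strand: str
    refined_tss: int
    tts: int
    body_start: int
    body_end: int
    mask_intervals: list[tuple[int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.body_end - self.body_start

    def analysis_mask(self) -> np.ndarray:
        """Boolean per body position, True where the position is analyzed."""
        mask = np.ones(self.length, dtype=bool)
        for a, b in self.mask_intervals:
            mask[max(a - self.body_start, 0) : max(b - self.body_start, 0)] = False
        return mask


def refine_tss(annotated_tss: int, five_prime_signal: np.ndarray,
               window: int = 1500) -> int:
    """Re-position a TSS at the 5'-end signal maximum within +/- window.

    ``five_prime_signal`` covers [annotated_tss - window,
    annotated_tss + window] inclusive (length 2*window + 1).  Ties are
    broken toward the annotation (and upstream on exact distance ties);
    an all-zero window keeps the annotated TSS with a warning.
    """
    sig = np.asarray(five_prime_signal, dtype=float)
    if sig.size != 2 * window + 1:
        raise ValueError(f"signal must cover the full window (length {2 * window + 1})")
    if sig.max() <= 0:
        warnings.warn("no 5' signal in refinement window; keeping annotated TSS")
        return annotated_tss
    peaks = np.where(sig == sig.max())[0]
    offsets = peaks - window
    best = offsets[np.lexsort((offsets, np.abs(offsets)))][0]
    return annotated_tss + int(best)


def define_gene_body(tss: int, tts: int, strand: str, *,
                     gene_id: str = "", chrom: str = "",
                     min_length: int = MIN_BODY_LENGTH) -> GeneBodyDefinition | None:
    """Apply the gene-body offsets in the direction of transcription.

    Plus strand: [tss + 2250, tts - 250).  Minus strand (tss > tts in
    genomic coordinates): [tts + 250, tss - 2250).  Returns None when the
    resulting body is shorter than ``min_length`` or empty.
    """
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    if strand == "+":
        start, end = tss + BODY_OFFSET_TSS, tts - BODY_OFFSET_TTS
    else:
        start, end = tts + BODY_OFFSET_TTS, tss - BODY_OFFSET_TSS
    if end - start < max(min_length, 1):
        return None
    return GeneBodyDefinition(gene_id=gene_id, chrom=chrom, strand=strand,
                              refined_tss=tss, tts=tts,
                              body_start=start, body_end=end)


def mask_internal_tss(body: GeneBodyDefinition,
                      cap_peaks: list[tuple[int, float]] | None = None,
                      dreg_intervals: list[tuple[int, int]] | None = None,
                      *, use_dreg: bool = True,
                      halfwidth: int = CAP_PEAK_HALFWIDTH,
                      min_count: float = CAP_PEAK_MIN_COUNT) -> list[tuple[int, int]]:
    """Mask plausible internal TSSs inside a gene body.

    The mask is the union of predicted regulatory-element intervals
    (dREG-style; skipped with ``use_dreg=False``) and 2-kb intervals
    centered on capped-5'-end peaks whose read count is strictly greater
    than ``min_count``, intersected with the body.  The intervals are
    stored on the body and returned.
    """
    intervals: list[tuple[int, int]] = []
    if use_dreg and dreg_intervals:
        intervals.extend((int(a), int(b)) for a, b in dreg_intervals)
    for pos, count in cap_peaks or []:
        if count > min_count:
            intervals.append((int(pos) - halfwidth, int(pos) + halfwidth))
    clipped = []
    for a, b in intervals:
        a, b = max(a, body.body_start), min(b, body.body_end)
        if b > a:
            clipped.append((a, b))
    clipped.sort()
    merged: list[tuple[int, int]] = []
    for a, b in clipped:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    body.mask_intervals = merged
    return merged


def ushape_correct(
    counts: list[np.ndarray],
    masks: list[np.ndarray] | None = None,
    n_bins: int = 1000,
    loess_frac: float = 0.3,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Remove the shared metagene trend from gene-body read counts.

    Genes are scaled to a common relative-position grid after dividing each
    gene's counts by its median (mean fallback when the median is zero, as
    it typically is for sparse data); the pooled profile is LOESS-smoothed,
    the curve rescaled to mean height 1, and every raw count divided by the
    curve height at its relative position.  Masked positions contribute to
    neither the medians nor the pooled profile, but are rescaled like their
    neighbors.  Returns (adjusted counts, smoothed curve over n_bins).
    """
    if len(counts) < 10:
        raise ValueError("metagene correction needs at least 10 genes")
    if masks is None:
        masks = [np.ones(x.size, dtype=bool) for x in counts]
    sums = np.zeros(n_bins)
    nobs = np.zeros(n_bins)
    norms = []
    for x, m in zip(counts, masks):
        x = np.asarray(x, dtype=float)
        m = np.asarray(m, dtype=bool)
        used = x[m]
        if used.size == 0:
            norms.append(1.0)
            continue
        med = float(np.median(used))
        if med <= 0:
            med = float(used.mean())
            if med <= 0:
                med = 1.0
            else:
                warnings.warn("gene median count is 0; using mean for normalization")
        norms.append(med)
        pos = np.where(m)[0]
        bins = np.minimum((pos * n_bins) // x.size, n_bins - 1)
        sums += np.bincount(bins, weights=used / med, minlength=n_bins)
        nobs += np.bincount(bins, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        profile = np.where(nobs > 0, sums / np.maximum(nobs, 1), np.nan)
    good = np.isfinite(profile)
    grid = (np.arange(n_bins) + 0.5) / n_bins
    from statsmodels.nonparametric.smoothers_lowess import lowess

    smooth = lowess(profile[good], grid[good], frac=loess_frac, return_sorted=False)
    curve = np.interp(grid, grid[good], smooth)
    curve = np.clip(curve, 1e-6, None)
    curve = curve / curve.mean()  # average height exactly one
    adjusted = []
    for x in counts:
        x = np.asarray(x, dtype=float)
        pos = np.arange(x.size)
        bins = np.minimum((pos * n_bins) // x.size, n_bins - 1)
        adjusted.append(x / curve[bins])
    return adjusted, curve


def pause_windows(counts: np.ndarray, width: int = 200, top: int = 5) -> list[tuple[int, int]]:
    """Top-k fixed-width windows by summed read count.

    The gene body is tiled with non-overlapping ``width``-bp windows from
    position 0 (a trailing partial window is dropped); windows are ranked
    by summed counts, ties broken leftmost.  Returns the (start, end)
    intervals of the top ``top`` windows in rank order — candidate
    gene-body pausing locations.
    """
    counts = np.asarray(counts, dtype=float)
    n_win = counts.size // width
    if n_win == 0:
        raise ValueError("gene body shorter than the window width")
    sums = counts[: n_win * width].reshape(n_win, width).sum(axis=1)
    order = np.lexsort((np.arange(n_win), -sums))
    return [(int(i) * width, (int(i) + 1) * width) for i in order[:top]]
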