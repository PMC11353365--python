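"""The local ancestry information vector (LAIV).

For a haplotype and a window of panel SNPs, the ancestry information for
population k is the moment estimator of the local ancestral proportion

    p_hat_k = (number of population-k-specific alleles observed in the
               window) / (sum of their panel MAFs f_km over the window)

If the haplotype's window descends entirely from population k the numerator
has expectation equal to the denominator, so E[p_hat_k] = 1; under partial
ancestry p the expectation is p.  The estimator involves only allele counts
and MAF sums, so it does not rely on independence between SNPs; windows with
no population-k SNP report p_hat_k = 0 (no evidence) by convention.  Values
may exceed 1 by sampling noise — they are information scores, not
probabilities.

Sliding evaluation centres a window of ``window_size`` base pairs at every
panel SNP on the chromosome (half-width ``window_size // 2`` on each side,
inclusive bounds, truncated at chromosome ends) and is computed with
per-population cumulative sums; :func:`compute_laiv` is the single-window
form used as its reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .panel import SNPPanel

logger = logging.getLogger(__name__)


@dataclass
class LAIV:
    """Ancestry information for one haplotype window.

    ``phat[k]`` is the moment estimate for population k, with its integer
    specific-allele count ``counts[k]`` and MAF-sum denominator
    ``maf_sums[k]``.  ``chrom``/``center`` locate the window ([lo, hi] bp,
    inclusive) when it came from a sliding scan.
    """

    populations: list[str]
    phat: np.ndarray
    counts: np.ndarray
    maf_sums: np.ndarray
    chrom: str | None = None
    center: int | None = None
    lo: int | None = None
    hi: int | None = None

    def __post_init__(self) -> None:
        self.phat = np.asarray(self.phat, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.maf_sums = np.asarray(self.maf_sums, dtype=np.float64)
        K = len(self.populations)
        if not (len(self.phat) == len(self.counts) == len(self.maf_sums) == K):
            raise ValueError("LAIV arrays must all have length K")


def compute_laiv(presence_window: np.ndarray, panel_window: SNPPanel,
                 chrom: str | None = None, center: int | None = None,
                 lo: int | None = None, hi: int | None = None) -> LAIV:
    """Evaluate the LAIV on one window.

    ``presence_window`` is the binary allele-presence vector aligned to
    ``panel_window`` rows.
    """
    presence_window = np.asarray(presence_window)
    if presence_window.ndim != 1 or len(presence_window) != panel_window.M:
        raise ValueError(
            f"presence window length {presence_window.shape} does not match "
            f"panel slice of {panel_window.M} SNPs")
    K = panel_window.K
    counts = np.bincount(panel_window.pop_index,
                         weights=presence_window.astype(np.float64),
                         minlength=K).astype(np.int64)
    maf_sums = np.bincount(panel_window.pop_index, weights=panel_window.maf,
                           minlength=K)
    phat = np.divide(counts, maf_sums, out=np.zeros(K, dtype=np.float64),
                     where=maf_sums > 0)
    return LAIV(populations=list(panel_window.populations), phat=phat,
                counts=counts, maf_sums=maf_sums, chrom=chrom, center=center,
                lo=lo, hi=hi)


def sliding_window_stats(presence_row: np.ndarray, panel: SNPPanel,
                         window_size: int):
    """Window statistics at every panel SNP, vectorised.

    Returns ``(counts, maf_sums, phat, lo, hi)`` where the first three have
    shape ``(M, K)`` and ``lo``/``hi`` are the inclusive bp window bounds per
    centre.  Windows never cross chromosome boundaries.  Counts are exact
    integers; denominators come from float64 cumulative sums (window sums of
    at most a few thousand terms, so round-off is far below 1e-9 relative).
    """
    presence_row = np.asarray(presence_row, dtype=np.int64)
    if presence_row.shape != (panel.M,):
        raise ValueError("presence row does not match panel size")
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    K = panel.K
    half = window_size // 2
    counts = np.zeros((panel.M, K), dtype=np.int64)
    maf_sums = np.zeros((panel.M, K), dtype=np.float64)
    lo = np.zeros(panel.M, dtype=np.int64)
    hi = np.zeros(panel.M, dtype=np.int64)
    onehot_cache = np.eye(K, dtype=np.int64)
    for chrom in panel.chromosomes():
        sl = panel.chrom_slice(chrom)
        pos = panel.pos[sl]
        pres = presence_row[sl]
        popk = panel.pop_index[sl]
        w = onehot_cache[popk]                      # (m, K)
        cum_x = np.vstack([np.zeros((1, K), dtype=np.int64),
                           np.cumsum(pres[:, None] * w, axis=0)])
        cum_f = np.vstack([np.zeros((1, K)),
                           np.cumsum(panel.maf[sl][:, None] * w, axis=0)])
        lo_b = pos - half
        hi_b = pos + half
        i0 = np.searchsorted(pos, lo_b, side="left")
        i1 = np.searchsorted(pos, hi_b, side="right")
        counts[sl] = cum_x[i1] - cum_x[i0]
        maf_sums[sl] = cum_f[i1] - cum_f[i0]
        lo[sl] = np.maximum(lo_b, 1)
        hi[sl] = hi_b
    phat = np.divide(counts, maf_sums, out=np.zeros_like(maf_sums),
                     where=maf_sums > 0)
    return counts, maf_sums, phat, lo, hi


def sliding_laivs(presence_row: np.ndarray, panel: SNPPanel,
                  window_size: int = 2_000_000) -> list[LAIV]:
    """One LAIV per panel SNP for a single haplotype, in panel order."""
    if panel.M == 0:
        logger.info("empty panel: no sliding LAIVs to compute")
        return []
    counts, maf_sums, phat, lo, hi = sliding_window_stats(
        presence_row, panel, window_size)
    pops = list(panel.populations)
    return [LAIV(populations=pops, phat=phat[m], counts=counts[m],
                 maf_sums=maf_sums[m], chrom=panel.chrom[m],
                 center=int(panel.pos[m]), lo=int(lo[m]), hi=int(hi[m]))
            for m in range(panel.M)]
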