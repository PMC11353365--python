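"""Per-haplotype presence encoding of panel-specific alleles.

For each phased sample and each panel SNP, record whether each of the two
haplotypes carries the panel's population-specific allele (the binary
haplotype matrix X).  Phase is required: the method estimates ancestry per
haploid genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

from .panel import SNPPanel

logger = logging.getLogger(__name__)


class PhaseError(ValueError):
    """An unphased genotype was found at a panel site."""


class AlleleMismatchError(ValueError):
    """VCF alleles at a matched position do not include the panel allele."""


@dataclass
class PresenceMatrix:
    """Binary indicators X[n, h, m] of population-specific alleles.

    Shape ``(n_samples, 2, M)`` aligned to ``panel`` row order (sorted by
    chromosome then position).  Haplotype indices are reported 1-based
    (1, 2) in all outputs.
    """

    sample_ids: list[str]
    X: np.ndarray
    panel: SNPPanel

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.uint8)
        if self.X.ndim != 3 or self.X.shape[1] != 2:
            raise ValueError("X must have shape (n_samples, 2, M)")
        if self.X.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids do not match X rows")
        if self.X.shape[2] != self.panel.M:
            raise ValueError("X columns do not match panel size")
        if self.X.size and self.X.max() > 1:
            raise ValueError("X must be binary")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return 2 * self.n_samples

    def haplotypes(self) -> Iterator[tuple[str, int, np.ndarray]]:
        """Yield (sample_id, haplotype 1/2, presence row over panel SNPs)."""
        for i, sid in enumerate(self.sample_ids):
            for h in (1, 2):
                yield sid, h, self.X[i, h - 1]

    def restrict(self, subpanel: SNPPanel) -> "PresenceMatrix":
        """Presence matrix over a sub-panel (matched by chrom, pos).

        Every sub-panel SNP must exist in this matrix's panel.
        """
        index = {(c, int(p)): i
                 for i, (c, p) in enumerate(zip(self.panel.chrom, self.panel.pos))}
        try:
            cols = np.array([index[(c, int(p))]
                             for c, p in zip(subpanel.chrom, subpanel.pos)],
                            dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"sub-panel SNP not present in matrix panel: {exc}")
        return PresenceMatrix(sample_ids=list(self.sample_ids),
                              X=self.X[:, :, cols], panel=subpanel)


def load_phased_haplotypes(vcf_path: str | Path, panel: SNPPanel) -> PresenceMatrix:
    """Encode panel-allele presence per haplotype from a phased VCF.

    Panel SNPs are matched by (chromosome, position); the VCF record's REF or
    one of its ALT alleles must equal the panel's specific allele, otherwise
    an :class:`AlleleMismatchError` is raised.  Panel SNPs absent from the
    VCF are kept as all-zero columns with a warning (their MAFs still count
    in estimator denominators).  Unphased genotypes at panel sites raise
    :class:`PhaseError`.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    n = len(samples)
    X = np.zeros((n, 2, panel.M), dtype=np.uint8)
    index = {(c, int(p)): i
             for i, (c, p) in enumerate(zip(panel.chrom, panel.pos))}
    matched = np.zeros(panel.M, dtype=bool)
    n_missing_calls = 0
    for v in vcf:
        key = (v.CHROM, int(v.POS))
        m = index.get(key)
        if m is None:
            continue
        spec = panel.allele[m]
        if spec == v.REF:
            code = 0
        elif spec in (v.ALT or []):
            code = list(v.ALT).index(spec) + 1
        else:
            raise AlleleMismatchError(
                f"{v.CHROM}:{v.POS}: VCF alleles {v.REF}/{v.ALT} do not include "
                f"panel allele {spec}")
        g = np.asarray(v.genotypes, dtype=np.int64)
        if g.shape != (n, 3):
            raise PhaseError(f"{v.CHROM}:{v.POS}: expected diploid genotypes")
        missing = (g[:, 0] < 0) | (g[:, 1] < 0)
        if missing.any():
            n_missing_calls += int(missing.sum())
        unphased = (g[:, 2] == 0) & ~missing
        if unphased.any():
            bad = samples[int(np.flatnonzero(unphased)[0])]
            raise PhaseError(
                f"{v.CHROM}:{v.POS}: unphased genotype for sample {bad}; "
                "phased input is required for per-haplotype inference")
        X[:, 0, m] = (g[:, 0] == code)
        X[:, 1, m] = (g[:, 1] == code)
        matched[m] = True
    n_unmatched = int((~matched).sum())
    if n_unmatched:
        logger.warning(
            "%d of %d panel SNPs absent from %s; treated as allele-absent "
            "(all-zero columns)", n_unmatched, panel.M, vcf_path)
    if n_missing_calls:
        logger.warning("%d missing genotype calls at panel sites treated as "
                       "allele-absent", n_missing_calls)
    return PresenceMatrix(sample_ids=samples, X=X, panel=panel)
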