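"""VCF and sample-map ingestion/export.

Reading goes through cyvcf2 (htslib), so plain and bgzipped VCFs both work.
Writing targets plain-text VCF 4.2 with ``##contig`` length headers, which
is all the simulator needs to round-trip through the inference CLI.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np

from .haplotypes import PresenceMatrix
from .panel import ReferenceCohort

logger = logging.getLogger(__name__)


def read_pop_map(path: str | Path) -> dict[str, str]:
    """Two-column (sample, population) TSV without header."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected "
                                 "'sample<TAB>population'")
            if parts[0] in out:
                raise ValueError(f"{path}: line {lineno}: duplicate sample "
                                 f"{parts[0]!r}")
            out[parts[0]] = parts[1]
    return out


def read_reference_cohort(vcf_path: str | Path,
                          sample_to_pop: Mapping[str, str]) -> ReferenceCohort:
    """Load reference genotypes for screening.

    Populations are ordered by first appearance in the sample map.  SNPs
    with missing genotypes are dropped (counted in a warning); records that
    are not diallelic SNPs are skipped with a warning.  Phase is ignored:
    only allele dosages matter for screening.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    missing_samples = [s for s in samples if s not in sample_to_pop]
    if missing_samples:
        raise ValueError(f"samples absent from population map: "
                         f"{missing_samples[:5]}...")
    populations: list[str] = []
    for s in sample_to_pop:
        if sample_to_pop[s] not in populations:
            populations.append(sample_to_pop[s])
    pop_to_idx = {p: i for i, p in enumerate(populations)}
    sample_pop = np.array([pop_to_idx[sample_to_pop[s]] for s in samples],
                          dtype=np.int64)

    chroms, poss, refs, alts, genos = [], [], [], [], []
    n_skipped = n_missing = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        g = np.asarray(v.genotypes, dtype=np.int64)
        if (g[:, :2] < 0).any():
            n_missing += 1
            continue
        chroms.append(v.CHROM)
        poss.append(int(v.POS))
        refs.append(v.REF)
        alts.append(v.ALT[0])
        genos.append(g[:, :2].sum(axis=1).astype(np.int8))
    if n_skipped:
        logger.warning("skipped %d non-diallelic-SNP records", n_skipped)
    if n_missing:
        logger.warning("dropped %d SNPs with missing genotypes", n_missing)
    geno = (np.vstack(genos) if genos
            else np.zeros((0, len(samples)), dtype=np.int8))
    return ReferenceCohort(
        populations=populations,
        sample_ids=samples,
        sample_pop=sample_pop,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        genotypes=geno,
    )


def read_chrom_lengths(vcf_path: str | Path) -> dict[str, int]:
    """Chromosome lengths from ``##contig`` VCF headers (may be empty)."""
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    out: dict[str, int] = {}
    try:
        for name, length in zip(vcf.seqnames, vcf.seqlens):
            out[name] = int(length)
    except AttributeError:       # header has contigs without lengths
        pass
    return out


def _vcf_header(chrom_lengths: Mapping[str, int], sample_ids) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=laikit"]
    for chrom, length in chrom_lengths.items():
        lines.append(f"##contig=<ID={chrom},length={int(length)}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids))
    return "\n".join(lines) + "\n"


def write_reference_vcf(cohort: ReferenceCohort,
                        chrom_lengths: Mapping[str, int],
                        path: str | Path) -> Path:
    """Write a reference cohort as unphased plain-text VCF."""
    path = Path(path)
    gt_strings = np.array(["0/0", "0/1", "1/1"], dtype=object)
    with open(path, "w") as fh:
        fh.write(_vcf_header(chrom_lengths, cohort.sample_ids))
        for i in range(cohort.n_snps):
            row = gt_strings[cohort.genotypes[i]]
            fh.write(f"{cohort.chrom[i]}\t{cohort.pos[i]}\t.\t{cohort.ref[i]}"
                     f"\t{cohort.alt[i]}\t.\tPASS\t.\tGT\t"
                     + "\t".join(row) + "\n")
    return path


def write_admixed_vcf(presence: PresenceMatrix,
                      chrom_lengths: Mapping[str, int],
                      path: str | Path,
                      ref_allele: str = "A") -> Path:
    """Write admixed haplotypes as a phased VCF over the panel sites.

    The panel's specific allele is emitted as ALT (REF defaults to ``A``,
    or ``C`` when the specific allele is itself ``A``).
    """
    path = Path(path)
    panel = presence.panel
    with open(path, "w") as fh:
        fh.write(_vcf_header(chrom_lengths, presence.sample_ids))
        for m in range(panel.M):
            alt = panel.allele[m]
            ref = ref_allele if alt != ref_allele else "C"
            gts = [f"{presence.X[i, 0, m]}|{presence.X[i, 1, m]}"
                   for i in range(presence.n_samples)]
            fh.write(f"{panel.chrom[m]}\t{panel.pos[m]}\t.\t{ref}\t{alt}"
                     f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")
    return path
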