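"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive per-SNP / per-bp loops so they share no
code path with the vectorised implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from laikit.caller import UNCALLED, AncestrySegment
from laikit.panel import ReferenceCohort, SNPPanel


# -- cohort/panel builders ---------------------------------------------------

def make_cohort(populations, pop_sizes, snps):
    """Build a ReferenceCohort from per-SNP per-population ALT copy counts.

    ``snps`` is a list of dicts with keys chrom, pos, ref, alt,
    alt_copies (tuple of ALT copies per population).  Copies are laid out
    deterministically across samples (2,2,...,1,0,...), which fixes counts
    exactly.
    """
    pop_sizes = list(pop_sizes)
    sample_pop = np.repeat(np.arange(len(populations)), pop_sizes)
    n_samples = int(sample_pop.size)
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    geno = np.zeros((len(snps), n_samples), dtype=np.int8)
    for i, snp in enumerate(snps):
        for k, copies in enumerate(snp["alt_copies"]):
            cols = np.flatnonzero(sample_pop == k)
            full, rem = divmod(copies, 2)
            assert full + (1 if rem else 0) <= len(cols)
            geno[i, cols[:full]] = 2
            if rem:
                geno[i, cols[full]] = 1
    return ReferenceCohort(
        populations=list(populations),
        sample_ids=sample_ids,
        sample_pop=sample_pop,
        chrom=[s["chrom"] for s in snps],
        pos=[s["pos"] for s in snps],
        ref=[s.get("ref", "A") for s in snps],
        alt=[s.get("alt", "G") for s in snps],
        genotypes=geno,
    )


def make_panel(populations, rows):
    """Panel from (chrom, pos, pop_label, allele, maf, count) tuples."""
    pop_to_idx = {p: i for i, p in enumerate(populations)}
    return SNPPanel(
        populations=list(populations),
        chrom=[r[0] for r in rows],
        pos=[r[1] for r in rows],
        pop_index=[pop_to_idx[r[2]] for r in rows],
        allele=[r[3] for r in rows],
        maf=[r[4] for r in rows],
        count=[r[5] for r in rows],
    )


def random_panel(rng, n_snps, K=3, length=10_000_000, chrom="1"):
    pos = np.sort(rng.choice(np.arange(1, length + 1), size=n_snps,
                             replace=False))
    return SNPPanel(
        populations=[f"P{k}" for k in range(K)],
        chrom=np.full(n_snps, chrom, dtype=object),
        pos=pos,
        pop_index=rng.integers(0, K, size=n_snps),
        allele=np.full(n_snps, "G", dtype=object),
        maf=rng.uniform(0.01, 0.5, size=n_snps),
        count=np.full(n_snps, 5),
    )


# -- oracles -----------------------------------------------------------------

def screen_oracle(cohort, min_copies):
    """Per-SNP, per-population, per-allele loop re-statement of screening."""
    sizes = cohort.pop_sizes
    hits = []
    for i in range(cohort.n_snps):
        for allele_name in ("alt", "ref"):
            copies_by_pop = []
            for k in range(cohort.K):
                cols = np.flatnonzero(cohort.sample_pop == k)
                alt_copies = sum(int(cohort.genotypes[i, c]) for c in cols)
                copies_by_pop.append(alt_copies if allele_name == "alt"
                                     else 2 * len(cols) - alt_copies)
            carriers = [k for k, c in enumerate(copies_by_pop) if c > 0]
            if len(carriers) != 1:
                continue
            k = carriers[0]
            copies = copies_by_pop[k]
            freq = copies / (2 * sizes[k])
            if copies >= min_copies and freq <= 0.5:
                allele = cohort.alt[i] if allele_name == "alt" else cohort.ref[i]
                hits.append((str(cohort.chrom[i]), int(cohort.pos[i]), k,
                             str(allele), freq, copies))
    return sorted(hits)


def panel_rows(panel):
    return sorted((str(panel.chrom[i]), int(panel.pos[i]),
                   int(panel.pop_index[i]), str(panel.allele[i]),
                   float(panel.maf[i]), int(panel.count[i]))
                  for i in range(panel.M))


def laiv_oracle(presence, panel, center, window_size):
    """Naive per-SNP loop evaluation of one window's ancestry information."""
    half = window_size // 2
    K = panel.K
    counts = [0] * K
    denoms = [0.0] * K
    for m in range(panel.M):
        if center - half <= panel.pos[m] <= center + half:
            k = int(panel.pop_index[m])
            counts[k] += int(presence[m])
            denoms[k] += float(panel.maf[m])
    phat = [c / d if d > 0 else 0.0 for c, d in zip(counts, denoms)]
    return np.array(counts), np.array(denoms), np.array(phat)


def paint_oracle(calls, length):
    """Per-bp painting of segments_from_calls semantics.

    ``calls`` is a list of (pos, label); returns an object array of length
    ``length`` with one label per bp (0-based).
    """
    paint = np.empty(length, dtype=object)
    if not calls:
        paint[:] = UNCALLED
        return paint
    calls = sorted(calls)
    pos = [p for p, _ in calls]
    labs = [l for _, l in calls]
    paint[: pos[0] - 1] = labs[0]
    for i, (p, l) in enumerate(calls):
        paint[p - 1] = l
        if i + 1 < len(calls):
            fill = l if labs[i + 1] == l else UNCALLED
            paint[p: pos[i + 1] - 1] = fill
    paint[pos[-1]:] = labs[-1]
    return paint


def segments_to_paint(segments, length):
    paint = np.empty(length, dtype=object)
    for s in segments:
        paint[s.start: s.end] = s.label
    assert not (paint == None).any()  # noqa: E711 - tiling check
    return paint


@pytest.fixture
def rng():
    return np.random.default_rng(20240821)
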