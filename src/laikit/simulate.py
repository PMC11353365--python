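"""Synthetic reference cohorts and admixed haplotype mosaics.

The generator emulates the data regime the method is built for: K reference
populations each carrying a private set of diallelic SNPs whose minor allele
segregates in that population only, and admixed haplotypes formed as
recombination mosaics of those populations.

Reference haplotypes draw each population-private allele independently as
Bernoulli(f) with the SNP's designed frequency f — the independence model
underlying the moment estimator — so reference cohorts have no background
LD.  Admixed haplotypes place recombination breakpoints as a Poisson process
of intensity ``generations x recomb_rate`` per bp (the expected breakpoint
density after g generations under a uniform genetic map) and draw each
tract's ancestry independently from the admixture proportions (a pool
model: the simplest process with the right marginal proportions and
1/(g·r) mean tract length; no Markov self-transition structure).

An optional misclassification model plants, for a fraction ``epsilon`` of
panel SNPs, a hidden low-frequency allele (default 0.005) in one random
other population — the screening artefact caused by finite reference
samples — so the caller's ``allele_min`` guard can be exercised.

All randomness flows from ``config.seed`` through three fixed-purpose
substreams (panel design, reference genotypes, admixed haplotypes), so each
output is independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._intervals import group_segments, overlay
from .caller import UNCALLED, AncestrySegment
from .haplotypes import PresenceMatrix
from .panel import ConfigurationError, ReferenceCohort, SNPPanel

logger = logging.getLogger(__name__)

_REF_ALLELE = "A"
_SPEC_ALLELE = "G"


def _broadcast(value, K: int, name: str) -> tuple:
    seq = tuple(value) if isinstance(value, (list, tuple, np.ndarray)) else (value,) * K
    if len(seq) != K:
        raise ConfigurationError(f"{name} must have length K={K}, got {len(seq)}")
    return seq


@dataclass
class SimulationConfig:
    """Study conditions for one simulated admixture experiment.

    Defaults describe a two-way admixture typical of the validation setting:
    a 100 Mbp chromosome, one designed population-specific SNP per 10 kbp
    per population with MAF ~ U(0.05, 0.5), reference panels of 100 diploids
    per population, 50 admixed diploids with proportions (0.7, 0.3) mixed 10
    generations ago at a uniform 1e-8 Morgan/bp recombination rate, and no
    panel misclassification.
    """

    populations: tuple[str, ...] = ("POP1", "POP2")
    ref_sizes: tuple[int, ...] | int = 100          # diploids per population
    n_admixed: int = 50                              # admixed diploid samples
    chrom: str = "1"
    chrom_length: int = 100_000_000                  # bp
    snp_density: tuple[float, ...] | float = 1e-4    # specific SNPs per bp per pop
    maf_range: tuple[float, float] = (0.05, 0.5)
    proportions: tuple[float, ...] = (0.7, 0.3)      # admixture simplex
    generations: float = 10.0                        # generations since admixture
    recomb_rate: float = 1e-8                        # Morgans per bp
    epsilon: float = 0.0                             # misclassified panel fraction
    epsilon_freq: float = 0.005                      # hidden allele frequency
    seed: int = 0

    def __post_init__(self) -> None:
        self.populations = tuple(self.populations)
        K = self.K
        if K < 2:
            raise ConfigurationError("need at least two reference populations")
        self.ref_sizes = tuple(int(v) for v in _broadcast(self.ref_sizes, K, "ref_sizes"))
        self.snp_density = tuple(float(v) for v in
                                 _broadcast(self.snp_density, K, "snp_density"))
        self.proportions = tuple(float(v) for v in
                                 _broadcast(self.proportions, K, "proportions"))
        if any(s < 1 for s in self.ref_sizes):
            raise ConfigurationError("ref_sizes must be >= 1")
        if any(d <= 0 for d in self.snp_density):
            raise ConfigurationError("snp_density must be > 0")
        if abs(sum(self.proportions) - 1.0) > 1e-9 or any(p < 0 for p in self.proportions):
            raise ConfigurationError("proportions must be a simplex over K")
        if self.generations < 1:
            raise ConfigurationError("generations must be >= 1")
        if not (0 <= self.epsilon < 1):
            raise ConfigurationError("epsilon must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.chrom_length < 1 or self.n_admixed < 1:
            raise ConfigurationError("chrom_length and n_admixed must be >= 1")

    @property
    def K(self) -> int:
        return len(self.populations)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def _streams(self) -> list[np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(3)
        return [np.random.default_rng(c) for c in children]


@dataclass
class TruthTracts:
    """Ground-truth ancestry mosaic per simulated haplotype.

    ``tracts[(sample, hap)] = (bounds, labels)`` with 0-based bp bounds of
    length t+1 tiling [0, chrom_length) and per-tract population labels.
    Adjacent tracts may share a label (breakpoints are kept as drawn).
    """

    chrom: str
    chrom_length: int
    tracts: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]]

    def to_segments(self) -> list[AncestrySegment]:
        out = []
        for (sample, hap), (bounds, labels) in self.tracts.items():
            # merge equal-label runs so segment invariants hold
            keep = np.concatenate([[True], labels[1:] != labels[:-1]])
            idx = np.flatnonzero(keep)
            starts = bounds[:-1][idx]
            ends = np.append(bounds[1:][idx[1:] - 1], bounds[-1])
            for s, e, l in zip(starts, ends, labels[idx]):
                out.append(AncestrySegment(self.chrom, int(s), int(e),
                                           sample, hap, str(l)))
        return out


def _draw_unique_positions(rng: np.random.Generator, length: int,
                           n: int) -> np.ndarray:
    """n distinct 1-based positions on [1, length]."""
    if n > length:
        raise ConfigurationError("more SNPs requested than base pairs")
    pos = np.unique(rng.integers(1, length + 1, size=n))
    while len(pos) < n:
        extra = rng.integers(1, length + 1, size=n - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return pos


def design_panel(config: SimulationConfig,
                 rng: np.random.Generator) -> SNPPanel:
    """Draw the designed population-specific SNP map for one chromosome."""
    K = config.K
    n_per_pop = rng.poisson(np.array(config.snp_density) * config.chrom_length)
    if (n_per_pop == 0).any():
        bad = [p for p, n in zip(config.populations, n_per_pop) if n == 0]
        raise ConfigurationError(
            f"populations {bad} received zero specific SNPs; increase "
            "chrom_length or snp_density")
    total = int(n_per_pop.sum())
    pos = _draw_unique_positions(rng, config.chrom_length, total)
    pop_index = rng.permutation(np.repeat(np.arange(K), n_per_pop))
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=total)
    mis = rng.random(total) < config.epsilon
    hidden_pop = np.full(total, -1, dtype=np.int64)
    if mis.any():
        offsets = rng.integers(1, K, size=int(mis.sum()))
        hidden_pop[mis] = (pop_index[mis] + offsets) % K
    hidden_freq = np.where(hidden_pop >= 0, config.epsilon_freq, 0.0)
    return SNPPanel(
        populations=list(config.populations),
        chrom=np.full(total, config.chrom, dtype=object),
        pos=pos,
        pop_index=pop_index,
        allele=np.full(total, _SPEC_ALLELE, dtype=object),
        maf=maf,
        count=np.zeros(total, dtype=np.int64),
        hidden_pop=hidden_pop,
        hidden_freq=hidden_freq,
    )


def simulate_reference(config: SimulationConfig
                       ) -> tuple[ReferenceCohort, SNPPanel]:
    """Simulate reference-population genotypes and the designed SNP panel.

    Each designed SNP's specific (ALT) allele segregates at its designed
    frequency in its own population, is absent elsewhere — except for the
    ``epsilon`` fraction carrying a hidden 0.005-frequency allele in one
    other population — and the returned panel records the designed
    frequencies together with the copy counts realised in the cohort.
    """
    rng_design, rng_geno, _ = config._streams()
    panel = design_panel(config, rng_design)
    M = panel.M
    sizes = np.array(config.ref_sizes)
    n_samples = int(sizes.sum())
    sample_pop = np.repeat(np.arange(config.K), sizes)
    sample_ids = [f"{config.populations[k]}_{i:04d}"
                  for k in range(config.K)
                  for i in range(sizes[k])]
    # per-(SNP, sample) ALT probability: designed f in the specific
    # population, hidden_freq in the hidden population, 0 elsewhere
    prob = np.zeros((M, n_samples))
    for k in range(config.K):
        cols = sample_pop == k
        rows = panel.pop_index == k
        prob[np.ix_(rows, cols)] = panel.maf[rows, None]
        if panel.hidden_pop is not None:
            hrows = panel.hidden_pop == k
            if hrows.any():
                prob[np.ix_(hrows, cols)] = panel.hidden_freq[hrows, None]
    genotypes = rng_geno.binomial(2, prob).astype(np.int8)
    cohort = ReferenceCohort(
        populations=list(config.populations),
        sample_ids=sample_ids,
        sample_pop=sample_pop,
        chrom=panel.chrom.copy(),
        pos=panel.pos.copy(),
        ref=np.full(M, _REF_ALLELE, dtype=object),
        alt=panel.allele.copy(),
        genotypes=genotypes,
    )
    # realised specific-allele copy counts in the specific population
    alt_c = cohort.alt_counts()
    panel.count = alt_c[np.arange(M), panel.pop_index]
    return cohort, panel


def simulate_admixed(config: SimulationConfig, panel: SNPPanel
                     ) -> tuple[PresenceMatrix, TruthTracts]:
    """Simulate admixed haplotypes as ancestry mosaics over ``panel``.

    Breakpoint counts per haplotype are Poisson with mean
    ``generations * recomb_rate * chrom_length``; tract ancestries are iid
    draws from the admixture proportions.  At each panel SNP the specific
    allele is present with probability f if the covering tract has the
    SNP's population, with the hidden frequency if the tract has a
    misclassified SNP's hidden population, and 0 otherwise.
    """
    _, _, rng = config._streams()
    L = config.chrom_length
    M = panel.M
    K = config.K
    pops = np.array(config.populations, dtype=object)
    intensity = config.generations * config.recomb_rate * L
    sample_ids = [f"ADM_{i:04d}" for i in range(config.n_admixed)]
    X = np.zeros((config.n_admixed, 2, M), dtype=np.uint8)
    tracts: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}
    pos0 = panel.pos - 1            # 0-based coordinates of panel SNPs
    for i, sid in enumerate(sample_ids):
        for h in (1, 2):
            nb = rng.poisson(intensity)
            bp = np.sort(rng.integers(1, L, size=nb)) if nb else \
                np.empty(0, dtype=np.int64)
            bp = np.unique(bp)
            labels_idx = rng.choice(K, size=len(bp) + 1, p=config.proportions)
            bounds = np.concatenate([[0], bp, [L]]).astype(np.int64)
            tracts[(sid, h)] = (bounds, pops[labels_idx])
            anc = labels_idx[np.searchsorted(bp, pos0, side="right")]
            p = np.where(anc == panel.pop_index, panel.maf, 0.0)
            if panel.hidden_pop is not None:
                hidden = (panel.hidden_pop >= 0) & (anc == panel.hidden_pop)
                p = np.where(hidden, panel.hidden_freq, p)
            X[i, h - 1] = rng.random(M) < p
    presence = PresenceMatrix(sample_ids=sample_ids, X=X, panel=panel)
    truth = TruthTracts(chrom=config.chrom, chrom_length=L, tracts=tracts)
    return presence, truth


@dataclass
class RecoveryResult:
    """Base-pair accuracy of inferred segments against truth tracts."""

    per_haplotype: pd.DataFrame   # sample, haplotype, correct, wrong, uncalled
    correct: float                # cohort means (fractions of bp)
    wrong: float
    uncalled: float
    by_ancestry: pd.DataFrame     # per true ancestry, bp-weighted fractions

    def __repr__(self) -> str:
        return (f"RecoveryResult(correct={self.correct:.4f}, "
                f"wrong={self.wrong:.4f}, uncalled={self.uncalled:.4f}, "
                f"n_haplotypes={len(self.per_haplotype)})")


def evaluate_recovery(segments: Iterable[AncestrySegment],
                      truth: TruthTracts) -> RecoveryResult:
    """Score called segments against the simulator's truth tracts.

    Per haplotype, the chromosome's bp are partitioned into called-and-
    correct, called-and-wrong, and uncalled fractions (summing to 1).
    ``by_ancestry`` reports the same fractions within the bp that truly
    descend from each population, aggregated over the cohort.
    """
    grouped = group_segments(segments)
    truth_keys = set(truth.tracts)
    if set(grouped) != truth_keys:
        raise ValueError(
            f"haplotype sets differ between segments and truth: "
            f"{sorted(set(grouped) ^ truth_keys)}")
    rows = []
    anc_bp: dict[str, np.ndarray] = {}
    for key in sorted(grouped):
        if list(grouped[key]) != [truth.chrom]:
            raise ValueError(f"haplotype {key}: expected chromosome "
                             f"{truth.chrom!r} only")
        bounds, labels = truth.tracts[key]
        lengths, called, true_lab = overlay(grouped[key][truth.chrom],
                                            (bounds, labels))
        unc = called == UNCALLED
        correct = ~unc & (called == true_lab)
        wrong = ~unc & ~correct
        total = int(lengths.sum())
        rows.append({
            "sample": key[0], "haplotype": key[1],
            "correct": float(lengths[correct].sum() / total),
            "wrong": float(lengths[wrong].sum() / total),
            "uncalled": float(lengths[unc].sum() / total),
        })
        for lab in np.unique(true_lab):
            sel = true_lab == lab
            acc = anc_bp.setdefault(str(lab), np.zeros(3, dtype=np.int64))
            acc[0] += int(lengths[sel & correct].sum())
            acc[1] += int(lengths[sel & wrong].sum())
            acc[2] += int(lengths[sel & unc].sum())
    df = pd.DataFrame(rows)
    by_anc = pd.DataFrame([
        {"population": lab,
         "correct": bp[0] / bp.sum(), "wrong": bp[1] / bp.sum(),
         "uncalled": bp[2] / bp.sum(), "total_bp": int(bp.sum())}
        for lab, bp in sorted(anc_bp.items())])
    return RecoveryResult(
        per_haplotype=df,
        correct=float(df["correct"].mean()),
        wrong=float(df["wrong"].mean()),
        uncalled=float(df["uncalled"].mean()),
        by_ancestry=by_anc,
    )
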