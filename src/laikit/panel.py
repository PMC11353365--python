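"""Population-specific SNP screening and the SNP panel container.

A diallelic SNP is *specific* to reference population ``k`` when one of its
alleles

* is carried at least ``min_copies`` times in population ``k``,
* has zero copies in every other reference population, and
* is the minor allele within population ``k`` (frequency <= 0.5 there;
  a frequency of exactly 0.5 is allowed).

The retained allele's frequency in its population, ``f_km = copies /
(2 * diploid sample size)``, is the panel MAF used downstream as the
denominator weight of the ancestry-information estimator.  Screening is
performed independently per contig and considers *both* alleles of every
SNP, since either the REF or the ALT allele may be the population-specific
minor allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

PANEL_COLUMNS = ("chrom", "pos", "specific_pop", "specific_allele", "maf", "count")


class ConfigurationError(ValueError):
    """The inputs cannot define a valid screening/simulation problem."""


class PanelFormatError(ValueError):
    """A panel (or segment) file violates its format contract."""


def _as_str_array(values) -> np.ndarray:
    return np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                      dtype=object)


@dataclass
class ReferenceCohort:
    """Diallelic genotypes of K reference populations.

    ``genotypes`` holds ALT-allele dosages (0/1/2) with shape
    ``(n_snps, n_samples)``; no missing values are allowed (SNPs with
    missingness are dropped at load time).  ``sample_pop`` maps each sample
    column to an index into ``populations``.
    """

    populations: list[str]
    sample_ids: list[str]
    sample_pop: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.sample_pop = np.asarray(self.sample_pop, dtype=np.int64)
        self.chrom = _as_str_array(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = _as_str_array(self.ref)
        self.alt = _as_str_array(self.alt)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n_snps, n_samples = self.genotypes.shape
        if len(self.sample_ids) != n_samples or len(self.sample_pop) != n_samples:
            raise ValueError("sample metadata does not match genotype columns")
        for arr in (self.chrom, self.pos, self.ref, self.alt):
            if len(arr) != n_snps:
                raise ValueError("per-SNP arrays do not match genotype rows")
        if self.sample_pop.size and (self.sample_pop.min() < 0
                                     or self.sample_pop.max() >= len(self.populations)):
            raise ValueError("sample_pop indices out of range")

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    @property
    def K(self) -> int:
        return len(self.populations)

    @property
    def pop_sizes(self) -> np.ndarray:
        """Diploid sample count per population."""
        return np.bincount(self.sample_pop, minlength=self.K)

    def alt_counts(self) -> np.ndarray:
        """ALT-allele copy counts per SNP and population, shape (n_snps, K)."""
        out = np.zeros((self.n_snps, self.K), dtype=np.int64)
        geno = self.genotypes.astype(np.int64)
        for k in range(self.K):
            cols = np.flatnonzero(self.sample_pop == k)
            if cols.size:
                out[:, k] = geno[:, cols].sum(axis=1)
        return out

    def restrict_to(self, mask: np.ndarray) -> "ReferenceCohort":
        """Cohort limited to the SNP rows selected by ``mask``."""
        return ReferenceCohort(
            populations=list(self.populations),
            sample_ids=list(self.sample_ids),
            sample_pop=self.sample_pop.copy(),
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            genotypes=self.genotypes[mask],
        )


@dataclass
class SNPPanel:
    """An ordered panel of population-specific SNPs.

    Rows are sorted by (chrom, pos) and unique on that key.  ``pop_index``
    assigns each SNP to the single population its minor allele is specific
    to; ``theta(k)`` returns the row indices of population ``k``'s SNPs.

    ``hidden_pop`` / ``hidden_freq`` are simulation-only annotations marking
    panel SNPs that are secretly polymorphic at low frequency in one other
    population (panel misclassification errors); they are never serialized.
    """

    populations: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    pop_index: np.ndarray
    allele: np.ndarray
    maf: np.ndarray
    count: np.ndarray
    hidden_pop: np.ndarray | None = None
    hidden_freq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.populations = list(self.populations)
        self.chrom = _as_str_array(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.pop_index = np.asarray(self.pop_index, dtype=np.int64)
        self.allele = _as_str_array(self.allele)
        self.maf = np.asarray(self.maf, dtype=np.float64)
        self.count = np.asarray(self.count, dtype=np.int64)
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        if not np.array_equal(order, np.arange(len(order))):
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
            self.pop_index = self.pop_index[order]
            self.allele = self.allele[order]
            self.maf = self.maf[order]
            self.count = self.count[order]
            if self.hidden_pop is not None:
                self.hidden_pop = np.asarray(self.hidden_pop)[order]
            if self.hidden_freq is not None:
                self.hidden_freq = np.asarray(self.hidden_freq)[order]
        if self.hidden_pop is not None:
            self.hidden_pop = np.asarray(self.hidden_pop, dtype=np.int64)
        if self.hidden_freq is not None:
            self.hidden_freq = np.asarray(self.hidden_freq, dtype=np.float64)
        key = list(zip(self.chrom.tolist(), self.pos.tolist()))
        if len(set(key)) != len(key):
            raise PanelFormatError("duplicate (chrom, pos) in panel")
        if self.pop_index.size and (self.pop_index.min() < 0
                                    or self.pop_index.max() >= self.K):
            raise ValueError("pop_index out of range")

    # -- basic introspection -------------------------------------------------

    @property
    def K(self) -> int:
        return len(self.populations)

    @property
    def M(self) -> int:
        return len(self.pos)

    def __len__(self) -> int:
        return self.M

    def M_k(self) -> np.ndarray:
        """Panel size per population; sums to M."""
        return np.bincount(self.pop_index, minlength=self.K)

    def theta(self, k: int) -> np.ndarray:
        """Row indices of SNPs specific to population ``k``."""
        return np.flatnonzero(self.pop_index == k)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous row slice of one chromosome (panel is chrom-sorted)."""
        idx = np.flatnonzero(self.chrom == chrom)
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def restrict(self, index: np.ndarray) -> "SNPPanel":
        """Sub-panel given row indices or a boolean mask."""
        index = np.asarray(index)
        return SNPPanel(
            populations=list(self.populations),
            chrom=self.chrom[index],
            pos=self.pos[index],
            pop_index=self.pop_index[index],
            allele=self.allele[index],
            maf=self.maf[index],
            count=self.count[index],
            hidden_pop=None if self.hidden_pop is None else self.hidden_pop[index],
            hidden_freq=None if self.hidden_freq is None else self.hidden_freq[index],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SNPPanel):
            return NotImplemented
        return (self.populations == other.populations
                and np.array_equal(self.chrom, other.chrom)
                and np.array_equal(self.pos, other.pos)
                and np.array_equal(self.pop_index, other.pop_index)
                and np.array_equal(self.allele, other.allele)
                and np.array_equal(self.maf, other.maf)
                and np.array_equal(self.count, other.count))

    def key_set(self) -> set[tuple[str, int]]:
        return set(zip(self.chrom.tolist(), self.pos.tolist()))


def screen_specific_snps(cohort: ReferenceCohort, min_copies: int = 5) -> SNPPanel:
    """Screen a reference cohort for population-specific SNPs.

    Both alleles of every SNP are tested: an allele is retained when its copy
    count is >= ``min_copies`` in exactly one population, zero in all others,
    and its frequency in that population is <= 0.5 (minor there).

    Raises :class:`ConfigurationError` for K < 2 or an empty population.
    """
    if cohort.K < 2:
        raise ConfigurationError("screening requires at least two reference populations")
    sizes = cohort.pop_sizes
    if (sizes == 0).any():
        empty = [p for p, s in zip(cohort.populations, sizes) if s == 0]
        raise ConfigurationError(f"reference population(s) with zero samples: {empty}")
    if min_copies < 1:
        raise ValueError("min_copies must be >= 1")

    total = 2 * sizes.astype(np.int64)
    alt_c = cohort.alt_counts()
    ref_c = total[None, :] - alt_c

    rows_chrom: list[np.ndarray] = []
    rows_pos: list[np.ndarray] = []
    rows_pop: list[np.ndarray] = []
    rows_allele: list[np.ndarray] = []
    rows_maf: list[np.ndarray] = []
    rows_count: list[np.ndarray] = []
    for counts, alleles in ((alt_c, cohort.alt), (ref_c, cohort.ref)):
        present = counts > 0
        only_one = present.sum(axis=1) == 1
        k = counts.argmax(axis=1)
        copies = counts[np.arange(counts.shape[0]), k]
        freq = copies / total[k]
        keep = only_one & (copies >= min_copies) & (freq <= 0.5)
        rows_chrom.append(cohort.chrom[keep])
        rows_pos.append(cohort.pos[keep])
        rows_pop.append(k[keep])
        rows_allele.append(alleles[keep])
        rows_maf.append(freq[keep])
        rows_count.append(copies[keep])

    panel = SNPPanel(
        populations=list(cohort.populations),
        chrom=np.concatenate(rows_chrom),
        pos=np.concatenate(rows_pos),
        pop_index=np.concatenate(rows_pop),
        allele=np.concatenate(rows_allele),
        maf=np.concatenate(rows_maf),
        count=np.concatenate(rows_count),
    )
    logger.info("screened %d population-specific SNPs (min_copies=%d): %s",
                panel.M, min_copies,
                dict(zip(panel.populations, panel.M_k().tolist())))
    return panel


# -- panel TSV ---------------------------------------------------------------

def write_panel(panel: SNPPanel, path: str | Path) -> Path:
    """Write a panel as TSV (1-based positions).

    A ``#populations=`` comment line precedes the header so populations with
    zero panel SNPs survive a round trip.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#populations=" + ",".join(panel.populations) + "\n")
        fh.write("\t".join(PANEL_COLUMNS) + "\n")
        for i in range(panel.M):
            fh.write("\t".join((
                str(panel.chrom[i]),
                str(int(panel.pos[i])),
                panel.populations[panel.pop_index[i]],
                str(panel.allele[i]),
                repr(float(panel.maf[i])),
                str(int(panel.count[i])),
            )) + "\n")
    return path


def read_panel(path: str | Path) -> SNPPanel:
    """Read a panel TSV written by :func:`write_panel`.

    Raises :class:`PanelFormatError` naming the offending line for malformed
    rows, unsorted positions, or duplicate (chrom, pos) keys.
    """
    path = Path(path)
    populations: list[str] | None = None
    chroms: list[str] = []
    poss: list[int] = []
    pops: list[str] = []
    alleles: list[str] = []
    mafs: list[float] = []
    counts: list[int] = []
    header_seen = False
    last_key: tuple[str, int] | None = None
    finished_chroms: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#populations="):
                populations = line.split("=", 1)[1].split(",") if line.split("=", 1)[1] else []
                continue
            if not header_seen:
                if tuple(line.split("\t")) != PANEL_COLUMNS:
                    raise PanelFormatError(
                        f"{path}: line {lineno}: expected header {PANEL_COLUMNS}")
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != len(PANEL_COLUMNS):
                raise PanelFormatError(
                    f"{path}: line {lineno}: expected {len(PANEL_COLUMNS)} columns, "
                    f"got {len(parts)}")
            try:
                pos = int(parts[1])
                maf = float(parts[4])
                count = int(parts[5])
            except ValueError as exc:
                raise PanelFormatError(f"{path}: line {lineno}: {exc}") from exc
            key = (parts[0], pos)
            if last_key is not None:
                if key == last_key:
                    raise PanelFormatError(
                        f"{path}: line {lineno}: duplicate position {key}")
                if parts[0] == last_key[0]:
                    if pos < last_key[1]:
                        raise PanelFormatError(
                            f"{path}: line {lineno}: unsorted position {key}")
                else:
                    finished_chroms.add(last_key[0])
                    if parts[0] in finished_chroms:
                        raise PanelFormatError(
                            f"{path}: line {lineno}: chromosome {parts[0]!r} "
                            "rows are not contiguous (unsorted file)")
            last_key = key
            chroms.append(parts[0])
            poss.append(pos)
            pops.append(parts[2])
            alleles.append(parts[3])
            mafs.append(maf)
            counts.append(count)
    if not header_seen:
        raise PanelFormatError(f"{path}: missing header line")
    if populations is None:
        populations = sorted(set(pops))
    pop_to_idx = {p: i for i, p in enumerate(populations)}
    try:
        pop_index = np.array([pop_to_idx[p] for p in pops], dtype=np.int64)
    except KeyError as exc:
        raise PanelFormatError(f"{path}: unknown population {exc}") from exc
    try:
        return SNPPanel(
            populations=populations,
            chrom=np.array(chroms, dtype=object),
            pos=np.array(poss, dtype=np.int64),
            pop_index=pop_index,
            allele=np.array(alleles, dtype=object),
            maf=np.array(mafs, dtype=np.float64),
            count=np.array(counts, dtype=np.int64),
        )
    except PanelFormatError as exc:
        raise PanelFormatError(f"{path}: {exc}") from exc
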