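"""Ancestry calling and segmentation.

Per-locus rule: the winning population is the argmax of the window's
ancestry-information vector.  A locus stays UNCALLED when (a) the maximum
is below ``laiv_min``, (b) the maximum is tied (an arbitrary winner would
fabricate ancestry), or (c) the window contains specific alleles of two or
more populations but the winner carries fewer than ``allele_min`` of them —
the guard against sporadic panel-misclassification alleles.

Segments: each called locus anchors its label at its own base pair; the gap
between two neighbouring loci inherits their shared label when their calls
coincide and is UNCALLED otherwise; chromosome ends extend the terminal
call.  Defaults follow the reference analysis settings: 2 Mbp windows,
laiv_min = 1e-6, allele_min = 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .haplotypes import PresenceMatrix
from .laiv import LAIV, sliding_window_stats
from .panel import PanelFormatError, SNPPanel

logger = logging.getLogger(__name__)

#: Label used for loci/segments without an ancestry call.
UNCALLED = "UNCALLED"

DEFAULT_WINDOW_SIZE = 2_000_000
DEFAULT_LAIV_MIN = 1e-6
DEFAULT_ALLELE_MIN = 2

SEGMENT_COLUMNS = ("chrom", "start", "end", "sample", "haplotype", "label")


@dataclass
class LocusCall:
    """Ancestry decision at one panel-SNP locus of one haplotype."""

    chrom: str
    pos: int
    call: str                 # population label or UNCALLED
    value: float              # winning ancestry information
    count: int                # winning specific-allele count in the window
    sample: str | None = None
    haplotype: int | None = None


@dataclass
class AncestrySegment:
    """A maximal single-label interval, 0-based half-open in bp."""

    chrom: str
    start: int
    end: int
    sample: str
    haplotype: int
    label: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty segment [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def call_codes(phat: np.ndarray, counts: np.ndarray,
               laiv_min: float = DEFAULT_LAIV_MIN,
               allele_min: int = DEFAULT_ALLELE_MIN) -> np.ndarray:
    """Vectorised calling: (n, K) stats -> population codes, -1 = UNCALLED."""
    phat = np.atleast_2d(phat)
    counts = np.atleast_2d(counts)
    n = phat.shape[0]
    winner = phat.argmax(axis=1)
    rows = np.arange(n)
    maxv = phat[rows, winner]
    tied = (phat == maxv[:, None]).sum(axis=1) > 1
    multi_pop = (counts > 0).sum(axis=1) >= 2
    win_count = counts[rows, winner]
    uncalled = tied | (maxv < laiv_min) | (multi_pop & (win_count < allele_min))
    return np.where(uncalled, -1, winner)


def call_locus(laiv: LAIV, laiv_min: float = DEFAULT_LAIV_MIN,
               allele_min: int = DEFAULT_ALLELE_MIN) -> LocusCall:
    """Apply the calling rule to a single LAIV."""
    if laiv_min < 0 or allele_min < 0:
        raise ValueError("thresholds must be nonnegative")
    code = int(call_codes(laiv.phat[None, :], laiv.counts[None, :],
                          laiv_min, allele_min)[0])
    winner = int(laiv.phat.argmax())
    return LocusCall(
        chrom=laiv.chrom if laiv.chrom is not None else "",
        pos=int(laiv.center) if laiv.center is not None else 0,
        call=laiv.populations[code] if code >= 0 else UNCALLED,
        value=float(laiv.phat[winner]),
        count=int(laiv.counts[winner]),
    )


def _segments_core(pos: np.ndarray, labels: np.ndarray, length: int):
    """Tile [0, length) from per-locus calls.

    ``pos`` 1-based strictly increasing, ``labels`` object array (may contain
    UNCALLED).  Returns (starts, ends, labels) arrays of merged segments.
    """
    n = len(pos)
    if n == 0:
        return (np.array([0]), np.array([length]),
                np.array([UNCALLED], dtype=object))
    if pos[0] < 1 or pos[-1] > length:
        raise ValueError("call position outside chromosome")
    # pieces: leading flank, then per locus an anchor and a trailing piece
    starts = np.empty(2 * n + 1, dtype=np.int64)
    ends = np.empty(2 * n + 1, dtype=np.int64)
    labs = np.empty(2 * n + 1, dtype=object)
    starts[0], ends[0], labs[0] = 0, pos[0] - 1, labels[0]
    starts[1::2], ends[1::2], labs[1::2] = pos - 1, pos, labels
    starts[2::2] = pos
    ends[2::2] = np.append(pos[1:] - 1, length)
    gap_labs = np.where(labels[:-1] == labels[1:], labels[:-1], UNCALLED)
    labs[2::2] = np.append(gap_labs, labels[-1])
    keep = ends > starts
    starts, ends, labs = starts[keep], ends[keep], labs[keep]
    # merge adjacent equal labels (pieces tile, so runs are contiguous)
    first = np.concatenate([[True], labs[1:] != labs[:-1]])
    idx = np.flatnonzero(first)
    seg_starts = starts[idx]
    seg_ends = ends[np.append(idx[1:] - 1, len(ends) - 1)]
    return seg_starts, seg_ends, labs[idx]


def segments_from_calls(calls: Sequence[LocusCall], chromosome_length: int,
                        sample: str = "", haplotype: int = 1) -> list[AncestrySegment]:
    """Merge one haplotype's ordered locus calls into ancestry segments.

    Calls must be on a single chromosome and sorted by strictly increasing
    position.  An empty call list yields one UNCALLED segment covering the
    chromosome.
    """
    if not calls:
        return [AncestrySegment("", 0, int(chromosome_length), sample,
                                haplotype, UNCALLED)]
    chroms = {c.chrom for c in calls}
    if len(chroms) > 1:
        raise ValueError("calls span multiple chromosomes")
    pos = np.array([c.pos for c in calls], dtype=np.int64)
    if not np.all(np.diff(pos) > 0):
        raise ValueError("calls must be sorted by strictly increasing position")
    labels = np.array([c.call for c in calls], dtype=object)
    starts, ends, labs = _segments_core(pos, labels, int(chromosome_length))
    chrom = calls[0].chrom
    return [AncestrySegment(chrom, int(s), int(e), sample, haplotype, str(l))
            for s, e, l in zip(starts, ends, labs)]


def infer_ancestry(presence: PresenceMatrix,
                   chrom_lengths: Mapping[str, int],
                   window_size: int = DEFAULT_WINDOW_SIZE,
                   laiv_min: float = DEFAULT_LAIV_MIN,
                   allele_min: int = DEFAULT_ALLELE_MIN,
                   return_calls: bool = False):
    """Full pipeline: presence matrix -> per-haplotype ancestry segments.

    Returns the segment list, or ``(segments, calls_df)`` when
    ``return_calls`` is set (one row per haplotype x panel SNP).
    """
    panel = presence.panel
    pops = np.array(panel.populations + [UNCALLED], dtype=object)
    segments: list[AncestrySegment] = []
    call_frames: list[pd.DataFrame] = []
    for chrom in panel.chromosomes():
        if chrom not in chrom_lengths:
            raise ValueError(f"no chromosome length provided for {chrom!r}")
    for sample, hap, row in presence.haplotypes():
        counts, maf_sums, phat, lo, hi = sliding_window_stats(
            row, panel, window_size)
        codes = call_codes(phat, counts, laiv_min, allele_min)
        labels = pops[codes]          # -1 indexes the trailing UNCALLED entry
        for chrom in panel.chromosomes():
            sl = panel.chrom_slice(chrom)
            starts, ends, labs = _segments_core(
                panel.pos[sl], labels[sl], int(chrom_lengths[chrom]))
            segments.extend(
                AncestrySegment(chrom, int(s), int(e), sample, hap, str(l))
                for s, e, l in zip(starts, ends, labs))
        if return_calls:
            rows = np.arange(panel.M)
            winner = phat.argmax(axis=1)
            call_frames.append(pd.DataFrame({
                "sample": sample, "haplotype": hap,
                "chrom": panel.chrom.astype(str), "pos": panel.pos,
                "call": labels.astype(str),
                "value": phat[rows, winner],
                "count": counts[rows, winner],
            }))
    if return_calls:
        calls_df = (pd.concat(call_frames, ignore_index=True) if call_frames
                    else pd.DataFrame(columns=["sample", "haplotype", "chrom",
                                               "pos", "call", "value", "count"]))
        return segments, calls_df
    return segments


def laiv_table(presence: PresenceMatrix,
               window_size: int = DEFAULT_WINDOW_SIZE) -> pd.DataFrame:
    """Per-haplotype, per-centre LAIV dump (debugging aid for the CLI)."""
    panel = presence.panel
    frames = []
    for sample, hap, row in presence.haplotypes():
        counts, maf_sums, phat, lo, hi = sliding_window_stats(
            row, panel, window_size)
        df = pd.DataFrame({"sample": sample, "haplotype": hap,
                           "chrom": panel.chrom.astype(str),
                           "pos": panel.pos})
        for k, pop in enumerate(panel.populations):
            df[f"phat_{pop}"] = phat[:, k]
        for k, pop in enumerate(panel.populations):
            df[f"count_{pop}"] = counts[:, k]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# -- segment BED-like IO -----------------------------------------------------

def _sorted_segments(segments: Iterable[AncestrySegment]) -> list[AncestrySegment]:
    return sorted(segments,
                  key=lambda s: (s.sample, s.haplotype, s.chrom, s.start))


def write_segments(segments: Iterable[AncestrySegment], path: str | Path) -> Path:
    """Write segments as headered BED-like TSV (0-based half-open).

    Rows are sorted by (sample, haplotype, chrom, start); overlapping
    segments within a haplotype are refused.
    """
    path = Path(path)
    rows = _sorted_segments(segments)
    prev: AncestrySegment | None = None
    for seg in rows:
        if (prev is not None and (seg.sample, seg.haplotype, seg.chrom)
                == (prev.sample, prev.haplotype, prev.chrom)
                and seg.start < prev.end):
            raise ValueError(
                f"overlapping segments for {seg.sample} hap {seg.haplotype} "
                f"{seg.chrom}: [{prev.start},{prev.end}) and "
                f"[{seg.start},{seg.end})")
        prev = seg
    with open(path, "w") as fh:
        fh.write("\t".join(SEGMENT_COLUMNS) + "\n")
        for s in rows:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.sample}\t"
                     f"{s.haplotype}\t{s.label}\n")
    return path


def read_segments(path: str | Path) -> list[AncestrySegment]:
    """Read a segment TSV written by :func:`write_segments`."""
    path = Path(path)
    out: list[AncestrySegment] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if tuple(header.split("\t")) != SEGMENT_COLUMNS:
            raise PanelFormatError(f"{path}: line 1: expected header "
                                   f"{SEGMENT_COLUMNS}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(SEGMENT_COLUMNS):
                raise PanelFormatError(
                    f"{path}: line {lineno}: expected "
                    f"{len(SEGMENT_COLUMNS)} columns")
            try:
                out.append(AncestrySegment(parts[0], int(parts[1]),
                                           int(parts[2]), parts[3],
                                           int(parts[4]), parts[5]))
            except ValueError as exc:
                raise PanelFormatError(
                    f"{path}: line {lineno}: {exc}") from exc
    return out
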