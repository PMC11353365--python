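"""Internal interval arithmetic over per-haplotype segment tilings."""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

from .caller import AncestrySegment

HapKey = tuple[str, int]
# one haplotype+chromosome tiling: bounds (t+1,), labels (t,) object
Tiling = tuple[np.ndarray, np.ndarray]


def group_segments(segments: Iterable[AncestrySegment]
                   ) -> dict[HapKey, dict[str, Tiling]]:
    """Group segments into contiguous per-(sample, haplotype, chrom) tilings.

    Raises ``ValueError`` on gaps or overlaps within a haplotype/chromosome.
    """
    buckets: dict[HapKey, dict[str, list[AncestrySegment]]] = {}
    for seg in segments:
        buckets.setdefault((seg.sample, seg.haplotype), {}) \
               .setdefault(seg.chrom, []).append(seg)
    out: dict[HapKey, dict[str, Tiling]] = {}
    for key, by_chrom in buckets.items():
        out[key] = {}
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            starts = np.array([s.start for s in segs], dtype=np.int64)
            ends = np.array([s.end for s in segs], dtype=np.int64)
            if not np.array_equal(starts[1:], ends[:-1]):
                raise ValueError(
                    f"segments for {key} on {chrom} do not tile contiguously "
                    "(gap or overlap)")
            bounds = np.append(starts, ends[-1])
            labels = np.array([s.label for s in segs], dtype=object)
            out[key][chrom] = (bounds, labels)
    return out


def labels_on_grid(tiling: Tiling, cuts: np.ndarray) -> np.ndarray:
    """Piecewise labels over the intervals defined by ``cuts`` (sorted bounds
    refining the tiling's own bounds)."""
    bounds, labels = tiling
    idx = np.searchsorted(bounds, cuts[:-1], side="right") - 1
    idx = np.clip(idx, 0, len(labels) - 1)
    return labels[idx]


def overlay(a: Tiling, b: Tiling) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Refine two tilings of the same extent onto a common grid.

    Returns (piece lengths, labels of a, labels of b).
    """
    ba, _ = a
    bb, _ = b
    if ba[0] != bb[0] or ba[-1] != bb[-1]:
        raise ValueError(
            f"tilings cover different extents: [{ba[0]}, {ba[-1]}) vs "
            f"[{bb[0]}, {bb[-1]})")
    cuts = np.union1d(ba, bb)
    lengths = np.diff(cuts)
    return lengths, labels_on_grid(a, cuts), labels_on_grid(b, cuts)
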