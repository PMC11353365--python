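"""Callset comparison statistics.

``consistency_rate`` measures base-pair agreement between two local-ancestry
callsets.  By default the rate is computed over base pairs called by BOTH
callsets — agreeing bp / mutually called bp — with uncalled regions excluded
from numerator and denominator.  This denominator choice is a package
convention (comparison studies rarely state theirs); pass
``uncalled_as_disagreement=True`` to divide instead by the full shared
extent, which penalises uncalled bp in either callset.

``uncalled_rate`` is the fraction of base pairs a callset leaves without an
ancestry label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from ._intervals import group_segments, overlay
from .caller import UNCALLED, AncestrySegment


@dataclass
class CallsetComparison:
    """Per-haplotype and cohort-mean agreement between two callsets."""

    per_haplotype: pd.DataFrame   # sample, haplotype, agree_bp, both_called_bp,
                                  # either_uncalled_bp, total_bp, rate
    mean_rate: float

    def __repr__(self) -> str:  # keep the DataFrame out of casual printing
        return (f"CallsetComparison(mean_rate={self.mean_rate:.6g}, "
                f"n_haplotypes={len(self.per_haplotype)})")


def consistency_rate(a: Iterable[AncestrySegment],
                     b: Iterable[AncestrySegment],
                     uncalled_as_disagreement: bool = False) -> CallsetComparison:
    """Base-pair consistency between two callsets on the same haplotypes.

    Both callsets must tile the same haplotypes over the same chromosome
    extents.  The cohort mean averages per-haplotype rates (haplotypes with
    an undefined rate — no mutually called bp — are skipped).
    """
    ga = group_segments(a)
    gb = group_segments(b)
    if set(ga) != set(gb):
        raise ValueError(
            f"callsets cover different haplotypes: {sorted(set(ga) ^ set(gb))}")
    rows = []
    for key in sorted(ga):
        if set(ga[key]) != set(gb[key]):
            raise ValueError(f"haplotype {key}: chromosome sets differ")
        agree = both = either_unc = total = 0
        for chrom in ga[key]:
            lengths, la, lb = overlay(ga[key][chrom], gb[key][chrom])
            called = (la != UNCALLED) & (lb != UNCALLED)
            agree += int(lengths[called & (la == lb)].sum())
            both += int(lengths[called].sum())
            either_unc += int(lengths[~called].sum())
            total += int(lengths.sum())
        denom = total if uncalled_as_disagreement else both
        rate = agree / denom if denom > 0 else np.nan
        rows.append({"sample": key[0], "haplotype": key[1], "agree_bp": agree,
                     "both_called_bp": both, "either_uncalled_bp": either_unc,
                     "total_bp": total, "rate": rate})
    df = pd.DataFrame(rows)
    mean = float(df["rate"].mean(skipna=True)) if len(df) else np.nan
    return CallsetComparison(per_haplotype=df, mean_rate=mean)


@dataclass
class UncalledRates:
    """Fraction of bp left UNCALLED, per haplotype and cohort mean."""

    per_haplotype: pd.DataFrame   # sample, haplotype, uncalled_bp, total_bp, rate
    mean_rate: float

    def __repr__(self) -> str:
        return (f"UncalledRates(mean_rate={self.mean_rate:.6g}, "
                f"n_haplotypes={len(self.per_haplotype)})")


def uncalled_rate(segments: Iterable[AncestrySegment]) -> UncalledRates:
    """UNCALLED bp / total bp per haplotype; segments must tile each
    haplotype's chromosomes without gaps."""
    grouped = group_segments(segments)
    rows = []
    for key in sorted(grouped):
        unc = total = 0
        for chrom, (bounds, labels) in grouped[key].items():
            lengths = np.diff(bounds)
            unc += int(lengths[labels == UNCALLED].sum())
            total += int(lengths.sum())
        rows.append({"sample": key[0], "haplotype": key[1],
                     "uncalled_bp": unc, "total_bp": total,
                     "rate": unc / total if total else np.nan})
    df = pd.DataFrame(rows)
    mean = float(df["rate"].mean(skipna=True)) if len(df) else np.nan
    return UncalledRates(per_haplotype=df, mean_rate=mean)
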