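"""Infer local ancestry for simulated admixed haplotypes and score it.

Simulates a two-way admixture (70% POP1 / 30% POP2, 10 generations old) on
a 20 Mb chromosome, runs the sliding-window ancestry caller with default
thresholds, and compares the called segments against the simulator's truth
tracts.  The three printed fractions partition every base pair: called with
the true ancestry, called with a wrong ancestry, or left uncalled.
"""

from laikit import infer_ancestry, screen_specific_snps, uncalled_rate
from laikit.simulate import (SimulationConfig, evaluate_recovery,
                             simulate_admixed, simulate_reference)

cfg = SimulationConfig(chrom_length=20_000_000, n_admixed=20, seed=42)
cohort, designed = simulate_reference(cfg)
panel = screen_specific_snps(cohort, min_copies=5)
presence, truth = simulate_admixed(cfg, designed)

segments = infer_ancestry(presence.restrict(panel),
                          {cfg.chrom: cfg.chrom_length})
rec = evaluate_recovery(segments, truth)

print(f"haplotypes analysed: {len(rec.per_haplotype)}")
print(f"called and correct : {rec.correct:.4f}")
print(f"called but wrong   : {rec.wrong:.4f}")
print(f"uncalled           : {rec.uncalled:.4f}")
print(f"mean uncalled rate : {uncalled_rate(segments).mean_rate:.4f}")
print("\nper true ancestry (bp-weighted):")
print(rec.by_ancestry.to_string(index=False))
# Wrong calls concentrate near tract boundaries, where a 2 Mb window mixes
# alleles from the two flanking ancestries; uncalled bp lie in the gaps
# between differing neighbouring locus calls.
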