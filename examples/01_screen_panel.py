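"""Screen population-specific SNPs from a (simulated) reference cohort.

Builds a small three-population reference cohort, screens it for SNPs whose
minor allele is private to one population at >= 5 copies, and prints the
panel sizes.  The printed MAF is the allele's frequency within its own
population — the weight the ancestry estimator divides by.
"""

from laikit import screen_specific_snps
from laikit.simulate import SimulationConfig, simulate_reference

cfg = SimulationConfig(
    populations=("AFR", "EUR", "EAS"),
    proportions=(0.5, 0.3, 0.2),
    ref_sizes=50,
    chrom_length=10_000_000,
    snp_density=(1e-4, 5e-5, 5e-5),   # AFR-private SNPs are denser
    seed=1,
)
cohort, designed = simulate_reference(cfg)
panel = screen_specific_snps(cohort, min_copies=5)

print(f"designed specific SNPs: {designed.M}, screened: {panel.M}")
for pop, mk in zip(panel.populations, panel.M_k()):
    print(f"  {pop}: {mk} panel SNPs")
print("first panel SNP:", panel.chrom[0], int(panel.pos[0]),
      panel.populations[panel.pop_index[0]], panel.allele[0],
      f"maf={panel.maf[0]:.3f}", f"copies={int(panel.count[0])}")
# write_panel(panel, "panel.tsv") would persist it for the `laikit infer` CLI.
# The small screened/designed deficit is expected: a designed SNP whose
# sampled copy count fell below 5, or whose allele drifted above frequency
# 0.5 in its own sample, no longer satisfies the screening rule.
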