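# Methods

## Model

Consider K reference populations and a panel of M diallelic SNPs, each
specific to exactly one population: SNP m ∈ θ_k carries a minor allele with
frequency f_km > 0 in population k and frequency 0 in every other
reference population. For a haplotype segment with ancestral proportions
p_1 … p_K, carriage of SNP m's specific allele is Bernoulli with success
probability p_k · f_km. Treating the M indicators as independent gives a
product likelihood whose method-of-moments estimator for p_k is

    p̂_k = ( Σ_{m∈θ_k} X_m ) / ( Σ_{m∈θ_k} f_km ),

the ratio of observed specific-allele count to expected count under full
population-k ancestry. Only these two sums enter, so the estimator remains
unbiased under arbitrary linkage disequilibrium among panel SNPs (the
independence assumption affects only its variance); permuting SNPs within
a window provably leaves it unchanged, and the test suite asserts exactly
that. p̂_k is an information score, not a probability: it is nonnegative,
averages 1 over windows of true k ancestry, and can exceed 1 by sampling
noise.

## Panel screening

An allele is deemed population-specific when (i) it reaches at least
`min_copies` copies (default 5) in one reference population, (ii) has zero
copies in every other reference population, and (iii) is the minor allele
within its own population (sample frequency ≤ 0.5; exactly 0.5 allowed —
only the copy count is thresholded from below). Both REF and ALT alleles
of every SNP are tested, since either can be the private minor allele; the
two cannot qualify simultaneously (an allele absent from other populations
forces the complementary allele to be present there). SNPs with any
missing genotype are dropped before screening, non-diallelic records are
skipped with a warning, and contigs are screened independently. The panel
MAF is copy count / (2 × diploid sample size), estimated from the
reference sample — the same quantity the denominator uses downstream.

Finite reference panels cause misclassification: an allele present at low
frequency in a second population can go unsampled and be declared
specific. The simulator models this directly (below), and the caller's
`allele_min` guard exists to absorb it.

## Calling algorithm

For each haplotype, a window of `window_size` bp (default 2,000,000) is
centred at every panel SNP: half-width `window_size // 2` on each side,
inclusive bounds, truncated at chromosome ends, the centre SNP included
like any other. The per-window K-vector of p̂ values is computed for all
centres with per-population cumulative sums over the position-sorted
panel, which is algebraically identical to evaluating each window
independently (integer numerators are exact; float64 cumulative-sum
denominators agree with direct summation to well under 1e-9 relative — an
invariant the suite checks against a naive re-evaluation).

A locus is called as the argmax population unless:

* max p̂ < `laiv_min` (default 1e-6; the comparison is strict, so the
  default only suppresses all-zero windows),
* the maximum is tied — an arbitrary winner would fabricate ancestry, so
  ties stay uncalled, or
* specific alleles of ≥ 2 populations occur in the window and the winner
  has fewer than `allele_min` of them (default 2). A window containing one
  population's alleles only is exempt, so sparse but unambiguous evidence
  still calls.

Windows with no θ_k SNP report p̂_k = 0 rather than NaN: absence of
evidence must never win the argmax, and regions without panel coverage
should fall to the uncalled path rather than be guessed.

Segmentation: each called locus anchors its label on its own base pair
(1 bp, half-open [pos−1, pos)); the interval between two neighbouring loci
takes their shared label when the calls coincide and UNCALLED otherwise
(an uncalled neighbour never propagates a label); chromosome ends extend
the terminal locus's label outward. Adjacent same-label intervals merge.
Segments therefore tile [0, chromosome length) exactly — the suite asserts
the tiling bp-for-bp — and raising either threshold can only move bp from
called to uncalled (monotone conservatism, also asserted). End-extension
at telomeres is a documented choice; the conservative alternative (leave
flanks uncalled) amounts to dropping the two terminal pieces.

## Synthetic data

The simulator generates the regime the method targets, not real human
data:

* **Reference cohorts.** Per population, specific-SNP positions arrive as
  a Poisson draw at `snp_density` per bp (default 1e-4), unique across the
  chromosome; designed MAFs are uniform on `maf_range` (default
  0.05–0.5). Reference haplotypes draw each private allele independently —
  Bernoulli(f) in the own population, 0 elsewhere — so reference data have
  no background LD and no shared polymorphism.
* **Misclassification model.** With probability `epsilon` a designed SNP
  secretly segregates at frequency `epsilon_freq` (default 0.005) in one
  random other population, reproducing the screening artefact of finite
  reference samples.
* **Admixed haplotypes.** Breakpoints are a Poisson process of intensity
  `generations × recomb_rate` per bp (defaults 10 and 1e-8 Morgan/bp — the
  expected breakpoint density after g generations under a uniform genetic
  map), and each tract's ancestry is an iid draw from the admixture
  proportions (default 0.7/0.3). This pool model is a deliberate
  simplification of a Markov ancestry process: it has the right marginal
  proportions and the right 1/(g·r) tract-length scaling, but no
  correlation between neighbouring tracts. Allele presence then follows
  the tract's ancestry exactly as in the reference model.

Default cohort sizes are 100 reference diploids per population and 50
admixed diploids (100 haplotypes) on a 100 Mb chromosome — large enough
that screening retains almost the whole designed panel while the full
pipeline runs in seconds. All draws descend from `seed` through three
fixed-purpose substreams (panel design, reference genotypes, admixed
haplotypes), so every artefact is bit-reproducible.

What passing tests on these data do **not** show: robustness to background
LD within reference populations, to phasing errors, to non-uniform
recombination maps, to inaccurate reference panels (drifted proxies for
the true ancestral populations), or to genotyping error. They validate the
estimator's calibration, the calling algebra, and the qualitative
panel-sparsity behaviour.

## Metrics

* **Recovery** (against truth tracts): every bp is called-and-correct,
  called-and-wrong, or uncalled; the three fractions sum to 1 by
  construction, per haplotype and per true ancestry.
* **Consistency rate** between two callsets: agreeing bp / mutually called
  bp, computed by exact interval intersection and verified against per-bp
  brute force. Uncalled bp are excluded from numerator and denominator by
  default — a package convention, since published comparisons rarely state
  a denominator; `uncalled_as_disagreement=True` divides by the full
  shared extent instead. Comparison is per haplotype by index, with no
  phase-swap rematching (both callsets are assumed to consume identical
  phased data).
* **Uncalled rate**: UNCALLED bp / total bp.

## Numerical and design notes

* Panel and cohort positions are 1-based (VCF convention); segments are
  0-based half-open (BED convention).
* Panel files are TSV with a `#populations=` header comment so populations
  with zero panel SNPs survive round trips; MAFs are written at full repr
  precision and round-trip exactly.
* Unphased genotypes at panel sites are a hard error (per-haplotype
  inference is meaningless without phase); missing genotype calls in
  admixed samples are treated as allele-absent with a warning. Panel SNPs
  absent from an admixed VCF contribute 0 to numerators while their MAFs
  remain in denominators, keeping the denominator a property of the panel
  alone.
* Sliding windows are inclusive on both bounds; degenerate inputs (empty
  panel, empty call list, single-locus chromosomes) produce the obvious
  empty or fully-uncalled outputs rather than errors.

## Validation problem sizes

The automated checks run the full pipeline at 100 Mb × 100 haplotypes ×
~20,000 panel SNPs (seconds per run), estimator calibration over 500
replicate windows with 4-standard-error bands, exact-equivalence checks of
the sliding scan against naive per-window evaluation on random instances
up to 1,000 SNPs, and brute-force per-bp verification of screening,
segmentation and the metrics on small chromosomes.

## Known limitations

The method is bounded by panel density: ancestries with few specific SNPs
(the sparse-panel regime, reproduced in the tests by reducing one
population's density 10×) leave more bp uncalled, and chromosomal regions
without panel SNPs are labelled only when both flanking calls agree. There
is no variance or posterior attached to p̂, no diploid (unphased) mode, no
phase-error correction, and no genetic-map (cM) windows — windows are
physical bp.
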