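# laikit

Local ancestry inference for admixed genomes, driven entirely by
**population-specific SNPs** — variants whose minor allele segregates in
exactly one reference population and is absent from all others.

## The problem and the method

Admixed individuals (African Americans, Latin Americans, …) carry genomes
that are mosaics of chromosomal tracts inherited from distinct ancestral
populations. Local ancestry inference (LAI) assigns an ancestral origin to
each tract of each phased haplotype. Most LAI tools model full haplotype
structure (HMMs, random forests, neural networks); `laikit` instead uses
only the presence or absence of population-private alleles, which makes the
estimator transparent, assumption-light, and extremely fast.

Let θ<sub>k</sub> index the panel SNPs specific to reference population
*k*, with minor-allele frequencies *f<sub>km</sub>* in that population. For
a haplotype window, write *X<sub>m</sub>* ∈ {0, 1} for carriage of SNP
*m*'s specific allele. The **local ancestry information** for population
*k* is the method-of-moments estimate of the window's ancestral proportion
*p<sub>k</sub>*:

&nbsp;&nbsp;&nbsp;&nbsp;p̂<sub>k</sub> = Σ<sub>m∈θk</sub> X<sub>m</sub> / Σ<sub>m∈θk</sub> f<sub>km</sub>

If the window descends wholly from population *k*, E[p̂<sub>k</sub>] = 1
(and 0 for every other population); under fractional ancestry *p*,
E[p̂<sub>k</sub>] = *p*. Because only counts and frequency sums enter, the
estimator does not rely on linkage equilibrium between panel SNPs.

The caller slides a window (default 2 Mbp) centred on every panel SNP,
computes the K-vector of p̂ values per haplotype (the local ancestry
information vector), and labels the locus with the argmax — unless the
maximum falls below `laiv_min` (default 1e-6), the maximum is tied, or the
window mixes alleles from ≥ 2 populations while the winner has fewer than
`allele_min` (default 2) supporting alleles, a guard against sporadic
panel-misclassification alleles. Loci between two identically-called SNPs
inherit that label; gaps between differing calls stay uncalled; segments
are emitted as BED-like intervals per haplotype.

The package also provides the panel screener (an allele is
population-specific when it reaches ≥ `min_copies` copies, default 5, in
one population, zero elsewhere, and is minor in its own population), a
synthetic admixture simulator with known truth tracts, and the evaluation
metrics (bp-level consistency rate between callsets, uncalled rate, truth
recovery).

## Worked example

`examples/02_infer_local_ancestry.py` simulates a 70/30 two-way admixture
(10 generations old) on a 20 Mb chromosome, screens the panel, infers local
ancestry with default settings and scores it against the simulated truth:

```
haplotypes analysed: 40
called and correct : 0.9951
called but wrong   : 0.0043
uncalled           : 0.0005
mean uncalled rate : 0.0005

per true ancestry (bp-weighted):
population  correct    wrong  uncalled  total_bp
      POP1 0.994950 0.004550  0.000500 493575288
      POP2 0.995393 0.004001  0.000606 306424712
```

99.5% of base pairs receive the true ancestry; the few wrong or uncalled bp
sit at tract boundaries, where a 2 Mb window unavoidably mixes alleles from
both flanking ancestries. `examples/01_screen_panel.py` shows panel
screening and `examples/03_compare_callsets.py` the consistency rate
between two analyses of the same haplotypes.

## Command line

A thin CLI mirrors the library:

```bash
laikit screen   --vcf ref.vcf --pop-map pops.tsv --out panel.tsv
laikit simulate --config sim.yaml --out-dir sim/
laikit infer    --vcf admixed.vcf --panel panel.tsv --out-prefix out \
                --window-size 2000000 --laiv-min 0.000001 --allele-min 2
laikit compare  out_a.segments.bed out_b.segments.bed --out rates.tsv
```

`infer` writes per-haplotype ancestry segments (`.segments.bed`, 0-based
half-open) and per-locus calls (`.calls.tsv`); `--dump-laiv` adds the raw
information vectors.

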