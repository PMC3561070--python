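# enuibd

Identity-by-descent (IBD) mapping of causative point mutations in mouse
ENU-mutagenesis screens, from whole-genome sequencing of a handful of
affected G3 mice on a pure strain background — no outcrossing, no marker
panels, no extra generations of breeding.

## The problem and the model

A classic ENU screen treats G0 males with *N*-ethyl-*N*-nitrosourea, crosses
them to wild-type females, intercrosses the G1 offspring, and screens the G3
generation for phenotypes.  Every mouse in such a pedigree carries a local
genotype drawn from four founder haplotypes: two mutagenized (ENU1 from the
G1 sire's father, ENU2 from the G1 dam's father) and two wild-type (WT1,
WT2).  A fully penetrant recessive causative mutation must lie in a region
where every affected mouse is homozygous for the *same* ENU haplotype; a
dominant one, where every affected mouse carries at least one copy of it.

`enuibd` finds those regions with a modified Lander–Green hidden Markov
model.  The hidden state at a genomic window is the pedigree's *inheritance
vector* **v** — one bit per gamete of the 2 G2 parents and the *k* sequenced
G3 mice (2(k+2) bits; 1024 states for k=3) recording grand-paternal vs
grand-maternal origin.  Transitions between adjacent windows factorize over
bits,

  P(v → w) = θ^h (1−θ)^(n−h),  h = Hamming(v, w),
  θ = (1 − e^(−2d))/2 (Haldane), d from a recombination map,

so the transition operator is applied bit-by-bit without materializing the
matrix.  Emissions combine the variant caller's genotype likelihoods with
per-window priors of seeing a SNP on an ENU haplotype (ν_ENU, from the ENU
mutation rate) or a WT haplotype (ν_WT): for each SNP the likelihood of **v**
sums over the origin hypotheses {ENU1, ENU2, WT1, WT2, no-variant}, each
hypothesis implying a genotype for every mouse through the founder pairs
selected by **v**.  Windows with no called SNP use likelihoods weighted
towards 0/0 (a missed heterozygote has probability 1/10, a missed homozygote
1/100).  Forward–backward posteriors are summed over WT1↔WT2 relabelings
(the two wild-type haplotypes are genetically identical), decoded by
per-window maximum posterior, and smoothed: an A→B→A excursion of a gamete
bit spanning under 1 Mb is reverted.

Around the HMM sit the other pieces of a working pipeline:

* a **filter cascade** isolating ENU-induced SNVs: a cross-pedigree *union
  file* of variation seen in ≥2 independent pedigrees (strain background or
  systematic error, never ENU), dbSNP exclusion, a 1 kb cluster filter,
  quality and caller-bias-flag filters, homopolymer/di-nucleotide-repeat
  context, indel removal, and coverage-percentile exclusion;
* **region calling**: homozygous and shared-heterozygous IBD regions, and
  the candidate variants inside them (with the naive all-mice-shared
  comparator for benchmarking);
* **estimators** of the ENU mutation rate — homozygous-variant density in
  each mouse's homozygous-ENU regions minus the background density in its
  homozygous-WT regions — and of the mutation spectrum (Ts/Tv, A:T-site
  fraction, 12-substitution matrix);
* closed-form **breeding-design models**: the number M of the 48 G3 mice
  (4 G2 pairs × 3 litters × 4 pups) carrying a founder mutation at a given
  zygosity is a mixture of binomials convolved over pairs; the chance that
  k sequenced mice all share an unlinked locus is the hypergeometric average
  Σ_M P(M)·C(M,k)/C(48,k); expected shared candidates = that probability ×
  genome size × mutation rate × protein-sense fraction + 1 (the causative);
* a full **simulator** — ENU mutations at 1.54/Mb with the ENU substitution
  spectrum, shared background variation, mismapping-artifact sites,
  map-aware recombination through the pedigree, affected-mouse selection,
  and a Poisson/binomial read model emitting genotype likelihoods as VCF
  with ground truth attached — so the entire system is testable end to end
  with no external data.

## Worked example

Simulate a recessive pedigree (250 Mb genome, 24× coverage, 3 sequenced
affected G3 siblings, causative variant planted at chr1:25,000,000 on ENU1),
then run the pipeline:

```sh
enuibd simulate --seed 1 --genome-mb 250 --coverage 24 --out-prefix demo
enuibd filter   --vcf demo.vcf --union demo.union.tsv \
                --out demo.filtered.vcf --report demo.report.tsv
enuibd map      --vcf demo.filtered.vcf --out demo.states.tsv
enuibd call     --states demo.states.tsv --vcf demo.filtered.vcf \
                --exons demo.exons.bed --out-prefix demo
enuibd stats    --states demo.states.tsv --vcf demo.filtered.vcf \
                --out demo.stats.tsv
```

The filter report shows 3040 raw calls reduced to 594 putative ENU variants
(2384 removed by the union file, 6 clustered, 19 low-quality, 29
bias-flagged, 8 at extreme coverage).  `demo.regions.bed` contains the
decoded IBD regions, e.g.

```
chrom   start     end       cls
chr1    14100000  33000000  HOM_ENU2
chr1    33000000  50000000  HET_SHARED_ENU2
```

(the ENU1/ENU2 labels of decoded regions are exchangeable — the model cannot
tell the two mutagenized founders apart, only that all mice share one).
`demo.candidates.tsv` lists 26 homozygous and 106 shared-heterozygous
candidates; the planted causative mutation is among the homozygous ones:

```
chrom   pos       ref  alt  zygosity_class  origin
chr1    25000000  A    G    homozygous      ENU1
```

`demo.stats.tsv` reports per-mouse homozygous-variant densities and the
background-subtracted rate estimate — here 1.43 mutations/Mb against a
configured 1.54 (a single 250 Mb pedigree carries Poisson noise of roughly
±0.1) — plus the spectrum of the 49 homozygous-region mutations:
Ts/Tv 1.45 and 79.6% at A:T sites.

The design model needs no data at all:

```sh
$ enuibd design --zygosity homozygous --k 3
k  zygosity    p_shared     expected_candidates
1  homozygous  0.0625       3.678
2  homozygous  0.00664894   1.285
3  homozygous  0.000832924  1.036
```

Sequencing three affected mice is expected to leave a single homozygous
protein-sense candidate — the causative mutation itself.

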