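# Methods

This note records the models implemented in `enuibd`, the defaults and why
they were chosen, what the simulator does and does not emulate, and the
numerical and design decisions a maintainer would want to know.

## Pedigree state space

The pedigree is the standard ENU design: two mutagenized G0 males crossed to
wild-type females give a G1 sire carrying (ENU1, WT1) and a G1 dam carrying
(ENU2, WT2); one G2 pair produces the sequenced G3 mice.  The *non-originals*
(both parents in the pedigree) are the G2 sire, G2 dam and the k G3 mice, so
the hidden state is a binary inheritance vector of 2(k+2) gamete bits, 2^10 =
1024 states for the default k = 3.  The true phase of the G1 founders is
unknowable; we fix a convention (documented in `enuibd.pedigree`) under which
the all-zeros vector gives every G3 mouse the (ENU1, ENU2) genotype.  The
implementation generalizes to 1 ≤ k ≤ 6; beyond that the 2^(2(k+2)) state
space stops being practical, and k beyond 6 buys almost nothing (see the
design model: the unlinked shared-locus probability at k = 6 is already
~3 × 10⁻⁶ for homozygous sharing).

Two symmetries matter downstream:

* **WT1 ↔ WT2**: wild-type haplotypes carry no variants, so states whose
  induced G3 founder pairs agree after a consistent WT1↔WT2 relabeling are
  observationally identical.  We keep the transition algebra on raw states
  and merge posteriors over these equivalence classes before decoding.  The
  equivalence is defined over the G3 mice (the observed individuals): a swap
  of a G2-only assignment is not always realizable as another vector, and
  emissions depend on G2 bits only through the G3 pairs.
* **ENU1 ↔ ENU2** (swapping the two G1 founder couples) is a pedigree
  automorphism under equal ENU priors: posteriors are exactly tied between a
  class and its swapped image.  Decoded region labels ENU1/ENU2 are therefore
  exchangeable; every downstream classification (homozygous-ENU,
  shared-heterozygous, homozygous-WT) is invariant under the swap.  Because
  the tie is exact, the decoder treats posteriors within a relative 1e-9 of
  the maximum as tied and takes the smallest canonical state, which keeps
  decoding stable against floating-point noise.

## The HMM

* **Windows**: 100 kb by default, tiling each autosome (sex chromosomes are
  out of scope; the breeding design makes no claims about X inheritance).
  Window genetic lengths come from linear interpolation of a cumulative-cM
  recombination map; without a map, a uniform 0.5 cM/Mb (the genome-wide
  mouse average) is used.
* **Transitions**: per-bit recombination fraction θ from Haldane's map
  function on the genetic distance between window midpoints.  Haldane is a
  choice of convenience — any monotone map function with θ(0) = 0 behaves
  identically at these scales, and Haldane matches the simulator's
  no-interference crossover process exactly.  The transition matrix is the
  n-bit Kronecker power of [[1−θ, θ], [θ, 1−θ]] and is applied
  axis-by-axis on the reshaped message, keeping memory linear in the state
  count.
* **Emissions**: for each SNP in a window, the state likelihood is
  Σ_H π_H Π_m GL_m(g_m(H, v)) over hypotheses H ∈ {ENU1, ENU2, WT1, WT2,
  NULL}, where g_m(H, v) is the copy number of haplotype H in mouse m's
  founder pair under state v, mapped to genotype 0/0, 0/1 or 1/1, and GL are
  the caller's (linear, max-rescaled) genotype likelihoods.  π_ENU = ν_ENU,
  π_WT = ν_WT, π_NULL the remainder.  Restricting hypotheses to
  single-founder origins plus a false-call hypothesis is the realizable set:
  a true variant arose on exactly one founder haplotype (or is an artifact).
  SNPs within a window are treated as independent; the window likelihood is
  the product.  Empty windows use one virtual site with likelihoods
  (1, 1/10, 1/100) for (0/0, 0/1, 1/1) per mouse — the prior chance that a
  real heterozygous (homozygous) SNP was missed by calling.
* **Priors**: ν_ENU defaults to the estimated ENU rate, 1.54 × 10⁻⁶/bp ×
  window width; ν_WT to 10⁻⁷/bp × width, representing residual post-filter
  wild-type variation.  Both are configurable, and the decoded IBD
  classification is insensitive: varying the assumed ENU rate from 0.25 to
  3.0 mutations/Mb changes the per-window IBD class on under 1% of windows
  in simulation (tested at <5%).  Note the *raw* decoded state identity is
  not a stable quantity in SNP-free stretches — founder-exchange ties and
  near-ties among mixed non-IBD signatures flip it freely; the per-window
  IBD class is the mapper's deliverable.
* **Inference**: scaled forward–backward with a uniform initial
  distribution per chromosome; posteriors merged over WT classes; decoding
  by per-window maximum posterior (not Viterbi — each window's marginal call
  is wanted); smoothing per gamete bit reverts excursions to the opposite
  value whose bp span (start of the first to end of the last excursion
  window) is below 1 Mb, iterated to a fixpoint, leaving chromosome ends
  untouched.  "Within an allele" is read per gamete bit: a bit is an allele
  transmission.  Emissions are floored at 1e-300; an all-zero emission
  window raises an error naming the window.

## Variant filters

The cascade order is: union file → dbSNP → 1 kb cluster filter → quality →
caller bias flags → repeat context → indels → coverage percentiles.  Each
stage sees the survivors of the previous ones; the report tallies removals
per stage, and tallies plus survivors always sum to the input.

Decisions worth recording:

* the default quality threshold is Phred 20 (configurable; recorded in the
  output header);
* the cluster filter removes *every* member of a cluster, not all-but-one —
  clustered calls are a mismapping signature, and keeping one member would
  keep the artifact;
* "high local frequency of bad reads" is consumed as a caller flag
  (`badReads`, alongside `alleleBias`/`strandBias`) rather than recomputed
  from alignments: the package operates downstream of the caller and has no
  BAM access by design;
* coverage percentile bounds (1st/99th of total site depth) are computed
  over the raw input table once per run and recorded in the report.  Strict
  idempotence of the cascade holds when re-filtering with those recorded
  bounds; re-deriving percentiles from the cascade's own output would
  tighten them indefinitely, which is why `FilterConfig` accepts frozen
  bounds;
* repeat context flags homopolymers and perfect di-nucleotide tandem runs of
  ≥20 bp overlapping the site, from a supplied reference sequence or a
  precomputed mask; with neither, the stage passes everything through;
* variant coordinates are 1-based (VCF) throughout this module; region
  outputs are BED-style 0-based half-open, converted at the boundary.

## Rate and spectrum estimators

Within a mouse's homozygous-ENU regions every founder mutation appears
homozygous, so the homozygous-call density there is rate + residual noise;
the same residual is measured in the mouse's homozygous-WT regions
(WT1/WT2 in any combination — they are genetically identical) and
subtracted.  The reported rate is the mean of per-mouse differences, floored
at zero (per-mouse values are reported raw); Mb denominators are exact
bp/1e6.  Region perturbation (±δ Mb at both ends, clip, merge) quantifies
boundary sensitivity.  The spectrum summary (Ts/Tv, A:T fraction, 12-way
substitution matrix) deduplicates sites and refuses indels; biallelic
filtering happens at VCF read time.

## Breeding-design models

Each G2 parent inherits a given G1 founder mutation with probability 1/2
independently, so a G2 pair carries 0/1/2 copies with weights 1/4, 1/2, 1/4
(G2 mice are never homozygous for an ENU mutation).  Conditional on copies,
the count among the pair's 12 offspring is Binomial(12, p) with p = 1/4
(homozygous, both parents carriers) or p = 3/4, 1/2, 0 (carrier).  The
pedigree-wide count M convolves four independent pairs.  Sibling G3 mice are
*not* independent given the parents, but the model conditions on parental
copy number, which captures exactly that dependence; the single-locus
gamete-dropping Monte Carlo in the simulator reproduces the pmf to total
variation < 0.01 at 4 × 10⁵ replicates.

Shared-locus probability for k sequenced mice is the hypergeometric average
Σ_M P(M)·C(M,k)/C(n,k).  Expected shared protein-sense candidates add the
causative mutation as +1: the linked segment around it contributes well
under one further coding mutation, so the +1 absorbs it.  Defaults: rate
1.54/Mb, genome 2650 Mb, protein-sense fraction 1.05% (the product of the
exonic/splice fraction 9.3/647.3 and the 73% of that subset that is
missense/nonsense/splice).  With these constants the homozygous forecast at
k = 3 is 1.036 → 1 candidate; the carrier forecast at k = 6 is 1.76 → ~2.

## Simulator

The generator's defaults are the study conditions the rest of the package
is tested under: ENU rate 1.54 mutations/Mb per mutagenized haplotype with
the ENU spectrum; genome 5 × 50 Mb at 58% AT; 0.5 cM/Mb; background strain
variation at 10/Mb carried by both WT haplotypes; artifact sites at 1/Mb;
one G2 pair producing 12 G3 mice, of which the first 3 affected are
"sequenced" at 24× mean coverage with a 1% per-read error rate.

The 6-class spectrum is anchored on the two measured ENU signature classes —
A:T→G:C 45.0% and A:T→T:A 28.5% — and the remainder allocated so that 78.7%
of mutations fall at A:T sites and transitions are 60% (Ts/Tv 1.50):
A:T→C:G 5.2%, G:C→A:T 15.0%, G:C→T:A and G:C→C:G 3.15% each.  These three
constraints determine the allocation up to the even split of the residual
G:C transversions, which is the least-informative choice.  Background
variation uses the natural Ts/Tv of 2.17 and the genome's base composition.

Meioses place crossovers as a Poisson process on the genetic map with no
interference, matching the Haldane map used in inference.  G1 mice carry
intact founder haplotypes — mutagenesis happened in G0 spermatogonia, so the
G0→G1 transmission passes whole mutagenized chromosomes.  Affected G3 mice
are selected by causative genotype under the trait mode; an attempt with too
few affected mice is retried with fresh randomness up to a bound.

The read model draws per-site, per-mouse depth ~ Poisson(coverage) and
alternate reads ~ Binomial(depth, f) with f = error, 1/2, 1−error by true
genotype; genotype likelihoods are the same binomial model evaluated at the
three genotypes, the call is the maximum-likelihood genotype (missing at
zero depth), and only sites with at least one non-reference call are emitted
— a caller reports nothing otherwise.  Site quality is the Phred-scaled
summed log-likelihood ratio against all-reference.  Artifacts come in two
classes: *systematic* sites, shared across pedigrees of a study, with 3×
coverage (mismapping pileups concentrate reads) and a coherent site-level
alternate fraction; and *private* sites, sample-specific caller noise where
each sample is independently affected with probability 0.4 at a low
alternate fraction.  That split is what real error looks like: coherent
cross-sample artifacts are systematic and recur across pedigrees (hence
caught by the union file and the upper coverage percentile), while private
noise is incoherent.  A fraction of artifact sites carries caller bias
flags, exercising the flag filter.

What the simulator does **not** emulate: read-level data (FASTQ/BAM) and
hence realistic mapping error structure; indels; linked sequencing-error
haplotypes; variable coverage along the genome beyond Poisson noise;
strain-mixture pedigrees.  Passing tests therefore demonstrate correctness
of the inference and estimators under the stated generative model, not
robustness to every failure mode of real sequencing.  Down-sampling of real
reads is emulated only through the coverage parameter (re-emitting the same
truth at lower coverage).

## Problem sizes and determinism

The end-to-end acceptance properties run 20 seeded pedigrees on 250 Mb
genomes (5 chromosomes, k = 3, 1024 states, 2500 windows) at 24× and re-emit
the same pedigrees at 5× — chosen so a pedigree analyzes in a couple of
seconds while leaving the rate estimator ~2900 expected mutations for a
3-SE check.  All randomness flows from `numpy.random.default_rng` seeds
carried in configs; the same seed reproduces byte-identical VCFs, and every
CLI output records its version, seed and parameters in header lines.

## Known limitations

* Only the canonical G0→G3 topology (one analyzed G2 pair, k ≤ 6 sequenced
  G3 siblings); no half-sib or multi-pair analyses.
* Autosomes only.
* A mouse can genuinely possess no homozygous-WT (or homozygous-ENU)
  region, in which case the per-mouse rate recipe is undefined and the
  estimator raises; pool counts across pedigrees when aggregating.
* Region boundaries are window-quantized (±half a window per edge), which
  dilutes single-pedigree rate estimates by a percent or two on small
  genomes.
* The naive shared-variant comparator and candidate tolerance rules share
  the same weak-reference threshold (default 5 reads), deliberately, so the
  two routes differ only in the use of IBD information.
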