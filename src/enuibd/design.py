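"""Closed-form models of mutation transmission through an ENU pedigree.

These models answer design questions for a screening program: how often a
mutation carried by a G1 founder appears among the G3 offspring at a required
zygosity, and how many non-causative candidate mutations will survive an
IBD-sharing analysis when ``k`` affected G3 mice are sequenced.

Model.  Each G2 parent inherits a given G1 mutation independently with
probability 1/2, so a G2 pair carries 0, 1 or 2 copies with probabilities
1/4, 1/2, 1/4 (G2 mice are never homozygous for an ENU mutation).  Conditional
on the pair's copy number, the number of its ``n = litters x litter_size`` G3
offspring carrying the mutation at the required zygosity is binomial with
per-offspring probability

* homozygous: 1/4 if both parents are carriers, else 0;
* carrier (>= 1 allele): 3/4, 1/2 or 0 for 2, 1 or 0 parental copies.

The pedigree-wide count ``M`` over ``n_pairs`` independent G2 pairs is the
convolution of the per-pair mixtures.  The chance that ``k`` sequenced mice
all share an unlinked locus by descent is hypergeometric given ``M``:
``P_shared = sum_M P(M) * C(M, k) / C(n_g3, k)``.  The expected number of
shared candidate mutations follows by multiplying by the genome-wide number of
protein-sense-affecting mutations, plus one for the causative mutation, which
is always shared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import comb
from scipy.stats import binom

__all__ = [
    "PedigreeDesign",
    "Zygosity",
    "per_pair_pmf",
    "pedigree_pmf",
    "shared_locus_probability",
    "expected_candidates",
    "protein_sense_fraction",
    "CandidateForecast",
]

#: per-offspring transmission probability by (zygosity, G2-pair copy number)
_TRANSMISSION_P = {
    ("homozygous", 0): 0.0,
    ("homozygous", 1): 0.0,
    ("homozygous", 2): 0.25,
    ("carrier", 0): 0.0,
    ("carrier", 1): 0.5,
    ("carrier", 2): 0.75,
}

#: prior over the number of copies carried by a G2 pair
_COPY_WEIGHTS = {0: 0.25, 1: 0.5, 2: 0.25}

Zygosity = str  # "homozygous" | "carrier"


def _check_zygosity(zygosity: str) -> str:
    if zygosity not in ("homozygous", "carrier"):
        raise ValueError(f"zygosity must be 'homozygous' or 'carrier', got {zygosity!r}")
    return zygosity


@dataclass(frozen=True)
class PedigreeDesign:
    """Counts describing the breeding scheme: 4 G2 pairs x 3 litters x 4 pups."""

    n_pairs: int = 4
    litters_per_pair: int = 3
    litter_size: int = 4

    def __post_init__(self) -> None:
        if min(self.n_pairs, self.litters_per_pair, self.litter_size) < 1:
            raise ValueError("all design counts must be >= 1")

    @property
    def offspring_per_pair(self) -> int:
        return self.litters_per_pair * self.litter_size

    @property
    def n_g3(self) -> int:
        return self.n_pairs * self.offspring_per_pair


def per_pair_pmf(
    design: PedigreeDesign, zygosity: str, g2_copies: int
) -> np.ndarray:
    """PMF of the number of one G2 pair's offspring carrying the mutation.

    Binomial(litters x litter_size, p) with p determined by zygosity and the
    pair's copy number; a point mass at zero when transmission is impossible.
    """
    _check_zygosity(zygosity)
    if g2_copies not in (0, 1, 2):
        raise ValueError(f"g2_copies must be 0, 1 or 2, got {g2_copies}")
    n = design.offspring_per_pair
    p = _TRANSMISSION_P[zygosity, g2_copies]
    return binom.pmf(np.arange(n + 1), n, p)


def pedigree_pmf(design: PedigreeDesign, zygosity: str) -> np.ndarray:
    """PMF of M, the pedigree-wide G3 count at the required zygosity.

    Mixes the per-pair PMF over the (1/4, 1/2, 1/4) copy-number prior, then
    convolves across the independent G2 pairs.  Support is ``0..n_g3``.
    """
    mixed = sum(
        w * per_pair_pmf(design, zygosity, c) for c, w in _COPY_WEIGHTS.items()
    )
    pmf = np.array([1.0])
    for _ in range(design.n_pairs):
        pmf = np.convolve(pmf, mixed)
    return pmf


def shared_locus_probability(design: PedigreeDesign, zygosity: str, k: int) -> float:
    """Probability that k randomly chosen G3 mice all share an unlinked locus.

    Hypergeometric sampling of k mice without replacement from n_g3, of which
    M carry the locus at the required zygosity, averaged over the transmission
    PMF of M: ``sum_M P(M) C(M,k) / C(n_g3,k)``.
    """
    n = design.n_g3
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    pmf = pedigree_pmf(design, zygosity)
    m = np.arange(n + 1)
    return float(np.sum(pmf * comb(m, k)) / comb(n, k))


@dataclass(frozen=True)
class CandidateForecast:
    """Expected shared candidate-mutation count for a sequencing design."""

    k: int
    zygosity: str
    p_shared: float
    expected_candidates: float
    rate_per_mb: float
    genome_mb: float
    coding_fraction: float


def expected_candidates(
    design: PedigreeDesign,
    zygosity: str,
    k: int,
    rate_per_mb: float = 1.54,
    genome_mb: float = 2650.0,
    coding_fraction: float = 0.0105,
) -> CandidateForecast:
    """Expected number of protein-sense-affecting shared candidate mutations.

    The unlinked component is ``p_shared * genome_mb * rate_per_mb *
    coding_fraction``; one further mutation is added for the causative
    mutation, which is always shared (the small linkage surplus around it,
    ~0.7 mutations genome-wide and far less in coding sequence, is absorbed
    into that +1).
    """
    if min(rate_per_mb, genome_mb) < 0 or not 0 <= coding_fraction <= 1:
        raise ValueError("rate and genome size must be >= 0, coding fraction in [0,1]")
    p_shared = shared_locus_probability(design, zygosity, k)
    expected = p_shared * genome_mb * rate_per_mb * coding_fraction + 1.0
    return CandidateForecast(
        k=k,
        zygosity=zygosity,
        p_shared=p_shared,
        expected_candidates=expected,
        rate_per_mb=rate_per_mb,
        genome_mb=genome_mb,
        coding_fraction=coding_fraction,
    )


def protein_sense_fraction(
    exonic_fraction: float, damaging_proportion: float
) -> float:
    """Fraction of mutations affecting protein sense.

    Product of the fraction of mutations in exons or splice sites and the
    proportion of that subset that is missense, nonsense or splice-altering.
    """
    for x in (exonic_fraction, damaging_proportion):
        if not 0.0 <= x <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    return exonic_fraction * damaging_proportion
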