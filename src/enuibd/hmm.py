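"""Modified Lander-Green HMM for founder-haplotype assignment.

The hidden state at each 100 kb window is the pedigree's inheritance vector
(:mod:`enuibd.pedigree`).  Transitions between adjacent windows factorize over
gamete bits: a bit flips with the recombination fraction ``theta`` derived
from the local genetic distance via Haldane's map function, so the transition
probability between vectors at Hamming distance ``h`` is
``theta**h * (1-theta)**(n_bits-h)``.  The full transition matrix is the
``n_bits``-fold Kronecker power of the 2x2 single-bit kernel and is never
materialized; forward/backward messages are mixed bit by bit, keeping memory
linear in the number of states.

Emissions use the variant caller's genotype likelihoods.  For a window SNP,
the likelihood of a state ``v`` sums over the origin hypotheses H in
{ENU1, ENU2, WT1, WT2, NULL}: the prior of H (``nu_enu`` per ENU haplotype,
``nu_wt`` per WT haplotype, the remainder for a false call) times the product
over mice of the likelihood of the genotype implied by the copy number of H
in the mouse's founder pair under ``v``.  SNPs in a window are treated as
independent.  Windows with no called SNP use a virtual site whose likelihoods
are weighted towards 0/0 (1, 1/10, 1/100 for 0/0, 0/1, 1/1), modelling the
small chance that a real SNP was missed.

Posteriors are computed by the scaled forward-backward algorithm with a
uniform initial distribution per chromosome, summed within WT1/WT2
equivalence classes, decoded by per-window maximum posterior (ties to the
smallest canonical state), and smoothed per gamete bit: an excursion to the
opposite bit value spanning less than 1 Mb is reverted to the flanking value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import GeneticMap, Window, partition_windows
from .pedigree import PedigreeStructure, WTEquivalence, founder_pair_table
from .variants import VariantTable

__all__ = [
    "EmissionPriors",
    "recombination_fraction",
    "transition_probability",
    "window_emission",
    "forward_backward",
    "decode",
    "smooth",
    "map_states",
    "PosteriorField",
    "StatePath",
]

_EMISSION_FLOOR = 1e-300


@dataclass(frozen=True)
class EmissionPriors:
    """Per-window SNP priors for the emission model.

    ``nu_enu`` / ``nu_wt`` are the prior probabilities that a given ENU / WT
    founder haplotype carries a SNP in a window; the null (no true variant)
    prior is the remainder.  Defaults correspond to the estimated ENU rate of
    1.54 mutations/Mb and a residual post-filter wild-type rate of 0.1/Mb in
    100 kb windows.
    """

    nu_enu: float = 0.154
    nu_wt: float = 0.01
    miss_het: float = 0.1
    miss_hom: float = 0.01

    def __post_init__(self) -> None:
        if self.p_null < 0 or min(self.nu_enu, self.nu_wt) < 0:
            raise ValueError("SNP priors must be >= 0 and sum to <= 1")

    @property
    def p_null(self) -> float:
        return 1.0 - 2.0 * self.nu_enu - 2.0 * self.nu_wt

    @classmethod
    def from_rates(
        cls,
        enu_per_mb: float = 1.54,
        wt_per_mb: float = 0.1,
        width: int = 100_000,
        miss_het: float = 0.1,
        miss_hom: float = 0.01,
    ) -> "EmissionPriors":
        scale = width / 1e6
        return cls(enu_per_mb * scale, wt_per_mb * scale, miss_het, miss_hom)

    @property
    def weights(self) -> np.ndarray:
        """Hypothesis priors ordered (ENU1, ENU2, WT1, WT2, NULL)."""
        return np.array(
            [self.nu_enu, self.nu_enu, self.nu_wt, self.nu_wt, self.p_null]
        )


def recombination_fraction(genetic_length: float) -> float:
    """Haldane map function: theta = (1 - exp(-2 d)) / 2, d in Morgans."""
    if genetic_length < 0:
        raise ValueError("genetic length must be >= 0")
    return 0.5 * (1.0 - np.exp(-2.0 * genetic_length))


def transition_probability(v_from: int, v_to: int, theta: float, n_bits: int) -> float:
    """theta**h * (1-theta)**(n_bits - h) for Hamming distance h."""
    if not 0 <= theta <= 0.5:
        raise ValueError("theta must lie in [0, 0.5]")
    h = bin((int(v_from) ^ int(v_to)) & ((1 << n_bits) - 1)).count("1")
    if int(v_from) >> n_bits or int(v_to) >> n_bits:
        raise ValueError("state exceeds n_bits")
    return float(theta**h * (1.0 - theta) ** (n_bits - h))


def genotype_hypothesis_table(structure: PedigreeStructure) -> np.ndarray:
    """Implied genotype index per (state, hypothesis, mouse).

    Shape (n_states, 5, n_g3); entry = copy number (0, 1 or 2) of the
    hypothesis haplotype in the mouse's founder pair, which indexes the
    (0/0, 0/1, 1/1) likelihood triple.  Hypothesis 4 (NULL) implies 0/0.
    """
    pairs = founder_pair_table(structure)  # (S, k, 2)
    geno = np.zeros((structure.n_states, 5, structure.n_g3), dtype=np.int8)
    for hyp in range(4):
        geno[:, hyp, :] = (pairs == hyp).sum(axis=2)
    return geno


def _snp_likelihoods(
    gl: np.ndarray, geno: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Per-SNP state likelihoods.

    gl: (n_snp, k, 3) linear genotype likelihoods; geno: (S, 5, k);
    returns (n_snp, S).
    """
    n_snp, k, _ = gl.shape
    idx_n = np.arange(n_snp)[:, None, None, None]
    idx_m = np.arange(k)[None, None, None, :]
    picked = gl[idx_n, idx_m, geno[None]]  # (n_snp, S, 5, k)
    return picked.prod(axis=3) @ weights


def window_emission(
    gl: np.ndarray | None,
    geno: np.ndarray,
    priors: EmissionPriors,
) -> np.ndarray:
    """Emission likelihood of every state for one window.

    ``gl`` holds the window's SNP likelihoods, shape (n_snp, k, 3); None or
    empty means no SNP was called and the missed-SNP virtual site is used.
    The result is rescaled to a maximum of 1 per window (forward-backward
    scaling makes emissions only meaningful up to a constant).
    """
    k = geno.shape[2]
    if gl is None or len(gl) == 0:
        gl = np.tile(
            np.array([1.0, priors.miss_het, priors.miss_hom]), (1, k, 1)
        )
    if not np.isfinite(gl).all():
        raise ValueError("non-finite genotype likelihood in window")
    liks = _snp_likelihoods(np.asarray(gl, dtype=float), geno, priors.weights)
    # normalize per SNP before taking the product to avoid underflow
    m = liks.max(axis=1, keepdims=True)
    if np.any(m <= 0):
        raise ValueError("window has a SNP with zero likelihood under all states")
    out = np.prod(liks / m, axis=0)
    return np.maximum(out, _EMISSION_FLOOR)


def _mix_bits(x: np.ndarray, theta: float, n_bits: int) -> np.ndarray:
    """Apply the Kronecker-factorized transition operator to a state vector."""
    if theta == 0.0:
        return x
    y = x.reshape((2,) * n_bits)
    for axis in range(n_bits):
        y = (1.0 - theta) * y + theta * np.flip(y, axis=axis)
    return y.reshape(-1)


@dataclass
class PosteriorField:
    """Per-window posteriors over WT-collapsed state classes."""

    windows: list[Window]
    posteriors: np.ndarray  # (n_windows, n_classes)
    equivalence: WTEquivalence
    thetas: np.ndarray  # (n_windows - 1,) inter-window recombination fractions


@dataclass
class StatePath:
    """Decoded canonical inheritance state per window."""

    windows: list[Window]
    states: np.ndarray  # (n_windows,) canonical state ints
    posterior: np.ndarray  # (n_windows,) posterior of the chosen class
    structure: PedigreeStructure


def _window_thetas(windows: list[Window]) -> np.ndarray:
    """Recombination fractions between consecutive window midpoints."""
    gl = np.array([w.genetic_length for w in windows])
    d = 0.5 * (gl[:-1] + gl[1:])
    return 0.5 * (1.0 - np.exp(-2.0 * d))


def forward_backward(
    windows: list[Window],
    window_gls: list[np.ndarray | None],
    priors: EmissionPriors,
    structure: PedigreeStructure,
    equivalence: WTEquivalence | None = None,
) -> PosteriorField:
    """Exact HMM posteriors for one chromosome's windows.

    ``window_gls[i]`` is the (n_snp, k, 3) likelihood array of window i (None
    when empty).  Posteriors are summed within WT1/WT2 equivalence classes.
    """
    if not windows:
        raise ValueError("need at least one window")
    if equivalence is None:
        equivalence = WTEquivalence(structure)
    geno = genotype_hypothesis_table(structure)
    n_bits, n_states = structure.n_bits, structure.n_states
    T = len(windows)
    emissions = np.empty((T, n_states))
    for t in range(T):
        em = window_emission(window_gls[t], geno, priors)
        if not em.any():
            raise ValueError(
                f"all-zero emission in window {windows[t].chrom}:"
                f"{windows[t].start}-{windows[t].end}"
            )
        emissions[t] = em
    thetas = _window_thetas(windows)

    fwd = np.empty((T, n_states))
    f = emissions[0] / n_states
    fwd[0] = f / f.sum()
    for t in range(1, T):
        f = _mix_bits(fwd[t - 1], thetas[t - 1], n_bits) * emissions[t]
        fwd[t] = f / f.sum()
    bwd = np.empty((T, n_states))
    bwd[-1] = 1.0 / n_states
    for t in range(T - 2, -1, -1):
        b = _mix_bits(bwd[t + 1] * emissions[t + 1], thetas[t], n_bits)
        bwd[t] = b / b.sum()

    post = fwd * bwd
    post /= post.sum(axis=1, keepdims=True)
    merged = np.zeros((T, equivalence.n_classes))
    for t in range(T):
        merged[t] = np.bincount(
            equivalence.class_id, weights=post[t], minlength=equivalence.n_classes
        )
    merged /= merged.sum(axis=1, keepdims=True)
    return PosteriorField(windows, merged, equivalence, thetas)


def decode(field: PosteriorField, structure: PedigreeStructure) -> StatePath:
    """Per-window maximum-posterior canonical state.

    Classes are ordered by canonical state and ties break to the numerically
    smallest canonical state.  Exact ties occur structurally (swapping the
    two mutagenized founders is a model symmetry), so near-ties within a
    1e-9 relative band are treated as ties to keep decoding stable against
    floating-point noise.
    """
    post = field.posteriors
    m = post.max(axis=1, keepdims=True)
    best = (post >= m * (1.0 - 1e-9)).argmax(axis=1)  # first near-maximal
    states = field.equivalence.class_reps[best]
    chosen = post[np.arange(len(best)), best]
    return StatePath(field.windows, states, chosen, structure)


def smooth(path: StatePath, max_gap: int = 1_000_000) -> StatePath:
    """Revert sub-1 Mb excursions of individual gamete bits.

    Operates per gamete bit along the chromosome: a maximal run of the
    opposite bit value flanked on both sides by the same value, whose bp span
    (run start to run end) is below ``max_gap``, is set to the flanking
    value; applied to a fixpoint.  Chromosome ends are left untouched.  The
    resulting vectors are re-canonicalized.
    """
    structure = path.structure
    n_bits = structure.n_bits
    bits = ((path.states[:, None] >> np.arange(n_bits)) & 1).astype(np.int8)
    starts = np.array([w.start for w in path.windows])
    ends = np.array([w.end for w in path.windows])
    for b in range(n_bits):
        col = bits[:, b]
        stable = False
        while not stable:
            stable = True
            boundaries = np.flatnonzero(np.diff(col) != 0) + 1
            runs = np.concatenate([[0], boundaries, [len(col)]])
            # interior runs only; flanks of a binary signal's run are equal
            for r in range(1, len(runs) - 2):
                i, j = int(runs[r]), int(runs[r + 1])  # run is [i, j)
                span = ends[j - 1] - starts[i]
                if span < max_gap:
                    col[i:j] = col[i - 1]
                    stable = False
                    break
    states = (bits * (1 << np.arange(n_bits))).sum(axis=1)
    eq = WTEquivalence(structure)
    canon = eq.canonical[states]
    return StatePath(path.windows, canon, path.posterior.copy(), structure)


def map_states(
    table: VariantTable,
    structure: PedigreeStructure,
    chrom_lengths: dict[str, int],
    gmap: GeneticMap | None = None,
    width: int = 100_000,
    priors: EmissionPriors | None = None,
    smooth_gap: int = 1_000_000,
) -> tuple[pd.DataFrame, dict[str, StatePath]]:
    """Run the full mapper: windows, forward-backward, decode, smooth.

    ``table`` must be the filtered SNV table whose samples are the sequenced
    G3 mice in pedigree order.  Returns a per-window state table (chrom,
    start, end, state, posterior) and the smoothed per-chromosome paths.
    """
    if table.n_samples != structure.n_g3:
        raise ValueError(
            f"table has {table.n_samples} samples but structure expects "
            f"{structure.n_g3} G3 mice"
        )
    if priors is None:
        priors = EmissionPriors.from_rates(width=width)
    windows_by_chrom = partition_windows(chrom_lengths, gmap, width)
    equivalence = WTEquivalence(structure)
    paths: dict[str, StatePath] = {}
    rows = []
    snv = table.subset(np.flatnonzero(table.is_snv))
    for chrom, windows in windows_by_chrom.items():
        on_chrom = np.flatnonzero(snv.chrom == chrom)
        widx = (snv.pos[on_chrom] - 1) // width
        gls: list[np.ndarray | None] = [None] * len(windows)
        for w in np.unique(widx):
            gls[int(w)] = snv.gl[on_chrom[widx == w]]
        field = forward_backward(windows, gls, priors, structure, equivalence)
        path = smooth(decode(field, structure), smooth_gap)
        paths[chrom] = path
        for w, s, p in zip(windows, path.states, path.posterior):
            rows.append((chrom, w.start, w.end, int(s), float(p)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "state", "posterior"])
    return df, paths
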