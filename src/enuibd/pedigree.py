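"""Pedigree state space for ENU screens.

An ENU pedigree starts from two mutagenized G0 males crossed to wild-type
females.  The resulting G1 pair together carries four founder haplotypes at
every locus: two mutagenized ones (``ENU1`` from the G1 sire, ``ENU2`` from the
G1 dam) and two wild-type ones (``WT1``, ``WT2``).  A G2 sire and dam and the
``k`` sequenced G3 offspring are the pedigree's *non-originals* (both parents
in the pedigree); each contributes two gametes, so local inheritance is encoded
by a binary vector of ``2*(k+2)`` bits -- the hidden state of the Lander-Green
HMM.  Bit value 0 means the gamete carries grand-paternal DNA at the locus, 1
grand-maternal.

Phase convention (the true phase is arbitrary; this one is fixed so that
decoded states are reproducible): the G1 sire carries (ENU1, WT1) and the G1
dam carries (ENU2, WT2), each with the mutagenized haplotype as its "paternal"
one.  Bits are ordered pairwise (paternal gamete, maternal gamete) for the
G2 sire, G2 dam, then G3_1 .. G3_k; bit ``i`` of state ``s`` is
``(s >> i) & 1``.  States are enumerated in binary counting order
``0 .. 2**n_bits - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = [
    "FounderHaplotype",
    "PedigreeStructure",
    "enumerate_states",
    "founder_pair",
    "founder_pair_table",
    "hamming_distance",
    "WTEquivalence",
    "wt_equivalence_class",
]

MAX_G3 = 6  # 2**(2*(6+2)) = 65536 states; beyond this the HMM is impractical


class FounderHaplotype(IntEnum):
    """The four founder haplotypes segregating in an ENU pedigree."""

    ENU1 = 0
    ENU2 = 1
    WT1 = 2
    WT2 = 3

    @property
    def mutagenized(self) -> bool:
        return self in (FounderHaplotype.ENU1, FounderHaplotype.ENU2)


#: WT1 <-> WT2 relabeling (ENU labels fixed).
_WT_SWAP = np.array([0, 1, 3, 2], dtype=np.int8)


@dataclass(frozen=True)
class PedigreeStructure:
    """The fixed G0->G3 breeding design with ``n_g3`` sequenced G3 mice.

    Non-originals are ordered (G2 sire, G2 dam, G3_1 .. G3_k).
    """

    n_g3: int

    def __post_init__(self) -> None:
        if not 1 <= self.n_g3 <= MAX_G3:
            raise ValueError(
                f"n_g3 must be in [1, {MAX_G3}], got {self.n_g3}"
            )

    @property
    def n_non_originals(self) -> int:
        return self.n_g3 + 2

    @property
    def n_bits(self) -> int:
        return 2 * self.n_non_originals

    @property
    def n_states(self) -> int:
        return 1 << self.n_bits


def enumerate_states(structure: PedigreeStructure) -> np.ndarray:
    """All inheritance vectors, as integers in binary counting order."""
    return np.arange(structure.n_states, dtype=np.int64)


def _bits(states: np.ndarray, n_bits: int) -> np.ndarray:
    """(n_states, n_bits) bit matrix; column i is bit i."""
    states = np.asarray(states, dtype=np.int64)
    return (states[..., None] >> np.arange(n_bits)) & 1


def founder_pair_table(structure: PedigreeStructure) -> np.ndarray:
    """Founder-haplotype pair of every G3 mouse under every state.

    Returns an int8 array of shape ``(n_states, n_g3, 2)`` whose entries are
    :class:`FounderHaplotype` values; the last axis is (paternally derived
    haplotype, maternally derived haplotype).  The G2 sire's two bits select
    ENU1 (0) vs WT1 (1) and ENU2 (0) vs WT2 (1); the G2 dam's select ENU2 (0)
    vs WT2 (1) and ENU1 (0) vs WT1 (1).  A G3's paternal bit selects the G2
    sire's first (0) or second (1) haplotype slot, and its maternal bit the
    same for the G2 dam, so the all-zeros vector gives every G3 the
    (ENU1, ENU2) genotype.
    """
    b = _bits(enumerate_states(structure), structure.n_bits)
    enu1, enu2 = FounderHaplotype.ENU1, FounderHaplotype.ENU2
    wt1, wt2 = FounderHaplotype.WT1, FounderHaplotype.WT2
    # G2 haplotype slots, shape (n_states,).  The sire's slots are ordered
    # (from G1 sire: ENU1/WT1, from G1 dam: ENU2/WT2); the dam's slots are
    # mirrored (ENU2/WT2 first) so that the all-zeros vector yields the
    # (ENU1, ENU2) genotype in every G3 mouse.
    g2 = {
        ("sire", 0): np.where(b[:, 0] == 0, enu1, wt1),
        ("sire", 1): np.where(b[:, 1] == 0, enu2, wt2),
        ("dam", 0): np.where(b[:, 2] == 0, enu2, wt2),
        ("dam", 1): np.where(b[:, 3] == 0, enu1, wt1),
    }
    out = np.empty((structure.n_states, structure.n_g3, 2), dtype=np.int8)
    for m in range(structure.n_g3):
        pbit = b[:, 2 * (m + 2)]
        mbit = b[:, 2 * (m + 2) + 1]
        out[:, m, 0] = np.where(pbit == 0, g2["sire", 0], g2["sire", 1])
        out[:, m, 1] = np.where(mbit == 0, g2["dam", 0], g2["dam", 1])
    return out


def founder_pair(
    structure: PedigreeStructure, state: int, g3_index: int
) -> tuple[FounderHaplotype, FounderHaplotype]:
    """Unordered founder-haplotype pair of G3 mouse ``g3_index`` (0-based)."""
    if not 0 <= g3_index < structure.n_g3:
        raise IndexError(f"g3_index {g3_index} out of range for k={structure.n_g3}")
    if not 0 <= state < structure.n_states:
        raise ValueError(f"state {state} out of range")
    pair = founder_pair_table(structure)[state, g3_index]
    a, b = sorted(int(x) for x in pair)
    return FounderHaplotype(a), FounderHaplotype(b)


def hamming_distance(v1: int, v2: int) -> int:
    """Number of gamete bits at which two inheritance vectors differ.

    Equals the number of recombinations required for the transition.
    """
    return int(bin(int(v1) ^ int(v2)).count("1"))


def _signatures(structure: PedigreeStructure) -> tuple[np.ndarray, np.ndarray]:
    """Per-state G3 genotype signatures, plain and WT1<->WT2 relabeled.

    A signature is the tuple over G3 mice of the *unordered* founder pair,
    encoded as ``4*min + max``; shape (n_states, n_g3).
    """
    table = founder_pair_table(structure)
    lo = np.minimum(table[..., 0], table[..., 1])
    hi = np.maximum(table[..., 0], table[..., 1])
    sig = (4 * lo + hi).astype(np.int16)
    sw = _WT_SWAP[table]
    lo = np.minimum(sw[..., 0], sw[..., 1])
    hi = np.maximum(sw[..., 0], sw[..., 1])
    sig_swapped = (4 * lo + hi).astype(np.int16)
    return sig, sig_swapped


class WTEquivalence:
    """Partition of the state space by WT1/WT2 indistinguishability.

    Two states are equivalent when they induce, for every G3 mouse, the same
    unordered founder pair -- either exactly or after relabeling WT1 <-> WT2
    consistently across all mice.  Wild-type haplotypes carry no variants, so
    equivalent states are observationally identical and their posteriors are
    merged before decoding.

    Attributes
    ----------
    canonical : (n_states,) int64
        Numerically smallest equivalent state, per state.
    class_id : (n_states,) int64
        Index of each state's class; classes are ordered by their canonical
        state, so ``class_reps`` is increasing.
    class_reps : (n_classes,) int64
        Canonical representative state of each class.
    """

    def __init__(self, structure: PedigreeStructure):
        self.structure = structure
        sig, sig_swapped = _signatures(structure)
        by_sig: dict[bytes, list[int]] = {}
        for s in range(structure.n_states):
            by_sig.setdefault(sig[s].tobytes(), []).append(s)
        canonical = np.empty(structure.n_states, dtype=np.int64)
        for s in range(structure.n_states):
            members = by_sig[sig[s].tobytes()]
            partners = by_sig.get(sig_swapped[s].tobytes(), ())
            canonical[s] = min(members[0], partners[0]) if partners else members[0]
        self.canonical = canonical
        self.class_reps, self.class_id = np.unique(canonical, return_inverse=True)

    @property
    def n_classes(self) -> int:
        return len(self.class_reps)


def wt_equivalence_class(structure: PedigreeStructure, state: int) -> int:
    """Canonical (numerically smallest) state equivalent to ``state``."""
    return int(WTEquivalence(structure).canonical[state])
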