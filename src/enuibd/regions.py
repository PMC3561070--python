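"""IBD region calling and candidate-variant selection.

A decoded state path assigns each window a founder-haplotype pair per G3
mouse.  A window is *IBD homozygous* for an ENU founder when every sequenced
mouse carries two copies of that founder's haplotype, and *IBD heterozygous
shared* when every mouse carries at least one copy but the window is not
homozygous.  Maximal runs of same-class windows form IBD regions (BED-style
0-based half-open coordinates).  Candidate causative variants are the
filtered SNVs that lie inside a region of matching zygosity and are carried
by every mouse, tolerating missing genotypes and weakly supported reference
calls exactly as the naive shared-variant rule does.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hmm import StatePath
from .pedigree import FounderHaplotype, PedigreeStructure, founder_pair_table
from .variants import MISSING, VariantTable

__all__ = [
    "classify_pairs",
    "call_ibd_regions",
    "per_mouse_homozygous_regions",
    "candidate_variants",
    "naive_shared_variants",
    "merge_adjacent",
    "merge_intervals",
    "region_mb",
]

HOM_CLASSES = ("HOM_ENU1", "HOM_ENU2")
HET_CLASSES = ("HET_SHARED_ENU1", "HET_SHARED_ENU2")


def classify_pairs(pairs: np.ndarray) -> str | None:
    """IBD class of one locus given the (n_mice, 2) founder-label array.

    Homozygous classes take precedence; if all mice share both ENU founders
    heterozygously the ENU1 class is reported (documented tie-break).
    """
    pairs = np.asarray(pairs)
    for label, name in ((FounderHaplotype.ENU1, "HOM_ENU1"),
                        (FounderHaplotype.ENU2, "HOM_ENU2")):
        if np.all(pairs == int(label)):
            return name
    for label, name in ((FounderHaplotype.ENU1, "HET_SHARED_ENU1"),
                        (FounderHaplotype.ENU2, "HET_SHARED_ENU2")):
        if np.all((pairs == int(label)).any(axis=1)):
            return name
    return None


def merge_adjacent(df: pd.DataFrame) -> pd.DataFrame:
    """Merge bookended or overlapping intervals of the same class."""
    if df.empty:
        return df.reset_index(drop=True)
    out = []
    for (chrom, cls), grp in df.groupby(["chrom", "cls"], sort=False):
        grp = grp.sort_values("start")
        cur_s, cur_e = None, None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e, cls))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e, cls))
    res = pd.DataFrame(out, columns=["chrom", "start", "end", "cls"])
    chrom_order = {c: i for i, c in enumerate(pd.unique(df["chrom"]))}
    return res.sort_values(
        by=["chrom", "start"],
        key=lambda s: s.map(chrom_order) if s.name == "chrom" else s,
    ).reset_index(drop=True)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/bookended intervals regardless of class."""
    tmp = df.assign(cls="_")
    res = merge_adjacent(tmp)
    return res.drop(columns="cls")


def region_mb(df: pd.DataFrame) -> float:
    """Total span in Mb (exact bp / 1e6)."""
    if df.empty:
        return 0.0
    return float((df["end"] - df["start"]).sum() / 1e6)


def call_ibd_regions(paths: dict[str, StatePath],
                     structure: PedigreeStructure) -> pd.DataFrame:
    """Maximal IBD regions from smoothed per-chromosome state paths."""
    table = founder_pair_table(structure)
    rows = []
    for chrom, path in paths.items():
        for w, s in zip(path.windows, path.states):
            cls = classify_pairs(table[int(s)])
            if cls is not None:
                rows.append((chrom, w.start, w.end, cls))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "cls"])
    out = merge_adjacent(df)
    out["n_mice"] = structure.n_g3
    return out


def per_mouse_homozygous_regions(
    paths: dict[str, StatePath], structure: PedigreeStructure
) -> list[dict[str, pd.DataFrame]]:
    """Per-G3-mouse homozygous-ENU and homozygous-WT regions.

    A mouse is homozygous ENU at a window when its founder pair is
    (ENUi, ENUi) for either mutagenized founder, and homozygous WT when both
    haplotypes are wild type (WT1/WT2 in any combination, which are
    genetically identical).
    """
    table = founder_pair_table(structure)
    wt = (int(FounderHaplotype.WT1), int(FounderHaplotype.WT2))
    out = []
    for m in range(structure.n_g3):
        rows = []
        for chrom, path in paths.items():
            pairs = table[path.states, m]  # (n_win, 2)
            is_enu_hom = (
                (pairs[:, 0] == pairs[:, 1])
                & np.isin(pairs[:, 0],
                          [int(FounderHaplotype.ENU1), int(FounderHaplotype.ENU2)])
            )
            is_wt_hom = np.isin(pairs, wt).all(axis=1)
            for w, eh, wh in zip(path.windows, is_enu_hom, is_wt_hom):
                if eh:
                    rows.append((chrom, w.start, w.end, "HOM_ENU"))
                elif wh:
                    rows.append((chrom, w.start, w.end, "HOM_WT"))
        df = merge_adjacent(
            pd.DataFrame(rows, columns=["chrom", "start", "end", "cls"])
        )
        out.append({
            "hom_enu": df[df["cls"] == "HOM_ENU"].reset_index(drop=True),
            "hom_wt": df[df["cls"] == "HOM_WT"].reset_index(drop=True),
        })
    return out


def _in_regions(table: VariantTable, regions: pd.DataFrame) -> np.ndarray:
    """Mask of variants (1-based pos) inside any 0-based half-open region."""
    mask = np.zeros(table.n_sites, dtype=bool)
    for chrom, grp in regions.groupby("chrom", sort=False):
        on = np.flatnonzero(table.chrom == chrom)
        if len(on) == 0:
            continue
        pos0 = table.pos[on] - 1
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        hit = ((pos0[:, None] >= starts[None, :])
               & (pos0[:, None] < ends[None, :])).any(axis=1)
        mask[on[hit]] = True
    return mask


def _tolerated(table: VariantTable, min_ref_reads: int) -> np.ndarray:
    """Per-call tolerance mask: missing, or a weak reference call with at
    least one supporting variant read and < ``min_ref_reads`` reference reads."""
    weak_ref = ((table.gt == 0) & (table.alt_support >= 1)
                & (table.ref_support < min_ref_reads))
    return (table.gt == MISSING) | weak_ref


def naive_shared_variants(
    table: VariantTable, min_ref_reads: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """The non-IBD comparator: variants shared by all mice, with tolerance.

    A SNV is *shared* when at least one mouse has a variant genotype and every
    remaining mouse is variant, has no genotype, or has a reference call with
    >= 1 supporting variant read and fewer than ``min_ref_reads`` reference
    reads.  Returns boolean masks (homozygous-shared, heterozygous-shared):
    homozygous-shared requires every variant call to be 1/1.
    """
    tol = _tolerated(table, min_ref_reads)
    is_var = (table.gt == 1) | (table.gt == 2)
    ok = (is_var | tol).all(axis=1) & is_var.any(axis=1) & table.is_snv
    hom = ok & ((table.gt == 2) | tol).all(axis=1) & (table.gt == 2).any(axis=1)
    het = ok & ~hom
    return hom, het


def candidate_variants(
    table: VariantTable,
    regions: pd.DataFrame,
    structure: PedigreeStructure,
    min_ref_reads: int = 5,
    exons: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Candidate causative mutations inside matching IBD regions.

    Homozygous candidates: SNVs homozygous-shared by the naive rule inside a
    homozygous region; heterozygous candidates: SNVs shared (>= 1 variant
    allele per mouse, with tolerance) inside a shared-heterozygous region and
    not homozygous candidates.  Variants inside a homozygous region whose
    zygosity is contradicted by a well-covered mouse (depth >=
    ``min_ref_reads``) are returned separately as the rejected-inconsistent
    report.  ``exons`` (BED-style) adds a boolean ``coding`` column.
    """
    hom_shared, het_shared = naive_shared_variants(table, min_ref_reads)
    in_hom = _in_regions(table, regions[regions["cls"].isin(HOM_CLASSES)])
    in_het = _in_regions(table, regions[regions["cls"].isin(HET_CLASSES)])
    hom_cand = hom_shared & in_hom
    het_cand = het_shared & in_het & ~hom_cand

    # in a homozygous region, a variant carried by some mice but ruled out by
    # a confidently reference/heterozygous, well-covered mouse is inconsistent
    some_alt = ((table.gt == 1) | (table.gt == 2)).any(axis=1)
    contradicts = ((table.gt != 2) & (table.gt != MISSING)
                   & (table.depth >= min_ref_reads)
                   & ~_tolerated(table, min_ref_reads))
    inconsistent = in_hom & some_alt & ~hom_cand & contradicts.any(axis=1) \
        & table.is_snv

    def frame(mask: np.ndarray, zygosity: np.ndarray | str) -> pd.DataFrame:
        idx = np.flatnonzero(mask)
        df = pd.DataFrame({
            "chrom": table.chrom[idx],
            "pos": table.pos[idx],
            "ref": table.ref[idx],
            "alt": table.alt[idx],
            "zygosity_class": zygosity if isinstance(zygosity, str)
            else zygosity[idx],
        })
        if table.origin is not None:
            df["origin"] = table.origin[idx]
        if exons is not None:
            sub = table.subset(idx)
            df["coding"] = _in_regions(sub, exons.assign(cls="exon"))
        return df

    zyg = np.where(hom_cand, "homozygous", "heterozygous")
    candidates = frame(hom_cand | het_cand, zyg)
    rejected = frame(inconsistent, "inconsistent")
    return candidates, rejected
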