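"""ENU mutation-rate and spectrum estimators.

The mutation rate is estimated by background subtraction: within each
sequenced mouse's homozygous-ENU regions every ENU mutation on the shared
founder haplotype appears as a homozygous call, so the homozygous-variant
density there equals the ENU rate plus whatever residual background and
artifact calls survive the filters; the same residual is measured in the
mouse's homozygous-WT regions and subtracted.  The reported rate is the mean
of the per-mouse differences.

The spectrum summary characterizes the mutations found in homozygous-ENU
regions: the transition:transversion ratio, the fraction of mutations at A:T
reference sites, and the full 12-substitution count matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import merge_intervals, region_mb
from .variants import VariantTable

__all__ = ["RateEstimate", "SpectrumSummary", "estimate_rate",
           "perturb_regions", "spectrum"]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = ("A", "C", "G", "T")


@dataclass
class RateEstimate:
    """Background-subtracted ENU mutation-rate estimate, mutations/Mb."""

    per_mouse: list[tuple[float, float, float]]  # (enu_density, wt_density, diff)
    mean_rate: float
    enu_mb: list[float]
    wt_mb: list[float]
    enu_counts: list[int]
    wt_counts: list[int]

    def to_tsv(self) -> str:
        lines = ["mouse\tenu_density\twt_density\tdifference\tenu_mb\twt_mb"]
        for i, (e, w, d) in enumerate(self.per_mouse):
            lines.append(
                f"G3_{i + 1}\t{e:.4f}\t{w:.4f}\t{d:.4f}"
                f"\t{self.enu_mb[i]:.3f}\t{self.wt_mb[i]:.3f}"
            )
        lines.append(f"mean_rate\t{self.mean_rate:.4f}")
        return "\n".join(lines) + "\n"


def homozygous_count_in(table: VariantTable, mouse: int,
                        regions: pd.DataFrame) -> int:
    """Number of homozygous-alt SNV calls of one mouse inside regions."""
    from .regions import _in_regions

    if regions.empty:
        return 0
    mask = _in_regions(table, regions)
    return int(((table.gt[:, mouse] == 2) & mask & table.is_snv).sum())


_count_hom_in = homozygous_count_in


def estimate_rate(
    table: VariantTable,
    per_mouse_hom_enu: list[pd.DataFrame],
    per_mouse_hom_wt: list[pd.DataFrame],
) -> RateEstimate:
    """Per-mouse homozygous-variant densities and their mean difference.

    ``table`` is the filtered call set; the region lists hold one BED-style
    frame per sequenced mouse.  The mean rate over mice is floored at zero;
    per-mouse differences are reported raw.
    """
    if len(per_mouse_hom_enu) != len(per_mouse_hom_wt):
        raise ValueError("per-mouse region lists must have equal length")
    per_mouse, enu_mb, wt_mb, enu_n, wt_n = [], [], [], [], []
    for m, (enu_df, wt_df) in enumerate(zip(per_mouse_hom_enu, per_mouse_hom_wt)):
        e_mb = region_mb(enu_df)
        w_mb = region_mb(wt_df)
        if e_mb == 0 or w_mb == 0:
            raise ValueError(f"mouse {m} has zero span in a region class")
        ne = _count_hom_in(table, m, enu_df)
        nw = _count_hom_in(table, m, wt_df)
        e_d, w_d = ne / e_mb, nw / w_mb
        per_mouse.append((e_d, w_d, e_d - w_d))
        enu_mb.append(e_mb)
        wt_mb.append(w_mb)
        enu_n.append(ne)
        wt_n.append(nw)
    mean_rate = max(float(np.mean([d for _, _, d in per_mouse])), 0.0)
    return RateEstimate(per_mouse, mean_rate, enu_mb, wt_mb, enu_n, wt_n)


def perturb_regions(
    regions: pd.DataFrame,
    delta_mb: float,
    chrom_lengths: dict[str, int],
) -> tuple[pd.DataFrame, int]:
    """Grow (or shrink, negative delta) every region symmetrically.

    Each region's ends move outward by ``delta_mb`` megabases, are clipped to
    the chromosome bounds, and overlapping regions are merged.  Over-shrunk
    regions are dropped; their count is returned alongside the result.
    """
    delta = int(round(delta_mb * 1e6))
    rows = []
    dropped = 0
    for _, r in regions.iterrows():
        s = max(0, int(r["start"]) - delta)
        e = min(chrom_lengths[r["chrom"]], int(r["end"]) + delta)
        if e <= s:
            dropped += 1
            continue
        rows.append((r["chrom"], s, e))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return merge_intervals(out) if not out.empty else out, dropped


@dataclass
class SpectrumSummary:
    """Substitution spectrum of a set of SNVs."""

    n: int
    ts: int
    tv: int
    at_count: int
    sub_matrix: pd.DataFrame  # 12 ordered (ref, alt) counts

    @property
    def ts_tv(self) -> float | None:
        return self.ts / self.tv if self.tv else None

    @property
    def at_fraction(self) -> float | None:
        return self.at_count / self.n if self.n else None

    def class_fraction(self, name: str) -> float | None:
        """Fraction in a strand-symmetric class, e.g. ``"AT>GC"``."""
        if self.n == 0:
            return None
        pair, alt_pair = name.split(">")
        combos = {(pair[0], alt_pair[0]), (pair[1], alt_pair[1])}
        c = sum(
            int(self.sub_matrix.loc[r, a]) for r, a in combos
        )
        return c / self.n


def spectrum(table: VariantTable) -> SpectrumSummary:
    """Spectrum summary of the (SNV-only) variants in homozygous-ENU regions.

    Raises on indels; multi-allelic records are already excluded at VCF read
    time, and duplicate (chrom, pos) records are counted once.
    """
    if table.n_sites and not bool(table.is_snv.all()):
        raise ValueError("spectrum requires SNVs only; remove indels first")
    seen = set()
    keep = []
    for i, (c, p) in enumerate(zip(table.chrom, table.pos)):
        if (c, p) not in seen:
            seen.add((c, p))
            keep.append(i)
    ref = table.ref[keep].astype(str)
    alt = table.alt[keep].astype(str)
    mat = pd.DataFrame(0, index=list(_BASES), columns=list(_BASES))
    for r, a in zip(ref, alt):
        mat.loc[r, a] += 1
    ts = sum(int(mat.loc[r, a]) for r, a in _TRANSITIONS)
    n = len(ref)
    tv = n - ts
    at = int(np.isin(ref, ["A", "T"]).sum())
    return SpectrumSummary(n=n, ts=ts, tv=tv, at_count=at, sub_matrix=mat)
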