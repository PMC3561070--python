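"""Recombination maps and genomic window partitioning.

A recombination map is, per chromosome, a monotone piecewise-linear function
from physical position (bp) to cumulative genetic position (cM).  Genetic
lengths of intervals come from linear interpolation; where no map is supplied
a uniform rate (default 0.5 cM/Mb, the genome-wide mouse average) is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneticMap", "Window", "partition_windows", "DEFAULT_CM_PER_MB"]

DEFAULT_CM_PER_MB = 0.5


class GeneticMap:
    """Piecewise-linear bp -> cumulative cM maps, one per chromosome.

    Positions outside the mapped range are extrapolated at the flanking
    segment's average rate (constant extrapolation of cM would make terminal
    windows recombination-free).
    """

    def __init__(self, anchors: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._anchors = {}
        for chrom, (bp, cm) in anchors.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if bp.ndim != 1 or bp.shape != cm.shape or len(bp) < 2:
                raise ValueError(f"map for {chrom} needs >= 2 (bp, cM) anchors")
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"map positions for {chrom} must be strictly increasing")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"negative cM increment in map for {chrom}")
            self._anchors[chrom] = (bp, cm)

    @classmethod
    def uniform(
        cls, chrom_lengths: dict[str, int], cm_per_mb: float = DEFAULT_CM_PER_MB
    ) -> "GeneticMap":
        """Constant-rate map covering each chromosome end to end."""
        return cls(
            {
                c: (np.array([0.0, float(L)]), np.array([0.0, cm_per_mb * L / 1e6]))
                for c, L in chrom_lengths.items()
            }
        )

    @classmethod
    def read(cls, path) -> "GeneticMap":
        """Read a tab-separated chrom / position (bp) / cumulative cM table."""
        df = pd.read_csv(
            path, sep="\t", comment="#", names=["chrom", "pos", "cm"],
            dtype={"chrom": str},
        )
        anchors = {
            str(c): (g["pos"].to_numpy(float), g["cm"].to_numpy(float))
            for c, g in df.groupby("chrom", sort=False)
        }
        return cls(anchors)

    def chromosomes(self) -> list[str]:
        return list(self._anchors)

    def cm_at(self, chrom: str, pos) -> np.ndarray:
        """Cumulative cM at physical position(s), with linear extrapolation."""
        bp, cm = self._anchors[chrom]
        pos = np.asarray(pos, dtype=float)
        out = np.interp(pos, bp, cm)
        # np.interp clamps; extrapolate with the terminal segment rates
        lo_rate = (cm[1] - cm[0]) / (bp[1] - bp[0])
        hi_rate = (cm[-1] - cm[-2]) / (bp[-1] - bp[-2])
        out = np.where(pos < bp[0], cm[0] + (pos - bp[0]) * lo_rate, out)
        out = np.where(pos > bp[-1], cm[-1] + (pos - bp[-1]) * hi_rate, out)
        return out

    def genetic_length(self, chrom: str, start: float, end: float) -> float:
        """Genetic length of [start, end) in Morgans."""
        if end < start:
            raise ValueError("end < start")
        a, b = self.cm_at(chrom, [start, end])
        return max(float(b - a), 0.0) / 100.0

    def bp_at_cm(self, chrom: str, cm_values) -> np.ndarray:
        """Inverse map: physical positions of cumulative cM values."""
        bp, cm = self._anchors[chrom]
        # make cm strictly increasing for inversion of flat segments
        eps = np.arange(len(cm)) * 1e-12
        return np.interp(np.asarray(cm_values, dtype=float), cm + eps, bp)

    def total_morgans(self, chrom: str, length: float | None = None) -> float:
        bp, cm = self._anchors[chrom]
        end = float(bp[-1]) if length is None else float(length)
        return self.genetic_length(chrom, 0.0, end)


@dataclass
class Window:
    """A fixed-width genomic interval of the HMM (0-based half-open)."""

    chrom: str
    start: int
    end: int
    genetic_length: float  # Morgans
    snp_indices: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64)
    )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


def partition_windows(
    chrom_lengths: dict[str, int],
    gmap: GeneticMap | None = None,
    width: int = 100_000,
) -> dict[str, list[Window]]:
    """Tile each chromosome with contiguous windows of at most ``width`` bp.

    The final window of a chromosome is truncated to the chromosome end.
    Genetic lengths come from ``gmap`` (uniform fallback when None).
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    if gmap is None:
        gmap = GeneticMap.uniform(chrom_lengths)
    out: dict[str, list[Window]] = {}
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        starts = np.arange(0, length, width, dtype=np.int64)
        ends = np.minimum(starts + width, length)
        out[chrom] = [
            Window(chrom, int(s), int(e), gmap.genetic_length(chrom, s, e))
            for s, e in zip(starts, ends)
        ]
    return out
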