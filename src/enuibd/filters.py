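"""The ENU variant-filter cascade.

Raw multi-sample calls contain, besides genuine ENU-induced point mutations,
strain background variation from the reference, systematic calling artifacts
(mismapping pileups, repeat slippage) and low-quality calls.  Candidate ENU
variants are isolated by applying, in order:

1. union-file exclusion (variation seen in >= 2 independent pedigrees is
   background or systematic error, never ENU);
2. dbSNP-style known-variant exclusion;
3. cluster filter: every variant with another variant within ``cluster_bp``
   on the same chromosome is removed (both members of a cluster);
4. Phred quality threshold;
5. caller bias flags (allele bias, strand bias, bad reads);
6. homopolymer / di-nucleotide tandem-repeat context;
7. indel removal (ENU overwhelmingly causes point mutations);
8. total-site-depth percentile exclusion (default: outside the 1st-99th
   percentiles of the raw input's depth distribution).

Each stage sees only the survivors of the previous ones; the returned report
tallies removals per stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .variants import VariantTable

__all__ = [
    "FilterConfig",
    "UnionFile",
    "FilterReport",
    "build_union_file",
    "apply_filters",
    "repeat_context",
]

VariantKey = tuple[str, int, str, str]

STAGES = (
    "union_file",
    "dbsnp",
    "cluster",
    "quality",
    "bias_flags",
    "repeat_context",
    "indel",
    "depth_percentile",
)


@dataclass
class UnionFile:
    """Cross-pedigree catalogue of shared (hence non-ENU) variation."""

    keys: set[VariantKey]
    provenance: dict[VariantKey, int] = field(default_factory=dict)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.keys

    def __len__(self) -> int:
        return len(self.keys)


def build_union_file(pedigree_keys: dict[str, list[VariantKey]]) -> UnionFile:
    """Union file: variant keys observed in at least two pedigrees.

    ``pedigree_keys`` maps pedigree names to their (chrom, pos, ref, alt)
    call keys.  A variant seen in only one pedigree may be ENU-induced and is
    excluded from the union file.
    """
    if len(pedigree_keys) < 2:
        raise ValueError("a union file requires calls from >= 2 pedigrees")
    counts: dict[VariantKey, int] = {}
    for keys in pedigree_keys.values():
        for key in set(keys):
            counts[key] = counts.get(key, 0) + 1
    shared = {k: c for k, c in counts.items() if c >= 2}
    return UnionFile(keys=set(shared), provenance=shared)


@dataclass
class FilterConfig:
    """Parameters of the filter cascade."""

    min_qual: float = 20.0
    cluster_bp: int = 1000
    repeat_min_len: int = 20
    coverage_low_pct: float = 1.0
    coverage_high_pct: float = 99.0
    union: UnionFile | None = None
    dbsnp: set[VariantKey] | None = None
    #: frozen total-depth bounds; when None they are computed from the input
    #: table's site-depth distribution and recorded in the report
    depth_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.coverage_low_pct < self.coverage_high_pct <= 100:
            raise ValueError("need 0 <= low percentile < high percentile <= 100")
        if self.cluster_bp <= 0:
            raise ValueError("cluster_bp must be positive")


@dataclass
class FilterReport:
    """Per-stage removal tallies plus the depth bounds actually applied."""

    n_input: int
    removed: dict[str, int]
    depth_bounds: tuple[float, float]

    @property
    def n_passed(self) -> int:
        return self.n_input - sum(self.removed.values())

    def to_tsv(self) -> str:
        lines = ["stage\tremoved"]
        lines += [f"{s}\t{self.removed[s]}" for s in STAGES]
        lines.append(f"passed\t{self.n_passed}")
        return "\n".join(lines) + "\n"


def repeat_context(reference_window: str, pos: int, min_len: int = 20
                   ) -> tuple[bool, int]:
    """Repeat status of offset ``pos`` within a reference sequence window.

    Returns ``(is_repeat, run_length)`` where ``run_length`` is the longest
    homopolymer or perfect di-nucleotide tandem run overlapping ``pos`` and
    ``is_repeat`` flags runs of at least ``min_len`` bases.  The window must
    extend at least ``min_len`` bases on both sides of ``pos`` (or to the
    sequence end where ``pos`` is near a boundary of the full sequence).
    """
    seq = reference_window.upper()
    n = len(seq)
    if not 0 <= pos < n:
        raise ValueError("pos outside window")
    if n < min_len:
        raise ValueError("reference window shorter than the minimum run length")
    best = 1
    for period in (1, 2):
        # a maximal stretch of matches seq[j] == seq[j+period] for
        # j in [j0, j1] is a tandem run spanning [j0, j1+period]
        j = 0
        while j < n - period:
            if seq[j] != seq[j + period]:
                j += 1
                continue
            j0 = j
            while j < n - period and seq[j] == seq[j + period]:
                j += 1
            start, end = j0, j - 1 + period  # inclusive bases of the run
            if start <= pos <= end:
                best = max(best, end - start + 1)
    return best >= min_len, best


def _cluster_mask(chrom: np.ndarray, pos: np.ndarray, cluster_bp: int) -> np.ndarray:
    """True for sites with another site within ``cluster_bp`` on the same chromosome."""
    n = len(pos)
    clustered = np.zeros(n, dtype=bool)
    order = np.lexsort((pos, chrom.astype(str)))
    c_sorted = chrom[order]
    p_sorted = pos[order]
    for i in range(n):
        if i + 1 < n and c_sorted[i + 1] == c_sorted[i] and \
                p_sorted[i + 1] - p_sorted[i] < cluster_bp:
            clustered[order[i]] = True
            clustered[order[i + 1]] = True
    return clustered


def apply_filters(
    table: VariantTable,
    cfg: FilterConfig,
    reference: dict[str, str] | None = None,
    repeat_mask: set[tuple[str, int]] | None = None,
) -> tuple[VariantTable, FilterReport]:
    """Run the filter cascade; returns (survivors, per-stage report).

    ``reference`` maps chromosome names to sequences for repeat-context
    checks; alternatively a precomputed ``repeat_mask`` of (chrom, pos) sites
    may be supplied.  With neither, the repeat stage removes nothing.
    """
    if not table.is_sorted():
        raise ValueError("variant table must be sorted by (chrom, pos)")
    removed = {s: 0 for s in STAGES}
    if table.n_sites == 0:
        bounds = cfg.depth_bounds or (0.0, 0.0)
        return table, FilterReport(0, removed, bounds)

    site_depth = table.site_depth
    if cfg.depth_bounds is not None:
        bounds = cfg.depth_bounds
    else:
        bounds = (
            float(np.percentile(site_depth, cfg.coverage_low_pct)),
            float(np.percentile(site_depth, cfg.coverage_high_pct)),
        )

    alive = np.ones(table.n_sites, dtype=bool)
    keys = table.keys()

    def drop(stage: str, mask: np.ndarray) -> None:
        mask = mask & alive
        removed[stage] = int(mask.sum())
        alive[mask] = False

    if cfg.union is not None:
        drop("union_file", np.array([k in cfg.union for k in keys]))
    if cfg.dbsnp:
        drop("dbsnp", np.array([k in cfg.dbsnp for k in keys]))

    idx = np.flatnonzero(alive)
    cl = _cluster_mask(table.chrom[idx], table.pos[idx], cfg.cluster_bp)
    mask = np.zeros(table.n_sites, dtype=bool)
    mask[idx[cl]] = True
    drop("cluster", mask)

    drop("quality", np.nan_to_num(table.qual, nan=0.0) < cfg.min_qual)
    drop("bias_flags", table.flags != 0)

    if reference is not None or repeat_mask is not None:
        rep = np.zeros(table.n_sites, dtype=bool)
        for i in np.flatnonzero(alive):
            c, p = str(table.chrom[i]), int(table.pos[i])
            if repeat_mask is not None:
                rep[i] = (c, p) in repeat_mask
            else:
                seq = reference.get(c)
                if seq is None:
                    continue
                off = p - 1  # variants are 1-based, sequences 0-based
                lo = max(0, off - 2 * cfg.repeat_min_len)
                hi = min(len(seq), off + 2 * cfg.repeat_min_len + 1)
                rep[i], _ = repeat_context(seq[lo:hi], off - lo, cfg.repeat_min_len)
        drop("repeat_context", rep)

    drop("indel", ~table.is_snv)
    drop("depth_percentile", (site_depth < bounds[0]) | (site_depth > bounds[1]))

    report = FilterReport(table.n_sites, removed, bounds)
    return table.subset(alive), report
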