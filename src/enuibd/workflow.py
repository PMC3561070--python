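"""End-to-end pipeline: filter -> map -> call regions -> candidates -> stats.

Convenience layer used by the command-line interface and by analyses of
simulated pedigrees: runs the filter cascade, the Lander-Green mapper, IBD
region calling, candidate selection, and the rate/spectrum estimators on an
in-memory variant table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filters import FilterConfig, FilterReport, apply_filters
from .genmap import GeneticMap
from .hmm import EmissionPriors, StatePath, map_states
from .pedigree import PedigreeStructure
from .regions import (call_ibd_regions, candidate_variants,
                      per_mouse_homozygous_regions)
from .stats import RateEstimate, SpectrumSummary, estimate_rate, spectrum
from .variants import VariantTable

__all__ = ["AnalysisResult", "analyze_pedigree"]


@dataclass
class AnalysisResult:
    filtered: VariantTable
    filter_report: FilterReport
    state_table: pd.DataFrame
    paths: dict[str, StatePath]
    regions: pd.DataFrame
    per_mouse_regions: list[dict[str, pd.DataFrame]]
    candidates: pd.DataFrame
    rejected: pd.DataFrame
    rate: RateEstimate | None
    spectrum: SpectrumSummary | None


def _hom_enu_spectrum_table(table: VariantTable,
                            per_mouse: list[dict[str, pd.DataFrame]]
                            ) -> VariantTable:
    """Unique SNVs homozygous in at least one mouse's homozygous-ENU regions."""
    from .regions import _in_regions

    mask = np.zeros(table.n_sites, dtype=bool)
    for m, regs in enumerate(per_mouse):
        if regs["hom_enu"].empty:
            continue
        mask |= (table.gt[:, m] == 2) & _in_regions(table, regs["hom_enu"])
    return table.subset(np.flatnonzero(mask & table.is_snv))


def analyze_pedigree(
    table: VariantTable,
    chrom_lengths: dict[str, int],
    filter_cfg: FilterConfig | None = None,
    gmap: GeneticMap | None = None,
    width: int = 100_000,
    priors: EmissionPriors | None = None,
    exons: pd.DataFrame | None = None,
    min_ref_reads: int = 5,
) -> AnalysisResult:
    """Run the whole mapping pipeline on one pedigree's raw call table."""
    structure = PedigreeStructure(table.n_samples)
    filtered, report = apply_filters(table, filter_cfg or FilterConfig())
    state_table, paths = map_states(
        filtered, structure, chrom_lengths, gmap=gmap, width=width, priors=priors
    )
    regions = call_ibd_regions(paths, structure)
    per_mouse = per_mouse_homozygous_regions(paths, structure)
    candidates, rejected = candidate_variants(
        filtered, regions, structure, min_ref_reads=min_ref_reads, exons=exons
    )
    rate = None
    try:
        rate = estimate_rate(
            filtered,
            [pm["hom_enu"] for pm in per_mouse],
            [pm["hom_wt"] for pm in per_mouse],
        )
    except ValueError:
        pass  # a mouse with no decoded region of some class: rate undefined
    spec_summary = None
    spec_table = _hom_enu_spectrum_table(filtered, per_mouse)
    if spec_table.n_sites:
        spec_summary = spectrum(spec_table)
    return AnalysisResult(
        filtered=filtered,
        filter_report=report,
        state_table=state_table,
        paths=paths,
        regions=regions,
        per_mouse_regions=per_mouse,
        candidates=candidates,
        rejected=rejected,
        rate=rate,
        spectrum=spec_summary,
    )
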