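"""Shared fixtures and in-memory table builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from enuibd.variants import MISSING, VariantTable


def make_table(records, samples=None):
    """Build a VariantTable from per-site dicts.

    Each record: chrom, pos, ref, alt, and optionally qual (default 100),
    flags (default 0), gt (list per sample, default all 1/1), depth,
    ref_support, alt_support, gl.
    """
    n = len(records)
    if samples is None:
        k = len(records[0].get("gt", [2])) if n else 1
        samples = [f"G3_{i + 1}" for i in range(k)]
    k = len(samples)
    chrom = np.array([r["chrom"] for r in records], dtype=object)
    pos = np.array([r["pos"] for r in records], dtype=np.int64)
    ref = np.array([r.get("ref", "A") for r in records], dtype=object)
    alt = np.array([r.get("alt", "G") for r in records], dtype=object)
    qual = np.array([r.get("qual", 100.0) for r in records], dtype=float)
    flags = np.array([r.get("flags", 0) for r in records], dtype=np.uint8)
    gt = np.array([r.get("gt", [2] * k) for r in records], dtype=np.int8
                  ).reshape(n, k)
    depth = np.array([r.get("depth", [20] * k) for r in records],
                     dtype=np.int32).reshape(n, k)
    ref_support = np.array(
        [r.get("ref_support", [0] * k) for r in records], dtype=np.int32
    ).reshape(n, k)
    alt_support = np.array(
        [r.get("alt_support", [20] * k) for r in records], dtype=np.int32
    ).reshape(n, k)
    gl = np.zeros((n, k, 3))
    for i, r in enumerate(records):
        if "gl" in r:
            gl[i] = np.asarray(r["gl"], dtype=float).reshape(k, 3)
        else:
            for j in range(k):
                g = gt[i, j]
                gl[i, j, g if g != MISSING else 0] = 1.0
                if g == MISSING:
                    gl[i, j] = 1.0
    return VariantTable(
        samples=list(samples), chrom=chrom, pos=pos, ref=ref, alt=alt,
        qual=qual, flags=flags, gt=gt, gl=gl, depth=depth,
        ref_support=ref_support, alt_support=alt_support,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def sim_pedigree():
    """One medium simulated pedigree (250 Mb, 24x) shared across tests."""
    from enuibd.filters import FilterConfig, build_union_file
    from enuibd.sim import SimConfig, simulate_study
    from enuibd.workflow import analyze_pedigree

    cfg = SimConfig(seed=1)
    result, union_keys = simulate_study(cfg)
    union = build_union_file(union_keys)
    analysis = analyze_pedigree(result.table, cfg.chrom_lengths,
                                filter_cfg=FilterConfig(union=union))
    return cfg, result, union, analysis
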