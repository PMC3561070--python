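"""Synthetic pedigree/WGS generator: founders, gametes, read model."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import binom as binom_dist

from enuibd.design import PedigreeDesign
from enuibd.pedigree import FounderHaplotype
from enuibd.sim import (DEFAULT_SPECTRUM, Mosaic, SimConfig, drop_gametes,
                        emit_table, sample_shared_locus,
                        sample_transmission_counts, simulate_exons,
                        simulate_founders, simulate_pedigree)

SMALL = {"chr1": 2_000_000, "chr2": 2_000_000}


def test_default_spectrum_is_consistent():
    assert sum(DEFAULT_SPECTRUM.values()) == pytest.approx(1.0)
    at = sum(v for k, v in DEFAULT_SPECTRUM.items() if k.startswith("AT"))
    ts = DEFAULT_SPECTRUM["AT>GC"] + DEFAULT_SPECTRUM["GC>AT"]
    assert at == pytest.approx(0.787)
    assert ts / (1 - ts) == pytest.approx(1.50, abs=0.01)


class TestFounders:
    def test_zero_rate_plants_nothing_without_causative(self):
        cfg = SimConfig(seed=0, chrom_lengths=dict(SMALL), enu_rate_per_mb=0.0)
        founders = simulate_founders(cfg)
        # only the planted causative mutation remains
        assert len(founders.enu[FounderHaplotype.ENU1]) == 1
        assert len(founders.enu[FounderHaplotype.ENU2]) == 0

    def test_degenerate_spectrum(self):
        spec = {k: (1.0 if k == "AT>GC" else 0.0) for k in DEFAULT_SPECTRUM}
        cfg = SimConfig(seed=3, chrom_lengths=dict(SMALL),
                        enu_rate_per_mb=20.0, spectrum=spec)
        founders = simulate_founders(cfg)
        df = founders.enu[FounderHaplotype.ENU2]
        assert set(zip(df["ref"], df["alt"])) <= {("A", "G"), ("T", "C")}

    def test_poisson_mean_count(self):
        """Mean ENU2 mutation count over seeds matches rate x genome size."""
        cfg0 = SimConfig(seed=0, chrom_lengths={"chr1": 50_000_000},
                         enu_rate_per_mb=1.54)
        counts = []
        for seed in range(60):
            cfg = dataclasses.replace(cfg0, seed=seed)
            founders = simulate_founders(cfg)
            counts.append(len(founders.enu[FounderHaplotype.ENU2]))
        expected = 1.54 * 50
        se = np.sqrt(expected / len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_invalid_spectrum_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(spectrum={"AT>GC": 0.5})


class TestGametes:
    def test_zero_genetic_length_transmits_intact_haplotypes(self):
        cfg = SimConfig(seed=1, chrom_lengths=dict(SMALL), cm_per_mb=0.0,
                        n_sequenced=1, max_retries=2000)
        founders = simulate_founders(cfg)
        truth = drop_gametes(cfg, founders)
        for pair in truth.g3:
            for hap in pair:
                for chrom in SMALL:
                    assert len(hap.labels[chrom]) == 1

    def test_mosaics_tile_chromosomes(self):
        cfg = SimConfig(seed=4, chrom_lengths=dict(SMALL), cm_per_mb=50.0,
                        n_sequenced=1, max_retries=2000)
        truth = drop_gametes(cfg, simulate_founders(cfg))
        for pair in truth.g3:
            for hap in pair:
                for chrom, L in SMALL.items():
                    assert hap.breaks[chrom][-1] == L
                    assert (np.diff(hap.breaks[chrom]) > 0).all()
                    assert set(hap.labels[chrom]) <= {0, 1, 2, 3}

    def test_affected_satisfy_trait_mode(self):
        cfg = SimConfig(seed=5, chrom_lengths=dict(SMALL), n_sequenced=2,
                        max_retries=2000)
        truth = drop_gametes(cfg, simulate_founders(cfg))
        for m in truth.sequenced:
            g = truth.g3_genotype(m, cfg.causative_chrom,
                                  cfg.causative_pos,
                                  carrier_label=cfg.causative_founder)
            assert int(g) == 2  # recessive: homozygous causative

    def test_neutral_locus_homozygosity_matches_transmission_model(self):
        """Cross-module check: at a locus unlinked to the causative one, the
        per-G3 homozygosity rate equals E[M]/n_g3 = 1/16 from the closed-form
        transmission model (conditioning on the causative locus is local)."""
        cfg = SimConfig(seed=6, chrom_lengths=dict(SMALL), cm_per_mb=0.0,
                        n_sequenced=1, max_retries=5000)
        n_hom = n_tot = 0
        for seed in range(150):
            c = dataclasses.replace(cfg, seed=seed)
            truth = drop_gametes(c, simulate_founders(c))
            for m in range(len(truth.g3)):
                g = truth.g3_genotype(m, "chr2", 1_000_000,
                                      carrier_label=FounderHaplotype.ENU1)
                n_hom += int(g) == 2
                n_tot += 1
        p = 1 / 16
        se = np.sqrt(p * (1 - p) / n_tot)
        assert abs(n_hom / n_tot - p) < 4 * se


class TestReadModel:
    def test_zero_coverage_emits_no_calls(self):
        cfg = SimConfig(seed=2, chrom_lengths=dict(SMALL), coverage=0.0,
                        n_sequenced=1, max_retries=2000)
        res = simulate_pedigree(cfg)
        assert res.table.n_sites == 0

    def test_high_coverage_recovers_truth(self):
        cfg = SimConfig(seed=2, chrom_lengths=dict(SMALL), coverage=1000.0,
                        error_rate=0.0, background_rate_per_mb=0.0,
                        artifact_rate_per_mb=0.0, n_sequenced=2,
                        max_retries=2000)
        res = simulate_pedigree(cfg)
        assert res.table.n_sites > 0
        np.testing.assert_array_equal(res.table.gt, res.table.truth_gt)

    def test_het_dropout_rate_matches_closed_form(self):
        """At coverage c, a true heterozygote shows zero alternate reads with
        probability sum_d Pois(d; c) (1/2)^d = exp(-c/2)."""
        cfg = SimConfig(seed=8, chrom_lengths={"chr1": 40_000_000},
                        coverage=5.0, background_rate_per_mb=0.0,
                        artifact_rate_per_mb=0.0, enu_rate_per_mb=10.0,
                        n_sequenced=3, max_retries=2000)
        res = simulate_pedigree(cfg)
        t = res.table
        n_zero = n_het = 0
        for j in range(3):
            others = [o for o in range(3) if o != j]
            anchored = ((t.gt[:, others] == 1) | (t.gt[:, others] == 2)
                        ).any(axis=1)
            het = (t.truth_gt[:, j] == 1) & anchored
            n_het += int(het.sum())
            n_zero += int((het & (t.alt_support[:, j] == 0)).sum())
        p = np.exp(-cfg.coverage / 2)
        se = np.sqrt(p * (1 - p) / n_het)
        assert abs(n_zero / n_het - p) < 3 * se

    def test_same_seed_byte_identical_vcf(self, tmp_path):
        cfg = SimConfig(seed=9, chrom_lengths=dict(SMALL), n_sequenced=2,
                        max_retries=2000)
        for name in ("a.vcf", "b.vcf"):
            simulate_pedigree(cfg).table.to_vcf(
                tmp_path / name, chrom_lengths=cfg.chrom_lengths,
                meta={"seed": cfg.seed})
        assert (tmp_path / "a.vcf").read_bytes() == \
            (tmp_path / "b.vcf").read_bytes()


class TestSingleLocusMonteCarlo:
    def test_transmission_support(self, rng):
        design = PedigreeDesign()
        m = sample_transmission_counts(design, "homozygous", 2_000, rng)
        assert m.min() >= 0 and m.max() <= 48

    def test_carrier_dominates_homozygous(self, rng):
        design = PedigreeDesign()
        hom = sample_transmission_counts(design, "homozygous", 5_000, rng)
        car = sample_transmission_counts(design, "carrier", 5_000, rng)
        assert car.mean() > hom.mean()

    def test_shared_locus_k_equals_one(self, rng):
        design = PedigreeDesign()
        p = sample_shared_locus(design, "homozygous", 1, 40_000, rng)
        se = np.sqrt(0.0625 * (1 - 0.0625) / 40_000)
        assert abs(p - 0.0625) < 4 * se


def test_exon_model_coding_fraction():
    cfg = SimConfig(seed=0, chrom_lengths={"chr1": 50_000_000})
    exons = simulate_exons(cfg)
    frac = (exons["end"] - exons["start"]).sum() / 50_000_000
    assert frac == pytest.approx(0.0105, rel=0.05)
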