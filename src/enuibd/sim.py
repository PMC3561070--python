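"""Synthetic ENU pedigree and WGS generator.

Simulates the full data-generating process the mapper consumes: ENU point
mutations planted on the two mutagenized founder haplotypes at a configurable
per-Mb rate with the ENU substitution spectrum; shared strain background
variation on the wild-type haplotypes; sequencing/mapping artifact sites;
recombinant gamete dropping through the G0->G3 pedigree on a genetic map
(Poisson crossovers, no interference); selection of affected G3 mice by the
causative genotype; and coverage-dependent genotype likelihoods emitted as a
multi-sample variant table / VCF with the ground truth carried along.

The generator's defaults are the study conditions of the empirical screen it
emulates: 1.54 ENU mutations/Mb, the ENU spectrum (45.0% A:T>G:C, 28.5%
A:T>T:A, 78.7% of mutations at A:T sites, Ts/Tv 1.50), 58% genomic AT
content, a 0.5 cM/Mb genetic map, 3 sequenced affected G3 siblings from one
G2 pair, mean coverage 24x and a 1% per-read error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import binom as _binom

from .design import PedigreeDesign
from .filters import VariantKey
from .genmap import GeneticMap
from .pedigree import FounderHaplotype

__all__ = [
    "SimConfig",
    "Mosaic",
    "SimTruth",
    "Founders",
    "DEFAULT_SPECTRUM",
    "simulate_founders",
    "drop_gametes",
    "emit_table",
    "simulate_pedigree",
    "simulate_study",
    "sample_transmission_counts",
    "sample_shared_locus",
    "simulate_exons",
]

#: ENU substitution spectrum over the six strand-symmetric classes, percent.
#: A:T>G:C and A:T>T:A are the measured ENU signature values; the remainder is
#: allocated so that 78.7% of mutations fall at A:T sites and the overall
#: transition:transversion ratio is 1.50 (transitions: 45.0 + 15.0 = 60%).
DEFAULT_SPECTRUM: dict[str, float] = {
    "AT>GC": 0.450,
    "AT>TA": 0.285,
    "AT>CG": 0.052,
    "GC>AT": 0.150,
    "GC>TA": 0.0315,
    "GC>CG": 0.0315,
}

#: ordered substitutions per class: (ref, alt) on each strand
_CLASS_SUBS = {
    "AT>GC": (("A", "G"), ("T", "C")),
    "AT>TA": (("A", "T"), ("T", "A")),
    "AT>CG": (("A", "C"), ("T", "G")),
    "GC>AT": (("G", "A"), ("C", "T")),
    "GC>TA": (("G", "T"), ("C", "A")),
    "GC>CG": (("G", "C"), ("C", "G")),
}

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _default_chroms() -> dict[str, int]:
    return {f"chr{i}": 50_000_000 for i in range(1, 6)}


@dataclass
class SimConfig:
    """Generator parameters; defaults are the emulated study's conditions."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(default_factory=_default_chroms)
    at_fraction: float = 0.58
    enu_rate_per_mb: float = 1.54
    spectrum: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPECTRUM))
    background_rate_per_mb: float = 10.0
    background_ts_tv: float = 2.17
    artifact_rate_per_mb: float = 1.0
    shared_artifact_fraction: float = 0.5
    cm_per_mb: float = 0.5
    gmap: GeneticMap | None = None
    trait_mode: str = "recessive"  # "recessive" | "dominant"
    causative_chrom: str | None = None  # default: first chromosome
    causative_pos: int | None = None  # default: middle of that chromosome
    causative_founder: FounderHaplotype = FounderHaplotype.ENU1
    coverage: float = 24.0
    error_rate: float = 0.01
    design: PedigreeDesign = field(default_factory=PedigreeDesign)
    n_sequenced: int = 3
    coding_fraction: float = 0.0105
    max_retries: int = 500

    def __post_init__(self) -> None:
        if abs(sum(self.spectrum.values()) - 1.0) > 1e-9:
            raise ValueError("spectrum must sum to 1")
        if self.trait_mode not in ("recessive", "dominant"):
            raise ValueError("trait_mode must be 'recessive' or 'dominant'")
        if self.causative_chrom is None:
            self.causative_chrom = next(iter(self.chrom_lengths))
        if self.causative_pos is None:
            self.causative_pos = self.chrom_lengths[self.causative_chrom] // 2
        if not 1 <= self.causative_pos <= self.chrom_lengths[self.causative_chrom]:
            raise ValueError("causative locus outside the genome")

    @property
    def genome_mb(self) -> float:
        return sum(self.chrom_lengths.values()) / 1e6

    def genetic_map(self) -> GeneticMap:
        if self.gmap is not None:
            return self.gmap
        return GeneticMap.uniform(self.chrom_lengths, self.cm_per_mb)


# ---------------------------------------------------------------------------
# founder mutations

def _draw_positions(cfg: SimConfig, n: int, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray]:
    """n distinct (chrom, pos) pairs, uniform over the genome; pos is 1-based."""
    chroms = list(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    out_c, out_p, seen = [], [], set()
    while len(out_p) < n:
        ci = rng.choice(len(chroms), p=lengths / lengths.sum())
        p = int(rng.integers(1, lengths[ci] + 1))
        if (ci, p) not in seen:
            seen.add((ci, p))
            out_c.append(chroms[ci])
            out_p.append(p)
    return np.array(out_c, dtype=object), np.array(out_p, dtype=np.int64)


def _draw_enu_substitutions(cfg: SimConfig, n: int, rng: np.random.Generator
                            ) -> tuple[np.ndarray, np.ndarray]:
    """(ref, alt) pairs from the ENU spectrum; strands equally likely."""
    classes = list(cfg.spectrum)
    probs = np.array([cfg.spectrum[c] for c in classes])
    picks = rng.choice(len(classes), size=n, p=probs)
    strands = rng.integers(0, 2, size=n)
    refs = np.array([_CLASS_SUBS[classes[i]][s][0] for i, s in zip(picks, strands)],
                    dtype=object)
    alts = np.array([_CLASS_SUBS[classes[i]][s][1] for i, s in zip(picks, strands)],
                    dtype=object)
    return refs, alts


def _draw_background_substitutions(cfg: SimConfig, n: int, rng: np.random.Generator
                                   ) -> tuple[np.ndarray, np.ndarray]:
    """Natural (non-ENU) substitutions: base drawn from the genome composition,
    transition vs transversion at the natural ratio."""
    at = cfg.at_fraction
    refs = rng.choice(np.array(["A", "T", "G", "C"], dtype=object), size=n,
                      p=[at / 2, at / 2, (1 - at) / 2, (1 - at) / 2])
    p_ts = cfg.background_ts_tv / (1.0 + cfg.background_ts_tv)
    ts = {"A": "G", "G": "A", "C": "T", "T": "C"}
    tv = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
    alts = np.empty(n, dtype=object)
    for i, r in enumerate(refs):
        if rng.random() < p_ts:
            alts[i] = ts[r]
        else:
            alts[i] = tv[r][rng.integers(0, 2)]
    return refs, alts


def _mutation_frame(chrom, pos, ref, alt) -> pd.DataFrame:
    df = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt})
    chrom_order = {c: i for i, c in enumerate(pd.unique(df["chrom"]))}
    return df


@dataclass
class Founders:
    """Planted variation: per-ENU-haplotype mutations and shared background."""

    enu: dict[FounderHaplotype, pd.DataFrame]
    background: pd.DataFrame  # carried by both WT haplotypes
    causative_index: int  # row in enu[causative_founder]


def simulate_founders(cfg: SimConfig, rng: np.random.Generator | None = None
                      ) -> Founders:
    """Draw ENU mutations (Poisson per haplotype) and background variation.

    The causative mutation is planted at the configured locus on the
    configured ENU founder haplotype (in addition to the Poisson draws).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    enu: dict[FounderHaplotype, pd.DataFrame] = {}
    for hap in (FounderHaplotype.ENU1, FounderHaplotype.ENU2):
        n = rng.poisson(cfg.enu_rate_per_mb * cfg.genome_mb)
        chrom, pos = _draw_positions(cfg, n, rng)
        ref, alt = _draw_enu_substitutions(cfg, n, rng)
        enu[hap] = _mutation_frame(chrom, pos, ref, alt)
    # plant the causative mutation (an A:T>G:C transition unless taken)
    ca = pd.DataFrame(
        {"chrom": [cfg.causative_chrom], "pos": [cfg.causative_pos],
         "ref": ["A"], "alt": ["G"]}
    )
    target = cfg.causative_founder
    df = pd.concat([enu[target], ca], ignore_index=True)
    df = df.drop_duplicates(subset=["chrom", "pos"], keep="last").reset_index(drop=True)
    enu[target] = df
    causative_index = int(
        np.flatnonzero((df["chrom"] == cfg.causative_chrom)
                       & (df["pos"] == cfg.causative_pos))[0]
    )
    n_bg = rng.poisson(cfg.background_rate_per_mb * cfg.genome_mb)
    chrom, pos = _draw_positions(cfg, n_bg, rng)
    ref, alt = _draw_background_substitutions(cfg, n_bg, rng)
    background = _mutation_frame(chrom, pos, ref, alt)
    return Founders(enu=enu, background=background, causative_index=causative_index)


# ---------------------------------------------------------------------------
# gamete dropping

@dataclass
class Mosaic:
    """One haplotype of one mouse: founder-label segments per chromosome.

    ``breaks[c]`` are ascending segment end positions (the last equals the
    chromosome length); ``labels[c]`` the founder label of each segment.
    """

    breaks: dict[str, np.ndarray]
    labels: dict[str, np.ndarray]

    @classmethod
    def intact(cls, chrom_lengths: dict[str, int], label: FounderHaplotype
               ) -> "Mosaic":
        return cls(
            breaks={c: np.array([L], dtype=np.int64) for c, L in chrom_lengths.items()},
            labels={c: np.array([int(label)], dtype=np.int8) for c in chrom_lengths},
        )

    def label_at(self, chrom: str, pos) -> np.ndarray:
        """Founder label(s) at 1-based position(s)."""
        idx = np.searchsorted(self.breaks[chrom], np.asarray(pos) - 1, side="right")
        return self.labels[chrom][idx]


def _splice(hap_a: Mosaic, hap_b: Mosaic, chrom: str, xpos: np.ndarray,
            start_with_b: bool) -> tuple[np.ndarray, np.ndarray]:
    """Recombinant chromosome: alternate between the two parental haplotypes
    at crossover positions ``xpos`` (0-based cut coordinates)."""
    length = int(hap_a.breaks[chrom][-1])
    cuts = np.concatenate([[0], np.sort(xpos).astype(np.int64), [length]])
    out_breaks: list[int] = []
    out_labels: list[int] = []
    use_b = start_with_b
    for a, b in zip(cuts[:-1], cuts[1:]):
        if b <= a:
            use_b = not use_b
            continue
        src = hap_b if use_b else hap_a
        i0 = np.searchsorted(src.breaks[chrom], a, side="right")
        i1 = np.searchsorted(src.breaks[chrom], b - 1, side="right")
        for j in range(i0, i1 + 1):
            end = min(int(src.breaks[chrom][j]), b)
            lab = int(src.labels[chrom][j])
            if out_labels and out_labels[-1] == lab:
                out_breaks[-1] = end
            else:
                out_breaks.append(end)
                out_labels.append(lab)
        use_b = not use_b
    return np.array(out_breaks, dtype=np.int64), np.array(out_labels, dtype=np.int8)


def _gamete(parent: tuple[Mosaic, Mosaic], cfg: SimConfig, gmap: GeneticMap,
            rng: np.random.Generator) -> Mosaic:
    """One meiotic product: Poisson crossovers on the genetic map, no
    interference, random starting phase per chromosome."""
    breaks: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    for chrom, length in cfg.chrom_lengths.items():
        morgans = gmap.total_morgans(chrom, length)
        n_x = rng.poisson(morgans)
        cm = rng.uniform(0.0, morgans * 100.0, size=n_x)
        xpos = gmap.bp_at_cm(chrom, cm)
        start_with_b = bool(rng.integers(0, 2))
        b, l = _splice(parent[0], parent[1], chrom, xpos, start_with_b)
        breaks[chrom] = b
        labels[chrom] = l
    return Mosaic(breaks=breaks, labels=labels)


@dataclass
class SimTruth:
    """Ground truth of one simulated pedigree."""

    config: SimConfig
    founders: Founders
    g2: list[tuple[Mosaic, Mosaic]]  # (sire, dam)
    g3: list[tuple[Mosaic, Mosaic]]
    affected: np.ndarray  # bool per G3
    sequenced: list[int]  # indices of the sequenced affected G3 mice

    def g3_genotype(self, mouse: int, chrom: str, pos,
                    carrier_label: FounderHaplotype | None = None,
                    wt_carried: bool = False) -> np.ndarray:
        """Copy number of a variant at position(s) for one G3 mouse.

        ``carrier_label`` marks an ENU variant private to that founder
        haplotype; ``wt_carried`` marks background variation carried by both
        WT haplotypes.
        """
        a, b = self.g3[mouse]
        la = a.label_at(chrom, pos)
        lb = b.label_at(chrom, pos)
        if wt_carried:
            wt = (int(FounderHaplotype.WT1), int(FounderHaplotype.WT2))
            return np.isin(la, wt).astype(np.int8) + np.isin(lb, wt).astype(np.int8)
        return ((la == int(carrier_label)).astype(np.int8)
                + (lb == int(carrier_label)).astype(np.int8))

    def founder_pairs_at(self, mice: list[int], chrom: str, pos) -> np.ndarray:
        """(n_mice, 2) founder labels at a position for the given G3 mice."""
        return np.array(
            [[int(self.g3[m][0].label_at(chrom, pos)),
              int(self.g3[m][1].label_at(chrom, pos))] for m in mice]
        )

    def ibd_segments(self, mice: list[int] | None = None) -> pd.DataFrame:
        """Exact per-position IBD classification for a set of sequenced mice.

        Returns 0-based half-open regions with cls in {HOM_ENU1, HOM_ENU2,
        HET_SHARED_ENU1, HET_SHARED_ENU2}; maximal and non-overlapping.
        """
        from .regions import classify_pairs, merge_adjacent

        if mice is None:
            mice = self.sequenced
        rows = []
        for chrom, length in self.config.chrom_lengths.items():
            cut = {0, length}
            for m in mice:
                for hap in self.g3[m]:
                    cut.update(int(x) for x in hap.breaks[chrom])
            cuts = np.array(sorted(cut))
            for a, b in zip(cuts[:-1], cuts[1:]):
                pairs = self.founder_pairs_at(mice, chrom, a + 1)
                cls = classify_pairs(pairs)
                if cls is not None:
                    rows.append((chrom, int(a), int(b), cls))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "cls"])
        return merge_adjacent(df)


def drop_gametes(cfg: SimConfig, founders: Founders,
                 rng: np.random.Generator | None = None) -> SimTruth:
    """Drop gametes through G1 -> G2 -> G3 and select affected mice.

    Each G1 mouse carries one intact mutagenized and one intact wild-type
    haplotype (sire: ENU1/WT1, dam: ENU2/WT2).  One G2 pair produces
    ``design.offspring_per_pair`` G3 mice; the attempt is retried with a
    fresh stream when fewer than ``n_sequenced`` G3 mice are affected.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    gmap = cfg.genetic_map()
    g1_sire = (Mosaic.intact(cfg.chrom_lengths, FounderHaplotype.ENU1),
               Mosaic.intact(cfg.chrom_lengths, FounderHaplotype.WT1))
    g1_dam = (Mosaic.intact(cfg.chrom_lengths, FounderHaplotype.ENU2),
              Mosaic.intact(cfg.chrom_lengths, FounderHaplotype.WT2))
    ca_chrom, ca_pos = cfg.causative_chrom, cfg.causative_pos
    ca_label = cfg.causative_founder
    for _ in range(cfg.max_retries):
        g2_sire = (_gamete(g1_sire, cfg, gmap, rng), _gamete(g1_dam, cfg, gmap, rng))
        g2_dam = (_gamete(g1_sire, cfg, gmap, rng), _gamete(g1_dam, cfg, gmap, rng))
        g3 = [
            (_gamete(g2_sire, cfg, gmap, rng), _gamete(g2_dam, cfg, gmap, rng))
            for _ in range(cfg.design.offspring_per_pair)
        ]
        copies = np.array([
            int((m[0].label_at(ca_chrom, ca_pos) == int(ca_label)))
            + int((m[1].label_at(ca_chrom, ca_pos) == int(ca_label)))
            for m in g3
        ])
        affected = copies >= (2 if cfg.trait_mode == "recessive" else 1)
        if affected.sum() >= cfg.n_sequenced:
            sequenced = np.flatnonzero(affected)[: cfg.n_sequenced].tolist()
            return SimTruth(cfg, founders, [(g2_sire[0], g2_sire[1]),
                                            (g2_dam[0], g2_dam[1])],
                            g3, affected, sequenced)
    raise RuntimeError(
        f"no attempt out of {cfg.max_retries} produced "
        f"{cfg.n_sequenced} affected G3 mice"
    )


# ---------------------------------------------------------------------------
# read-model emission

def _site_frame(truth: SimTruth) -> pd.DataFrame:
    """All true variant sites with per-sequenced-mouse true genotypes."""
    cfg = truth.config
    frames = []
    for hap in (FounderHaplotype.ENU1, FounderHaplotype.ENU2):
        df = truth.founders.enu[hap].copy()
        df["origin"] = hap.name
        frames.append(df)
    bg = truth.founders.background.copy()
    bg["origin"] = "BACKGROUND"
    frames.append(bg)
    sites = pd.concat(frames, ignore_index=True)
    k = len(truth.sequenced)
    tg = np.zeros((len(sites), k), dtype=np.int8)
    for o, label, wt in (("ENU1", FounderHaplotype.ENU1, False),
                         ("ENU2", FounderHaplotype.ENU2, False),
                         ("BACKGROUND", None, True)):
        rows = np.flatnonzero((sites["origin"] == o).to_numpy())
        if len(rows) == 0:
            continue
        sub = sites.iloc[rows]
        for chrom, grp in sub.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            for j, m in enumerate(truth.sequenced):
                g = truth.g3_genotype(m, str(chrom), pos,
                                      carrier_label=label, wt_carried=wt)
                tg[rows[np.isin(rows, grp.index)], j] = g
    sites["truth"] = list(tg)
    return sites


def emit_table(cfg: SimConfig, truth: SimTruth,
               rng: np.random.Generator | None = None,
               shared_artifacts: pd.DataFrame | None = None):
    """Emit the multi-sample variant table seen by the pipeline.

    Per site and mouse: depth ~ Poisson(coverage); alt reads ~ Binomial(depth,
    f) with f = error, 1/2, 1-error by true genotype; genotype likelihoods
    from the same binomial read model; called genotype by maximum likelihood
    (missing at zero depth).  Only sites with at least one called non-ref
    genotype are reported (a caller emits no record otherwise).

    Two artifact classes are added, with no true variant at either:
    *systematic* sites (``shared_artifacts``; mismapping pileups, present in
    every pedigree of a study) have elevated coverage and a coherent
    site-level alternate-read fraction across samples; *private* sites model
    sample-specific caller noise -- each sample is independently affected with
    probability 0.4 and receives a low alternate-read fraction.  A fraction
    of artifact sites carries caller bias flags.  Site quality is the summed
    log-likelihood-ratio of the calls against all-reference, Phred-scaled.
    """
    from .variants import MISSING, VariantTable, FLAG_ALLELE_BIAS, \
        FLAG_STRAND_BIAS, FLAG_BAD_READS

    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    sites = _site_frame(truth)
    k = len(truth.sequenced)

    frames = [sites]
    n_priv = rng.poisson(
        cfg.artifact_rate_per_mb * (1.0 - cfg.shared_artifact_fraction)
        * cfg.genome_mb
    )
    priv_c, priv_p = _draw_positions(cfg, n_priv, rng)
    priv_ref, priv_alt = _draw_background_substitutions(cfg, n_priv, rng)
    priv = pd.DataFrame({"chrom": priv_c, "pos": priv_p, "ref": priv_ref,
                         "alt": priv_alt})
    priv["origin"] = "ARTIFACT_PRIVATE"
    priv["truth"] = [np.zeros(k, dtype=np.int8)] * len(priv)
    frames.append(priv)
    if shared_artifacts is not None and len(shared_artifacts):
        sa = shared_artifacts[["chrom", "pos", "ref", "alt"]].copy()
        sa["origin"] = "ARTIFACT_SHARED"
        sa["truth"] = [np.zeros(k, dtype=np.int8)] * len(sa)
        frames.append(sa)
    sites = pd.concat(frames, ignore_index=True)
    sites = sites.drop_duplicates(subset=["chrom", "pos"], keep="first")

    chrom_order = {c: i for i, c in enumerate(cfg.chrom_lengths)}
    sites = sites.sort_values(
        by=["chrom", "pos"], key=lambda s: s.map(chrom_order) if s.name == "chrom" else s
    ).reset_index(drop=True)

    n = len(sites)
    truth_gt = np.stack(sites["truth"].to_numpy()) if n else np.zeros((0, k), np.int8)
    is_shared_art = (sites["origin"] == "ARTIFACT_SHARED").to_numpy()
    is_priv_art = (sites["origin"] == "ARTIFACT_PRIVATE").to_numpy()
    is_artifact = is_shared_art | is_priv_art

    mean_depth = np.where(is_shared_art, 3.0 * cfg.coverage, cfg.coverage)
    depth = rng.poisson(np.repeat(mean_depth[:, None], k, axis=1)).astype(np.int32)
    err = cfg.error_rate
    f_by_gt = np.array([err, 0.5, 1.0 - err])
    f = f_by_gt[truth_gt]
    shared_f = rng.uniform(0.1, 0.6, size=n)  # coherent mismapped fraction
    priv_f = np.where(rng.random((n, k)) < 0.4,
                      rng.uniform(0.05, 0.35, size=(n, k)), err)
    f = np.where(is_shared_art[:, None], shared_f[:, None], f)
    f = np.where(is_priv_art[:, None], priv_f, f)
    alt_reads = rng.binomial(depth, f).astype(np.int32)
    ref_reads = (depth - alt_reads).astype(np.int32)

    d = depth[..., None]
    a = alt_reads[..., None]
    gl = _binom.pmf(a, d, f_by_gt[None, None, :])
    gl = np.where(d == 0, 1.0, gl)
    m = gl.max(axis=2, keepdims=True)
    gl = gl / np.where(m > 0, m, 1.0)
    gt = gl.argmax(axis=2).astype(np.int8)
    gt[depth == 0] = MISSING

    with np.errstate(divide="ignore"):
        ll_best = np.log10(np.maximum(gl.max(axis=2), 1e-300))
        ll_ref = np.log10(np.maximum(gl[:, :, 0], 1e-300))
    qual = np.clip(10.0 * (ll_best - ll_ref).sum(axis=1), 0.0, 3000.0)
    # a fraction of artifact sites carries caller bias flags
    flags = np.zeros(n, dtype=np.uint8)
    flag_choices = np.array([FLAG_ALLELE_BIAS, FLAG_STRAND_BIAS, FLAG_BAD_READS],
                            dtype=np.uint8)
    flagged = is_artifact & (rng.random(n) < 0.4)
    flags[flagged] = rng.choice(flag_choices, size=int(flagged.sum()))

    table = VariantTable(
        samples=[f"G3_{i + 1}" for i in range(k)],
        chrom=sites["chrom"].to_numpy(dtype=object),
        pos=sites["pos"].to_numpy(dtype=np.int64),
        ref=sites["ref"].to_numpy(dtype=object),
        alt=sites["alt"].to_numpy(dtype=object),
        qual=qual,
        flags=flags,
        gt=gt,
        gl=gl,
        depth=depth,
        ref_support=ref_reads,
        alt_support=alt_reads,
        truth_gt=truth_gt,
        origin=sites["origin"].to_numpy(dtype=object),
    )
    # a caller only reports sites with at least one non-reference call
    called = ((table.gt == 1) | (table.gt == 2)).any(axis=1)
    return table.subset(np.flatnonzero(called))


@dataclass
class SimResult:
    truth: SimTruth
    table: object  # VariantTable


def simulate_pedigree(cfg: SimConfig) -> SimResult:
    """Founders -> gamete dropping -> read-model emission, from one seed."""
    rng = np.random.default_rng(cfg.seed)
    founders = simulate_founders(cfg, rng)
    truth = drop_gametes(cfg, founders, rng)
    table = emit_table(cfg, truth, rng)
    return SimResult(truth=truth, table=table)


def simulate_study(cfg: SimConfig, n_pedigrees: int = 3):
    """One fully emitted pedigree plus sibling pedigrees for the union file.

    All pedigrees share the strain background and a systematic-artifact site
    set (mismapping loci are genomic properties); ENU mutations and private
    artifacts are pedigree specific.  Returns ``(result, union_keys)`` where
    ``union_keys`` maps pedigree names to their raw call keys, suitable for
    :func:`enuibd.filters.build_union_file`.
    """
    if n_pedigrees < 2:
        raise ValueError("need >= 2 pedigrees to build a union file")
    rng = np.random.default_rng(cfg.seed)
    founders = simulate_founders(cfg, rng)
    # shared systematic artifact sites, present in every pedigree's calls
    n_shared = rng.poisson(
        cfg.artifact_rate_per_mb * cfg.shared_artifact_fraction * cfg.genome_mb
    )
    sa_c, sa_p = _draw_positions(cfg, n_shared, rng)
    sa_ref, sa_alt = _draw_background_substitutions(cfg, n_shared, rng)
    shared_art = pd.DataFrame({"chrom": sa_c, "pos": sa_p, "ref": sa_ref,
                               "alt": sa_alt})
    shared_art_keys: list[VariantKey] = list(
        zip(sa_c.tolist(), sa_p.tolist(), sa_ref.tolist(), sa_alt.tolist())
    )
    bg = founders.background
    bg_keys: list[VariantKey] = list(
        zip(bg["chrom"].tolist(), bg["pos"].tolist(),
            bg["ref"].tolist(), bg["alt"].tolist())
    )
    truth = drop_gametes(cfg, founders, rng)
    table = emit_table(cfg, truth, rng, shared_artifacts=shared_art)
    union_keys: dict[str, list[VariantKey]] = {"main": table.keys()}
    for i in range(1, n_pedigrees):
        sib_rng = np.random.default_rng(rng.integers(0, 2**31))
        sib_cfg = replace(cfg, seed=int(sib_rng.integers(0, 2**31)))
        n_mut = sib_rng.poisson(cfg.enu_rate_per_mb * cfg.genome_mb * 2)
        mc, mp = _draw_positions(cfg, n_mut, sib_rng)
        mr, ma = _draw_enu_substitutions(cfg, n_mut, sib_rng)
        n_priv = sib_rng.poisson(
            cfg.artifact_rate_per_mb * (1 - cfg.shared_artifact_fraction)
            * cfg.genome_mb
        )
        pc, pp = _draw_positions(cfg, n_priv, sib_rng)
        pr, pa = _draw_background_substitutions(cfg, n_priv, sib_rng)
        union_keys[f"sibling_{i}"] = (
            list(zip(mc.tolist(), mp.tolist(), mr.tolist(), ma.tolist()))
            + bg_keys + shared_art_keys
            + list(zip(pc.tolist(), pp.tolist(), pr.tolist(), pa.tolist()))
        )
    return SimResult(truth=truth, table=table), union_keys


def simulate_exons(cfg: SimConfig, rng: np.random.Generator | None = None,
                   exon_bp: int = 150) -> pd.DataFrame:
    """Random exon model covering ``coding_fraction`` of the genome (BED-style)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    rows = []
    for chrom, length in cfg.chrom_lengths.items():
        n_exon = int(round(cfg.coding_fraction * length / exon_bp))
        starts = np.sort(rng.integers(0, max(1, length - exon_bp), size=n_exon))
        for s in starts:
            rows.append((chrom, int(s), int(s) + exon_bp))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# single-locus Monte-Carlo (cross-validation of the closed-form design model)

def sample_transmission_counts(
    design: PedigreeDesign, zygosity: str, n_reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gamete-dropping replicates of M, the pedigree-wide G3 count.

    Every G2 parent inherits the G1 mutation with an independent fair coin;
    every G3 offspring receives each parental allele with a fair coin.  No
    binomial shortcut is taken, so this is an independent check of the
    closed-form transmission model.
    """
    if zygosity not in ("homozygous", "carrier"):
        raise ValueError("zygosity must be 'homozygous' or 'carrier'")
    shape = (n_reps, design.n_pairs)
    off = design.offspring_per_pair
    sire_carries = rng.random(shape) < 0.5
    dam_carries = rng.random(shape) < 0.5
    sire_transmits = (rng.random(shape + (off,)) < 0.5) & sire_carries[..., None]
    dam_transmits = (rng.random(shape + (off,)) < 0.5) & dam_carries[..., None]
    if zygosity == "homozygous":
        hit = sire_transmits & dam_transmits
    else:
        hit = sire_transmits | dam_transmits
    return hit.sum(axis=(1, 2))


def sample_shared_locus(
    design: PedigreeDesign, zygosity: str, k: int, n_reps: int,
    rng: np.random.Generator,
) -> float:
    """Empirical probability that k randomly sampled G3 mice share a locus."""
    shape = (n_reps, design.n_pairs)
    off = design.offspring_per_pair
    sire_carries = rng.random(shape) < 0.5
    dam_carries = rng.random(shape) < 0.5
    sire_transmits = (rng.random(shape + (off,)) < 0.5) & sire_carries[..., None]
    dam_transmits = (rng.random(shape + (off,)) < 0.5) & dam_carries[..., None]
    if zygosity == "homozygous":
        hit = sire_transmits & dam_transmits
    else:
        hit = sire_transmits | dam_transmits
    hit = hit.reshape(n_reps, design.n_g3)
    pick = np.argsort(rng.random((n_reps, design.n_g3)), axis=1)[:, :k]
    chosen = np.take_along_axis(hit, pick, axis=1)
    return float(chosen.all(axis=1).mean())
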