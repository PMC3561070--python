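"""In-memory variant table and VCF input/output.

:class:`VariantTable` is the package's working container for multi-sample SNV
and indel calls: site-level arrays (chromosome, 1-based position, alleles,
quality, caller filter flags) plus per-sample genotypes, genotype likelihoods,
depths and allele supports.  Genotype likelihoods are kept on a linear scale,
rescaled so each sample's maximum is 1; VCFs store them as log10 (``GL``) and
are converted at the boundary by :func:`read_vcf` / :meth:`VariantTable.to_vcf`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pysam

__all__ = [
    "VariantTable",
    "read_vcf",
    "FLAG_ALLELE_BIAS",
    "FLAG_STRAND_BIAS",
    "FLAG_BAD_READS",
    "FLAG_NAMES",
]

# caller filter flags, stored as a bitmask (names follow the Platypus caller)
FLAG_ALLELE_BIAS = 1
FLAG_STRAND_BIAS = 2
FLAG_BAD_READS = 4
FLAG_NAMES = {
    FLAG_ALLELE_BIAS: "alleleBias",
    FLAG_STRAND_BIAS: "strandBias",
    FLAG_BAD_READS: "badReads",
}
_NAME_TO_FLAG = {v: k for k, v in FLAG_NAMES.items()}

MISSING = -1  # genotype code for ./.


@dataclass
class VariantTable:
    """Column-oriented multi-sample variant calls.

    Per-sample genotype codes: 0 = 0/0, 1 = 0/1, 2 = 1/1, -1 = missing.
    ``gl`` has shape (n_sites, n_samples, 3) ordered (0/0, 0/1, 1/1).
    """

    samples: list[str]
    chrom: np.ndarray  # (n,) str
    pos: np.ndarray  # (n,) int64, 1-based
    ref: np.ndarray  # (n,) str
    alt: np.ndarray  # (n,) str
    qual: np.ndarray  # (n,) float64
    flags: np.ndarray  # (n,) uint8 bitmask
    gt: np.ndarray  # (n, s) int8
    gl: np.ndarray  # (n, s, 3) float64, linear, max-rescaled
    depth: np.ndarray  # (n, s) int32
    ref_support: np.ndarray  # (n, s) int32
    alt_support: np.ndarray  # (n, s) int32
    truth_gt: np.ndarray | None = None  # (n, s) int8, simulator ground truth
    origin: np.ndarray | None = None  # (n,) str, simulator variant origin

    def __post_init__(self) -> None:
        n = len(self.pos)
        s = len(self.samples)
        if self.gl.shape != (n, s, 3):
            raise ValueError(f"gl must have shape {(n, s, 3)}, got {self.gl.shape}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def is_snv(self) -> np.ndarray:
        reflen = np.char.str_len(self.ref.astype(str))
        altlen = np.char.str_len(self.alt.astype(str))
        return (reflen == 1) & (altlen == 1)

    @property
    def site_depth(self) -> np.ndarray:
        """Total read depth per site, summed over samples."""
        return self.depth.sum(axis=1)

    def keys(self) -> list[tuple[str, int, str, str]]:
        return list(zip(self.chrom.tolist(), self.pos.tolist(),
                        self.ref.tolist(), self.alt.tolist()))

    def subset(self, mask_or_idx) -> "VariantTable":
        idx = np.asarray(mask_or_idx)
        return replace(
            self,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            qual=self.qual[idx],
            flags=self.flags[idx],
            gt=self.gt[idx],
            gl=self.gl[idx],
            depth=self.depth[idx],
            ref_support=self.ref_support[idx],
            alt_support=self.alt_support[idx],
            truth_gt=None if self.truth_gt is None else self.truth_gt[idx],
            origin=None if self.origin is None else self.origin[idx],
        )

    def is_sorted(self) -> bool:
        """True if sites are ordered by (chromosome block, position)."""
        seen: list[str] = []
        for i, c in enumerate(self.chrom):
            if not seen or seen[-1] != c:
                if c in seen:
                    return False
                seen.append(c)
            elif i and self.chrom[i - 1] == c and self.pos[i] < self.pos[i - 1]:
                return False
        return True

    # -- VCF output ---------------------------------------------------------

    def to_vcf(
        self,
        path,
        chrom_lengths: dict[str, int] | None = None,
        meta: dict[str, object] | None = None,
    ) -> None:
        """Write an uncompressed multi-sample VCF.

        ``meta`` key/value pairs are emitted as ``##enuibd_<key>=`` header
        lines (used to record seeds and parameters in all outputs).
        """
        header = pysam.VariantHeader()
        chroms: dict[str, int] = dict(chrom_lengths or {})
        for c in self.chrom:
            chroms.setdefault(str(c), 2**29)
        for c, ln in chroms.items():
            header.contigs.add(str(c), length=int(ln))
        for flag, name in FLAG_NAMES.items():
            header.filters.add(name, None, None, "caller bias/quality flag")
        header.formats.add("GT", 1, "String", "Genotype")
        header.formats.add("GL", "G", "Float", "log10 genotype likelihoods (0/0,0/1,1/1)")
        header.formats.add("AD", "R", "Integer", "Allele read depths (ref, alt)")
        header.formats.add("DP", 1, "Integer", "Read depth")
        header.info.add("TGT", 1, "String", "True genotype codes per sample (simulation)")
        header.info.add("ORIGIN", 1, "String", "Founder haplotype of origin (simulation)")
        for key, value in (meta or {}).items():
            header.add_meta(f"enuibd_{key}", str(value))
        for s in self.samples:
            header.add_sample(s)
        gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
        with pysam.VariantFile(str(path), "w", header=header) as vcf:
            for i in range(self.n_sites):
                rec = vcf.new_record(
                    contig=str(self.chrom[i]),
                    start=int(self.pos[i]) - 1,
                    stop=int(self.pos[i]) - 1 + len(str(self.ref[i])),
                    alleles=(str(self.ref[i]), str(self.alt[i])),
                    qual=float(self.qual[i]),
                )
                fl = int(self.flags[i])
                if fl == 0:
                    rec.filter.add("PASS")
                else:
                    for bit, name in FLAG_NAMES.items():
                        if fl & bit:
                            rec.filter.add(name)
                if self.truth_gt is not None:
                    rec.info["TGT"] = "".join(
                        "." if g == MISSING else str(int(g)) for g in self.truth_gt[i]
                    )
                if self.origin is not None:
                    rec.info["ORIGIN"] = str(self.origin[i])
                for j, sample in enumerate(self.samples):
                    rs = rec.samples[sample]
                    rs["GT"] = gt_map[int(self.gt[i, j])]
                    with np.errstate(divide="ignore"):
                        log10gl = np.log10(np.maximum(self.gl[i, j], 1e-300))
                    rs["GL"] = tuple(float(x) for x in log10gl)
                    rs["AD"] = (int(self.ref_support[i, j]), int(self.alt_support[i, j]))
                    rs["DP"] = int(self.depth[i, j])
                vcf.write(rec)


def _rescale_gl(gl: np.ndarray) -> np.ndarray:
    """Rescale linear likelihood triples so each sample's max is 1."""
    m = gl.max(axis=-1, keepdims=True)
    m[m <= 0] = 1.0
    return gl / m


def read_vcf(path, require_biallelic: bool = True) -> VariantTable:
    """Read a multi-sample VCF into a :class:`VariantTable`.

    Expects GT and, ideally, GL (log10) or PL (Phred) plus AD/DP; absent
    likelihoods are reconstructed as certainty in the called genotype.
    """
    cols: dict[str, list] = {k: [] for k in
                             ("chrom", "pos", "ref", "alt", "qual", "flags")}
    gts, gls, dps, ads_r, ads_a, tgts, origins = [], [], [], [], [], [], []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or (require_biallelic and len(rec.alts) != 1):
                continue
            cols["chrom"].append(rec.contig)
            cols["pos"].append(rec.pos)
            cols["ref"].append(rec.ref)
            cols["alt"].append(rec.alts[0])
            cols["qual"].append(rec.qual if rec.qual is not None else np.nan)
            fl = 0
            for name in rec.filter.keys():
                fl |= _NAME_TO_FLAG.get(name, 0)
            cols["flags"].append(fl)
            tgts.append(rec.info.get("TGT", None))
            origins.append(rec.info.get("ORIGIN", None))
            row_gt, row_gl, row_dp, row_ar, row_aa = [], [], [], [], []
            for s in samples:
                rs = rec.samples[s]
                alleles = rs.get("GT", (None, None))
                if alleles is None or any(a is None for a in alleles):
                    g = MISSING
                else:
                    g = int(sum(alleles))
                row_gt.append(g)
                gl = rs.get("GL", None)
                pl = rs.get("PL", None)
                if gl is not None and len(gl) == 3 and gl[0] is not None:
                    lin = np.power(10.0, np.asarray(gl, dtype=float))
                elif pl is not None and len(pl) == 3 and pl[0] is not None:
                    lin = np.power(10.0, -np.asarray(pl, dtype=float) / 10.0)
                else:
                    lin = np.zeros(3)
                    lin[g if g != MISSING else 0] = 1.0
                    if g == MISSING:
                        lin[:] = 1.0
                row_gl.append(lin)
                ad = rs.get("AD", None)
                if ad is not None and len(ad) >= 2 and ad[0] is not None:
                    row_ar.append(int(ad[0]))
                    row_aa.append(int(ad[1]))
                else:
                    row_ar.append(0)
                    row_aa.append(0)
                dp = rs.get("DP", None)
                row_dp.append(int(dp) if dp is not None else row_ar[-1] + row_aa[-1])
            gts.append(row_gt)
            gls.append(row_gl)
            dps.append(row_dp)
            ads_r.append(row_ar)
            ads_a.append(row_aa)
    n = len(cols["pos"])
    s = len(samples)
    truth = None
    if n and all(t is not None for t in tgts):
        truth = np.array(
            [[MISSING if ch == "." else int(ch) for ch in t] for t in tgts],
            dtype=np.int8,
        )
    origin = None
    if n and all(o is not None for o in origins):
        origin = np.array(origins, dtype=object)
    return VariantTable(
        samples=samples,
        chrom=np.array(cols["chrom"], dtype=object),
        pos=np.array(cols["pos"], dtype=np.int64),
        ref=np.array(cols["ref"], dtype=object),
        alt=np.array(cols["alt"], dtype=object),
        qual=np.array(cols["qual"], dtype=float),
        flags=np.array(cols["flags"], dtype=np.uint8),
        gt=np.array(gts, dtype=np.int8).reshape(n, s),
        gl=_rescale_gl(np.array(gls, dtype=float).reshape(n, s, 3)),
        depth=np.array(dps, dtype=np.int32).reshape(n, s),
        ref_support=np.array(ads_r, dtype=np.int32).reshape(n, s),
        alt_support=np.array(ads_a, dtype=np.int32).reshape(n, s),
        truth_gt=truth,
        origin=origin,
    )
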