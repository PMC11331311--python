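"""Genotype/haplotype containers and file I/O.

The pipeline works on two in-memory containers: a phased
:class:`HaplotypePanel` (substrate for EHH-family statistics) and an
unphased :class:`GenotypeMatrix` (substrate for ROH calling and allele
frequencies).  Readers and writers cover the plain-text exchange formats
the scans touch: VCF 4.2 with phased GT, PLINK .bed/.bim/.fam
(SNP-major v1.0), BED / GFF3 gene annotation and TSV tracks.

Internal coordinates are 1-based inclusive everywhere; BED's 0-based
half-open convention is converted at the boundary.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

MISSING = -1  # missing genotype code in GenotypeMatrix

__all__ = [
    "HaplotypePanel",
    "GenotypeMatrix",
    "GeneAnnotation",
    "read_vcf_haplotypes",
    "write_vcf",
    "intersect_sites",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_plink",
    "write_plink",
    "write_track",
    "read_track",
]


def _check_sites(chrom: np.ndarray, positions: np.ndarray) -> None:
    """Positions must be strictly increasing within each chromosome."""
    if len(chrom) != len(positions):
        raise ValueError("chromosome labels and positions differ in length")
    for c in pd.unique(chrom):
        pos = positions[chrom == c]
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on {c}")


@dataclass
class HaplotypePanel:
    """Phased 0/1 haplotype matrix with site metadata.

    Parameters
    ----------
    alleles : (n_hap, n_sites) array of {0, 1}
        Row ``2i`` and ``2i+1`` are the two haplotypes of individual ``i``.
    positions : int array, bp, 1-based, strictly increasing per chromosome.
    chrom : str array, one label per site.
    samples : individual identifiers (half the number of haplotype rows).
    genetic_pos : optional cM per site; defaults to a 1 cM/Mb linear map.
    ref, alt : optional REF/ALT allele strings per site (used for
        harmonization when intersecting two panels).
    """

    alleles: np.ndarray
    positions: np.ndarray
    chrom: np.ndarray
    samples: list[str]
    genetic_pos: np.ndarray | None = None
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        if self.alleles.ndim != 2:
            raise ValueError("allele matrix must be 2-D")
        if self.alleles.shape[0] % 2 != 0:
            raise ValueError("haplotype count must be even (two per individual)")
        if self.alleles.shape[0] != 2 * len(self.samples):
            raise ValueError("sample list inconsistent with haplotype count")
        if self.alleles.shape[1] != len(self.positions):
            raise ValueError("site metadata inconsistent with allele matrix")
        _check_sites(self.chrom, self.positions)
        if self.genetic_pos is not None:
            self.genetic_pos = np.asarray(self.genetic_pos, dtype=float)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def cm(self) -> np.ndarray:
        """Genetic positions in cM (1 cM/Mb linear map when none supplied)."""
        if self.genetic_pos is not None:
            return self.genetic_pos
        return self.positions / 1e6

    def to_genotypes(self) -> "GenotypeMatrix":
        """Collapse haplotype pairs into 0/1/2 genotype counts."""
        g = self.alleles[0::2].astype(np.int8) + self.alleles[1::2]
        return GenotypeMatrix(
            genotypes=g,
            positions=self.positions.copy(),
            chrom=self.chrom.copy(),
            samples=list(self.samples),
        )

    def take_sites(self, idx: np.ndarray) -> "HaplotypePanel":
        return HaplotypePanel(
            alleles=self.alleles[:, idx],
            positions=self.positions[idx],
            chrom=self.chrom[idx],
            samples=list(self.samples),
            genetic_pos=None if self.genetic_pos is None else self.genetic_pos[idx],
            ref=None if self.ref is None else np.asarray(self.ref)[idx],
            alt=None if self.alt is None else np.asarray(self.alt)[idx],
        )


@dataclass
class GenotypeMatrix:
    """Per-individual genotypes in {0, 1, 2, MISSING(-1)} with site metadata."""

    genotypes: np.ndarray
    positions: np.ndarray
    chrom: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        if self.genotypes.ndim != 2:
            raise ValueError("genotype matrix must be 2-D")
        if self.genotypes.shape[0] != len(self.samples):
            raise ValueError("sample list inconsistent with genotype matrix")
        if self.genotypes.shape[1] != len(self.positions):
            raise ValueError("site metadata inconsistent with genotype matrix")
        _check_sites(self.chrom, self.positions)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene interval, 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end < start")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_haplotypes(path: str | Path, strict: bool = True) -> HaplotypePanel:
    """Read phased biallelic SNPs from a VCF into a haplotype panel.

    Multiallelic records are skipped (counted).  Unphased genotypes raise
    in ``strict`` mode and skip the record otherwise.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    chroms: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_skipped += 1
            continue
        gts = v.genotypes  # [a0, a1, phased] per sample
        if any(not g[2] for g in gts):
            if strict:
                raise ValueError(
                    f"unphased genotype at {v.CHROM}:{v.POS} in strict mode"
                )
            n_skipped += 1
            continue
        col = np.array([[g[0], g[1]] for g in gts], dtype=np.int8).reshape(-1)
        cols.append(col)
        chroms.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
    if not cols:
        raise ValueError(f"no usable phased biallelic records in {path}")
    panel = HaplotypePanel(
        alleles=np.stack(cols, axis=1),
        positions=np.array(pos),
        chrom=np.array(chroms, dtype=object),
        samples=samples,
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
    )
    panel.n_skipped = n_skipped  # type: ignore[attr-defined]
    return panel


def write_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a panel as an uncompressed phased VCF 4.2."""
    ref = panel.ref if panel.ref is not None else np.full(panel.n_sites, "A", object)
    alt = panel.alt if panel.alt is not None else np.full(panel.n_sites, "C", object)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(panel.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        h = panel.alleles
        for j in range(panel.n_sites):
            gts = "\t".join(
                f"{h[2 * i, j]}|{h[2 * i + 1, j]}" for i in range(len(panel.samples))
            )
            fh.write(
                f"{panel.chrom[j]}\t{panel.positions[j]}\t.\t{ref[j]}\t{alt[j]}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Site intersection
# ---------------------------------------------------------------------------

def intersect_sites(
    panel_a: HaplotypePanel,
    panel_b: HaplotypePanel,
    strict: bool = False,
) -> tuple[HaplotypePanel, HaplotypePanel, pd.DataFrame]:
    """Restrict two panels to their shared sites and harmonize alleles.

    Sites are matched on (chromosome, position).  When REF/ALT strings are
    available and one panel has them swapped, that panel's allele column is
    flipped so allele 1 refers to the same nucleotide in both.  Sites whose
    allele pairs cannot be reconciled are dropped (counted) or raise in
    ``strict`` mode.  Returns both restricted panels plus the shared site
    index as a DataFrame (chrom, pos, flipped, dropped counts in attrs).
    """
    key_a = {(c, p): i for i, (c, p) in enumerate(zip(panel_a.chrom, panel_a.positions))}
    idx_a: list[int] = []
    idx_b: list[int] = []
    flip_b: list[bool] = []
    n_mismatch = 0
    for j, (c, p) in enumerate(zip(panel_b.chrom, panel_b.positions)):
        i = key_a.get((c, p))
        if i is None:
            continue
        flip = False
        if panel_a.ref is not None and panel_b.ref is not None:
            ra, aa = panel_a.ref[i], panel_a.alt[i]
            rb, ab = panel_b.ref[j], panel_b.alt[j]
            if (ra, aa) == (rb, ab):
                flip = False
            elif (ra, aa) == (ab, rb):
                flip = True
            else:
                if strict:
                    raise ValueError(f"allele mismatch at {c}:{p}")
                n_mismatch += 1
                continue
        idx_a.append(i)
        idx_b.append(j)
        flip_b.append(flip)
    idx_a_arr = np.array(idx_a, dtype=int)
    idx_b_arr = np.array(idx_b, dtype=int)
    out_a = panel_a.take_sites(idx_a_arr)
    out_b = panel_b.take_sites(idx_b_arr)
    flip_arr = np.array(flip_b, dtype=bool)
    if flip_arr.any():
        out_b.alleles[:, flip_arr] = 1 - out_b.alleles[:, flip_arr]
        if out_b.ref is not None:
            r = out_b.ref.copy()
            out_b.ref = np.where(flip_arr, out_b.alt, out_b.ref)
            out_b.alt = np.where(flip_arr, r, out_b.alt)
    sites = pd.DataFrame({"chrom": out_a.chrom, "pos": out_a.positions,
                          "flipped": flip_arr})
    sites.attrs["n_allele_mismatch_dropped"] = n_mismatch
    return out_a, out_b, sites


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def read_gene_annotation(path: str | Path, fmt: str | None = None) -> list[GeneAnnotation]:
    """Read gene intervals from BED (0-based half-open) or GFF3 (1-based).

    ``fmt`` is inferred from the file suffix when omitted.  Output is
    unified to 1-based inclusive coordinates.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "gff3" if suffix in {".gff", ".gff3"} else "bed"
    fmt = fmt.lower()
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            try:
                if fmt == "bed":
                    chrom, start, end = fields[0], int(fields[1]) + 1, int(fields[2])
                    gene_id = fields[3] if len(fields) > 3 else f"interval_{lineno}"
                elif fmt == "gff3":
                    if fields[2].lower() != "gene":
                        continue
                    chrom, start, end = fields[0], int(fields[3]), int(fields[4])
                    gene_id = _gff3_gene_id(fields[8]) or f"gene_{lineno}"
                else:
                    raise ValueError(f"unknown annotation format {fmt!r}")
                if end < start:
                    raise ValueError("end < start")
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from exc
            genes.append(GeneAnnotation(gene_id, chrom, start, end))
    return genes


def _gff3_gene_id(attrs: str) -> str | None:
    for part in attrs.split(";"):
        k, _, v = part.strip().partition("=")
        if k in {"ID", "gene_id", "Name"}:
            return v.removeprefix("gene:")
    return None


def write_gene_annotation(genes: list[GeneAnnotation], path: str | Path) -> None:
    """Write genes as a TSV (gene_id, chrom, start, end; 1-based inclusive)."""
    df = pd.DataFrame(
        [(g.gene_id, g.chrom, g.start, g.end) for g in genes],
        columns=["gene_id", "chrom", "start", "end"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_annotation_tsv(path: str | Path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t")
    return [
        GeneAnnotation(str(r.gene_id), str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# PLINK .bed/.bim/.fam (SNP-major v1.0)
# ---------------------------------------------------------------------------

_BED_MAGIC = b"\x6c\x1b\x01"
# 2-bit PLINK codes -> allele-1 dosage of the A1 allele (we store ALT as A1)
_BED_DECODE = {0b00: 2, 0b01: MISSING, 0b10: 1, 0b11: 0}
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def write_plink(g: GenotypeMatrix, prefix: str | Path,
                ref: np.ndarray | None = None, alt: np.ndarray | None = None) -> None:
    """Write a genotype matrix as PLINK .bed/.bim/.fam (SNP-major v1.0)."""
    prefix = Path(prefix)
    n = g.n_individuals
    ref = ref if ref is not None else np.full(g.n_sites, "A", object)
    alt = alt if alt is not None else np.full(g.n_sites, "C", object)
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in g.samples:
            fh.write(f"{s} {s} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j in range(g.n_sites):
            cm = g.positions[j] / 1e6
            fh.write(
                f"{g.chrom[j]}\tsnp{j}\t{cm:.6f}\t{g.positions[j]}\t{alt[j]}\t{ref[j]}\n"
            )
    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(g.n_sites):
            col = g.genotypes[:, j]
            buf = bytearray(n_bytes)
            for i, geno in enumerate(col):
                buf[i // 4] |= _BED_ENCODE[int(geno)] << (2 * (i % 4))
            fh.write(bytes(buf))


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read PLINK .bed/.bim/.fam; only SNP-major v1.0 .bed is supported."""
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    samples = [str(s) for s in fam[1]]
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None)
    chrom = bim[0].astype(str).to_numpy(dtype=object)
    positions = bim[3].to_numpy(dtype=np.int64)
    n = len(samples)
    n_sites = len(bim)
    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError("not a SNP-major PLINK v1.0 .bed file")
        data = fh.read()
    if len(data) != n_bytes * n_sites:
        raise ValueError(".bed size inconsistent with .bim/.fam")
    geno = np.empty((n, n_sites), dtype=np.int8)
    for j in range(n_sites):
        block = data[j * n_bytes:(j + 1) * n_bytes]
        for i in range(n):
            code = (block[i // 4] >> (2 * (i % 4))) & 0b11
            geno[i, j] = _BED_DECODE[code]
    return GenotypeMatrix(geno, positions, chrom, samples)


# ---------------------------------------------------------------------------
# TSV tracks
# ---------------------------------------------------------------------------

def write_track(chrom: np.ndarray, positions: np.ndarray, values: np.ndarray,
                path: str | Path, name: str = "value") -> None:
    pd.DataFrame({"chrom": chrom, "pos": positions, name: values}).to_csv(
        path, sep="\t", index=False
    )


def read_track(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
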