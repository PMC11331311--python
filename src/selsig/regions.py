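"""Merging significant SNPs into regions and annotating them with genes.

Adjacent significant SNPs on one chromosome are chained when their
inter-SNP distance is strictly below ``max_gap`` (1 Mb by default); each
maximal chain becomes a region spanning its first to last SNP, 1-based
inclusive.  Genes overlap a region when the two inclusive intervals
share at least one bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GeneAnnotation

__all__ = ["Region", "merge_regions", "annotate_regions", "summarize_regions"]


@dataclass
class Region:
    chrom: str
    start: int
    end: int
    n_snps: int
    genes: list[str] = field(default_factory=list)

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def merge_regions(
    chrom: np.ndarray,
    positions: np.ndarray,
    significant: np.ndarray,
    max_gap: int = 1_000_000,
) -> list[Region]:
    """Chain consecutive significant SNPs separated by < max_gap bp.

    Chains never cross chromosomes; a gap of exactly ``max_gap`` splits.
    Returns regions sorted by (chromosome order of appearance, start).
    """
    chrom = np.asarray(chrom, dtype=object)
    positions = np.asarray(positions)
    significant = np.asarray(significant, dtype=bool)
    regions: list[Region] = []
    for c in pd.unique(chrom):
        sel = (chrom == c) & significant
        pos = np.sort(positions[sel])
        if len(pos) == 0:
            continue
        start = pos[0]
        prev = pos[0]
        n = 1
        for p in pos[1:]:
            if p - prev < max_gap:
                n += 1
            else:
                regions.append(Region(str(c), int(start), int(prev), n))
                start = p
                n = 1
            prev = p
        regions.append(Region(str(c), int(start), int(prev), n))
    return regions


def annotate_regions(
    regions: list[Region],
    genes: list[GeneAnnotation],
) -> list[Region]:
    """Attach overlapping genes (1-based inclusive, >=1 shared bp) in order.

    Warns when the chromosome name sets of regions and genes are disjoint
    (likely a naming mismatch).
    """
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: (g.start, g.end))
    region_chroms = {r.chrom for r in regions}
    if regions and genes and not (region_chroms & set(by_chrom)):
        import warnings

        warnings.warn(
            f"no shared chromosome names between {len(regions)} regions "
            f"and {len(genes)} genes"
        )
    for r in regions:
        r.genes = [
            g.gene_id
            for g in by_chrom.get(r.chrom, [])
            if g.start <= r.end and g.end >= r.start
        ]
    return regions


def summarize_regions(regions: list[Region]) -> dict:
    """Counts, total/mean/SD length, per-chromosome counts, distinct genes."""
    if not regions:
        return {"n_regions": 0, "total_length_bp": 0, "mean_length_bp": 0.0,
                "sd_length_bp": 0.0, "per_chromosome": {}, "n_genes_distinct": 0}
    lengths = np.array([r.length_bp for r in regions], dtype=float)
    per_chrom = pd.Series([r.chrom for r in regions]).value_counts().to_dict()
    distinct = {g for r in regions for g in r.genes}
    return {
        "n_regions": len(regions),
        "total_length_bp": int(lengths.sum()),
        "mean_length_bp": float(lengths.mean()),
        "sd_length_bp": float(np.std(lengths, ddof=1)) if len(lengths) > 1 else 0.0,
        "per_chromosome": per_chrom,
        "n_genes_distinct": len(distinct),
    }


def regions_frame(regions: list[Region]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.chrom, r.start, r.end, r.n_snps, r.length_bp, len(r.genes),
          ";".join(r.genes)) for r in regions],
        columns=["chrom", "start", "end", "n_snps", "length_bp", "n_genes", "genes"],
    )


def write_regions_bed(regions: list[Region], path) -> None:
    """BED export (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\tregion\t{r.n_snps}\n")
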