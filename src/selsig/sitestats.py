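"""Allele-frequency-based measures: per-SNP FST and heterozygosity.

FST here is the per-SNP form used for two equally weighted populations:
the squared deviation of one population's allele frequency from the
baseline (the mean of the two frequencies), divided by the allelic
variance of the baseline, FST = (p1 - p̄)² / (p̄(1 - p̄)).  With equal
weights the deviation is identical for either population, so one
deviation suffices.  Sites with a monomorphic baseline are masked (NaN),
not zeroed, so they drop out of downstream rank-based p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genio import MISSING, GenotypeMatrix

__all__ = [
    "SiteFrequencyTable",
    "allele_frequencies",
    "site_frequency_table",
    "fst_per_snp",
    "mean_fst",
    "observed_heterozygosity",
]


@dataclass
class SiteFrequencyTable:
    """Per-SNP allele-1 frequencies for two populations and their baseline."""

    p1: np.ndarray
    p2: np.ndarray
    n_calls1: np.ndarray
    n_calls2: np.ndarray

    @property
    def p_bar(self) -> np.ndarray:
        return (self.p1 + self.p2) / 2.0


def allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Allele-1 frequency per SNP; missing calls excluded from the denominator.

    SNPs with zero non-missing calls are NaN.
    """
    geno = g.genotypes
    valid = geno != MISSING
    counts = np.where(valid, geno, 0).sum(axis=0).astype(float)
    denom = 2.0 * valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(denom > 0, counts / denom, np.nan)
    return freq


def site_frequency_table(g1: GenotypeMatrix, g2: GenotypeMatrix) -> SiteFrequencyTable:
    if g1.n_sites != g2.n_sites:
        raise ValueError("populations have different site counts")
    return SiteFrequencyTable(
        p1=allele_frequencies(g1),
        p2=allele_frequencies(g2),
        n_calls1=(g1.genotypes != MISSING).sum(axis=0),
        n_calls2=(g2.genotypes != MISSING).sum(axis=0),
    )


def fst_per_snp(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Per-SNP FST = (p1 - p̄)² / (p̄(1 - p̄)) with p̄ = (p1 + p2)/2.

    Returns NaN where the baseline is monomorphic (denominator zero) or
    either frequency is missing.  Values lie in [0, 1].
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("frequency vectors differ in length")
    p_bar = (p1 + p2) / 2.0
    num = (p1 - p_bar) ** 2
    den = p_bar * (1.0 - p_bar)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(den > 0, num / den, np.nan)
    return fst


def mean_fst(p1: np.ndarray, p2: np.ndarray) -> float:
    """Genome-wide FST as the standard multi-locus ratio of averages.

    Σ(p1 - p̄)² / Σ p̄(1 - p̄) over polymorphic-baseline sites.  Under the
    Balding–Nichols model with parameter F this converges to F/(2 - F)
    (the per-locus expectations are F·p(1-p)/2 and p(1-p)(1-F/2)); the
    naive mean of per-SNP ratios is biased below that limit and depends
    on the ancestral frequency spectrum.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p_bar = (p1 + p2) / 2.0
    num = (p1 - p_bar) ** 2
    den = p_bar * (1.0 - p_bar)
    ok = np.isfinite(num) & np.isfinite(den) & (den > 0)
    if not ok.any():
        raise ValueError("no polymorphic-baseline sites")
    return float(num[ok].sum() / den[ok].sum())


def observed_heterozygosity(g: GenotypeMatrix) -> float:
    """Proportion of non-missing genotype calls that are heterozygous."""
    geno = g.genotypes
    valid = geno != MISSING
    n_valid = valid.sum()
    if n_valid == 0:
        raise ValueError("no non-missing genotype calls")
    return float((geno == 1).sum() / n_valid)
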