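# Methods

## Overview

`selsig` implements a two-population selection scan: four per-SNP
statistics (ROH-based autozygosity, smoothed |iHS|, smoothed per-SNP
F<sub>ST</sub>, XP-EHH) are combined into a decorrelated composite
(DCMS), calibrated to empirical-normal p-values, FDR-adjusted
(Benjamini–Hochberg), and segmented into candidate selected regions
that are annotated with overlapping genes.  A synthetic two-population
generator with a recorded truth table provides the test substrate.

## Per-SNP statistics

**Allele frequencies and F<sub>ST</sub>.**  Frequencies count allele 1
over non-missing calls.  Per-SNP F<sub>ST</sub> is the squared
deviation of one population's frequency from the baseline
p̄ = (p₁+p₂)/2, divided by p̄(1−p̄); with equal population weights the
two deviations are identical, so one suffices — this is why the
multi-locus calibration below should not be mistaken for a bug when it
differs from the naive average.  Monomorphic-baseline sites are masked
(NaN), not zeroed, so they are excluded from rank-based p-values rather
than piling up as ties.  The *genome-wide* F<sub>ST</sub>
(`mean_fst`) is the standard ratio of averages
Σ(p₁−p̄)²/Σp̄(1−p̄): under the Balding–Nichols model with parameter F
its expectation is F/(2−F) for any ancestral frequency spectrum,
whereas the mean of per-SNP ratios is biased downward (≈0.090 instead
of 0.111 at F = 0.2 with uniform ancestral frequencies) and
spectrum-dependent.

**ROH.**  A sliding window of `window_snp` SNPs (default 100, the
sequence-density choice; array-density callers use 50) moves one SNP at
a time; a window is homozygous if it has ≤1 heterozygous and ≤5 missing
calls.  A SNP is eligible when ≥5% of the *full* windows containing it
are homozygous — truncated windows at chromosome ends are never formed,
which keeps the contract simple and reproducible.  Maximal eligible
runs are split at adjacent-SNP gaps >1,000 kb and kept if they have
≥100 SNPs, ≥1,000 kb, and ≤50 kb per SNP.  Autozygosity at a SNP is
the fraction of individuals with at least one covering segment
(overlapping segments of one individual count once).

**EHH family.**  EHH at marker distance d from a core allele is
Σ_g C(n_g,2)/C(n,2) over the identity classes of the carriers on the
closed core-to-marker interval.  Identity classes are maintained by
incremental partition refinement (one O(n) step per marker); the O(n²)
pairwise definition is kept in the test suite as the oracle and the two
agree exactly.  iHH integrates EHH over genetic distance (default map:
1 cM/Mb, configurable; physical distance is the same code path with
cM = Mb) by the trapezoid rule, outward from the core per side,
truncated at the first marker where EHH < 0.05 with the crossing point
interpolated linearly.  A side that reaches the chromosome end before
decaying marks the SNP invalid; such SNPs are excluded from
standardization, since their truncated integrals would otherwise bias
bin dispersions.  iHS = ln(iHH_anc/iHH_der) is standardized to mean
0/SD 1 within 50 equal-width derived-frequency bins on
[0.05, 0.95] (bins with zero SD yield 0).  Ancestral alleles come from
simulation truth, or the allele-0-as-ancestral convention on real VCFs;
since the composite uses |iHS|, polarization errors only permute signs.
XP-EHH integrates the *all-haplotype* EHH of both populations outward
from each core, both truncated at the same boundary — the nearer point
where either population's curve crosses 0.05 — and standardizes
ln(iHH_A/iHH_B) genome-wide.  No gap penalty is applied between
distant markers.

**Smoothing.**  |iHS| (after standardization) and F<sub>ST</sub> are
smoothed with a centered running median over k SNPs (default 1,001 at
genome scale; the analysis drivers use 101 on the 2,000-SNP fixture,
the same ~5% fraction of the scan).  Within k//2 of a track end the
window shrinks symmetrically to k′ = 2·min(i, n−1−i)+1; NaNs are
excluded per window.  This end rule is implemented directly because
library median filters pad with zeros or reflections instead of
shrinking.  XP-EHH enters the composite unsmoothed by default (a
config switch enables smoothing); it is oriented so positive values
point toward the focal breed.

## Composite and significance

Each track is converted to a right-tailed p-value from ascending
fractional ranks, p = 1 − (rank − 0.5)/n with average ties, which keeps
p strictly inside (0,1) — necessary because the DCMS log term diverges
at 0 and 1.  The signal correlation matrix is the Pearson correlation
of the absolute-valued tracks on pairwise-complete sites.  DCMS weights
are w_t = 1/Σ_i |r_it| with the self term included; absolute values
are used in the denominator because signed sums can be non-positive
and the inputs are already magnitude transforms.  Duplicating a track
that is uncorrelated with the rest leaves every score unchanged (the
duplicated pair's weights halve); when the duplicate correlates with
other tracks their weights shift too, so the identity is exact only in
the uncorrelated case — the tests demonstrate it on exactly orthogonal
balanced designs.

Loci missing any component (masked F<sub>ST</sub>, invalid iHS) are
dropped from the composite (complete case); imputing p = 0.5 is
available behind `missing_policy="impute_half"`.  A component track
that is constant (e.g. an all-zero autozygosity track in a small null
cohort with no ROH) is removed from the composite with a log line
rather than aborting the scan, since its correlation with anything is
undefined.  Raw DCMS is converted to upper-tail p-values using a
normal with the scan's own empirical mean and SD, BH-adjusted, and
SNPs with q < alpha (default 0.05) that lie strictly less than 1 Mb
apart (same chromosome) are chained into regions spanning their first
to last SNP, 1-based inclusive; region length is end − start + 1, so a
single-SNP region has length 1.  Genes overlap a region when their
1-based inclusive intervals share ≥1 bp; genes merely near a region
are not assigned.

## Synthetic data generator

The generator emulates the structure a two-breed scan consumes, not
population-genetic history:

- **Differentiation** — Balding–Nichols: per-SNP ancestral frequency
  uniform on (0.05, 0.95); population frequencies Beta-distributed with
  mean p and variance F·p(1−p) (F = 0 is the degenerate point mass);
  genotypes binomial.  Sites are unlinked.
- **LD** — founder mosaics: `n_founders` (default 30) founder
  haplotypes; each sample haplotype copies a founder and switches to a
  random founder between adjacent SNPs with probability
  1 − exp(−switch_rate·gap) (default 2×10⁻⁶/bp, one switch per 500 kb
  expected).
- **Hard sweeps** — a carrier haplotype of an uncommon core allele
  (the nearest SNP with allele-1 frequency in [0.02, 0.30]) is copied
  onto random recipients until the carrier fraction reaches the
  target.  Each recipient copies a contiguous interval
  [core − u·flank, core + v·flank], u,v ~ U(0,1] (default flank
  250 kb), so haplotype sharing decays with distance from the core the
  way recombination erodes a real swept haplotype; a fixed-window
  variant (`taper=None`) copies the full flank onto every recipient and
  is the variant under which EHH at the core provably never decreases.
  The fixed-window variant leaves a *flat* statistic plateau in which
  the core is exchangeable with every flank SNP — useless for testing
  localization, which is why the tapered footprint is the default.
- **ROH** — planted homozygous segments: the chosen individuals' two
  haplotypes are overwritten with one shared template over the
  interval (phased path), or set to the per-site major homozygote
  (genotype path).
- Optional missing genotypes at a configurable rate (default 0).

Defaults describe the desk-scale study: 5 Mb, 2,000 SNPs (2.5 kb
spacing), 100 individuals per population, F = 0.05.  Everything is
deterministic under a fixed seed.

What the generator does **not** emulate: coalescent/recombination
history, mutation, allele-frequency spectra of real cattle,
ascertainment, imputation error, variable recombination rate, and
genome-scale track lengths.  Passing tests therefore show the
*pipeline machinery* is correct and can recover planted signals at
desk scale; they do not certify power or error rates on real
whole-genome data.

## Small-sample behavior of the null

On a 5 Mb/1,000-SNP null cohort pair the scan occasionally (roughly a
fifth to a third of random seeds) calls a borderline region
(q ≈ 0.045): a chance single-SNP XP-EHH excursion has rank-p ≈ 1/(2n),
and the DCMS sum is heavier-tailed than the normal used to calibrate
it, so BH's smallest threshold (alpha/n) can be crossed when moderate
co-signals align.  At genome scale (millions of SNPs) the BH bar is
about four orders of magnitude stricter and the same mechanism is
negligible.  The null-calibration driver reports this rate rather than
asserting an exact error level.  Relatedly, the empirical-normal
calibration assumes signals occupy a negligible fraction of the scan;
a planted 1.2 Mb island on a 5 Mb toy genome inflates the empirical
mean/SD enough to keep itself below q < 0.05 even when it is the
top-ranked signal.

## Numerical and design choices

- Internal coordinates are 1-based inclusive everywhere; BED converted
  at the boundary.  Allele harmonization at site intersection keys on
  REF/ALT strings (swapped pairs are flipped; irreconcilable pairs are
  dropped and counted, or raise in strict mode); strand flips are
  unsupported.
- PLINK .bed I/O is the SNP-major v1.0 layout only, written/read by a
  small built-in codec.
- BH q-values are computed via statsmodels (`fdr_bh`); a quadratic
  min-over-tails oracle verifies them in the tests.  Significance is
  strict: q < alpha.
- ROH length classes are half-open [a,b) Mb so they partition; the SD
  of a single value is NaN by default (0 on request).
- iHS subsampling (`subsample_average`) partitions individuals into
  near-equal random bins, scans each and averages standardized scores
  per SNP, reporting between-bin correlations as an agreement
  diagnostic; agreement is driven by true genomic signal and is weak
  on pure-null fixtures.
- Problem sizes in tests and the acceptance script (10,000-SNP
  calibration cohorts, 2,000-SNP scan fixtures, 20-run null) were
  chosen so the whole suite runs in a couple of minutes on one core
  while keeping every stage's assertions sharp.

## Known limitations

No Weir–Cockerham/Hudson F<sub>ST</sub> estimators, nSL/H12 variants,
HMM-based ROH callers, local-FDR or alternative composites; no tabix
or bgzip support; two populations only.
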