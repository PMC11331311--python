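"""Haplotype-based selection statistics: EHH, iHH, iHS and XP-EHH.

Extended haplotype homozygosity (EHH) at marker distance d from a core
SNP is the probability that two randomly drawn carrier haplotypes of a
core allele are identical over the closed interval between the core and
that marker: EHH(d) = Σ_g C(n_g, 2) / C(n, 2) over the identity classes
g of the carriers.  iHH integrates the EHH decay curve over genetic
distance (trapezoid rule, truncated where EHH first falls below a
cutoff, with the crossing interpolated linearly); iHS is the ln ratio of
the ancestral and derived allele iHH, standardized within
derived-allele-frequency bins; XP-EHH is the ln ratio of two
populations' all-haplotype iHH, standardized genome-wide.

The identity classes are tracked by incremental partition refinement,
so one outward step costs O(n) rather than O(n²) pairwise comparisons;
the pairwise brute force is kept in the test suite as the oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import HaplotypePanel

__all__ = [
    "EhhCurve",
    "ehh_curve",
    "ihh",
    "ihs_scan",
    "xpehh_scan",
    "subsample_average",
]

DECAY_CUTOFF = 0.05


@dataclass
class EhhCurve:
    """EHH decay left and right of a core SNP for one core allele.

    Distance 0 (the core itself, EHH = 1) is included on both sides.
    Arrays run outward from the core.
    """

    core_index: int
    allele: int
    left_pos: np.ndarray
    left_cm: np.ndarray
    left_ehh: np.ndarray
    right_pos: np.ndarray
    right_cm: np.ndarray
    right_ehh: np.ndarray


def _chrom_bounds(panel: HaplotypePanel, core: int) -> tuple[int, int]:
    """Inclusive index range of the core's chromosome (contiguous block)."""
    c = panel.chrom[core]
    lo = core
    while lo > 0 and panel.chrom[lo - 1] == c:
        lo -= 1
    hi = core
    n = panel.n_sites
    while hi < n - 1 and panel.chrom[hi + 1] == c:
        hi += 1
    return lo, hi


class _Partition:
    """Identity classes of a haplotype set, refined one site at a time."""

    __slots__ = ("labels", "n", "n_groups", "_map")

    def __init__(self, n: int) -> None:
        self.n = n
        self.labels = np.zeros(n, dtype=np.intp)
        self.n_groups = 1
        self._map = np.empty(2 * n, dtype=np.intp)

    def refine(self, col: np.ndarray) -> float:
        """Split classes by the next site's alleles; return the new EHH."""
        keys = (self.labels << 1) | col
        counts = np.bincount(keys, minlength=2 * self.n_groups)
        nz = np.flatnonzero(counts)
        self._map[nz] = np.arange(len(nz))
        self.labels = self._map[keys]
        self.n_groups = len(nz)
        c = counts[nz]
        return float((c * (c - 1)).sum() / (self.n * (self.n - 1)))


def _ehh_outward(sub: np.ndarray, core: int, stop: int, step: int):
    """Yield (site index, EHH) stepping outward from the core to ``stop``.

    ``sub`` holds the carrier haplotypes only (rows already subset).
    """
    part = _Partition(sub.shape[0])
    j = core
    ehh = 1.0
    while j != stop:
        j += step
        if ehh > 0.0:
            ehh = part.refine(sub[:, j].astype(np.intp))
        yield j, ehh


def ehh_curve(panel: HaplotypePanel, core: int, allele: int) -> EhhCurve:
    """Full EHH decay curve for carriers of ``allele`` at the core SNP."""
    carriers = np.flatnonzero(panel.alleles[:, core] == allele)
    if len(carriers) < 2:
        raise ValueError("EHH undefined: fewer than 2 carrier haplotypes")
    lo, hi = _chrom_bounds(panel, core)
    cm = panel.cm()
    sub = panel.alleles[carriers]
    sides = {}
    for name, stop, step in (("left", lo, -1), ("right", hi, 1)):
        idx = [core]
        vals = [1.0]
        for j, e in _ehh_outward(sub, core, stop, step):
            idx.append(j)
            vals.append(e)
        idx_arr = np.array(idx)
        sides[name] = (panel.positions[idx_arr], cm[idx_arr], np.array(vals))
    return EhhCurve(
        core_index=core,
        allele=allele,
        left_pos=sides["left"][0], left_cm=sides["left"][1], left_ehh=sides["left"][2],
        right_pos=sides["right"][0], right_cm=sides["right"][1],
        right_ehh=sides["right"][2],
    )


def _ihh_side(sub: np.ndarray, cm: np.ndarray, core: int, stop: int,
              step: int, cutoff: float) -> tuple[float, bool]:
    """Integrate EHH outward; returns (area, decayed-before-chromosome-end)."""
    area = 0.0
    prev_cm = cm[core]
    prev_ehh = 1.0
    for j, ehh in _ehh_outward(sub, core, stop, step):
        d = abs(cm[j] - prev_cm)
        if ehh < cutoff:
            # linear interpolation of the crossing point within this interval
            frac = (prev_ehh - cutoff) / (prev_ehh - ehh)
            area += frac * d * (prev_ehh + cutoff) / 2.0
            return area, True
        area += d * (prev_ehh + ehh) / 2.0
        prev_cm, prev_ehh = cm[j], ehh
    return area, False  # hit the chromosome end before decaying


def ihh(panel: HaplotypePanel, core: int, allele: int,
        decay_cutoff: float = DECAY_CUTOFF) -> tuple[float, bool]:
    """Integrated EHH (left + right) for one core allele.

    Integration is over genetic distance in cM (1 cM/Mb by default).
    ``valid`` is False when either side reaches a chromosome end before
    EHH decays below the cutoff.
    """
    carriers = np.flatnonzero(panel.alleles[:, core] == allele)
    if len(carriers) < 2:
        return float("nan"), False
    lo, hi = _chrom_bounds(panel, core)
    cm = panel.cm()
    sub = panel.alleles[carriers]
    left, ok_l = _ihh_side(sub, cm, core, lo, -1, decay_cutoff)
    right, ok_r = _ihh_side(sub, cm, core, hi, 1, decay_cutoff)
    return left + right, ok_l and ok_r


def _standardize_binned(unstd: np.ndarray, freq: np.ndarray, valid: np.ndarray,
                        n_bins: int, lo: float, hi: float) -> np.ndarray:
    """Subtract bin mean / divide by bin SD within equal-width freq bins."""
    std = np.full(len(unstd), np.nan)
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.searchsorted(edges, freq, side="right") - 1, 0, n_bins - 1)
    for b in range(n_bins):
        sel = valid & (which == b)
        if not sel.any():
            continue
        vals = unstd[sel]
        mu = vals.mean()
        sd = vals.std(ddof=0)
        std[sel] = (vals - mu) / sd if sd > 0 else 0.0
    return std


def ihs_scan(
    panel: HaplotypePanel,
    ancestral: np.ndarray | None = None,
    decay_cutoff: float = DECAY_CUTOFF,
    n_freq_bins: int = 50,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Per-SNP iHS over a phased panel.

    ``ancestral`` gives the ancestral allele (0/1) per site; by default
    allele 0 is taken as ancestral.  SNPs are scored when the derived
    allele frequency lies in [maf_min, 1 - maf_min] and the EHH of both
    alleles decays before the chromosome ends.  The unstandardized score
    ln(iHH_ancestral / iHH_derived) is standardized to mean 0 / SD 1
    within ``n_freq_bins`` equal-width derived-frequency bins.

    Returns a DataFrame with columns chrom, pos, freq_der, ihh_anc,
    ihh_der, ihs_unstd, ihs_std, valid.
    """
    n_sites = panel.n_sites
    n_hap = panel.n_haplotypes
    anc = np.zeros(n_sites, dtype=np.int8) if ancestral is None else np.asarray(ancestral)
    der = 1 - anc
    freq_der = np.array([
        np.mean(panel.alleles[:, j] == der[j]) for j in range(n_sites)
    ])
    ihh_anc = np.full(n_sites, np.nan)
    ihh_der = np.full(n_sites, np.nan)
    unstd = np.full(n_sites, np.nan)
    valid = np.zeros(n_sites, dtype=bool)
    in_band = (freq_der >= maf_min) & (freq_der <= 1 - maf_min)
    for j in np.flatnonzero(in_band):
        a, ok_a = ihh(panel, j, int(anc[j]), decay_cutoff)
        d, ok_d = ihh(panel, j, int(der[j]), decay_cutoff)
        ihh_anc[j] = a
        ihh_der[j] = d
        if ok_a and ok_d and a > 0 and d > 0:
            unstd[j] = np.log(a / d)
            valid[j] = True
    if not valid.any():
        import warnings

        warnings.warn("no valid SNPs in iHS scan")
    std = _standardize_binned(unstd, freq_der, valid, n_freq_bins, maf_min, 1 - maf_min)
    return pd.DataFrame({
        "chrom": panel.chrom, "pos": panel.positions, "freq_der": freq_der,
        "ihh_anc": ihh_anc, "ihh_der": ihh_der,
        "ihs_unstd": unstd, "ihs_std": std, "valid": valid,
    })


def _xp_side(hA: np.ndarray, hB: np.ndarray, cm: np.ndarray, core: int,
             stop: int, step: int, cutoff: float) -> tuple[float, float, bool]:
    """Joint outward integration of two populations' all-haplotype EHH.

    Both areas are truncated at the same boundary: the nearer point where
    either population's EHH crosses the cutoff (crossing interpolated
    linearly).  Returns (area_A, area_B, decayed_flag).
    """
    gen_a = _ehh_outward(hA, core, stop, step)
    gen_b = _ehh_outward(hB, core, stop, step)
    area_a = area_b = 0.0
    prev_cm = cm[core]
    pa = pb = 1.0
    for (j, ea), (_, eb) in zip(gen_a, gen_b):
        d = abs(cm[j] - prev_cm)
        if ea < cutoff or eb < cutoff:
            frac = 1.0
            if ea < cutoff:
                frac = min(frac, (pa - cutoff) / (pa - ea))
            if eb < cutoff:
                frac = min(frac, (pb - cutoff) / (pb - eb))
            ia = pa + frac * (ea - pa)  # EHH interpolated at the boundary
            ib = pb + frac * (eb - pb)
            area_a += frac * d * (pa + ia) / 2.0
            area_b += frac * d * (pb + ib) / 2.0
            return area_a, area_b, True
        area_a += d * (pa + ea) / 2.0
        area_b += d * (pb + eb) / 2.0
        prev_cm, pa, pb = cm[j], ea, eb
    return area_a, area_b, False


def xpehh_scan(
    panel_a: HaplotypePanel,
    panel_b: HaplotypePanel,
    decay_cutoff: float = DECAY_CUTOFF,
) -> pd.DataFrame:
    """Per-SNP XP-EHH between two panels sharing a site index.

    Both populations' all-haplotype EHH curves are integrated outward
    from each core, truncated at the same boundary (where either curve
    first drops below the cutoff); the unstandardized score
    ln(iHH_A / iHH_B) is standardized genome-wide.  Positive values mean
    longer haplotypes — candidate selection — in population A.
    """
    if panel_a.n_sites != panel_b.n_sites or np.any(
        panel_a.positions != panel_b.positions
    ):
        raise ValueError("panels must share the site index (run intersect_sites)")
    n_sites = panel_a.n_sites
    cm = panel_a.cm()
    ihh_a = np.full(n_sites, np.nan)
    ihh_b = np.full(n_sites, np.nan)
    unstd = np.full(n_sites, np.nan)
    valid = np.zeros(n_sites, dtype=bool)
    for j in range(n_sites):
        lo, hi = _chrom_bounds(panel_a, j)
        la, lb, ok_l = _xp_side(panel_a.alleles, panel_b.alleles, cm, j, lo, -1,
                                decay_cutoff)
        ra, rb, ok_r = _xp_side(panel_a.alleles, panel_b.alleles, cm, j, hi, 1,
                                decay_cutoff)
        a, b = la + ra, lb + rb
        ihh_a[j], ihh_b[j] = a, b
        if ok_l and ok_r and a > 0 and b > 0:
            unstd[j] = np.log(a / b)
            valid[j] = True
    std = np.full(n_sites, np.nan)
    if valid.any():
        vals = unstd[valid]
        sd = vals.std(ddof=0)
        if sd > 0:
            std[valid] = (vals - vals.mean()) / sd
        else:
            std[valid] = 0.0
    return pd.DataFrame({
        "chrom": panel_a.chrom, "pos": panel_a.positions,
        "ihh_a": ihh_a, "ihh_b": ihh_b,
        "xpehh_unstd": unstd, "xpehh_std": std, "valid": valid,
    })


def subsample_average(
    panel: HaplotypePanel,
    n_bins: int,
    seed: int,
    **ihs_kwargs,
) -> tuple[pd.DataFrame, np.ndarray]:
    """iHS averaged over random individual bins (memory-bounded scanning).

    Individuals are partitioned at random into ``n_bins`` near-equal
    groups; iHS is computed per group and the standardized scores are
    averaged per SNP over the groups where they are valid.  Returns the
    averaged track plus the pairwise Pearson correlation matrix between
    group tracks (complete cases), a diagnostic of between-bin agreement.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins == 1:
        track = ihs_scan(panel, **ihs_kwargs)
        return track, np.ones((1, 1))
    rng = np.random.default_rng(seed)
    n_ind = len(panel.samples)
    order = rng.permutation(n_ind)
    groups = np.array_split(order, n_bins)
    if min(len(g) for g in groups) < 2:
        raise ValueError("each bin must contain at least 2 individuals")
    tracks = []
    for grp in groups:
        hap_rows = np.sort(np.concatenate([[2 * i, 2 * i + 1] for i in grp]))
        sub = HaplotypePanel(
            alleles=panel.alleles[hap_rows],
            positions=panel.positions.copy(),
            chrom=panel.chrom.copy(),
            samples=[panel.samples[i] for i in np.sort(grp)],
            genetic_pos=panel.genetic_pos,
        )
        tracks.append(ihs_scan(sub, **ihs_kwargs)["ihs_std"].to_numpy())
    stack = np.vstack(tracks)
    n_obs = np.isfinite(stack).sum(axis=0)
    mean_track = np.where(
        n_obs > 0, np.nansum(np.nan_to_num(stack, nan=0.0), axis=0)
        / np.maximum(n_obs, 1), np.nan,
    )
    corr = pd.DataFrame(stack.T).corr().to_numpy()
    out = pd.DataFrame({
        "chrom": panel.chrom, "pos": panel.positions,
        "ihs_std": mean_track,
        "valid": ~np.isnan(mean_track),
    })
    return out, corr
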