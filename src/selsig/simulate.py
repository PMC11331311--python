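"""Two-population synthetic genotype/haplotype generator with known truth.

Emulates the data a two-breed selection scan consumes: two diverged
populations with tunable differentiation (Balding–Nichols model),
background linkage disequilibrium (founder-mosaic haplotypes), hard
selective sweeps (a founder haplotype copied to high frequency, leaving
the long shared-haplotype footprint EHH statistics detect) and planted
homozygous segments for ROH calling.  Every generator is deterministic
under a fixed seed and records what it planted in a truth table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genio import MISSING, GenotypeMatrix, HaplotypePanel

__all__ = [
    "SimConfig",
    "TruthTable",
    "SweepTruth",
    "RohTruth",
    "sim_balding_nichols",
    "sim_mosaic_haplotypes",
    "inject_sweep",
    "plant_roh",
    "simulate_two_populations",
]


@dataclass(frozen=True)
class SweepTruth:
    population: int
    core_index: int
    core_pos: int
    realized_freq: float
    flank_bp: int
    applied: bool = True


@dataclass(frozen=True)
class RohTruth:
    population: int
    individuals: tuple[int, ...]
    start: int
    end: int


@dataclass
class TruthTable:
    """What the simulator planted: sweeps and homozygous segments."""

    sweeps: list[SweepTruth] = field(default_factory=list)
    roh: list[RohTruth] = field(default_factory=list)


@dataclass
class SimConfig:
    """Study conditions for the synthetic two-population cohort.

    Defaults describe a desk-scale chromosome: 5 Mb carrying 2,000 SNPs
    (2.5 kb spacing, sequence-like density), 100 individuals per
    population, moderate divergence (Balding–Nichols F = 0.05), and
    mosaic haplotypes built from 30 founders with an expected founder
    switch every 500 kb — enough background LD for EHH decay to be
    measurable but fast enough to scan in seconds.
    """

    n_ind_per_pop: int = 100
    n_snps: int = 2000
    chrom_length: int = 5_000_000
    chrom: str = "1"
    fst_param: float = 0.05
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    n_founders: int = 30
    switch_rate: float = 2e-6
    sweep_specs: list[tuple[int, int, float]] = field(default_factory=list)
    # (population, core position bp, target carrier frequency)
    roh_specs: list[tuple[int, float, tuple[int, int]]] = field(default_factory=list)
    # (population, fraction of individuals, (start bp, end bp))
    missing_rate: float = 0.0
    sweep_flank_bp: int = 250_000
    seed: int = 0
    n_pops: int = 2

    def __post_init__(self) -> None:
        if self.n_pops != 2:
            raise ValueError("only two populations are supported")
        if not 0 <= self.fst_param < 1:
            raise ValueError("fst_param must be in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("ancestral_freq_range must lie in (0, 1)")
        if self.switch_rate < 0:
            raise ValueError("switch_rate must be non-negative")
        if self.n_founders < 1:
            raise ValueError("n_founders must be >= 1")

    def positions(self) -> np.ndarray:
        """Evenly spaced 1-based positions along the chromosome."""
        return np.linspace(1, self.chrom_length, self.n_snps).astype(np.int64)


def _ancestral_freqs(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.ancestral_freq_range
    return rng.uniform(lo, hi, config.n_snps)


def _population_freqs(p: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    """Balding–Nichols draw: Beta with mean p, variance fst·p(1−p)."""
    if fst == 0.0:
        return p.copy()  # degenerate point mass at p
    scale = (1.0 - fst) / fst
    return rng.beta(p * scale, (1.0 - p) * scale)


def sim_balding_nichols(config: SimConfig) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Simulate unlinked genotypes for two populations under Balding–Nichols.

    Each SNP's ancestral frequency is uniform over
    ``ancestral_freq_range``; each population frequency is Beta-distributed
    around it with variance ``fst_param * p * (1 - p)``; genotypes are
    binomial(2, population frequency) per individual.  Sites are unlinked
    by construction.
    """
    rng = np.random.default_rng(config.seed)
    p = _ancestral_freqs(config, rng)
    positions = config.positions()
    chrom = np.full(config.n_snps, config.chrom, dtype=object)
    out = []
    for k in range(2):
        pk = _population_freqs(p, config.fst_param, rng)
        g = rng.binomial(2, pk, size=(config.n_ind_per_pop, config.n_snps)).astype(np.int8)
        g = _inject_missing(g, config.missing_rate, rng)
        out.append(
            GenotypeMatrix(
                g, positions.copy(), chrom.copy(),
                [f"pop{k + 1}_ind{i}" for i in range(config.n_ind_per_pop)],
            )
        )
    return out[0], out[1]


def _inject_missing(g: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate > 0:
        mask = rng.random(g.shape) < rate
        g[mask] = MISSING
    return g


def sim_mosaic_haplotypes(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    pop_freqs: np.ndarray | None = None,
    pop_label: str = "pop1",
) -> HaplotypePanel:
    """Simulate a phased panel with background LD from a founder mosaic.

    ``n_founders`` founder haplotypes are drawn per site from the given
    allele frequencies; each sample haplotype copies one founder and
    switches to a random founder between adjacent SNPs with probability
    ``1 - exp(-switch_rate * gap_bp)``.  Small founder pools and low
    switch rates give long shared segments, i.e. strong local LD.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = pop_freqs if pop_freqs is not None else _ancestral_freqs(config, rng)
    positions = config.positions()
    founders = (rng.random((config.n_founders, config.n_snps)) < p).astype(np.int8)
    n_hap = 2 * config.n_ind_per_pop
    gaps = np.diff(positions)
    p_switch = 1.0 - np.exp(-config.switch_rate * gaps)
    # vectorized mosaic: draw switch events and founder choices per haplotype
    choice = rng.integers(0, config.n_founders, size=(n_hap, config.n_snps))
    switch = np.ones((n_hap, config.n_snps), dtype=bool)
    switch[:, 1:] = rng.random((n_hap, config.n_snps - 1)) < p_switch
    # founder index at SNP j = last chosen founder at or before j
    idx = np.where(switch, np.arange(config.n_snps), 0)
    idx = np.maximum.accumulate(idx, axis=1)
    source = np.take_along_axis(choice, idx, axis=1)
    alleles = founders[source, np.arange(config.n_snps)]
    return HaplotypePanel(
        alleles=alleles,
        positions=positions,
        chrom=np.full(config.n_snps, config.chrom, dtype=object),
        samples=[f"{pop_label}_ind{i}" for i in range(config.n_ind_per_pop)],
    )


def inject_sweep(
    panel: HaplotypePanel,
    core_index: int,
    target_freq: float,
    flank_bp: int,
    seed: int,
    population: int = 0,
    taper: str | None = "uniform",
) -> tuple[HaplotypePanel, SweepTruth]:
    """Drive one haplotype to high frequency around a core SNP (hard sweep).

    A carrier haplotype of the core's allele-1 is chosen and its alleles
    around the core are copied onto randomly chosen non-carrier
    haplotypes until the carrier fraction of the core allele reaches
    ``target_freq``.  With ``taper="uniform"`` (default) each recipient
    copies a contiguous interval ``[core - u*flank_bp, core + v*flank_bp]``
    with u, v ~ U(0, 1] — mimicking recombination eating into the swept
    haplotype, so haplotype sharing decays with distance from the core
    the way a real hard sweep's footprint does.  ``taper=None`` copies
    the full ``core ± flank_bp`` window onto every recipient.  Sites
    outside the flank are never touched.  If the core allele already
    exceeds the target the panel is returned unchanged and the truth
    entry is marked not applied.
    """
    if not 0 < target_freq < 1:
        raise ValueError("target_freq must be in (0, 1)")
    if taper not in (None, "uniform"):
        raise ValueError("taper must be None or 'uniform'")
    rng = np.random.default_rng(seed)
    h = panel.alleles.copy()
    n_hap = h.shape[0]
    core_pos = int(panel.positions[core_index])
    carriers = np.flatnonzero(h[:, core_index] == 1)
    if len(carriers) == 0:
        raise ValueError("core SNP is not segregating for allele 1")
    current = len(carriers) / n_hap
    if current >= target_freq:
        warnings.warn("sweep target below current frequency; no-op")
        return panel, SweepTruth(population, core_index, core_pos,
                                 current, flank_bp, applied=False)
    donor = int(rng.choice(carriers))
    need = int(np.ceil(target_freq * n_hap)) - len(carriers)
    non_carriers = np.flatnonzero(h[:, core_index] != 1)
    recipients = rng.choice(non_carriers, size=need, replace=False)
    for rec in recipients:
        if taper == "uniform":
            left_bp = int(np.ceil(rng.uniform(0, 1) * flank_bp))
            right_bp = int(np.ceil(rng.uniform(0, 1) * flank_bp))
        else:
            left_bp = right_bp = flank_bp
        lo = np.searchsorted(panel.positions, core_pos - left_bp, side="left")
        hi = np.searchsorted(panel.positions, core_pos + right_bp, side="right")
        h[rec, lo:hi] = h[donor, lo:hi]
    out = HaplotypePanel(
        alleles=h,
        positions=panel.positions.copy(),
        chrom=panel.chrom.copy(),
        samples=list(panel.samples),
        genetic_pos=None if panel.genetic_pos is None else panel.genetic_pos.copy(),
        ref=panel.ref,
        alt=panel.alt,
    )
    realized = np.mean(out.alleles[:, core_index] == 1)
    return out, SweepTruth(population, core_index, core_pos, float(realized), flank_bp)


def plant_roh(
    g: GenotypeMatrix,
    individuals: list[int],
    interval: tuple[int, int],
) -> GenotypeMatrix:
    """Make the listed individuals homozygous over a bp interval.

    The homozygous allele at each site is the per-site major allele
    (computed over non-missing calls in the input matrix).  An empty
    individual list is the identity.
    """
    if not individuals:
        return g
    start, end = interval
    if start > end:
        raise ValueError("interval start > end")
    geno = g.genotypes.copy()
    in_interval = (g.positions >= start) & (g.positions <= end)
    cols = np.flatnonzero(in_interval)
    for j in cols:
        col = g.genotypes[:, j]
        valid = col != MISSING
        freq1 = col[valid].sum() / (2 * valid.sum()) if valid.any() else 0.0
        major_geno = 2 if freq1 >= 0.5 else 0
        geno[individuals, j] = major_geno
    return GenotypeMatrix(geno, g.positions.copy(), g.chrom.copy(), list(g.samples))


def _pick_sweep_core(panel: HaplotypePanel, core_pos: int,
                     freq_band: tuple[float, float] = (0.02, 0.30),
                     search_bp: int = 250_000) -> int:
    """Nearest SNP to ``core_pos`` whose allele-1 frequency is sweepable.

    A sweep drives a rare haplotype to high frequency, so the core allele
    must start uncommon; the nearest SNP with frequency inside
    ``freq_band`` wins (falling back to the nearest SNP outright).
    """
    nearest = int(np.argmin(np.abs(panel.positions - core_pos)))
    freqs = panel.alleles.mean(axis=0)
    near = np.abs(panel.positions - core_pos) <= search_bp
    ok = near & (freqs >= freq_band[0]) & (freqs <= freq_band[1])
    if not ok.any():
        return nearest
    cand = np.flatnonzero(ok)
    return int(cand[np.argmin(np.abs(panel.positions[cand] - core_pos))])


def simulate_two_populations(
    config: SimConfig,
) -> tuple[HaplotypePanel, HaplotypePanel, TruthTable]:
    """Full synthetic study: two mosaic panels plus sweeps and planted ROH.

    Both populations share an ancestral frequency spectrum; each draws
    its own Balding–Nichols frequencies (differentiation ``fst_param``)
    and its own founder pool and mosaics (independent LD).  Sweeps from
    ``sweep_specs`` are injected into the phased panels; ``roh_specs``
    homozygous segments are planted by overwriting both haplotypes of
    the chosen individuals with one shared template over the interval.
    """
    rng = np.random.default_rng(config.seed)
    p = _ancestral_freqs(config, rng)
    truth = TruthTable()
    panels: list[HaplotypePanel] = []
    for k in range(2):
        pk = _population_freqs(p, config.fst_param, rng)
        panel = sim_mosaic_haplotypes(
            config, rng=rng, pop_freqs=pk, pop_label=f"pop{k + 1}"
        )
        panels.append(panel)
    for pop, core_pos, target in config.sweep_specs:
        core_index = _pick_sweep_core(panels[pop], core_pos)
        col = panels[pop].alleles[:, core_index]
        if col.sum() == 0:
            # force a few carriers so the sweep has a template to copy
            carriers = rng.choice(len(col), size=max(2, len(col) // 20), replace=False)
            panels[pop].alleles[carriers, core_index] = 1
        panels[pop], entry = inject_sweep(
            panels[pop], core_index, target, config.sweep_flank_bp,
            seed=int(rng.integers(2**31)), population=pop,
        )
        truth.sweeps.append(entry)
    for pop, fraction, (start, end) in config.roh_specs:
        n_planted = int(round(fraction * config.n_ind_per_pop))
        chosen = rng.choice(config.n_ind_per_pop, size=n_planted, replace=False)
        panel = panels[pop]
        in_iv = (panel.positions >= start) & (panel.positions <= end)
        cols = np.flatnonzero(in_iv)
        template = panel.alleles[2 * int(chosen[0]), cols]
        for i in chosen:
            panel.alleles[2 * i, cols] = template
            panel.alleles[2 * i + 1, cols] = template
        truth.roh.append(RohTruth(pop, tuple(int(i) for i in sorted(chosen)), start, end))
    return panels[0], panels[1], truth


def truth_table_frame(truth: TruthTable):
    """Truth table as a tidy DataFrame for TSV export."""
    import pandas as pd

    rows = []
    for s in truth.sweeps:
        rows.append({"kind": "sweep", "population": s.population,
                     "core_index": s.core_index, "core_pos": s.core_pos,
                     "realized_freq": round(s.realized_freq, 6),
                     "flank_bp": s.flank_bp, "applied": s.applied,
                     "individuals": "", "start": "", "end": ""})
    for r in truth.roh:
        rows.append({"kind": "roh", "population": r.population,
                     "core_index": "", "core_pos": "", "realized_freq": "",
                     "flank_bp": "", "applied": True,
                     "individuals": ";".join(map(str, r.individuals)),
                     "start": r.start, "end": r.end})
    return pd.DataFrame(rows)
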