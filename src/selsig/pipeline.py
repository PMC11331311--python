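"""End-to-end per-breed scan: statistic tracks → DCMS → regions.

``run_breed_scan`` executes the whole chain on two phased panels:
shared-site intersection, focal-breed ROH/autozygosity, focal-breed
smoothed |iHS|, smoothed per-SNP FST, focal-oriented XP-EHH, fractional
rank p-values, signal correlation, DCMS, empirical-normal p, BH FDR,
region merging and gene annotation.  Every stage is a pure function of
its inputs, so a rerun with the same config and panels is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composite, genio, haplostats, regions as regions_mod, roh, sitestats
from .genio import GeneAnnotation, HaplotypePanel
from .roh import ROHParams
from .simulate import SimConfig, simulate_two_populations, truth_table_frame

__all__ = ["PipelineConfig", "ScanResult", "run_breed_scan", "run_simulation"]


@dataclass
class PipelineConfig:
    """All knobs of the per-breed scan, with the scan's standard defaults.

    ``smooth_k`` is clamped (with a log line) to the largest odd window
    not exceeding the shared-site count, so small simulated chromosomes
    can run with the same config structure as genome-scale data.
    """

    focal: str = "A"  # which population the scan targets
    roh_params: ROHParams = field(default_factory=ROHParams)
    smooth_k: int = 1001
    decay_cutoff: float = 0.05
    n_freq_bins: int = 50
    maf_min: float = 0.05
    alpha: float = 0.05
    merge_gap: int = 1_000_000
    smooth_xpehh: bool = False
    missing_policy: str = "drop"  # or "impute_half"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.focal not in {"A", "B"}:
            raise ValueError("focal must be 'A' or 'B'")
        if self.missing_policy not in {"drop", "impute_half"}:
            raise ValueError("missing_policy must be 'drop' or 'impute_half'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        roh_raw = raw.pop("roh_params", {})
        return cls(roh_params=ROHParams(**roh_raw), **raw)


@dataclass
class ScanResult:
    table: pd.DataFrame
    regions: list[regions_mod.Region]
    summary: dict
    log: list[str]


def _clamp_odd(k: int, n: int) -> int:
    k = min(k, n if n % 2 == 1 else n - 1)
    return k if k % 2 == 1 else k - 1


def run_breed_scan(
    panel_a: HaplotypePanel,
    panel_b: HaplotypePanel,
    config: PipelineConfig,
    genes: list[GeneAnnotation] | None = None,
    out_dir: str | Path | None = None,
) -> ScanResult:
    """Full scan for the focal breed; see module docstring for the stages."""
    log: list[str] = []

    def note(stage: str, **kv) -> None:
        log.append(stage + "\t" + "\t".join(f"{k}={v}" for k, v in kv.items()))

    pa, pb, sites = genio.intersect_sites(panel_a, panel_b)
    n_sites = pa.n_sites
    note("intersect", n_sites=n_sites,
         dropped=sites.attrs.get("n_allele_mismatch_dropped", 0))

    focal_panel, other_panel = (pa, pb) if config.focal == "A" else (pb, pa)
    g_focal = focal_panel.to_genotypes()
    g_other = other_panel.to_genotypes()

    segments = roh.detect_roh(g_focal, config.roh_params)
    az = roh.autozygosity(segments, g_focal.chrom, g_focal.positions,
                          g_focal.n_individuals)
    note("roh", n_segments=len(segments), mean_autozygosity=round(float(az.mean()), 6))

    ihs = haplostats.ihs_scan(
        focal_panel, decay_cutoff=config.decay_cutoff,
        n_freq_bins=config.n_freq_bins, maf_min=config.maf_min,
    )
    k = _clamp_odd(config.smooth_k, n_sites)
    if k != config.smooth_k:
        note("smoothing", requested_k=config.smooth_k, used_k=k)
    ihs_abs = np.abs(ihs["ihs_std"].to_numpy())
    ihs_smooth = composite.running_median(ihs_abs, k)
    note("ihs", n_valid=int(ihs["valid"].sum()))

    p_focal = sitestats.allele_frequencies(g_focal)
    p_other = sitestats.allele_frequencies(g_other)
    fst = sitestats.fst_per_snp(p_focal, p_other)
    fst_smooth = composite.running_median(fst, k)
    note("fst", n_masked=int(np.isnan(fst).sum()),
         mean_fst=round(sitestats.mean_fst(p_focal, p_other), 6))

    xp = haplostats.xpehh_scan(pa, pb, decay_cutoff=config.decay_cutoff)
    xpehh = xp["xpehh_std"].to_numpy().copy()
    if config.focal == "B":
        xpehh = -xpehh  # orient positive toward the focal breed
    if config.smooth_xpehh:
        xpehh = composite.running_median(xpehh, k)
    note("xpehh", n_valid=int(xp["valid"].sum()))

    tracks = {
        "autozygosity": az,
        "ihs_smooth": ihs_smooth,
        "fst_smooth": fst_smooth,
        "xpehh": xpehh,
    }
    kept = {}
    for name, values in tracks.items():
        if np.all(~np.isfinite(values)) or np.nanstd(values) == 0:
            note("composite", dropped_constant_track=name)
            continue
        kept[name] = values
    if len(kept) < 2:
        raise RuntimeError(
            f"composite stage: only {len(kept)} informative tracks at "
            f"{n_sites} sites"
        )

    p_mat = np.column_stack([composite.rank_pvalues(v) for v in kept.values()])
    if config.missing_policy == "impute_half":
        p_mat = np.where(np.isfinite(p_mat), p_mat, 0.5)
    r = composite.signal_correlation(kept)
    dcms = composite.dcms_score(p_mat, r)
    p_emp = composite.empirical_pvalues(dcms)
    q, flags = composite.bh_fdr(p_emp, config.alpha)
    note("composite", n_tracks=len(kept), n_complete=int(np.isfinite(dcms).sum()),
         n_significant=int(flags.sum()))

    regs = regions_mod.merge_regions(pa.chrom, pa.positions, flags,
                                     max_gap=config.merge_gap)
    if genes is not None:
        regs = regions_mod.annotate_regions(regs, genes)
    summary = regions_mod.summarize_regions(regs)
    note("regions", n_regions=len(regs),
         total_length_bp=summary["total_length_bp"])

    table = pd.DataFrame({
        "chrom": pa.chrom, "pos": pa.positions,
        "autozygosity": az, "ihs_smooth": ihs_smooth,
        "fst_smooth": fst_smooth, "xpehh": xpehh,
        "dcms": dcms, "p": p_emp, "q": q, "significant": flags,
    })
    for i, name in enumerate(kept):
        table[f"p_{name}"] = p_mat[:, i]

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "per_snp_table.tsv", sep="\t", index=False)
        roh.segments_frame(segments).to_csv(out / "roh_segments.tsv", sep="\t",
                                            index=False)
        regions_mod.regions_frame(regs).to_csv(out / "regions.tsv", sep="\t",
                                               index=False)
        regions_mod.write_regions_bed(regs, out / "regions.bed")
        (out / "scan.log").write_text("\n".join(log) + "\n")

    return ScanResult(table=table, regions=regs, summary=summary, log=log)


def run_simulation(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write simulated fixtures: phased VCFs, PLINK trios, truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel_a, panel_b, truth = simulate_two_populations(config)
    paths = {}
    for name, panel in (("pop_a", panel_a), ("pop_b", panel_b)):
        vcf_path = out / f"{name}.vcf"
        genio.write_vcf(panel, vcf_path)
        genio.write_plink(panel.to_genotypes(), out / name)
        paths[name] = vcf_path
    truth_path = out / "truth.tsv"
    truth_table_frame(truth).to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths
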