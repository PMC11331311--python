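"""Shared study conditions for the numbered analysis drivers.

One synthetic two-breed cohort stands in for real (typically
access-restricted) livestock genotypes:
a 5 Mb chromosome with 2,000 SNPs, 100 individuals per breed, moderate
background differentiation, one hard sweep driven to carrier frequency
0.8 in breed A, and one planted homozygous segment (ROH island) in 30%
of breed B.  Each breed thus carries one distinct selection-like signal,
mirroring a two-breed scan where the breeds' signatures differ.  All
drivers read and write under results/.
"""

from pathlib import Path

from selsig.simulate import SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
SIM_DIR = RESULTS / "sim"
SEED = 1

STUDY = SimConfig(
    n_ind_per_pop=100,
    n_snps=2000,
    chrom_length=5_000_000,
    fst_param=0.05,
    sweep_specs=[(0, 2_500_000, 0.8)],
    roh_specs=[(1, 0.3, (500_000, 1_700_000))],
    seed=SEED,
)

SMOOTH_K = 101  # ~5% of the simulated chromosome, scaled from 1,001/6.8M SNPs
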