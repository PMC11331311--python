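"""EHH/iHS/XP-EHH against the O(n²) pairwise brute force and hand integrals."""

import numpy as np
import pytest

from selsig.genio import HaplotypePanel
from selsig.haplostats import (
    ehh_curve,
    ihh,
    ihs_scan,
    subsample_average,
    xpehh_scan,
)
from selsig.simulate import SimConfig, sim_mosaic_haplotypes
from conftest import random_panel


def ehh_brute(panel: HaplotypePanel, core: int, allele: int, marker: int) -> float:
    """Pairwise EHH over the closed interval between core and marker."""
    carriers = np.flatnonzero(panel.alleles[:, core] == allele)
    n = len(carriers)
    lo, hi = min(core, marker), max(core, marker)
    seg = panel.alleles[carriers, lo:hi + 1]
    identical = sum(
        np.array_equal(seg[a], seg[b])
        for a in range(n) for b in range(a + 1, n)
    )
    return identical / (n * (n - 1) / 2)


def make_panel(rows, spacing=10_000):
    h = np.asarray(rows, dtype=np.int8)
    n = h.shape[1]
    return HaplotypePanel(
        alleles=h,
        positions=np.arange(1, n + 1) * spacing,
        chrom=np.full(n, "1", dtype=object),
        samples=[f"s{i}" for i in range(h.shape[0] // 2)],
    )


class TestEhhCurve:
    def test_three_carriers_one_step(self):
        # carriers of allele 1 extend one site with alleles {0, 0, 1}
        panel = make_panel([[1, 0], [1, 0], [1, 1], [0, 0]])
        curve = ehh_curve(panel, 0, 1)
        assert curve.right_ehh[0] == 1.0  # distance 0 by definition
        assert curve.right_ehh[1] == pytest.approx(1 / 3)

    def test_identical_carriers_stay_at_one(self):
        panel = make_panel([[1, 0, 1, 0]] * 3 + [[0, 1, 1, 1]])
        curve = ehh_curve(panel, 0, 1)
        np.testing.assert_allclose(curve.right_ehh, 1.0)
        np.testing.assert_allclose(curve.left_ehh, 1.0)

    def test_single_carrier_rejected(self):
        panel = make_panel([[1, 0], [0, 0], [0, 1], [0, 1]])
        with pytest.raises(ValueError):
            ehh_curve(panel, 0, 1)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_pairwise_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        panel = random_panel(rng, n_hap=2 * rng.integers(3, 11),
                             n_snps=rng.integers(5, 51))
        core = int(rng.integers(0, panel.n_sites))
        allele = int(rng.integers(0, 2))
        if (panel.alleles[:, core] == allele).sum() < 2:
            allele = 1 - allele
        if (panel.alleles[:, core] == allele).sum() < 2:
            pytest.skip("monomorphic core")
        curve = ehh_curve(panel, core, allele)
        for k, marker in enumerate(range(core, panel.n_sites)):
            assert curve.right_ehh[k] == pytest.approx(
                ehh_brute(panel, core, allele, marker), abs=1e-12
            )
        for k, marker in enumerate(range(core, -1, -1)):
            assert curve.left_ehh[k] == pytest.approx(
                ehh_brute(panel, core, allele, marker), abs=1e-12
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_non_increasing(self, seed):
        rng = np.random.default_rng(100 + seed)
        panel = random_panel(rng, n_hap=16, n_snps=40)
        core = 20
        if (panel.alleles[:, core] == 1).sum() < 2:
            pytest.skip("monomorphic core")
        curve = ehh_curve(panel, core, 1)
        assert np.all(np.diff(curve.right_ehh) <= 1e-12)
        assert np.all(np.diff(curve.left_ehh) <= 1e-12)


class TestIhh:
    def test_hand_trapezoid_immediate_decay(self):
        # two carriers differing at both flanking markers: EHH 1 -> 0 in one
        # 0.01 cM step each side; integral truncated at the 0.05 crossing.
        panel = make_panel([
            [0, 1, 0],
            [1, 1, 1],
            [0, 0, 1],
            [1, 0, 0],
        ])
        value, valid = ihh(panel, 1, 1)
        frac = (1.0 - 0.05) / 1.0
        per_side = frac * 0.01 * (1.0 + 0.05) / 2.0
        assert valid
        assert value == pytest.approx(2 * per_side, abs=1e-12)

    def test_no_decay_before_chromosome_end_invalid(self):
        panel = make_panel([[1, 1, 1]] * 3 + [[0, 0, 0]])
        _, valid = ihh(panel, 1, 1)
        assert not valid

    def test_genetic_map_linearity(self):
        rng = np.random.default_rng(5)
        panel = random_panel(rng, n_hap=20, n_snps=60)
        core = 30
        base, ok = ihh(panel, core, 1)
        doubled = HaplotypePanel(
            alleles=panel.alleles, positions=panel.positions,
            chrom=panel.chrom, samples=panel.samples,
            genetic_pos=2.0 * panel.positions / 1e6,
        )
        v2, ok2 = ihh(doubled, core, 1)
        assert ok == ok2
        assert v2 == pytest.approx(2 * base)

    def test_haplotype_order_permutation_invariant(self):
        rng = np.random.default_rng(6)
        panel = random_panel(rng, n_hap=20, n_snps=60)
        perm = rng.permutation(20)
        shuffled = HaplotypePanel(
            alleles=panel.alleles[perm], positions=panel.positions,
            chrom=panel.chrom, samples=panel.samples,
        )
        assert ihh(shuffled, 30, 1)[0] == pytest.approx(ihh(panel, 30, 1)[0])


@pytest.fixture(scope="module")
def ld_panel():
    cfg = SimConfig(n_ind_per_pop=60, n_snps=400, chrom_length=1_000_000,
                    n_founders=12, seed=21)
    return sim_mosaic_haplotypes(cfg)


class TestIhsScan:
    def test_equal_ihh_gives_zero_unstd(self, ld_panel):
        track = ihs_scan(ld_panel)
        valid = track[track["valid"]]
        near = valid[np.isclose(valid["ihh_anc"], valid["ihh_der"])]
        assert np.allclose(near["ihs_unstd"], 0.0)

    def test_bin_standardization_identity(self, ld_panel):
        track = ihs_scan(ld_panel, n_freq_bins=10)
        valid = track[track["valid"]]
        edges = np.linspace(0.05, 0.95, 11)
        for b in range(10):
            sel = valid[(valid["freq_der"] >= edges[b])
                        & (valid["freq_der"] < edges[b + 1])]
            if len(sel) > 1 and sel["ihs_std"].std(ddof=0) > 0:
                assert sel["ihs_std"].mean() == pytest.approx(0.0, abs=1e-9)
                assert sel["ihs_std"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_maf_band_excluded(self, ld_panel):
        track = ihs_scan(ld_panel, maf_min=0.2)
        out_of_band = track[(track["freq_der"] < 0.2) | (track["freq_der"] > 0.8)]
        assert not out_of_band["valid"].any()


class TestXpehhScan:
    def test_identical_panels_give_zero(self, rng):
        panel = random_panel(rng, n_hap=20, n_snps=50)
        track = xpehh_scan(panel, panel)
        valid = track[track["valid"]]
        assert len(valid) > 0
        np.testing.assert_allclose(valid["xpehh_unstd"], 0.0, atol=1e-12)

    def test_population_swap_negates(self, rng):
        a = random_panel(rng, n_hap=20, n_snps=50)
        b = random_panel(rng, n_hap=16, n_snps=50)
        ab = xpehh_scan(a, b)
        ba = xpehh_scan(b, a)
        np.testing.assert_allclose(
            ab["xpehh_unstd"], -ba["xpehh_unstd"], atol=1e-12
        )

    def test_site_index_mismatch_rejected(self, rng):
        a = random_panel(rng, n_hap=8, n_snps=50)
        b = random_panel(rng, n_hap=8, n_snps=49)
        with pytest.raises(ValueError):
            xpehh_scan(a, b)


class TestSubsampleAverage:
    def test_one_bin_equals_plain_scan(self):
        cfg = SimConfig(n_ind_per_pop=30, n_snps=200, chrom_length=500_000,
                        n_founders=10, seed=3)
        panel = sim_mosaic_haplotypes(cfg)
        avg, corr = subsample_average(panel, n_bins=1, seed=0)
        plain = ihs_scan(panel)
        np.testing.assert_allclose(avg["ihs_std"], plain["ihs_std"], atol=1e-12)
        assert corr.shape == (1, 1)

    def test_deterministic_under_seed(self):
        cfg = SimConfig(n_ind_per_pop=20, n_snps=150, chrom_length=400_000,
                        n_founders=8, seed=4)
        panel = sim_mosaic_haplotypes(cfg)
        a, _ = subsample_average(panel, n_bins=2, seed=7)
        b, _ = subsample_average(panel, n_bins=2, seed=7)
        np.testing.assert_array_equal(a["ihs_std"].to_numpy(),
                                      b["ihs_std"].to_numpy())

    def test_groups_agree_on_large_fixture(self):
        # between-bin agreement is driven by true genomic signal, so the
        # fixture carries a sweep the way real scan data carries selection
        from selsig.simulate import simulate_two_populations

        cfg = SimConfig(n_ind_per_pop=200, n_snps=1000, chrom_length=2_500_000,
                        n_founders=20, sweep_specs=[(0, 1_250_000, 0.8)], seed=5)
        panel, _, _ = simulate_two_populations(cfg)
        _, corr = subsample_average(panel, n_bins=2, seed=1)
        assert corr[0, 1] > 0.5

    def test_tiny_groups_rejected(self):
        cfg = SimConfig(n_ind_per_pop=3, n_snps=50, chrom_length=100_000, seed=6)
        panel = sim_mosaic_haplotypes(cfg)
        with pytest.raises(ValueError):
            subsample_average(panel, n_bins=2, seed=0)
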