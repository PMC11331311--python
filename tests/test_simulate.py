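"""Synthetic-data generator: determinism, model calibration, truth tables."""

import numpy as np
import pytest

from selsig.haplostats import ehh_curve
from selsig.simulate import (
    SimConfig,
    inject_sweep,
    plant_roh,
    sim_balding_nichols,
    sim_mosaic_haplotypes,
    simulate_two_populations,
)


class TestSimConfig:
    def test_invalid_fst_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(fst_param=1.0)

    def test_invalid_freq_range_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(ancestral_freq_range=(0.0, 0.9))

    def test_negative_switch_rate_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(switch_rate=-1e-9)


class TestBaldingNichols:
    def test_zero_fst_equal_expected_frequencies(self):
        # F=0 collapses the Beta to a point mass: both populations draw
        # genotypes from identical per-SNP frequencies.
        cfg = SimConfig(n_ind_per_pop=2000, n_snps=200, fst_param=0.0, seed=0)
        g1, g2 = sim_balding_nichols(cfg)
        f1 = g1.genotypes.mean(axis=0) / 2
        f2 = g2.genotypes.mean(axis=0) / 2
        np.testing.assert_allclose(f1, f2, atol=0.05)

    def test_same_seed_identical(self):
        cfg = SimConfig(n_ind_per_pop=20, n_snps=100, fst_param=0.1, seed=42)
        a1, a2 = sim_balding_nichols(cfg)
        b1, b2 = sim_balding_nichols(cfg)
        np.testing.assert_array_equal(a1.genotypes, b1.genotypes)
        np.testing.assert_array_equal(a2.genotypes, b2.genotypes)

    def test_missing_rate_injected(self):
        cfg = SimConfig(n_ind_per_pop=100, n_snps=200, missing_rate=0.1, seed=1)
        g1, _ = sim_balding_nichols(cfg)
        frac = (g1.genotypes == -1).mean()
        assert 0.05 < frac < 0.15


class TestMosaicHaplotypes:
    def test_zero_switch_rate_copies_founders(self):
        cfg = SimConfig(n_ind_per_pop=20, n_snps=100, switch_rate=0.0,
                        n_founders=6, seed=9)
        panel = sim_mosaic_haplotypes(cfg)
        founders = {tuple(row) for row in panel.alleles}
        assert len(founders) <= 6

    def test_high_switch_rate_breaks_ld(self):
        cfg = SimConfig(n_ind_per_pop=200, n_snps=300, chrom_length=300_000,
                        switch_rate=1.0, seed=2)
        panel = sim_mosaic_haplotypes(cfg)
        h = panel.alleles.astype(float)
        r2 = []
        for j in range(h.shape[1] - 1):
            a, b = h[:, j], h[:, j + 1]
            if a.std() > 0 and b.std() > 0:
                r2.append(np.corrcoef(a, b)[0, 1] ** 2)
        # adjacent r² at the independent-draw level: ~1/n_hap
        assert np.mean(r2) < 3.0 / h.shape[0]

    def test_single_founder_monomorphic(self):
        cfg = SimConfig(n_ind_per_pop=10, n_snps=50, n_founders=1, seed=3)
        panel = sim_mosaic_haplotypes(cfg)
        assert np.all(panel.alleles == panel.alleles[0])

    def test_deterministic(self):
        cfg = SimConfig(n_ind_per_pop=15, n_snps=80, seed=13)
        a = sim_mosaic_haplotypes(cfg)
        b = sim_mosaic_haplotypes(cfg)
        np.testing.assert_array_equal(a.alleles, b.alleles)


class TestInjectSweep:
    @pytest.fixture()
    def panel(self):
        cfg = SimConfig(n_ind_per_pop=100, n_snps=400, chrom_length=1_000_000,
                        n_founders=15, seed=17)
        return sim_mosaic_haplotypes(cfg)

    def _segregating_core(self, panel, lo=0.05, hi=0.4):
        freqs = panel.alleles.mean(axis=0)
        mid = np.argsort(np.abs(np.arange(panel.n_sites) - panel.n_sites // 2))
        for j in mid:
            if lo <= freqs[j] <= hi:
                return int(j)
        raise AssertionError("no usable core")

    def test_realized_carrier_count(self, panel):
        core = self._segregating_core(panel)
        out, entry = inject_sweep(panel, core, 0.8, 200_000, seed=1)
        count = (out.alleles[:, core] == 1).sum()
        assert abs(count - 0.8 * 200) <= 1
        assert entry.realized_freq == pytest.approx(count / 200)

    def test_whole_chromosome_flank_full_identity(self, panel):
        core = self._segregating_core(panel)
        out, _ = inject_sweep(panel, core, 0.9, 2_000_000, seed=1, taper=None)
        carriers = np.flatnonzero(out.alleles[:, core] == 1)
        identical = (out.alleles[carriers] == out.alleles[carriers[0]]).all(axis=1)
        assert identical.sum() >= len(carriers) - (panel.alleles[:, core] == 1).sum()

    def test_target_below_current_is_noop(self, panel):
        freqs = panel.alleles.mean(axis=0)
        core = int(np.argmax(freqs))
        with pytest.warns(UserWarning):
            out, entry = inject_sweep(panel, core, freqs[core] / 2, 100_000, seed=1)
        assert not entry.applied
        np.testing.assert_array_equal(out.alleles, panel.alleles)

    def test_sites_outside_flank_untouched(self, panel):
        core = self._segregating_core(panel)
        flank = 100_000
        out, _ = inject_sweep(panel, core, 0.8, flank, seed=2)
        core_pos = panel.positions[core]
        outside = (panel.positions < core_pos - flank) | (
            panel.positions > core_pos + flank
        )
        np.testing.assert_array_equal(out.alleles[:, outside],
                                      panel.alleles[:, outside])

    def test_core_frequency_never_decreases(self, panel):
        core = self._segregating_core(panel)
        before = (panel.alleles[:, core] == 1).mean()
        out, _ = inject_sweep(panel, core, 0.7, 150_000, seed=3)
        assert (out.alleles[:, core] == 1).mean() >= before

    def test_ehh_never_decreases_with_full_window_copy(self, panel):
        core = self._segregating_core(panel)
        out, _ = inject_sweep(panel, core, 0.8, 2_000_000, seed=4, taper=None)
        before = ehh_curve(panel, core, 1)
        after = ehh_curve(out, core, 1)
        assert np.all(after.right_ehh >= before.right_ehh - 1e-12)
        assert np.all(after.left_ehh >= before.left_ehh - 1e-12)


class TestPlantRoh:
    def test_empty_list_identity(self, rng):
        from conftest import genotypes_from

        g = genotypes_from(rng.choice([0, 1, 2], size=(5, 50)))
        out = plant_roh(g, [], (1, 100_000))
        np.testing.assert_array_equal(out.genotypes, g.genotypes)

    def test_planted_individuals_homozygous_major(self, rng):
        from conftest import genotypes_from

        g = genotypes_from(rng.choice([0, 1, 2], size=(10, 50)))
        out = plant_roh(g, [0, 1, 2], (100_000, 300_000))
        sel = (g.positions >= 100_000) & (g.positions <= 300_000)
        planted = out.genotypes[np.ix_([0, 1, 2], np.flatnonzero(sel))]
        assert np.all((planted == 0) | (planted == 2))
        # untouched individuals and sites unchanged
        np.testing.assert_array_equal(out.genotypes[3:], g.genotypes[3:])
        np.testing.assert_array_equal(out.genotypes[:, ~sel], g.genotypes[:, ~sel])


class TestFullSimulation:
    def test_truth_rows_and_determinism(self):
        cfg = SimConfig(n_ind_per_pop=30, n_snps=500, chrom_length=1_250_000,
                        sweep_specs=[(0, 600_000, 0.8), (1, 300_000, 0.7)],
                        roh_specs=[(0, 0.4, (100_000, 400_000))], seed=8)
        a1, b1, t1 = simulate_two_populations(cfg)
        a2, b2, t2 = simulate_two_populations(cfg)
        np.testing.assert_array_equal(a1.alleles, a2.alleles)
        np.testing.assert_array_equal(b1.alleles, b2.alleles)
        assert len(t1.sweeps) == 2 and len(t1.roh) == 1
        assert t1.sweeps == t2.sweeps
        for s in t1.sweeps:
            assert 0 <= s.core_index < cfg.n_snps
            panel = a1 if s.population == 0 else b1
            realized = (panel.alleles[:, s.core_index] == 1).mean()
            assert realized == pytest.approx(s.realized_freq)
            assert abs(realized - (0.8 if s.population == 0 else 0.7)) <= 1 / 60

    def test_roh_plant_creates_homozygous_individuals(self):
        cfg = SimConfig(n_ind_per_pop=20, n_snps=400, chrom_length=1_000_000,
                        roh_specs=[(1, 0.5, (200_000, 800_000))], seed=15)
        _, pb, truth = simulate_two_populations(cfg)
        entry = truth.roh[0]
        sel = (pb.positions >= entry.start) & (pb.positions <= entry.end)
        for i in entry.individuals:
            h1 = pb.alleles[2 * i, sel]
            h2 = pb.alleles[2 * i + 1, sel]
            np.testing.assert_array_equal(h1, h2)
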