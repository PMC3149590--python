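import numpy as np
import pandas as pd
import pytest

from taintscan.io import MISSING
from taintscan.relationship import UNKNOWN
from taintscan.simulate import (
    QTLSpec,
    SimConfig,
    degrade_genotypes,
    gene_drop,
    simulate_founder_haplotypes,
    simulate_marker_map,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_study,
    _gamete,
)


class TestPedigree:
    def test_study_scale_family_sizes(self):
        cfg = SimConfig(n_sires=92, offspring_low=7, offspring_high=24, seed=5)
        ped = simulate_pedigree(cfg, np.random.default_rng(5))
        off = ped[ped["sire"] != UNKNOWN]
        assert 92 * 7 <= len(off) <= 92 * 24
        sizes = off.groupby("sire").size()
        assert len(sizes) == 92
        assert sizes.min() >= 7 and sizes.max() <= 24

    def test_minimal(self):
        cfg = SimConfig(n_sires=1, offspring_low=1, offspring_high=1)
        ped = simulate_pedigree(cfg, np.random.default_rng(0))
        assert len(ped) == 3

    def test_parents_precede_offspring(self, tiny_cfg):
        ped = simulate_pedigree(tiny_cfg, np.random.default_rng(1))
        seen = set()
        for r in ped.itertuples():
            for p in (r.sire, r.dam):
                assert p == UNKNOWN or p in seen
            seen.add(r.id)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            SimConfig(n_sires=0)
        with pytest.raises(ValueError):
            SimConfig(offspring_low=5, offspring_high=3)


class TestDeterminism:
    def test_same_seed_identical(self, tiny_cfg):
        a = simulate_study(tiny_cfg)
        b = simulate_study(tiny_cfg)
        pd.testing.assert_frame_equal(a.pedigree, b.pedigree)
        np.testing.assert_array_equal(a.haplotypes.alleles, b.haplotypes.alleles)
        np.testing.assert_array_equal(a.genotypes.values, b.genotypes.values)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)

    def test_different_seed_differs(self, tiny_cfg):
        a = simulate_study(tiny_cfg)
        b = simulate_study(tiny_cfg.with_(seed=tiny_cfg.seed + 1))
        assert not np.array_equal(a.haplotypes.alleles, b.haplotypes.alleles)


class TestFounderHaplotypes:
    def test_pool_closure(self):
        cfg = SimConfig(founder_pool_size=2, founder_mutation_rate=0.0,
                        n_chrom=1, snps_per_chrom=30)
        mm = simulate_marker_map(cfg)
        ids = [f"F{i}" for i in range(40)]
        haps = simulate_founder_haplotypes(cfg, mm, ids, np.random.default_rng(3))
        distinct = np.unique(haps.alleles.reshape(-1, 30), axis=0)
        assert len(distinct) <= 2

    def test_huge_pool_no_ld(self):
        """Pool of 2x founders + heavy mutation: distant-SNP r^2 ~ 0."""
        n = 1000
        cfg = SimConfig(founder_pool_size=2 * n, founder_mutation_rate=0.5,
                        n_chrom=1, snps_per_chrom=20)
        mm = simulate_marker_map(cfg)
        ids = [f"F{i}" for i in range(n)]
        haps = simulate_founder_haplotypes(cfg, mm, ids, np.random.default_rng(9))
        h = haps.alleles.reshape(2 * n, 20).astype(float)
        # mean r^2 over distant pairs ~ 1/(2n) under independence
        r2 = [
            np.corrcoef(h[:, i], h[:, i + 10])[0, 1] ** 2 for i in range(10)
        ]
        assert np.mean(r2) < 4.0 / (2 * n)

    def test_pool_too_small(self):
        cfg = SimConfig(n_chrom=1, snps_per_chrom=10)
        mm = simulate_marker_map(cfg)
        with pytest.raises(ValueError):
            simulate_founder_haplotypes(
                cfg.with_(founder_pool_size=1), mm, ["F1"], np.random.default_rng(0)
            )


class TestGeneDrop:
    def test_zero_length_no_crossover(self):
        pair = np.array([[0] * 10, [1] * 10], dtype=np.int8)
        rng = np.random.default_rng(0)
        for _ in range(50):
            g = _gamete(pair, np.zeros(10), 0.0, rng)
            assert g.min() == g.max()  # entire gamete from one strand

    def test_poisson_crossover_mean(self):
        """100 cM chromosome: ~Poisson(1) crossovers per gamete."""
        m = 201
        pair = np.array([[0] * m, [1] * m], dtype=np.int8)
        cm = np.linspace(0, 100, m)
        rng = np.random.default_rng(12)
        switches = [
            int(np.abs(np.diff(_gamete(pair, cm, 100.0, rng))).sum())
            for _ in range(10_000)
        ]
        mean = np.mean(switches)
        se = np.std(switches) / np.sqrt(len(switches))
        assert abs(mean - 1.0) < 3 * se + 1e-3

    def test_child_genotype_is_haplotype_sum(self, tiny_cfg):
        res = simulate_study(tiny_cfg)
        clean = res.haplotypes.dosages()
        np.testing.assert_array_equal(
            clean.values, res.haplotypes.alleles.sum(axis=1)
        )

    def test_mendelian_consistency_before_degradation(self, tiny_cfg):
        """No opposite-homozygote parent-child conflicts in truth data."""
        res = simulate_study(tiny_cfg)
        g = res.haplotypes.dosages()
        idx = {s: k for k, s in enumerate(g.samples)}
        for r in res.pedigree.itertuples():
            if r.sire == UNKNOWN:
                continue
            for parent in (r.sire, r.dam):
                gp = g.values[idx[parent]]
                gc = g.values[idx[r.id]]
                assert not (((gp == 0) & (gc == 2)) | ((gp == 2) & (gc == 0))).any()

    def test_single_known_parent_rejected(self, tiny_cfg):
        rng = np.random.default_rng(0)
        ped = pd.DataFrame(
            {"id": ["s", "o"], "sire": ["0", "s"], "dam": ["0", "0"]}
        )
        mm = simulate_marker_map(tiny_cfg.with_(n_chrom=1, snps_per_chrom=5))
        founders = simulate_founder_haplotypes(tiny_cfg, mm, ["s"], rng)
        with pytest.raises(ValueError, match="one known parent"):
            gene_drop(ped, founders, mm, rng)


class TestPhenotypes:
    def test_degenerate_all_zero_variances(self):
        cfg = SimConfig(
            n_sires=3, offspring_low=2, offspring_high=2, n_chrom=1,
            snps_per_chrom=20, sigma2_poly=0.0, sigma2_e=0.0,
            qtl_specs=(), mu=0.5, station_effects=(0.0, 0.0, 0.0),
            beta_age=0.0, beta_days=0.0, beta_litter=0.0, seed=1,
        )
        res = simulate_study(cfg)
        np.testing.assert_allclose(
            res.phenotypes["trait_ppm"], np.exp(0.5), atol=1e-12
        )

    def test_offspring_regression_on_sire(self):
        """Regression of offspring u on sire u is 1/2 (Mendelian sampling)."""
        cfg = SimConfig(
            n_sires=5000, offspring_low=1, offspring_high=1, n_chrom=1,
            snps_per_chrom=10, sigma2_poly=1.0, qtl_specs=(), seed=21,
        )
        res = simulate_study(cfg)
        u = res.truth.polygenic
        ped = res.pedigree.set_index("id")
        off = res.offspring_ids
        us = np.array([u[ped.at[o, "sire"]] for o in off])
        uo = np.array([u[o] for o in off])
        slope = np.cov(uo, us)[0, 1] / np.var(us)
        se = np.sqrt((1 - 0.25) / len(off))  # approximate slope SE
        assert abs(slope - 0.5) < 3 * se

    def test_qtl_variance_fraction_realized(self):
        cfg = SimConfig(
            n_sires=100, offspring_low=20, offspring_high=20, n_chrom=1,
            snps_per_chrom=50, qtl_specs=(QTLSpec(1, 50.0, 0.06),), seed=8,
        )
        res = simulate_study(cfg)
        off = res.offspring_ids
        a = res.truth.qtl_effects[0]
        dos = res.truth.qtl_dosages["qtl1"].to_numpy()
        vq = np.var(a * dos)
        vu = np.var(res.truth.polygenic[off].to_numpy())
        frac = vq / (vq + vu)
        assert frac == pytest.approx(0.06, abs=0.02)

    def test_monomorphic_qtl_rejected(self):
        cfg = SimConfig(
            n_sires=2, offspring_low=2, offspring_high=2, n_chrom=1,
            snps_per_chrom=10, founder_pool_size=2, founder_mutation_rate=0.0,
            qtl_specs=(QTLSpec(1, 0.0, 0.05),),
        )
        # force the pool to be monomorphic at the QTL by trying many seeds;
        # at least one small simulation will realize a monomorphic locus
        raised = False
        for seed in range(60):
            try:
                simulate_study(cfg.with_(seed=seed))
            except ValueError as e:
                assert "monomorphic" in str(e)
                raised = True
                break
        assert raised

    def test_censoring_applied(self):
        cfg = SimConfig(
            n_sires=50, offspring_low=10, offspring_high=10, n_chrom=1,
            snps_per_chrom=20, mu=-2.5, qtl_specs=(), seed=4,
        )
        res = simulate_study(cfg)
        ppm = res.phenotypes["trait_ppm"].to_numpy()
        assert (ppm == 0).any()  # censored records exist at low mu
        assert ((ppm == 0) | (ppm >= cfg.detection_limit)).all()
        # truth keeps uncensored log values
        assert np.isfinite(res.truth.log_values).all()

    def test_halfsib_intraclass_correlation(self):
        """No QTL, sigma2_poly = sigma2_e: sire-family ICC ~ h^2/4 = 0.125."""
        cfg = SimConfig(
            n_sires=300, offspring_low=10, offspring_high=10, n_chrom=1,
            snps_per_chrom=10, sigma2_poly=0.5, sigma2_e=0.5, qtl_specs=(),
            station_effects=(0.0, 0.0, 0.0), beta_age=0.0, beta_days=0.0,
            beta_litter=0.0, seed=13,
        )
        res = simulate_study(cfg)
        y = res.truth.log_values
        fam = res.pedigree.set_index("id").loc[y.index, "sire"]
        df = pd.DataFrame({"y": y.to_numpy(), "fam": fam.to_numpy()})
        gm = df.groupby("fam")["y"]
        n_per = 10
        ms_between = n_per * gm.mean().var(ddof=1)
        ms_within = gm.var(ddof=1).mean()
        icc = (ms_between - ms_within) / (ms_between + (n_per - 1) * ms_within)
        assert icc == pytest.approx(0.125, abs=0.03)


class TestDegrade:
    def test_zero_rates_identity(self, tiny_cfg):
        res = simulate_study(tiny_cfg)
        g = degrade_genotypes(res.haplotypes, 0.0, 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(g.values, res.haplotypes.alleles.sum(axis=1))

    def test_missing_fraction(self, tiny_cfg):
        res = simulate_study(tiny_cfg.with_(n_chrom=1, snps_per_chrom=50))
        g = degrade_genotypes(res.haplotypes, 0.3, 0.0, np.random.default_rng(1))
        frac = (g.values == MISSING).mean()
        assert abs(frac - 0.3) < 0.02

    def test_errors_can_create_mendelian_conflicts(self):
        cfg = SimConfig(
            n_sires=30, offspring_low=10, offspring_high=10, n_chrom=1,
            snps_per_chrom=60, seed=2,
        )
        res = simulate_study(cfg)
        g = degrade_genotypes(res.haplotypes, 0.0, 0.2, np.random.default_rng(3))
        idx = {s: k for k, s in enumerate(g.samples)}
        conflicts = 0
        for r in res.pedigree.itertuples():
            if r.sire == UNKNOWN:
                continue
            gp = g.values[idx[r.sire]]
            gc = g.values[idx[r.id]]
            conflicts += (((gp == 0) & (gc == 2)) | ((gp == 2) & (gc == 0))).sum()
        assert conflicts > 0
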