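"""Simulator unit and property tests: Mendelian transmission, mating,
phenotype construction, and bookkeeping."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from pgicorr import _numutil
from pgicorr.simulate import (
    ConfigError,
    Population,
    SimConfig,
    assign_phenotype,
    draw_effects,
    draw_founders,
    mate,
    reproduce,
    simulate,
    true_target_coefficient,
)


def _cfg(**kw):
    base = dict(n_snps=100, n_families_discovery1=10,
                n_families_discovery2=10, n_families_prediction=20, seed=1)
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        dict(h2=-0.1), dict(n2=-0.1), dict(h2=0.9, n2=0.4),
        dict(am_rho=1.5), dict(am_rho=-0.2),
        dict(rg_disc_pred=0.0), dict(rg_disc_disc=1.5),
        dict(rg_disc_pred=0.5, rg_disc_disc=0.5),
        dict(founder_maf_range=(0.0, 0.5)),
        dict(founder_maf_range=(0.1, 0.6)),
        dict(n_generations=0), dict(n_snps=0),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigError):
            _cfg(**bad)

    def test_generation_default_depends_on_assortment(self):
        assert _cfg(am_rho=0.0).resolved_generations == 1
        assert _cfg(am_rho=0.5).resolved_generations == 10
        assert _cfg(am_rho=0.5, n_generations=3).resolved_generations == 3


class TestDrawEffects:
    def test_perfect_correlation_gives_identical_variants(self):
        eff = draw_effects(_cfg(n_snps=500), np.random.default_rng(0))
        assert np.array_equal(eff.variants["discovery1"],
                              eff.variants["discovery2"])
        assert np.array_equal(eff.variants["discovery1"],
                              eff.variants["prediction"])

    @pytest.mark.parametrize("field,rg", [("rg_disc_disc", 0.5),
                                          ("rg_disc_pred", 0.75)])
    def test_variant_correlation_matches_configuration(self, field, rg):
        m = 5000
        eff = draw_effects(_cfg(n_snps=m, **{field: rg}),
                           np.random.default_rng(3))
        if field == "rg_disc_disc":
            a, b = eff.variants["discovery1"], eff.variants["discovery2"]
        else:
            a, b = eff.variants["discovery1"], eff.variants["prediction"]
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(rg, abs=3 / m ** 0.5)

    def test_direct_and_nurture_effects_independent(self):
        m = 5000
        eff = draw_effects(_cfg(n_snps=m), np.random.default_rng(4))
        r = np.corrcoef(eff.direct, eff.nurture)[0, 1]
        assert abs(r) < 3 / m ** 0.5


class TestFounders:
    def test_shape_and_allele_range(self):
        cfg = _cfg(n_snps=3, n_families_discovery1=1,
                   n_families_discovery2=1, n_families_prediction=1)
        pop = draw_founders(cfg, np.random.default_rng(0))
        assert pop.genotypes.shape == (6, 3)
        assert set(np.unique(pop.genotypes)) <= {0, 1, 2}

    def test_fixed_half_frequency_gives_mean_allele_count_one(self):
        cfg = _cfg(n_snps=200, n_families_prediction=2000,
                   founder_maf_range=(0.5, 0.5))
        pop = draw_founders(cfg, np.random.default_rng(1))
        assert pop.genotypes.mean() == pytest.approx(1.0, abs=0.01)

    def test_founder_latent_factor_standardized(self):
        cfg = _cfg(n_snps=300)
        rng = np.random.default_rng(2)
        pop = draw_founders(cfg, rng, draw_effects(cfg, rng))
        assert pop.true_pgi.mean() == pytest.approx(0.0, abs=1e-8)
        assert pop.true_pgi.var() == pytest.approx(1.0, abs=1e-8)


def _founder_pop_with_phenotype(n_fams, m, seed, h2=0.25):
    cfg = SimConfig(n_snps=m, n_families_discovery1=1,
                    n_families_discovery2=1,
                    n_families_prediction=max(n_fams - 2, 1),
                    h2=h2, seed=seed)
    rng = np.random.default_rng(seed)
    return draw_founders(cfg, rng, draw_effects(cfg, rng)), rng


class TestMating:
    @pytest.mark.parametrize("rho", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_realized_mate_correlation(self, rho):
        pop, rng = _founder_pop_with_phenotype(10000, 60, seed=5)
        couples = mate(pop, rho, rng)
        y = pop.phenotype
        r = np.corrcoef(y[couples[:, 0]], y[couples[:, 1]])[0, 1]
        if rho == 1.0:
            assert r > 0.99
        else:
            assert r == pytest.approx(rho, abs=0.03)

    def test_pairing_is_a_perfect_matching(self):
        pop, rng = _founder_pop_with_phenotype(500, 50, seed=6)
        couples = mate(pop, 0.5, rng)
        flat = couples.ravel()
        assert couples.shape == (pop.n // 2, 2)
        assert len(np.unique(flat)) == pop.n


def _enumerate_transmission(gf, gm):
    """Brute-force child allele-count distribution for one parent pair."""
    alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    probs = np.zeros(3)
    for af in alleles[gf]:
        for am in alleles[gm]:
            probs[af + am] += 0.25
    return probs


class TestReproduction:
    @pytest.mark.parametrize("gf,gm", [(0, 0), (1, 1), (2, 2), (1, 0),
                                       (2, 1), (2, 0)])
    def test_mendelian_transmission_matches_enumeration(self, gf, gm):
        n_couples = 50_000
        geno = np.tile(np.array([[gf], [gm]], dtype=np.int8),
                       (n_couples, 1))
        pop = Population(genotypes=geno,
                         iid=np.arange(1, 2 * n_couples + 1),
                         fid=np.arange(1, 2 * n_couples + 1),
                         pat=np.zeros(2 * n_couples, dtype=np.int64),
                         mat=np.zeros(2 * n_couples, dtype=np.int64),
                         generation=0, _next_iid=2 * n_couples + 1,
                         _next_fid=2 * n_couples + 1)
        couples = np.column_stack([np.arange(0, 2 * n_couples, 2),
                                   np.arange(1, 2 * n_couples, 2)])
        child = reproduce(couples, pop, np.random.default_rng(7))
        counts = np.bincount(child.genotypes[:, 0], minlength=3)
        expected = _enumerate_transmission(gf, gm) * child.n
        mask = expected > 0
        assert counts[~mask].sum() == 0
        if mask.sum() > 1:
            p = stats.chisquare(counts[mask], expected[mask]).pvalue
            assert p > 0.001

    def test_numba_and_numpy_kernels_agree(self):
        rng1 = np.random.default_rng(8)
        rng2 = np.random.default_rng(8)
        geno = np.random.default_rng(0).integers(
            0, 3, size=(400, 50), dtype=np.int8)
        f = np.arange(0, 400, 2)
        m = np.arange(1, 400, 2)
        c1, p1 = _numutil.mendelian_children(geno, f, m, 2, rng1,
                                             use_numba=True)
        c2, p2 = _numutil.mendelian_children(geno, f, m, 2, rng2,
                                             use_numba=False)
        assert np.array_equal(c1, c2)
        assert np.array_equal(p1, p2)
        b1 = _numutil.binomial2(np.full(50, 0.3), 200,
                                np.random.default_rng(9), use_numba=True)
        b2 = _numutil.binomial2(np.full(50, 0.3), 200,
                                np.random.default_rng(9), use_numba=False)
        assert np.array_equal(b1, b2)

    def test_sibling_genotype_correlation_near_half(self):
        cfg = _cfg(n_snps=200, n_families_prediction=5000, seed=10)
        pop, _ = simulate(cfg)
        sib1 = pop.genotypes[0::2].astype(float)
        sib2 = pop.genotypes[1::2].astype(float)
        rs = []
        for j in range(50):
            rs.append(np.corrcoef(sib1[:, j], sib2[:, j])[0, 1])
        assert np.mean(rs) == pytest.approx(0.5, abs=0.02)

    def test_allele_frequency_conserved_under_random_mating(self):
        cfg = _cfg(n_snps=400, n_families_prediction=5000, seed=12)
        rng = np.random.default_rng(cfg.seed)
        founders = draw_founders(cfg, rng, draw_effects(cfg, rng))
        couples = mate(founders, 0.0, rng)
        children = reproduce(couples, founders, rng)
        p0 = founders.genotypes.mean(axis=0) / 2
        p1 = children.genotypes.mean(axis=0) / 2
        se = np.sqrt(p0 * (1 - p0) / (2 * children.n))
        assert np.all(np.abs(p1 - p0) <= 4 * se)


class TestPhenotype:
    def test_pure_noise_phenotype_uncorrelated_with_genes(self):
        pop, rng = _founder_pop_with_phenotype(4000, 100, seed=13, h2=0.0)
        r = np.corrcoef(pop.phenotype, pop.true_pgi)[0, 1]
        assert abs(r) < 0.05

    def test_phenotypic_variance_explained_matches_h2(self):
        cfg = _cfg(n_snps=500, n_families_prediction=8000, h2=0.25, seed=14)
        pop, study = simulate(cfg)
        idx = study.prediction
        r2 = np.corrcoef(pop.phenotype[idx], pop.true_pgi[idx])[0, 1] ** 2
        assert r2 == pytest.approx(0.25, abs=0.02)

    def test_nurture_raises_snp_heritability_to_h2_plus_half_n2(self, gn_study):
        # empirical latent regression: own genotypes carry the direct factor
        # plus half the nurture variance, so the slope of Y on the total
        # additive SNP factor is sqrt(h2 + 0.5 * n2)
        pop, study = gn_study
        h2, n2 = study.config.h2, study.config.n2
        idx = study.prediction
        q_raw = pop.genotypes[idx].astype(float) @ study.effects.nurture
        _, p_sd = pop._nurture_scale
        u = (np.sqrt(h2) * pop.true_pgi[idx]
             + np.sqrt(n2) * (q_raw - q_raw.mean()) / p_sd)
        u_st = (u - u.mean()) / u.std()
        slope = np.cov(pop.phenotype[idx], u_st, ddof=0)[0, 1] / u_st.var()
        assert slope == pytest.approx(np.sqrt(h2 + 0.5 * n2), abs=0.05)
        assert true_target_coefficient(pop, study, "between") == \
            pytest.approx(np.sqrt(h2 + 0.5 * n2))
        assert true_target_coefficient(pop, study, "within") == \
            pytest.approx(np.sqrt(h2))

    def test_per_generation_standardization(self, tiny_study):
        pop, _ = tiny_study
        ped = pop.pedigree()
        for _, grp in ped.groupby("generation"):
            assert grp["true_pgi"].mean() == pytest.approx(0.0, abs=1e-8)
            assert grp["true_pgi"].var(ddof=0) == pytest.approx(1.0, abs=1e-8)

    def test_variance_budget_error_is_diagnosed(self):
        cfg = _cfg(n_snps=50, h2=0.9, n2=0.2, seed=15)
        rng = np.random.default_rng(0)
        pop = draw_founders(cfg, rng)
        pop.parent_genotype_sum = (2 * pop.genotypes).astype(np.int8)
        eff = draw_effects(cfg, rng)
        eff.nurture = eff.direct.copy()  # force corr(G, P) ~ 1
        from pgicorr.simulate import PhenotypeVarianceError
        with pytest.raises(PhenotypeVarianceError, match="variance budget"):
            assign_phenotype(pop, eff, cfg.h2, cfg.n2, rng)


class TestStudyStructure:
    def test_partition_bookkeeping(self, tiny_study):
        pop, study = tiny_study
        assert pop.n == 2 * (150 + 150 + 300)
        assert len(study.discovery1) == 300
        assert len(study.gwas_subset1) == 150
        fams = pop.fid
        sets = [set(fams[study.discovery1]), set(fams[study.discovery2]),
                set(fams[study.prediction])]
        assert not (sets[0] & sets[1] or sets[0] & sets[2]
                    or sets[1] & sets[2])
        # one GWAS individual per family
        for subset in (study.gwas_subset1, study.gwas_subset2):
            assert len(np.unique(fams[subset])) == len(subset)

    def test_every_child_has_both_parents_in_previous_generation(
            self, tiny_study):
        pop, _ = tiny_study
        ped = pop.pedigree()
        for g in range(1, ped["generation"].max() + 1):
            prev = set(ped.loc[ped["generation"] == g - 1, "iid"])
            cur = ped[ped["generation"] == g]
            assert cur["pat"].isin(prev).all()
            assert cur["mat"].isin(prev).all()
            sizes = cur.groupby("fid").size()
            assert (sizes == 2).all()

    def test_same_seed_is_bit_identical(self):
        cfg = _cfg(n_snps=120, seed=99)
        pop1, _ = simulate(cfg)
        pop2, _ = simulate(cfg)
        assert np.array_equal(pop1.genotypes, pop2.genotypes)
        assert np.array_equal(pop1.phenotype, pop2.phenotype)
        assert pop1.pedigree().equals(pop2.pedigree())


class TestTargetCoefficient:
    def test_baseline_target_is_half(self, tiny_study):
        pop, study = tiny_study
        assert true_target_coefficient(pop, study, "between") == 0.5

    def test_am_with_nurture_raises_between_target(self):
        cfg = SimConfig(n_snps=800, n_families_discovery1=50,
                        n_families_discovery2=50, n_families_prediction=1500,
                        h2=0.2, n2=0.1, am_rho=0.75, n_generations=6,
                        seed=17)
        pop, study = simulate(cfg)
        t = true_target_coefficient(pop, study, "between")
        assert t > np.sqrt(0.2 + 0.5 * 0.1)
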