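"""Founder draws, gene dropping, trait model, ascertainment, round trips."""

import numpy as np
import pytest

from owscore.dataio import align_samples, read_genotypes, read_phenotypes
from owscore.errors import AscertainmentError, SimulationError
from owscore.pedigree import phi_blocks, read_fam, validate_pedigree
from owscore.simulate import (
    SimulationConfig,
    ascertain_pedigrees,
    draw_founder_genotypes,
    gene_drop,
    polygenic_effects,
    simulate_study,
    study_pedigrees,
    template_pedigree,
    write_study,
)


class TestFounderGenotypes:
    def test_zero_maf_rejected(self):
        with pytest.raises(SimulationError):
            draw_founder_genotypes(np.array([0.0]), 10, np.random.default_rng(0))

    def test_maf_above_half_rejected(self):
        with pytest.raises(SimulationError):
            draw_founder_genotypes(np.array([0.6]), 10, np.random.default_rng(0))

    def test_half_maf_mean_dosage_one(self):
        g = draw_founder_genotypes(np.array([0.5]), 10_000, np.random.default_rng(1))
        se = np.sqrt(2 * 0.5 * 0.5 / 10_000)
        assert abs(g.mean() - 1.0) <= 3 * se

    def test_hardy_weinberg_heterozygote_fraction(self):
        maf = 0.01
        g = draw_founder_genotypes(np.array([maf]), 10_000, np.random.default_rng(2))
        expect = 2 * maf * (1 - maf)
        se = np.sqrt(expect * (1 - expect) / 10_000)
        assert abs((g == 1).mean() - expect) <= 3 * se

    def test_fixed_seed_bitwise_identical(self):
        a = draw_founder_genotypes(np.array([0.1, 0.3]), 50, np.random.default_rng(7))
        b = draw_founder_genotypes(np.array([0.1, 0.3]), 50, np.random.default_rng(7))
        assert np.array_equal(a, b)


class TestGeneDrop:
    def trio(self):
        return validate_pedigree(
            [("X", "F", "0", "0", 1), ("X", "M", "0", "0", 2),
             ("X", "C", "F", "M", 1)]
        )

    def test_no_allele_no_transmission(self):
        ped = self.trio()
        g = gene_drop(ped, np.zeros((2, 3)), np.random.default_rng(0))
        assert np.array_equal(g, np.zeros((3, 3)))

    def test_heterozygous_parent_transmits_half_the_time(self):
        ped = self.trio()
        rng = np.random.default_rng(3)
        # one het father, dosage-0 mother, many independent variants as drops
        founders = np.vstack([np.ones(10_000), np.zeros(10_000)])
        g = gene_drop(ped, founders, rng)
        carrier = g[2] > 0
        se = np.sqrt(0.25 / 10_000)
        assert abs(carrier.mean() - 0.5) <= 3 * se

    def test_allele_conservation_and_traceability(self):
        ped = template_pedigree("T", (2, 2))
        rng = np.random.default_rng(5)
        founders = draw_founder_genotypes(np.full(50, 0.2), len(ped.founders), rng)
        g = gene_drop(ped, founders, rng)
        founder_rows = [k for k, m in enumerate(ped.members) if m.is_founder]
        # a variant absent from every founder is absent from everyone
        absent = founders.sum(axis=0) == 0
        assert np.all(g[:, absent] == 0)
        assert np.array_equal(g[founder_rows], founders)

    def test_founder_count_mismatch(self):
        with pytest.raises(SimulationError):
            gene_drop(self.trio(), np.zeros((3, 2)), np.random.default_rng(0))

    def test_transmitted_frequency_unbiased(self):
        # non-founder allele frequency is an unbiased estimate of founder MAF
        ped = template_pedigree("T", (3, 3))
        rng = np.random.default_rng(11)
        maf = 0.2
        M = 4000
        founders = draw_founder_genotypes(np.full(M, maf), len(ped.founders), rng)
        g = gene_drop(ped, founders, rng)
        nf = [k for k, m in enumerate(ped.members) if not m.is_founder]
        freq = g[nf].mean() / 2
        se = np.sqrt(maf * (1 - maf) / (2 * len(nf) * M))  # upper bound on SE
        assert abs(freq - maf) <= 4 * se


class TestTemplatePedigree:
    def test_default_template_size_and_generations(self):
        ped = template_pedigree("P01")
        assert len(ped) == 44
        assert len(ped.founders) == 2 + 3 + 9

    def test_study_scale(self):
        peds = study_pedigrees(SimulationConfig())
        assert len(peds) == 20
        assert sum(len(p) for p in peds) == 880
        ids = [iid for p in peds for iid in p.ids]
        assert len(set(ids)) == len(ids)  # globally unique


class TestTraitModel:
    def test_degenerate_model_iid_normal(self):
        cfg = SimulationConfig(n_pedigrees=1, sibships=(2,), h2_polygenic=0.0,
                               with_covariates=False, sigma_total=2.0,
                               n_variants=2, intercept=5.0)
        peds = study_pedigrees(cfg)
        phi = phi_blocks(peds)
        rng = np.random.default_rng(0)
        ys = []
        from owscore.simulate import draw_mafs, drop_study_genotypes
        geno = drop_study_genotypes(peds, draw_mafs(cfg, rng), rng)
        from owscore.simulate import simulate_trait
        for _ in range(2500):
            y, _ = simulate_trait(geno, phi, cfg, rng)
            ys.append(y)
        ys = np.array(ys).ravel()
        n = ys.size
        assert abs(ys.mean() - 5.0) <= 3 * 2.0 / np.sqrt(n)
        assert abs(ys.var() - 4.0) <= 3 * 4.0 * np.sqrt(2.0 / n)

    def test_sib_covariance_under_polygenic_model(self):
        # full sibs: cov = h2 * 0.5 * sigma^2
        ped = validate_pedigree(
            [("X", "F", "0", "0", 1), ("X", "M", "0", "0", 2),
             ("X", "C1", "F", "M", 1), ("X", "C2", "F", "M", 2)]
        )
        phi = phi_blocks([ped])
        rng = np.random.default_rng(8)
        P = polygenic_effects(phi, 0.5, 1.0, rng, size=40_000)
        c1, c2 = P[2], P[3]
        cov = np.mean(c1 * c2)
        se = np.std(c1 * c2, ddof=1) / np.sqrt(c1.size)
        assert abs(cov - 0.25) <= 3 * se
        assert abs(np.var(c1) - 0.5) <= 3 * np.var(c1) * np.sqrt(2 / c1.size)

    def test_causal_allele_shifts_mean_by_beta(self):
        cfg = SimulationConfig(n_pedigrees=40, n_variants=5, maf_low=0.2,
                               maf_high=0.4, causal_indices=(0,), beta=(1.0,),
                               h2_polygenic=0.0, with_covariates=False)
        study = simulate_study(cfg, seed=4)
        y = study.phenotypes.data["trait"].to_numpy()
        g = study.genotypes.dosages[:, 0]
        slope = np.polyfit(g, y, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.15)

    def test_identical_seed_identical_study(self):
        cfg = SimulationConfig(n_pedigrees=2)
        s1 = simulate_study(cfg, seed=123)
        s2 = simulate_study(cfg, seed=123)
        assert np.array_equal(s1.genotypes.dosages, s2.genotypes.dosages)
        assert s1.phenotypes.data.equals(s2.phenotypes.data)

    def test_infeasible_h2_rejected(self):
        with pytest.raises(SimulationError):
            SimulationConfig(h2_polygenic=1.0)


class TestAscertainment:
    def small_study(self, seed=0):
        cfg = SimulationConfig(n_pedigrees=10, sibships=(2, 2), n_variants=10,
                               maf_low=0.05, maf_high=0.3)
        return simulate_study(cfg, seed)

    def test_random_keep_all_is_identity(self):
        study = self.small_study()
        kept = ascertain_pedigrees(study, "random", np.random.default_rng(0),
                                   keep_fraction=1.0)
        assert [p.family_id for p in kept.pedigrees] == [
            p.family_id for p in study.pedigrees
        ]

    def test_proband_extreme_postcondition(self):
        study = self.small_study(seed=5)
        trait = study.phenotypes.data["trait"]
        thr = float(np.quantile(trait, 0.5))
        kept = ascertain_pedigrees(study, "proband_extreme",
                                   np.random.default_rng(0), quantile=0.5)
        for ped in kept.pedigrees:
            proband = ped.nonfounders[0].individual_id
            assert trait.loc[proband] > thr

    def test_impossible_rule_raises(self):
        study = self.small_study()
        with pytest.raises(AscertainmentError):
            ascertain_pedigrees(study, "proband_extreme",
                                np.random.default_rng(0), quantile=1.0)

    def test_extreme_probands_enrich_causal_carriers(self):
        """Families kept for an extreme proband carry the positive-effect rare
        allele more often than the population frequency."""
        cfg = SimulationConfig(n_pedigrees=30, sibships=(2, 2), n_variants=1,
                               maf_values=np.array([0.05]), causal_indices=(0,),
                               beta=(1.5,), h2_polygenic=0.0,
                               with_covariates=False)
        rng = np.random.default_rng(99)
        kept_freq, pop_freq = [], []
        for s in range(200):
            study = simulate_study(cfg, seed=10_000 + s)
            pop_freq.append(study.genotypes.dosages.mean() / 2)
            try:
                kept = ascertain_pedigrees(study, "proband_extreme", rng,
                                           quantile=0.9)
            except AscertainmentError:
                continue
            kept_freq.append(kept.genotypes.dosages.mean() / 2)
        assert np.mean(kept_freq) > np.mean(pop_freq) + 0.01


def test_written_study_round_trips_through_dataio(tmp_path):
    cfg = SimulationConfig(n_pedigrees=3, n_variants=8, maf_low=0.05,
                           maf_high=0.3)
    study = simulate_study(cfg, seed=2)
    paths = write_study(study, str(tmp_path / "study"))
    peds = read_fam(paths["fam"])
    geno = read_genotypes(paths["geno"])
    pheno = read_phenotypes(paths["pheno"])
    g2, p2, _, phi = align_samples(geno, pheno, peds)
    assert g2.sample_ids == study.genotypes.sample_ids
    assert np.array_equal(g2.dosages, study.genotypes.dosages)
    assert phi.sample_ids == study.phi.sample_ids
    assert np.allclose(phi.full_matrix(), study.phi.full_matrix())
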