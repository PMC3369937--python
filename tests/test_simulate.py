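"""Generator sanity: Hardy-Weinberg structure, determinism, planted truth."""

import numpy as np
import pandas as pd
import pytest

from egwas.association import enumerate_cis_pairs, hwe_pvalues, run_egwas
from egwas.simulate import (
    SimulationConfig,
    plant_effects,
    simulate_catalog,
    simulate_genotypes,
    simulate_map_and_annotation,
    simulate_study,
)


def _one_snp_map(maf):
    return pd.DataFrame(
        {"chrom": ["1"], "pos": [500], "a1": ["A"], "a2": ["G"], "maf": [maf]},
        index=pd.Index(["rs1"], name="snp"),
    )


class TestGenotypes:
    def test_mean_dosage_matches_binomial_expectation(self):
        # dosage ~ Binomial(2, 0.5): mean 1.0, SE of the mean over 10,000
        # subjects is sqrt(2 * 0.25 / 10000)
        geno = simulate_genotypes(10_000, _one_snp_map(0.5), seed=3)
        se = np.sqrt(2 * 0.5 * 0.5 / 10_000)
        assert abs(geno.dosages.to_numpy().mean() - 1.0) < 3 * se

    def test_vanishing_maf_gives_all_zero_dosage(self):
        geno = simulate_genotypes(500, _one_snp_map(1e-12), seed=0)
        assert (geno.dosages.to_numpy() == 0).all()

    def test_maf_outside_domain_rejected(self):
        with pytest.raises(ValueError, match=r"\(0, 0.5\]"):
            simulate_genotypes(10, _one_snp_map(0.6), seed=0)
        with pytest.raises(ValueError):
            SimulationConfig(maf_range=(0.0, 0.5))

    def test_fixed_seed_reproduces_matrix(self):
        cfg = SimulationConfig(n_subjects=50, n_snps=100, n_probes=20, seed=5)
        rng1, rng2 = np.random.default_rng(1), np.random.default_rng(1)
        m1, _ = simulate_map_and_annotation(cfg, rng1)
        m2, _ = simulate_map_and_annotation(cfg, rng2)
        g1 = simulate_genotypes(50, m1, seed=9)
        g2 = simulate_genotypes(50, m2, seed=9)
        pd.testing.assert_frame_equal(g1.dosages, g2.dosages)

    def test_hardy_weinberg_holds_for_nearly_all_snps(self):
        cfg = SimulationConfig(n_subjects=500, n_snps=2000, n_probes=100,
                               maf_range=(0.05, 0.5), seed=13)
        rng = np.random.default_rng(13)
        snp_map, _ = simulate_map_and_annotation(cfg, rng)
        geno = simulate_genotypes(500, snp_map, rng)
        p = hwe_pvalues(geno)
        assert (p > 0.001).mean() >= 0.99


class TestStudy:
    def test_full_determinism_under_fixed_seed(self):
        cfg = SimulationConfig(n_subjects=40, n_snps=80, n_probes=20,
                               n_planted_effects=3, n_catalog=10, seed=21)
        s1, s2 = simulate_study(cfg), simulate_study(cfg)
        pd.testing.assert_frame_equal(s1.genotypes.dosages, s2.genotypes.dosages)
        for t in cfg.tissues:
            pd.testing.assert_frame_equal(
                s1.expression[t].values, s2.expression[t].values
            )
        pd.testing.assert_frame_equal(s1.truth, s2.truth)
        pd.testing.assert_frame_equal(s1.catalog, s2.catalog)

    def test_planted_pairs_round_trip_through_cis_enumeration(self, planted_study):
        cis = enumerate_cis_pairs(
            planted_study.genotypes.snp_map,
            planted_study.annotation,
            planted_study.config.window_bp,
        )
        pair_set = set(map(tuple, cis.pairs[["probe", "snp"]].to_numpy()))
        for _, row in planted_study.truth.iterrows():
            assert (row["probe"], row["snp"]) in pair_set

    def test_planting_outside_cis_window_rejected(self):
        cfg = SimulationConfig(n_subjects=20, n_snps=40, n_probes=10, seed=2)
        rng = np.random.default_rng(2)
        snp_map, ann = simulate_map_and_annotation(cfg, rng)
        # a SNP cis to probe 1 is not cis to probe 0 (windows are disjoint
        # by construction)
        other = snp_map.loc[snp_map["chrom"] == "2"].index[0]
        bad = SimulationConfig(
            n_subjects=20, n_snps=40, n_probes=10, seed=2,
            effect_table=[("PR00000", str(other), 1.0)],
        )
        with pytest.raises(ValueError, match="PR00000"):
            simulate_study(bad)

    def test_replicate_design(self):
        cfg = SimulationConfig(n_subjects=30, n_snps=40, n_probes=10,
                               n_replicate_subjects=4, n_replicates=5, seed=3)
        study = simulate_study(cfg)
        counts = study.covariates.groupby("subject").size()
        assert (counts >= 2).sum() == 4
        reps = study.covariates.loc[study.covariates["subject"] == "S0000"]
        assert reps["plate"].nunique() == 5  # replicates land on distinct plates


class TestPlantedEffectRecovery:
    def test_strong_effect_beta_recovered_within_sampling_error(self):
        """With beta=1, sigma=0.1 and n=200, the downstream OLS estimate
        must sit within 3 SEs of truth."""
        cfg = SimulationConfig(
            n_subjects=200, n_snps=60, n_probes=12, sigma_noise=0.1,
            sigma_subject=0.0, n_planted_effects=4, planted_beta=1.0, seed=17,
        )
        study = simulate_study(cfg)
        res = run_egwas(
            study.genotypes, study.expression["cerebellum"],
            study.annotation, study.covariates, cohort="all",
        ).results
        merged = study.truth.merge(res, on=["probe", "snp"])
        assert len(merged) == 4
        assert (np.abs(merged["beta"] - merged["beta_true"]) < 3 * merged["se"]).all()


class TestCatalog:
    @pytest.fixture
    def universe(self):
        cfg = SimulationConfig(n_subjects=10, n_snps=1000, n_probes=50,
                               maf_range=(0.01, 0.5), seed=4)
        snp_map, _ = simulate_map_and_annotation(cfg, np.random.default_rng(4))
        return snp_map

    def test_empty_catalog(self, universe):
        cat = simulate_catalog(universe, [], n_catalog=0, seed=0)
        assert cat.empty

    def test_null_factor_matches_uniform_sampling_rate(self, universe):
        sig = universe.index[:200]
        fracs = []
        for seed in range(40):
            cat = simulate_catalog(universe, sig, enrichment_factor=1.0,
                                   n_catalog=100, seed=seed,
                                   n_multi_decoys=0, n_nonrs_decoys=0,
                                   n_weak_decoys=0)
            fracs.append(cat["SNPs"].isin(sig).mean())
        # expected hit fraction = |sig| / |universe| = 0.2
        assert abs(np.mean(fracs) - 0.2) < 0.03

    def test_planted_factor_scales_hit_rate(self, universe):
        sig = universe.index[:200]
        fracs = [
            simulate_catalog(universe, sig, enrichment_factor=2.0,
                             n_catalog=100, seed=seed, n_multi_decoys=0,
                             n_nonrs_decoys=0, n_weak_decoys=0)["SNPs"]
            .isin(sig).mean()
            for seed in range(40)
        ]
        assert abs(np.mean(fracs) - 0.4) < 0.04

    def test_unattainable_enrichment_rejected(self, universe):
        sig = universe.index[:10]
        with pytest.raises(ValueError, match="unattainable"):
            simulate_catalog(universe, sig, enrichment_factor=500.0,
                             n_catalog=900, seed=0)

    def test_decoy_rows_present(self, universe):
        cat = simulate_catalog(universe, universe.index[:50], n_catalog=20,
                               seed=1, n_multi_decoys=3, n_nonrs_decoys=2,
                               n_weak_decoys=4)
        assert len(cat) == 29
        assert cat["SNPs"].str.contains(";").sum() == 3
        assert cat["SNPs"].str.startswith("chr").sum() == 2
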