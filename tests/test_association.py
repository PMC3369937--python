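"""Cis pairing, OLS equivalence, genomic control, q-values, best-SNP rules."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as hst

from egwas.association import (
    CHI2_MEDIAN,
    EgwasOptions,
    enumerate_cis_pairs,
    fit_cis_association,
    genomic_control,
    run_egwas,
    select_best_cissnp,
    storey_qvalues,
)
from egwas.data import ExpressionMatrix, GenotypeMatrix
from egwas.simulate import SimulationConfig, simulate_study


def _snp_map(rows):
    df = pd.DataFrame(rows, columns=["snp", "chrom", "pos"])
    df["a1"], df["a2"], df["maf"] = "A", "G", 0.3
    return df.set_index("snp")


class TestEnumerateCisPairs:
    def test_window_boundary_inclusive_at_both_ends(self, tiny_annotation):
        smap = _snp_map([("in", "1", 900_000), ("out", "1", 899_999),
                         ("far", "2", 5_000_500)])
        pairs = enumerate_cis_pairs(smap, tiny_annotation, 100_000).pairs
        got = set(map(tuple, pairs.to_numpy()))
        assert ("in", "PRA") in got
        assert ("out", "PRA") not in got
        assert ("far", "PRB") in got

    def test_zero_window_restricts_to_gene_body(self, tiny_annotation):
        smap = _snp_map([("inside", "1", 1_005_000), ("flank", "1", 999_999)])
        pairs = enumerate_cis_pairs(smap, tiny_annotation, 0).pairs
        assert pairs["snp"].tolist() == ["inside"]

    def test_unknown_chromosomes_listed_and_skipped(self, tiny_annotation):
        smap = _snp_map([("weird", "17", 1_000)])
        res = enumerate_cis_pairs(smap, tiny_annotation, 100_000)
        assert res.unknown_chroms == ["17"]
        assert res.pairs.empty
        assert set(res.probes_without_snps) == {"PRA", "PRB"}

    def test_matches_exhaustive_double_loop(self, rng):
        n_snps, n_genes, window = 1000, 50, 100_000
        chroms = rng.choice(["1", "2", "3"], size=n_genes)
        start = rng.integers(1, 5_000_000, size=n_genes)
        ann = pd.DataFrame(
            {"probe": [f"P{i}" for i in range(n_genes)],
             "symbol": [f"G{i}" for i in range(n_genes)],
             "chrom": chroms, "start": start, "end": start + 20_000}
        )
        smap = _snp_map(
            [(f"rs{i}", rng.choice(["1", "2", "3"]),
              int(rng.integers(1, 5_100_000))) for i in range(n_snps)]
        )
        got = set(map(tuple, enumerate_cis_pairs(smap, ann, window).pairs.to_numpy()))
        expected = {
            (s, row.probe)
            for s, srow in smap.iterrows()
            for row in ann.itertuples()
            if srow["chrom"] == row.chrom
            and row.start - window <= srow["pos"] <= row.end + window
        }
        assert got == expected


def _toy_inputs(n=8):
    """Hand-built single-SNP, single-probe study with noiseless structure."""
    subjects = [f"S{i}" for i in range(n)]
    dosage = np.array([0, 1, 2, 0, 1, 2, 0, 1], dtype=float)[:n]
    geno = GenotypeMatrix(
        dosages=pd.DataFrame({"rs1": dosage}, index=pd.Index(subjects, name="subject")),
        snp_map=_snp_map([("rs1", "1", 1_000_500)]),
    )
    age = np.linspace(60, 90, n)
    y = 2.0 * dosage + 0.5 * age
    expr = ExpressionMatrix(
        values=pd.DataFrame([y], index=pd.Index(["PRA"], name="probe"),
                            columns=subjects)
    )
    cov = pd.DataFrame(
        {"sample": subjects, "subject": subjects, "apoe4_dose": 0,
         "age_at_death": age, "sex": 0, "diagnosis": 0, "plate": "P1",
         "rin": 8.0, "replicate": 0}
    )
    return geno, expr, cov


class TestFitCisAssociation:
    def test_exact_recovery_on_noiseless_data(self):
        geno, expr, cov = _toy_inputs()
        with pytest.warns(UserWarning, match="aliased"):
            res = fit_cis_association("rs1", "PRA", expr, geno, cov)
        assert res.testable
        assert res.beta == pytest.approx(2.0, abs=1e-10)
        assert res.p < 1e-12

    def test_constant_genotype_flagged_untestable(self):
        geno, expr, cov = _toy_inputs()
        geno.dosages["rs1"] = 0.0
        res = fit_cis_association("rs1", "PRA", expr, geno, cov)
        assert not res.testable and np.isnan(res.beta)

    def test_bulk_route_matches_statsmodels_reference(self, planted_study):
        """The Frisch-Waugh residualization path must reproduce full OLS
        betas, SEs and p-values to numerical precision."""
        expr = planted_study.expression["cerebellum"]
        bulk = run_egwas(planted_study.genotypes, expr, planted_study.annotation,
                         planted_study.covariates, cohort="all").results
        sample = bulk.sample(8, random_state=0)
        for _, row in sample.iterrows():
            ref = fit_cis_association(row["snp"], row["probe"], expr,
                                      planted_study.genotypes,
                                      planted_study.covariates,
                                      include_diagnosis=True)
            assert row["beta"] == pytest.approx(ref.beta, abs=1e-8)
            assert row["se"] == pytest.approx(ref.se, abs=1e-8)
            assert row["p"] == pytest.approx(ref.p, rel=1e-6, abs=1e-12)

    def test_null_pvalues_are_uniform(self, small_null_study):
        res = run_egwas(small_null_study.genotypes,
                        small_null_study.expression["cerebellum"],
                        small_null_study.annotation,
                        small_null_study.covariates, cohort="all",
                        options=EgwasOptions(pi0=1.0)).results
        stat = st.kstest(res["p"], "uniform")
        assert stat.pvalue > 0.01


class TestGenomicControl:
    def test_closed_form_single_p(self):
        # chi2 = 1 at p = sf(1, df=1); lambda = 1 / 0.4549...
        p = st.chi2.sf(1.0, df=1)
        lam, adj = genomic_control([p])
        assert lam == pytest.approx(1.0 / CHI2_MEDIAN, rel=1e-6)
        assert adj[0] > p  # deflated significance

    def test_uniform_p_gives_lambda_one(self, rng):
        p = rng.uniform(size=10_000)
        lam, adj = genomic_control(p)
        assert lam == pytest.approx(1.0, abs=0.03)

    def test_doubled_chi_square_statistics(self, rng):
        chi2 = st.chi2.rvs(1, size=20_000, random_state=1) * 2.0
        p = st.chi2.sf(chi2, df=1)
        lam, adj = genomic_control(p)
        assert lam == pytest.approx(2.0, abs=0.06)
        adj_chi2 = st.chi2.isf(adj, df=1)
        assert np.median(adj_chi2) == pytest.approx(CHI2_MEDIAN, abs=0.02)

    def test_deflation_never_applied(self, rng):
        p = np.clip(rng.uniform(0.5, 1.0, size=1000), None, 1.0)  # deflated stats
        lam, adj = genomic_control(p)
        assert lam < 1
        np.testing.assert_array_equal(adj, p)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            genomic_control([])


class TestStoreyQvalues:
    def test_bh_hand_example_with_pi0_fixed(self):
        q = storey_qvalues([0.01, 0.04, 0.9], pi0=1.0)
        np.testing.assert_allclose(q, [0.03, 0.06, 0.9])

    def test_all_ones(self):
        np.testing.assert_array_equal(storey_qvalues([1.0, 1.0, 1.0], pi0=1.0),
                                      [1.0, 1.0, 1.0])

    @settings(deadline=None, max_examples=25)
    @given(hst.lists(hst.floats(min_value=1e-12, max_value=1.0), min_size=2,
                     max_size=200))
    def test_q_monotone_in_p(self, p):
        q = storey_qvalues(np.array(p))
        order = np.argsort(p)
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()
        assert (q <= 1.0 + 1e-12).all()

    def test_bonferroni_q_p_ordering(self, rng):
        p = rng.uniform(1e-6, 1, size=500)
        q = storey_qvalues(p, pi0=1.0)
        bonf = np.minimum(1.0, len(p) * p)
        assert ((p <= q + 1e-12) & (q <= bonf + 1e-12)).all()


class TestBestSnpSelection:
    @staticmethod
    def _frame(rows):
        df = pd.DataFrame(rows, columns=["snp", "p_gc", "beta"])
        df["probe"] = "PRA"
        df["testable"] = True
        return df

    def test_minimal_p_wins(self):
        best = select_best_cissnp(self._frame([("a", 1e-8, 0.1), ("b", 1e-3, 2.0)]))
        assert best["snp"] == "a"

    def test_tie_broken_by_larger_abs_beta_then_snp_id(self):
        best = select_best_cissnp(self._frame([("a", 1e-4, 0.5), ("b", 1e-4, -0.9)]))
        assert best["snp"] == "b"
        best = select_best_cissnp(self._frame([("b", 1e-4, 0.5), ("a", 1e-4, -0.5)]))
        assert best["snp"] == "a"

    def test_matches_exhaustive_scan(self, rng):
        rows = [(f"rs{i}", float(rng.uniform(1e-8, 1)), float(rng.normal()))
                for i in range(50)]
        frame = self._frame(rows)
        best = select_best_cissnp(frame)
        oracle = min(rows, key=lambda r: (r[1], -abs(r[2]), r[0]))
        assert best["snp"] == oracle[0]

    def test_all_untestable_returns_none(self):
        df = self._frame([("a", np.nan, np.nan)])
        df["testable"] = False
        assert select_best_cissnp(df) is None


class TestRunEgwas:
    def test_planted_pair_recovered_at_q05(self, planted_study):
        res = run_egwas(planted_study.genotypes,
                        planted_study.expression["cerebellum"],
                        planted_study.annotation, planted_study.covariates,
                        cohort="all").results
        merged = planted_study.truth.merge(res, on=["probe", "snp"])
        assert (merged["q"] < 0.05).mean() >= 0.9

    def test_cohort_betas_track_combined_run(self, planted_study):
        """AD-only and combined analyses of shared-truth data must agree on
        effect sizes (the internal-replication design)."""
        kw = dict(
            geno=planted_study.genotypes,
            expr=planted_study.expression["cerebellum"],
            annotation=planted_study.annotation,
            covariates=planted_study.covariates,
        )
        res_ad = run_egwas(cohort="AD", **kw).results
        res_all = run_egwas(cohort="all", **kw).results
        truth_pairs = planted_study.truth[["snp", "probe"]]
        m = truth_pairs.merge(res_ad, on=["snp", "probe"]).merge(
            res_all, on=["snp", "probe"], suffixes=("_ad", "_all")
        )
        r = np.corrcoef(m["beta_ad"], m["beta_all"])[0, 1]
        assert r > 0.9

    def test_eigenvector_inclusion_is_neutral_without_confounding(self, planted_study):
        """On structure-free synthetic data, adding ancestry eigenvectors
        must leave the -log10 p landscape on the identity line."""
        cov = planted_study.covariates.copy()
        rng = np.random.default_rng(0)
        for k in range(3):
            per_subject = dict(zip(cov["subject"].unique(),
                                   rng.normal(size=cov["subject"].nunique())))
            cov[f"ev{k + 1}"] = cov["subject"].map(per_subject)
        kw = dict(geno=planted_study.genotypes,
                  expr=planted_study.expression["cerebellum"],
                  annotation=planted_study.annotation, covariates=cov,
                  cohort="all")
        with_ev = run_egwas(options=EgwasOptions(include_eigenvectors=True), **kw)
        without_ev = run_egwas(options=EgwasOptions(include_eigenvectors=False), **kw)
        lp_with = -np.log10(with_ev.results.set_index(["snp", "probe"])["p"])
        lp_without = -np.log10(without_ev.results.set_index(["snp", "probe"])["p"])
        lp_with, lp_without = lp_with.align(lp_without, join="inner")
        slope = np.polyfit(lp_without, lp_with, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_monomorphic_snps_do_not_enter_qc_passed_results(self, small_null_study):
        res = run_egwas(small_null_study.genotypes,
                        small_null_study.expression["cerebellum"],
                        small_null_study.annotation,
                        small_null_study.covariates, cohort="all")
        assert res.results["testable"].all()
        assert (res.results["p_bonf"] >= res.results["q"] - 1e-12).all()
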