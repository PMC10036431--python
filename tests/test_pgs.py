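"""Polygenic score construction: harmonization, QC, P&T, scoring, CV."""

import numpy as np
import pandas as pd
import pytest

import pgsrisk as pr
from pgsrisk._exceptions import (CollinearityError, DegenerateScoreError,
                                 EmptyIntersectionError, ValidationError)
from pgsrisk.containers import GenotypeMatrix
from pgsrisk.pgs import _fold_assignment, _per_variant_assoc, \
    _status_by_horizon

from _oracles import greedy_pt_selection


def _stats(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "effect_allele",
                                       "other_allele", "beta", "se", "p",
                                       "eaf"])


class TestHarmonize:
    def test_allele_flip_negates_beta(self, toy_genotypes):
        # genotype counts A at 1:1000; stats count G (the other allele)
        stats = _stats([("1", 1000, "G", "A", 0.4, 0.05, 1e-9, 0.7)])
        aligned, rep = pr.harmonize(stats, toy_genotypes)
        assert rep.n_allele_flipped == 1
        assert aligned["beta"].iloc[0] == pytest.approx(-0.4)
        assert aligned["eaf"].iloc[0] == pytest.approx(0.3)
        assert aligned["effect_allele"].iloc[0] == "A"

    def test_palindromic_near_half_dropped(self, toy_genotypes):
        # 2:1000 in the toy is G/A; build a G/C palindromic variant there
        geno = toy_genotypes
        geno.variants.loc[2, ["effect_allele", "other_allele"]] = ["G", "C"]
        stats = _stats([("2", 1000, "G", "C", 0.2, 0.05, 1e-9, 0.52),
                        ("1", 1000, "A", "G", 0.1, 0.05, 1e-9, 0.3)])
        aligned, rep = pr.harmonize(stats, geno)
        assert rep.n_strand_ambiguous_dropped == 1
        assert rep.n_matched == 1

    def test_unmatched_logged_and_empty_intersection_raises(
            self, toy_genotypes):
        stats = _stats([("9", 999, "A", "G", 0.1, 0.05, 1e-9, 0.3)])
        with pytest.raises(EmptyIntersectionError):
            pr.harmonize(stats, toy_genotypes)
        both = _stats([("9", 999, "A", "G", 0.1, 0.05, 1e-9, 0.3),
                       ("1", 1000, "A", "G", 0.1, 0.05, 1e-9, 0.3)])
        aligned, rep = pr.harmonize(both, toy_genotypes)
        assert rep.n_unmatched == 1 and rep.n_matched == 1
        assert rep.n_matched + rep.n_unmatched \
            + rep.n_strand_ambiguous_dropped == len(both)

    def test_two_of_five_match_hand_weighted_sum(self, toy_genotypes):
        stats = _stats([
            ("1", 1000, "A", "G", 0.5, 0.05, 1e-9, 0.3),   # match, as-is
            ("1", 5000, "T", "C", -0.2, 0.05, 1e-9, 0.6),  # match, flip
            ("3", 100, "A", "G", 1.0, 0.05, 1e-9, 0.3),    # no such variant
            ("1", 7777, "A", "C", 1.0, 0.05, 1e-9, 0.3),   # no such variant
            ("2", 2000, "G", "A", 1.0, 0.05, 1e-9, 0.3),   # no such variant
        ])
        aligned, rep = pr.harmonize(stats, toy_genotypes)
        assert rep.n_matched == 2
        ps = pr.compute_ps(toy_genotypes, aligned)
        # hand: 0.5*dos[:,0] + (+0.2)*dos[:,1]  (flip negates -0.2)
        expected = 0.5 * toy_genotypes.dosages[:, 0] \
            + 0.2 * toy_genotypes.dosages[:, 1]
        assert np.allclose(ps.raw, expected, atol=1e-12)

    def test_involution_flipping_all_counted_alleles(self, adult_genotypes,
                                                     adult_sumstats):
        """Recoding every genotype to count the other allele leaves the
        (harmonized) score invariant."""
        g = adult_genotypes
        flipped = GenotypeMatrix(
            sample_ids=g.sample_ids,
            variants=g.variants.rename(columns={
                "effect_allele": "other_allele",
                "other_allele": "effect_allele"})[
                ["chrom", "pos", "effect_allele", "other_allele"]],
            dosages=2.0 - g.dosages,
            info_scores=g.info_scores, eaf=1.0 - g.eaf)
        a1, _ = pr.harmonize(adult_sumstats, g)
        a2, _ = pr.harmonize(adult_sumstats, flipped)
        ps1 = pr.compute_ps(g, a1)
        ps2 = pr.compute_ps(flipped, a2)
        # raw sums differ by the constant 2*sum(beta) under d -> 2-d flips,
        # so compare centred scores
        assert np.allclose(ps1.raw - ps1.raw.mean(),
                           ps2.raw - ps2.raw.mean(), atol=1e-12)


class TestQcFilter:
    def test_paper_thresholds(self):
        geno = GenotypeMatrix(
            sample_ids=["s1", "s2"],
            variants=pd.DataFrame({
                "chrom": ["1", "1", "1"], "pos": [1, 2, 3],
                "effect_allele": ["A", "A", "A"],
                "other_allele": ["G", "G", "G"]}),
            dosages=np.ones((2, 3)),
            info_scores=np.array([0.49, 0.5, 0.9]),
            eaf=np.array([0.3, 0.005, 0.995]))
        out = pr.qc_filter(geno, maf_min=0.01, info_min=0.5)
        # info 0.49 removed; maf 0.005 removed (both eaf and 1-eaf sides)
        assert out.n_variants == 0
        out2 = pr.qc_filter(geno, maf_min=0.0, info_min=0.5)
        assert out2.n_variants == 2

    def test_identity_when_all_pass(self, adult_genotypes):
        out = pr.qc_filter(adult_genotypes, maf_min=0.0, info_min=0.0)
        assert out.n_variants == adult_genotypes.n_variants
        assert np.array_equal(out.dosages, adult_genotypes.dosages)

    def test_six_variant_brute_force(self):
        info = np.array([0.2, 0.5, 0.6, 0.9, 0.51, 0.49])
        eaf = np.array([0.05, 0.009, 0.5, 0.99, 0.3, 0.2])
        keep_expected = [i for i in range(6)
                         if min(eaf[i], 1 - eaf[i]) >= 0.01
                         and info[i] >= 0.5]
        geno = GenotypeMatrix(
            sample_ids=["s"],
            variants=pd.DataFrame({
                "chrom": ["1"] * 6, "pos": list(range(1, 7)),
                "effect_allele": ["A"] * 6, "other_allele": ["G"] * 6}),
            dosages=np.ones((1, 6)), info_scores=info, eaf=eaf)
        out = pr.qc_filter(geno)
        assert list(out.variants["pos"]) == [p + 1 for p in keep_expected]


class TestSelectVariantsPT:
    def _geno_with_corr(self, seed=0):
        """8 variants; pairs (0,1) and (2,3) highly correlated & nearby."""
        rng = np.random.default_rng(seed)
        n = 300
        base = rng.binomial(2, 0.4, size=(n, 8)).astype(float)
        base[:, 1] = np.clip(base[:, 0] + (rng.random(n) < 0.05), 0, 2)
        base[:, 3] = np.clip(base[:, 2] + (rng.random(n) < 0.05), 0, 2)
        variants = pd.DataFrame({
            "chrom": ["1", "1", "1", "1", "2", "2", "3", "3"],
            "pos": [1000, 2000, 400_000, 401_000,
                    1000, 600_000, 1000, 2000],
            "effect_allele": list("AACCGGTT"),
            "other_allele": list("GGTTAACC"),
        })
        return GenotypeMatrix(
            sample_ids=[f"s{i}" for i in range(n)], variants=variants,
            dosages=base, info_scores=np.ones(8),
            eaf=base.mean(axis=0) / 2)

    def test_empty_when_nothing_significant(self, toy_genotypes):
        stats = _stats([("1", 1000, "A", "G", 0.1, 0.05, 0.5, 0.3)])
        sel = pr.select_variants_pt(stats, toy_genotypes, p_threshold=1e-4)
        assert len(sel) == 0

    def test_all_selected_when_independent(self, adult_genotypes,
                                           adult_sumstats):
        sig = adult_sumstats[adult_sumstats["p"] < 5e-8]
        sel = pr.select_variants_pt(adult_sumstats, adult_genotypes,
                                    r2_max=1.01)  # r2 can never exceed 1
        assert len(sel) == len(sig)

    def test_matches_exhaustive_greedy(self):
        geno = self._geno_with_corr()
        ps = [1e-12, 1e-10, 1e-9, 1e-11, 1e-10, 1e-9, 1e-8, 0.5]
        stats = geno.variants.copy()
        stats["beta"] = 0.1
        stats["se"] = 0.01
        stats["p"] = ps
        stats["eaf"] = geno.eaf
        sel = pr.select_variants_pt(stats, geno, p_threshold=5e-8,
                                    window_bp=500_000, r2_max=0.1)
        # oracle with explicit pairwise r2
        recs = stats.to_dict("records")
        r2 = {}
        for i in range(8):
            for j in range(i + 1, 8):
                r = np.corrcoef(geno.dosages[:, i], geno.dosages[:, j])[0, 1]
                r2[frozenset((i, j))] = r * r
        expected = greedy_pt_selection(recs, r2, 5e-8, 500_000, 0.1)
        got = [int(geno.variants[(geno.variants["pos"] == p)
                                 & (geno.variants["chrom"] == c)].index[0])
               for c, p in zip(sel["chrom"], sel["pos"])]
        assert sorted(got) == sorted(expected)
        # correlated nearby pairs must not both survive
        assert not {0, 1} <= set(got)
        assert not {2, 3} <= set(got)

    def test_order_invariance(self):
        geno = self._geno_with_corr()
        stats = geno.variants.copy()
        stats["beta"] = 0.1
        stats["se"] = 0.01
        stats["p"] = [1e-9] * 8  # all tied: tie-break decides
        stats["eaf"] = geno.eaf
        sel1 = pr.select_variants_pt(stats, geno)
        sel2 = pr.select_variants_pt(stats.iloc[::-1].reset_index(drop=True),
                                     geno)
        assert sel1[["chrom", "pos"]].to_dict("list") \
            == sel2[["chrom", "pos"]].to_dict("list")


class TestComputeAndStandardize:
    def test_zero_weights_zero_score(self, toy_genotypes):
        w = toy_genotypes.variants.copy()
        w["beta"], w["se"], w["p"], w["eaf"] = 0.0, 0.1, 0.5, 0.3
        assert np.all(pr.compute_ps(toy_genotypes, w).raw == 0.0)

    def test_single_variant_formula(self):
        geno = GenotypeMatrix(
            sample_ids=["s"], variants=pd.DataFrame({
                "chrom": ["1"], "pos": [1], "effect_allele": ["A"],
                "other_allele": ["G"]}),
            dosages=np.array([[2.0]]), info_scores=np.array([1.0]),
            eaf=np.array([0.3]))
        w = geno.variants.copy()
        w["beta"], w["se"], w["p"], w["eaf"] = np.log(1.5), 0.1, 1e-9, 0.3
        assert pr.compute_ps(geno, w).raw[0] == pytest.approx(
            2 * np.log(1.5), abs=1e-15)

    def test_matches_double_loop(self, toy_genotypes):
        rng = np.random.default_rng(8)
        w = toy_genotypes.variants.copy()
        w["beta"] = rng.normal(size=3)
        w["se"], w["p"], w["eaf"] = 0.1, 1e-9, toy_genotypes.eaf
        ps = pr.compute_ps(toy_genotypes, w)
        for i in range(5):
            expected = sum(toy_genotypes.dosages[i, j] * w["beta"].iloc[j]
                           for j in range(3))
            assert ps.raw[i] == pytest.approx(expected, abs=1e-12)

    def test_missing_dosage_mean_imputed(self, toy_genotypes):
        d = toy_genotypes.dosages.copy()
        d[0, 0] = np.nan
        geno = GenotypeMatrix(toy_genotypes.sample_ids,
                              toy_genotypes.variants, d,
                              toy_genotypes.info_scores, toy_genotypes.eaf)
        w = geno.variants.copy()
        w["beta"], w["se"], w["p"], w["eaf"] = 1.0, 0.1, 1e-9, geno.eaf
        ps = pr.compute_ps(geno, w)
        expected0 = 2 * 0.3 + d[0, 1] + d[0, 2]
        assert ps.raw[0] == pytest.approx(expected0)
        assert "mean-imputed" in ps.weight_source

    def test_standardize_exact_and_degenerate(self):
        ps = pr.PolygenicScore(["a", "b", "c"], np.array([1.0, 2.0, 3.0]))
        out = pr.standardize_ps(ps)
        assert abs(out.standardized.mean()) < 1e-12
        assert abs(out.standardized.std() - 1) < 1e-12
        with pytest.raises(DegenerateScoreError):
            pr.standardize_ps(pr.PolygenicScore(["a", "b"],
                                                np.array([1.0, 1.0])))

    def test_reference_subset_leaves_subcohort_sd_free(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(size=200)
        ps = pr.PolygenicScore([f"s{i}" for i in range(200)], raw)
        out = pr.standardize_ps(ps, reference_ids=[f"s{i}" for i in range(100)])
        ref = out.standardized[:100]
        sub = out.standardized[100:]
        assert abs(ref.mean()) < 1e-10 and abs(ref.std() - 1) < 1e-10
        assert abs(sub.std() - 1) > 1e-3  # not renormalized per subcohort


class TestCrossValidatedScores:
    def _toy(self, n=20, m=6, seed=0):
        rng = np.random.default_rng(seed)
        cfg = pr.SimulationConfig(n_individuals=n, n_variants=m, seed=seed)
        g = pr.simulate_genotypes(cfg)
        cohort = pr.simulate_cohort(g, pr.draw_true_effects(g, cfg), cfg)
        return g, cohort

    def test_leave_one_out_matches_explicit_loop(self):
        g, cohort = self._toy(n=20, m=4, seed=3)
        ps = pr.cv_weight_ps(g, cohort, k=20, seed=5, horizon=10.0)
        # explicit LOO: refit per-variant logistic leaving one person out
        folds = _fold_assignment(20, 20, np.random.default_rng(5))
        status = _status_by_horizon(cohort.set_index("id").loc[g.sample_ids],
                                    10.0)
        dos = g.dosages
        for i in range(20):
            train = folds != folds[i]
            y = status[train]
            keep = y >= 0
            beta, _ = _per_variant_assoc(y[keep].astype(float),
                                         dos[train][keep], "logistic")
            assert ps.raw[i] == pytest.approx(dos[i] @ beta, rel=1e-9)

    def test_null_phenotype_gives_null_hr(self):
        cfg = pr.SimulationConfig(n_individuals=2000, n_variants=30,
                                  frac_causal=0.0, true_ps_hr_per_sd=1.0,
                                  seed=13)
        g = pr.simulate_genotypes(cfg)
        cohort = pr.simulate_cohort(g, pr.draw_true_effects(g, cfg), cfg,
                                    covariate_effects="none")
        ps = pr.standardize_ps(pr.cv_weight_ps(g, cohort, k=10, seed=1))
        from pgsrisk.cox import CoxPH
        res = CoxPH(cohort["followup_time"], cohort["event"],
                    ps.standardized[:, None], ["ps"]).fit()
        assert abs(res.params[0]) < 3 * res.bse[0] + 1e-9

    def test_same_seed_same_scores(self):
        g, cohort = self._toy(n=60, m=8, seed=2)
        a = pr.cv_weight_ps(g, cohort, k=5, seed=7)
        b = pr.cv_weight_ps(g, cohort, k=5, seed=7)
        assert np.array_equal(a.raw, b.raw)

    def test_cv_variant_vacuous_selection_equals_cv_weights(self):
        g, cohort = self._toy(n=80, m=10, seed=4)
        a = pr.cv_variant_ps(g, cohort, n_select=10, k=2, seed=9)
        b = pr.cv_weight_ps(g, cohort, k=2, seed=9)
        assert np.allclose(a.raw, b.raw, atol=1e-12)

    def test_cv_variant_ranking_matches_brute_force(self):
        g, cohort = self._toy(n=200, m=30, seed=6)
        n_select = 5
        ps = pr.cv_variant_ps(g, cohort, n_select=n_select, k=2, seed=3)
        folds = _fold_assignment(200, 2, np.random.default_rng(3))
        status = _status_by_horizon(cohort.set_index("id").loc[g.sample_ids],
                                    10.0)
        for f in (0, 1):
            train = folds != f
            y = status[train]
            keep = y >= 0
            beta, pval = _per_variant_assoc(y[keep].astype(float),
                                            g.dosages[train][keep],
                                            "logistic")
            top = set(np.argsort(pval, kind="mergesort")[:n_select])
            # held-out scores only use top-ranked variants' weights
            test_rows = np.flatnonzero(~train)
            expected = g.dosages[test_rows][:, sorted(top)] \
                @ beta[sorted(top)]
            assert np.allclose(ps.raw[test_rows], expected, atol=1e-9)


class TestResidualize:
    def test_orthogonal_covariates_no_change(self):
        rng = np.random.default_rng(1)
        raw = rng.normal(size=50)
        ps = pr.standardize_ps(
            pr.PolygenicScore([f"s{i}" for i in range(50)], raw))
        cov = rng.normal(size=(50, 3))
        cov -= cov.mean(axis=0)
        # project out the PS component to make covariates orthogonal
        z = ps.standardized
        for j in range(3):
            cov[:, j] -= (cov[:, j] @ z) / (z @ z) * z
        out = pr.residualize_ps(ps, cov)
        assert np.allclose(out.standardized, ps.standardized, atol=1e-10)

    def test_exactly_linear_raises(self):
        rng = np.random.default_rng(2)
        cov = rng.normal(size=(30, 2))
        raw = cov @ np.array([0.5, -1.0]) + 3.0
        ps = pr.standardize_ps(
            pr.PolygenicScore([f"s{i}" for i in range(30)], raw))
        with pytest.raises(DegenerateScoreError):
            pr.residualize_ps(ps, cov)

    def test_rank_deficiency_raises(self):
        rng = np.random.default_rng(3)
        ps = pr.standardize_ps(pr.PolygenicScore(
            [f"s{i}" for i in range(10)], rng.normal(size=10)))
        c = rng.normal(size=10)
        with pytest.raises(CollinearityError):
            pr.residualize_ps(ps, np.column_stack([c, 2 * c]))

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(4)
        raw = rng.normal(size=10)
        cov = rng.normal(size=(10, 2))
        ps = pr.standardize_ps(
            pr.PolygenicScore([f"s{i}" for i in range(10)], raw))
        out = pr.residualize_ps(ps, cov)
        x = np.column_stack([np.ones(10), cov])
        coef = np.linalg.solve(x.T @ x, x.T @ ps.standardized)
        resid = ps.standardized - x @ coef
        expected = (resid - resid.mean()) / resid.std()
        assert np.allclose(out.standardized, expected, atol=1e-10)
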