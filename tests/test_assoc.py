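"""V_SNP, effective tests, genomic control and mixed-model GWAS."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from wildrecomb.assoc import (
    _lambda_gc, effective_tests, run_gwas, significance_threshold,
    snp_variance,
)
from wildrecomb.pedigree import GenotypePanel
from wildrecomb.simulate import (
    SimConfig, gene_drop, simulate_acc_phenotype, simulate_pedigree,
)
from wildrecomb.varcomp import pedigree_grm, reml_fit


# ---------------------------------------------------------------------------
# V_SNP
# ---------------------------------------------------------------------------

class TestSnpVariance:
    def test_symmetric_additive_case(self):
        v, _ = snp_variance(0.5, effect_ab=-1.0, effect_bb=-2.0)
        assert v == pytest.approx(0.5, abs=1e-15)

    def test_published_female_top_hit_magnitude(self):
        # MAF 0.43, AB -1.68, BB -3.37 evaluates near 1.39 on the
        # 2-decimal rounded effect sizes
        v, prop = snp_variance(0.57, -1.68, -3.37, v_a_without_snp=5.04)
        assert v == pytest.approx(1.39, abs=0.01)
        assert 0.2 < prop < 0.3

    def test_hardy_weinberg_brute_force_oracle(self):
        """Against exhaustive HW enumeration: the formula equals the
        variance of genotype-class means minus the dominance variance
        (2pqd)^2, exactly; with d = 0 it is the full class-mean variance."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.uniform(0.05, 0.95)
            q = 1 - p
            ab, bb = rng.normal(0, 2, 2)
            v, _ = snp_variance(p, ab, bb)
            w = np.array([p ** 2, 2 * p * q, q ** 2])
            vals = np.array([0.0, ab, bb])
            mean = w @ vals
            class_var = w @ (vals - mean) ** 2
            a = bb / 2
            d = ab - a
            assert v == pytest.approx(class_var - (2 * p * q * d) ** 2,
                                      abs=1e-12)
        v, _ = snp_variance(0.3, effect_ab=-0.75, effect_bb=-1.5)  # d = 0
        w = np.array([0.09, 0.42, 0.49])
        vals = np.array([0.0, -0.75, -1.5])
        mean = w @ vals
        assert v == pytest.approx(w @ (vals - mean) ** 2, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            snp_variance(0.0, 1.0, 2.0)
        with pytest.raises(ValueError):
            snp_variance(1.0, 1.0, 2.0)


# ---------------------------------------------------------------------------
# Effective number of tests
# ---------------------------------------------------------------------------

def _hadamard_genotypes(m):
    """Columns with exactly zero pairwise correlation, coded 0/2."""
    from scipy.linalg import hadamard
    order = 1 << max(2, m.bit_length())  # smallest power of two > m
    H = hadamard(order)
    return (H[:, 1: m + 1] + 1).astype(np.int8)  # values 0 or 2


class TestEffectiveTests:
    def test_independent_snps_count_fully(self):
        g = _hadamard_genotypes(10)
        n_eff, thr = effective_tests(g, window=50, alpha=0.05)
        assert n_eff == pytest.approx(10.0, abs=1e-9)
        assert thr == pytest.approx(0.005)

    def test_perfectly_correlated_block_counts_once(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, 100).astype(np.int8)
        g = np.tile(col[:, None], (1, 50))
        n_eff, _ = effective_tests(g, window=50)
        assert n_eff == pytest.approx(1.0, abs=1e-9)

    def test_published_threshold_arithmetic(self):
        assert significance_threshold(22273.61, 0.05) == pytest.approx(
            2.245e-6, abs=5e-10
        )

    def test_allele_relabel_invariance(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, size=(80, 30)).astype(np.int8)
        n1, _ = effective_tests(g, window=10)
        flip = g.copy()
        flip[:, ::2] = 2 - flip[:, ::2]
        n2, _ = effective_tests(flip, window=10)
        assert n1 == pytest.approx(n2, abs=1e-9)

    def test_window_resets_across_chromosomes(self):
        rng = np.random.default_rng(3)
        col = rng.integers(0, 3, 60).astype(np.int8)
        g = np.tile(col[:, None], (1, 4))
        chrom = np.array([1, 1, 2, 2])
        n_eff, _ = effective_tests(g, window=50, chrom=chrom)
        assert n_eff == pytest.approx(2.0, abs=1e-9)  # one per chromosome

    def test_all_missing_snp_contributes_one(self):
        rng = np.random.default_rng(4)
        g = rng.integers(0, 3, size=(30, 3)).astype(np.int8)
        g[:, 1] = -1
        with pytest.warns(UserWarning, match="all-missing"):
            n_eff, _ = effective_tests(g, window=10)
        assert n_eff >= 2.0


# ---------------------------------------------------------------------------
# Genomic control
# ---------------------------------------------------------------------------

class TestGenomicControl:
    def test_lambda_of_exact_null_median_is_one(self):
        chi2 = np.full(101, stats.chi2.ppf(0.5, 2))
        lam = _lambda_gc(chi2, np.full(101, 2))
        assert lam == pytest.approx(1.0, abs=1e-12)

    def test_df1_records_mapped_through_quantiles(self):
        # a df=1 statistic at its null median maps to the df=2 null median
        chi2 = np.full(11, stats.chi2.ppf(0.5, 1))
        lam = _lambda_gc(chi2, np.full(11, 1))
        assert lam == pytest.approx(1.0, abs=1e-12)

    def test_inflated_statistics_detected(self):
        rng = np.random.default_rng(5)
        chi2 = 1.5 * rng.chisquare(2, 4000)
        lam = _lambda_gc(chi2, np.full(4000, 2))
        assert 1.35 < lam < 1.65


# ---------------------------------------------------------------------------
# Wald test equals OLS F-test when only residual variance is present
# ---------------------------------------------------------------------------

def test_wald_equals_ols_f_times_df_under_iid():
    """With the additive variance absent the animal model is OLS, and the
    genotype-factor Wald chi-square equals q x the OLS F statistic."""
    rng = np.random.default_rng(8)
    n = 120
    geno = rng.integers(0, 3, n)
    X = np.column_stack([
        np.ones(n), (geno == 1).astype(float), (geno == 2).astype(float)
    ])
    y = 5 + 0.4 * (geno == 2) + rng.normal(0, 1, n)
    fit = reml_fit(y, X, [("residual", None)],
                   beta_names=["intercept", "ab", "bb"])
    chi2, dfree, _ = fit.wald_fixed(["ab", "bb"])

    ols = sm.OLS(y, X).fit()
    f = ols.f_test(np.array([[0, 1, 0], [0, 0, 1]]))
    assert chi2 == pytest.approx(float(f.fvalue) * 2, rel=1e-6)


# ---------------------------------------------------------------------------
# GWAS end to end
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def gwas_sim():
    """Pedigree + 300 unlinked SNPs + polygenic-null phenotype."""
    cfg = SimConfig(
        n_founders=100, offspring_per_pair=4, n_generations=3,
        chromosome_lengths_bp=tuple([50_000_000] * 6),
        snp_density_per_mb=1.0, map_male_cm=300, map_female_cm=240,
        male_subtelomeric_factor=1.0, v_a_acc=0.2, v_r_acc=0.6,
        genotyping_error_rate=0.0, genotyping_missing_rate=0.0, seed=41,
    )
    ped = simulate_pedigree(cfg)
    drop = gene_drop(ped, cfg)
    founders = set(ped.founders())
    pheno = simulate_acc_phenotype(ped, v_a=4.28, v_pe=0.0, v_r=25.28,
                                   seed=6)
    pheno = pheno[~pheno.fid.isin(founders)].reset_index(drop=True)
    pheno["fid_sex"] = [ped.sex(f) for f in pheno.fid]
    return cfg, ped, drop, pheno


class TestGwas:
    def test_null_lambda_and_uniform_pvalues(self, gwas_sim):
        """Polygenic null: lambda within [0.85, 1.15] and raw p-values
        compatible with uniformity (KS at alpha = 0.01)."""
        _, ped, drop, pheno = gwas_sim
        run = run_gwas(pheno, drop.panel, pedigree_grm(ped))
        assert 0.85 < run.lambda_gc < 1.15
        ks = stats.kstest(run.records["p_raw"], "uniform")
        assert ks.pvalue > 0.01

    def test_lambda_below_one_leaves_pvalues_uncorrected(self, gwas_sim):
        _, ped, drop, pheno = gwas_sim
        run = run_gwas(pheno, drop.panel, pedigree_grm(ped))
        if run.lambda_gc <= 1.0:
            assert not run.lambda_applied
            assert np.allclose(run.records["p"], run.records["p_raw"])
        else:
            assert run.lambda_applied
            assert (run.records["p"] >= run.records["p_raw"] - 1e-12).all()

    def test_qtl_found_in_carrier_sex_only(self, gwas_sim):
        """Female-limited additive QTL: genome-wide significant top hit in
        the female stratum, null in males."""
        cfg, ped, drop, _ = gwas_sim
        freqs = drop.panel.allele_freqs()
        q_idx = int(np.argmin(np.abs(freqs - 0.27)))
        dose = {i: int(drop.panel.row(i)[q_idx]) for i in drop.panel.ids}
        pheno = simulate_acc_phenotype(
            ped, v_a=2.66, v_pe=0.0, v_r=24.6,
            qtl_dose=dose, qtl_effect=2.455, qtl_sex_limited="F", seed=13,
        )
        founders = set(ped.founders())
        pheno = pheno[~pheno.fid.isin(founders)].reset_index(drop=True)
        pheno["fid_sex"] = [ped.sex(f) for f in pheno.fid]
        qtl_snp = drop.panel.markers["snp"].iloc[q_idx]

        fem = run_gwas(pheno, drop.panel, pedigree_grm(ped), stratum="female")
        top = fem.records.sort_values("p").iloc[0]
        assert top["snp"] == qtl_snp
        assert top["p"] < fem.threshold

        male = run_gwas(pheno, drop.panel, pedigree_grm(ped), stratum="male")
        qrec = male.records[male.records["snp"] == qtl_snp].iloc[0]
        assert qrec["p"] > male.threshold

    def test_trans_mode_keeps_global_qtl_significant(self, gwas_sim):
        """A QTL acting on every chromosome's crossover count stays
        significant when its own chromosome's counts are excluded."""
        from wildrecomb.detect import detect_crossovers
        from wildrecomb.pedigree import build_subpedigrees, mendelian_qc
        cfg, ped, drop, _ = gwas_sim
        freqs = drop.panel.allele_freqs()
        q_idx = int(np.argmin(np.abs(freqs - 0.5)))
        # Poisson (non-obligate) counts so the latent scaling acts on every
        # chromosome; obligate counts on short chromosomes pin at 1 and
        # cannot express a rate QTL.
        cfg2 = SimConfig(**{**vars(cfg), "qtl_marker": q_idx,
                            "qtl_effect": 3.0, "qtl_sex_limited": None,
                            "obligate": False,
                            "map_male_cm": 600, "map_female_cm": 480,
                            "v_a_acc": 0.3, "v_r_acc": 1.0, "seed": 43})
        ped2 = simulate_pedigree(cfg2)
        drop2 = gene_drop(ped2, cfg2)
        subs, _ = build_subpedigrees(ped2, drop2.panel.ids)
        clean, kept, _ = mendelian_qc(subs, drop2.panel)
        _, table = detect_crossovers(kept, clean)
        qtl_snp = drop2.panel.markers["snp"].iloc[q_idx]
        run = run_gwas(table, clean, pedigree_grm(ped2), trans_mode=True)
        qrec = run.records[run.records["snp"] == qtl_snp].iloc[0]
        assert qrec["p"] < run.threshold

    def test_monomorphic_snp_skipped(self, gwas_sim):
        _, ped, drop, pheno = gwas_sim
        panel = drop.panel.copy()
        panel.genotypes[:, 0] = 1  # single observed class
        run = run_gwas(pheno, panel, pedigree_grm(ped))
        assert panel.markers["snp"].iloc[0] not in set(run.records["snp"])

    def test_effect_sizes_relative_to_aa_intercept(self, gwas_sim):
        """Reported AB/BB effects reproduce the genotype-class contrasts."""
        _, ped, drop, _ = gwas_sim
        freqs = drop.panel.allele_freqs()
        q_idx = int(np.argmin(np.abs(freqs - 0.5)))
        dose = {i: int(drop.panel.row(i)[q_idx]) for i in drop.panel.ids}
        pheno = simulate_acc_phenotype(
            ped, v_a=0.5, v_pe=0.0, v_r=4.0,
            qtl_dose=dose, qtl_effect=1.7, seed=3,
        )
        founders = set(ped.founders())
        pheno = pheno[~pheno.fid.isin(founders)].reset_index(drop=True)
        pheno["fid_sex"] = [ped.sex(f) for f in pheno.fid]
        run = run_gwas(pheno, drop.panel, pedigree_grm(ped))
        rec = run.records[run.records["snp"]
                          == drop.panel.markers["snp"].iloc[q_idx]].iloc[0]
        assert rec["effect_bb"] == pytest.approx(3.4, abs=3 * rec["se_bb"])
        assert rec["effect_ab"] == pytest.approx(1.7, abs=3 * rec["se_ab"])
        assert rec["v_snp"] > 0
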