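"""GRM construction, REML animal models, bivariate fits, panel selection."""

import numpy as np
import pandas as pd
import pytest

from wildrecomb.pedigree import Pedigree
from wildrecomb.simulate import (
    SimConfig, _breeding_values, gene_drop, simulate_acc_phenotype,
    simulate_pedigree,
)
from wildrecomb.varcomp import (
    bivariate_analysis, compute_grm, fit_animal_model, fit_bivariate_acc,
    lrt_random_effect, pedigree_grm, reml_fit, select_reference_panel,
)


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

class TestGRM:
    def test_full_heterozygote_inbreeding_minus_one(self):
        """All-heterozygous genotypes at p=0.5: F-hat = -1, diagonal 0."""
        g = np.ones((3, 40), dtype=np.int8)
        grm = compute_grm(g, freqs=np.full(40, 0.5))
        assert grm.fhat == pytest.approx(np.full(3, -1.0))
        assert np.diag(grm.matrix) == pytest.approx(np.zeros(3))

    def test_population_mean_inbreeding_near_zero(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.2, 0.8, 500)
        g = rng.binomial(2, p, size=(60, 500)).astype(np.int8)
        grm = compute_grm(g, freqs=p)
        se = grm.fhat.std(ddof=1) / np.sqrt(len(grm.fhat))
        assert abs(grm.fhat.mean()) < 3 * se + 0.01

    def test_duplicate_individuals_offdiag_equals_diag(self):
        """At p=0.5 the cross-product and F^III diagonals coincide, so a
        duplicated individual's off-diagonal equals its diagonal exactly;
        at other frequencies they agree in expectation."""
        rng = np.random.default_rng(1)
        g1 = rng.integers(0, 3, 200).astype(np.int8)
        g = np.stack([g1, g1])
        grm = compute_grm(g, freqs=np.full(200, 0.5))
        assert grm.matrix[0, 1] == pytest.approx(grm.matrix[0, 0], abs=1e-12)

        p = rng.uniform(0.1, 0.9, 4000)
        g2 = rng.binomial(2, p, 4000).astype(np.int8)
        grm2 = compute_grm(np.stack([g2, g2]), freqs=p)
        assert grm2.matrix[0, 1] == pytest.approx(grm2.matrix[0, 0], abs=0.1)

    def test_monomorphic_marker_rejected(self):
        g = np.array([[0, 1], [0, 2]], dtype=np.int8)
        with pytest.raises(ValueError, match="monomorphic"):
            compute_grm(g, freqs=np.array([0.0, 0.5]))

    def test_adjusted_matrix_highly_correlated_with_raw(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.2, 0.8, 300)
        g = rng.binomial(2, p, size=(40, 300)).astype(np.int8)
        raw = compute_grm(g, freqs=p)
        adj = compute_grm(g, freqs=p, adjust=True)
        off = ~np.eye(40, dtype=bool)
        r = np.corrcoef(raw.matrix[off], adj.matrix[off])[0, 1]
        assert r ** 2 > 0.99

    def test_gcta_export(self, tmp_path):
        g = np.array([[0, 1, 2], [2, 1, 0]], dtype=np.int8)
        grm = compute_grm(g, ids=["a", "b"], freqs=np.full(3, 0.5))
        grm.to_gcta(str(tmp_path / "out"))
        assert (tmp_path / "out.grm.id").exists()
        assert (tmp_path / "out.grm.gz").exists()


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def _halfsib_data(n_sires, k, va, ve, seed):
    rng = np.random.default_rng(seed)
    sires = np.repeat(np.arange(n_sires), k)
    u = rng.normal(0, np.sqrt(va / 4), n_sires)
    y = 10 + u[sires] + rng.normal(0, np.sqrt(ve + 0.75 * va), n_sires * k)
    rows = [dict(id=f"S{i}", sire=None, dam=None, sex="M")
            for i in range(n_sires)]
    rows += [dict(id=f"D{j}", sire=None, dam=None, sex="F")
             for j in range(n_sires * k)]
    rows += [dict(id=f"O{j}", sire=f"S{sires[j]}", dam=f"D{j}", sex="U")
             for j in range(n_sires * k)]
    ped = Pedigree(pd.DataFrame(rows))
    df = pd.DataFrame(dict(fid=[f"O{j}" for j in range(n_sires * k)], acc=y))
    return ped, df, y, sires


class TestREML:
    def test_residual_only_equals_ols_variance(self):
        rng = np.random.default_rng(1)
        n = 150
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [2.0, 1.0] + rng.normal(size=n)
        fit = reml_fit(y, X, [("residual", None)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        s2 = float(np.sum((y - X @ beta) ** 2) / (n - 2))
        assert fit.components["residual"] == pytest.approx(s2, rel=1e-9)

    def test_halfsib_reml_matches_anova_oracle(self):
        """Balanced paternal half-sib design: REML V_A equals 4 x the
        ANOVA sire variance component when the estimate is interior."""
        ped, df, y, sires = _halfsib_data(50, 12, va=10.0, ve=6.0, seed=42)
        est = fit_animal_model(df, pedigree_grm(ped), fixed=(),
                               include_permanent_env=False)
        n_s, k = 50, 12
        ybar = y.reshape(n_s, k).mean(1)
        msb = k * np.sum((ybar - y.mean()) ** 2) / (n_s - 1)
        msw = np.sum((y.reshape(n_s, k) - ybar[:, None]) ** 2) / (n_s * (k - 1))
        anova_va = 4 * (msb - msw) / k
        assert est.v_a == pytest.approx(anova_va, abs=1e-6)

    def test_null_additive_variance_at_boundary(self):
        ped, df, _, _ = _halfsib_data(30, 6, va=0.0, ve=5.0, seed=7)
        est = fit_animal_model(df, pedigree_grm(ped), fixed=(),
                               include_permanent_env=False)
        assert est.h2 < 0.08

    def test_h2_components_partition_unity(self):
        ped, df, _, _ = _halfsib_data(25, 8, va=6.0, ve=6.0, seed=3)
        est = fit_animal_model(df, pedigree_grm(ped), fixed=())
        assert est.h2 + est.e2 + est.v_pe / est.v_p == pytest.approx(1.0, abs=1e-12)

    def test_grm_and_nrm_models_agree(self):
        """Genotype-built and pedigree-built relationship matrices give
        compatible heritability estimates on pedigree-generated data."""
        cfg = SimConfig(
            n_founders=80, offspring_per_pair=4, n_generations=3,
            chromosome_lengths_bp=(60_000_000, 50_000_000),
            snp_density_per_mb=8.0, map_male_cm=130, map_female_cm=110,
            male_subtelomeric_factor=1.0, v_a_acc=0.2, v_r_acc=0.6,
            genotyping_error_rate=0.0, genotyping_missing_rate=0.0, seed=19,
        )
        ped = simulate_pedigree(cfg)
        drop = gene_drop(ped, cfg)
        pheno = simulate_acc_phenotype(ped, v_a=8.0, v_pe=0.0, v_r=12.0,
                                       seed=4)
        founders = set(ped.founders())
        pheno = pheno[~pheno.fid.isin(founders)].reset_index(drop=True)
        pheno["fid_sex"] = [ped.sex(f) for f in pheno.fid]
        nrm_fit = fit_animal_model(pheno, pedigree_grm(ped), fixed=("fid_sex",))
        grm = compute_grm(drop.panel, freqs=drop.founder_freqs)
        grm_fit = fit_animal_model(pheno, grm, fixed=("fid_sex",))
        joint_se = np.hypot(nrm_fit.h2_se, grm_fit.h2_se)
        assert abs(nrm_fit.h2 - grm_fit.h2) < 2 * joint_se

    def test_wald_sex_effect(self):
        ped = simulate_pedigree(SimConfig(n_founders=60, offspring_per_pair=4,
                                          n_generations=2, seed=2))
        df = simulate_acc_phenotype(ped, v_a=0.5, v_pe=0.0, v_r=4.0, seed=5)
        df["fid_sex"] = [ped.sex(f) for f in df.fid]
        est = fit_animal_model(df, pedigree_grm(ped), fixed=("fid_sex",),
                               include_permanent_env=False)
        cols = [c for c in est.fit.beta.index if c.startswith("fid_sex")]
        chi2, dfree, p = est.fit.wald_fixed(cols)
        assert p < 1e-6  # 7-crossover sex difference is unmissable


class TestLRT:
    def test_identical_models_give_p_one(self):
        ped, df, _, _ = _halfsib_data(20, 5, va=4.0, ve=4.0, seed=1)
        est = fit_animal_model(df, pedigree_grm(ped), fixed=(),
                               include_permanent_env=False)
        chi2, dfree, p = lrt_random_effect(est, est)
        assert chi2 == 0.0 and p == 1.0

    def test_power_against_strong_heritability(self):
        ped, df, _, _ = _halfsib_data(80, 12, va=8.0, ve=12.0, seed=11)
        full = fit_animal_model(df, pedigree_grm(ped), fixed=(),
                                include_permanent_env=False)
        reduced = fit_animal_model(df, pedigree_grm(ped), fixed=(),
                                   include_additive=False,
                                   include_permanent_env=False)
        chi2, dfree, p = lrt_random_effect(full, reduced)
        assert p < 0.001

    def test_type_one_error_conservative_under_null(self):
        """Null (V_A = 0) LRT rejects at most ~alpha of the time; the zero
        boundary makes the plain chi-square conservative."""
        rejections = 0
        n_reps = 60
        for rep in range(n_reps):
            ped, df, _, _ = _halfsib_data(24, 5, va=0.0, ve=5.0,
                                          seed=500 + rep)
            full = fit_animal_model(df, pedigree_grm(ped), fixed=(),
                                    include_permanent_env=False)
            reduced = fit_animal_model(df, pedigree_grm(ped), fixed=(),
                                       include_additive=False,
                                       include_permanent_env=False)
            _, _, p = lrt_random_effect(full, reduced)
            rejections += p < 0.05
        assert rejections <= np.ceil(0.05 * n_reps + 3 * np.sqrt(0.05 * 0.95 * n_reps))

    def test_mixture_reference_halves_pvalue(self):
        ped, df, _, _ = _halfsib_data(30, 8, va=5.0, ve=10.0, seed=13)
        full = fit_animal_model(df, pedigree_grm(ped), fixed=(),
                                include_permanent_env=False)
        reduced = fit_animal_model(df, pedigree_grm(ped), fixed=(),
                                   include_additive=False,
                                   include_permanent_env=False)
        c1, _, plain = lrt_random_effect(full, reduced)
        c2, _, mixed = lrt_random_effect(full, reduced, mixture=True)
        if c1 > 0:
            assert mixed == pytest.approx(plain / 2)

    def test_reversed_nesting_raises(self):
        ped, df, _, _ = _halfsib_data(40, 8, va=8.0, ve=8.0, seed=21)
        full = fit_animal_model(df, pedigree_grm(ped), fixed=(),
                                include_permanent_env=False)
        reduced = fit_animal_model(df, pedigree_grm(ped), fixed=(),
                                   include_additive=False,
                                   include_permanent_env=False)
        with pytest.raises(Exception):
            lrt_random_effect(reduced, full)


# ---------------------------------------------------------------------------
# Bivariate cross-sex model
# ---------------------------------------------------------------------------

def _bivariate_pheno(ped, founders, va_m, va_f, r_a, vr_m, vr_f, seed):
    rng = np.random.default_rng(seed)
    g1 = _breeding_values(ped, 1.0, np.random.default_rng(seed + 1))
    g2 = _breeding_values(ped, 1.0, np.random.default_rng(seed + 2))
    rows = []
    for parent, off in ped.parent_offspring_links():
        if parent in founders:
            continue
        sex = ped.sex(parent)
        if sex == "M":
            y = 34 + np.sqrt(va_m) * g1[parent] + rng.normal(0, np.sqrt(vr_m))
        else:
            af = r_a * g1[parent] + np.sqrt(max(0.0, 1 - r_a ** 2)) * g2[parent]
            y = 27 + np.sqrt(va_f) * af + rng.normal(0, np.sqrt(vr_f))
        rows.append(dict(fid=parent, offspring=off, fid_sex=sex, acc=y))
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def bivariate_setup():
    cfg = SimConfig(n_founders=100, offspring_per_pair=4, n_generations=3,
                    seed=5)
    ped = simulate_pedigree(cfg)
    return ped, set(ped.founders()), pedigree_grm(ped)


class TestBivariate:
    def test_shared_architecture_recovered(self, bivariate_setup):
        """r_A = 1 with higher female V_A: the estimate is compatible with
        1 (LRT vs the 0.999 constraint not significant) but incompatible
        with 0, mirroring a genuinely shared genetic basis."""
        ped, founders, grm = bivariate_setup
        df = _bivariate_pheno(ped, founders, 4.0, 8.0, 1.0, 10.0, 12.0,
                              seed=42)
        res = bivariate_analysis(df, grm, include_permanent_env=False)
        assert res.r_a == res.free.r_a
        assert abs(res.r_a - 1.0) < 2 * res.r_a_se
        assert res.lrt_vs_one[2] > 0.05
        assert res.lrt_vs_zero[2] < 0.05
        assert res.free.v_a_female > res.free.v_a_male

    def test_null_correlation_not_rejected(self, bivariate_setup):
        ped, founders, grm = bivariate_setup
        n_sig = 0
        for rep in range(5):
            df = _bivariate_pheno(ped, founders, 4.0, 4.0, 0.0, 10.0, 10.0,
                                  seed=100 + rep)
            free = fit_bivariate_acc(df, grm, "free",
                                     include_permanent_env=False)
            zero = fit_bivariate_acc(df, grm, "rA0",
                                     include_permanent_env=False)
            _, _, p = lrt_random_effect(free, zero)
            n_sig += p < 0.05
        assert n_sig <= 1

    def test_constraint_loglik_ordering(self, bivariate_setup):
        ped, founders, grm = bivariate_setup
        df = _bivariate_pheno(ped, founders, 3.0, 5.0, 0.7, 12.0, 14.0,
                              seed=77)
        free = fit_bivariate_acc(df, grm, "free", include_permanent_env=False)
        for constraint in ("rA0", "rA1", "equalVA"):
            fit = fit_bivariate_acc(df, grm, constraint,
                                    include_permanent_env=False)
            assert fit.loglik <= free.loglik + 1e-4 * (1 + abs(free.loglik))


# ---------------------------------------------------------------------------
# Reference-panel selection
# ---------------------------------------------------------------------------

class TestReferencePanel:
    def _star(self, n_offspring=10):
        rows = [dict(id="SIRE", sire=None, dam=None, sex="M")]
        rows += [dict(id=f"D{i}", sire=None, dam=None, sex="F")
                 for i in range(n_offspring)]
        rows += [dict(id=f"O{i}", sire="SIRE", dam=f"D{i}", sex="U")
                 for i in range(n_offspring)]
        return Pedigree(pd.DataFrame(rows)).nrm()

    def test_star_pedigree_selects_sire_first(self):
        sel = select_reference_panel(self._star(), 1)
        assert sel == ["SIRE"]

    def test_exhaustive_first_pick_oracle(self):
        """The first greedy pick maximises the objective over all single
        candidates (checked by exhaustive evaluation)."""
        A = self._star(6)
        M = A.to_numpy()
        c = M.mean(axis=1)
        # objective for a single candidate i is p = A_ii^{-1} c_i
        objs = {A.index[i]: c[i] / M[i, i] for i in range(len(A))}
        best = max(sorted(objs), key=lambda k: objs[k])
        assert select_reference_panel(A, 1) == [best]

    def test_select_all_and_monotone_objective(self):
        A = self._star(5)
        n = len(A)
        sel = select_reference_panel(A, n)
        assert sorted(sel) == sorted(A.index)

        M = A.to_numpy()
        c = M.mean(axis=1)
        idx = {iid: k for k, iid in enumerate(A.index)}
        prev = -np.inf
        for m in range(1, n + 1):
            chosen = [idx[i] for i in select_reference_panel(A, m)]
            obj = float(np.linalg.solve(M[np.ix_(chosen, chosen)],
                                        c[chosen]).sum())
            assert obj >= prev - 1e-9
            prev = obj

    def test_m_out_of_range(self):
        A = self._star(3)
        with pytest.raises(ValueError):
            select_reference_panel(A, 0)
        with pytest.raises(ValueError):
            select_reference_panel(A, len(A) + 1)
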