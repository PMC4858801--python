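"""Per-SNP mixed-model association of autosomal crossover count.

Each SNP is tested as a genotype factor (two or three observed classes,
effects of AB and BB relative to AA) added to the animal model's fixed
effects; significance is a Wald chi-square with df = classes - 1.  The
polygenic background is held by the null model's variance components: the
null animal model is fitted once per stratum by REML, and the per-SNP fixed
effects are then estimated by generalised least squares under that fitted
covariance (set ``refit_variance=True`` to re-estimate components per SNP).

Genomic control divides the test statistics by lambda (median observed /
median null chi-square) only when lambda exceeds 1; the multiple-testing
threshold uses a sliding-window effective-number-of-tests computed from
local linkage disequilibrium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .detect import CrossoverTable
from .pedigree import MISSING, GenotypePanel
from .varcomp import GRM, _build_v, _incidence, design_matrix, fit_animal_model

CHI2_MEDIAN_DF2 = float(stats.chi2.ppf(0.5, 2))


# ---------------------------------------------------------------------------
# V_SNP
# ---------------------------------------------------------------------------

def snp_variance(
    p: float, effect_ab: float, effect_bb: float,
    v_a_without_snp: float | None = None,
) -> tuple[float, float]:
    """Phenotypic variance attributed to one SNP: V_SNP = 2pq [a + d(q-p)]^2.

    ``p`` and ``q = 1 - p`` are the A and B allele frequencies; ``a`` is half
    the AA-BB effect difference (signed toward BB) and ``d`` the difference
    between ``a`` and the AB effect, both on the model scale where AA is the
    intercept.  With these conventions the expression equals the additive
    (breeding-value regression) variance of the locus exactly.  Returns
    (V_SNP, V_SNP / (V_SNP + V_A)); the second element is NaN when
    ``v_a_without_snp`` is None.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("allele frequency must lie in (0, 1)")
    q = 1.0 - p
    a = effect_bb / 2.0
    d = a - effect_ab
    v_snp = 2.0 * p * q * (a + d * (q - p)) ** 2
    prop = (
        float("nan") if v_a_without_snp is None
        else v_snp / (v_snp + v_a_without_snp)
    )
    return float(v_snp), float(prop)


# ---------------------------------------------------------------------------
# Effective number of tests
# ---------------------------------------------------------------------------

def effective_tests(
    panel_or_geno, window: int = 50, alpha: float = 0.05,
    chrom: np.ndarray | None = None,
) -> tuple[float, float]:
    """LD-based effective number of tests and the Bonferroni-style threshold.

    The first SNP of each chromosome contributes 1; every further SNP
    contributes sqrt(1 - max r^2) with the preceding ``window - 1`` SNPs of
    the same chromosome, where r^2 is the squared genotype correlation.
    Returns (n_eff, alpha / n_eff).
    """
    if isinstance(panel_or_geno, GenotypePanel):
        g = panel_or_geno.genotypes
        chrom = panel_or_geno.markers["chrom"].to_numpy()
    else:
        g = np.asarray(panel_or_geno)
        if chrom is None:
            chrom = np.zeros(g.shape[1], dtype=int)
    g = g.astype(float)
    g[g == MISSING] = np.nan

    n_eff = 0.0
    for c in pd.unique(chrom):
        cols = np.flatnonzero(chrom == c)
        sub = g[:, cols]
        m = sub.shape[1]
        for j in range(m):
            if j == 0:
                n_eff += 1.0
                continue
            lo = max(0, j - (window - 1))
            max_r2 = 0.0
            xj = sub[:, j]
            if np.all(np.isnan(xj)):
                warnings.warn("all-missing SNP contributes 1 effective test")
                n_eff += 1.0
                continue
            for kk in range(lo, j):
                xk = sub[:, kk]
                ok = ~np.isnan(xj) & ~np.isnan(xk)
                if ok.sum() < 3:
                    continue
                a, b = xj[ok], xk[ok]
                sa, sb = a.std(), b.std()
                if sa == 0 or sb == 0:
                    continue
                r = float(np.corrcoef(a, b)[0, 1])
                max_r2 = max(max_r2, r * r)
            n_eff += float(np.sqrt(max(1.0 - max_r2, 0.0)))
    return n_eff, significance_threshold(n_eff, alpha)


def significance_threshold(n_eff: float, alpha: float = 0.05) -> float:
    """Genome-wide significance threshold alpha / n_eff."""
    return alpha / n_eff


# ---------------------------------------------------------------------------
# GWAS
# ---------------------------------------------------------------------------

@dataclass
class GwasRun:
    """Association records with genomic control and multiple-testing data."""

    records: pd.DataFrame
    lambda_gc: float
    lambda_applied: bool
    n_eff: float
    threshold: float
    stratum: str
    null_model: object


def _lambda_gc(chi2: np.ndarray, df: np.ndarray) -> float:
    """Genomic control parameter on the 2-df scale.

    Statistics with df = 1 are mapped onto the 2-df scale through their
    p-value quantile before the median is taken.
    """
    chi2 = np.asarray(chi2, float)
    df = np.asarray(df)
    x2 = chi2.copy()
    one = df == 1
    if one.any():
        p = stats.chi2.sf(chi2[one], 1)
        x2[one] = stats.chi2.isf(p, 2)
    return float(np.median(x2) / CHI2_MEDIAN_DF2)


def run_gwas(
    acc: CrossoverTable | pd.DataFrame,
    panel: GenotypePanel,
    relationship: GRM,
    stratum: str = "all",
    trans_mode: bool = False,
    fixed=("fid_sex",),
    window: int = 50,
    alpha: float = 0.05,
    refit_variance: bool = False,
) -> GwasRun:
    """Mixed-model association of ACC (or trans-ACC) at every SNP.

    ``stratum`` restricts gametes to ``"female"``/``"male"`` focal parents
    (the sex fixed effect is then dropped).  In ``trans_mode`` the response
    tested against a SNP excludes crossovers on the SNP's own chromosome,
    isolating genome-wide (trans) rate effects.  SNPs with a single observed
    genotype class in the stratum are skipped.
    """
    summary = acc.summary if isinstance(acc, CrossoverTable) else acc
    df = summary.reset_index(drop=True)
    if stratum == "female":
        df = df[df["fid_sex"] == "F"].reset_index(drop=True)
    elif stratum == "male":
        df = df[df["fid_sex"] == "M"].reset_index(drop=True)
    elif stratum != "all":
        raise ValueError(f"unknown stratum {stratum!r}")
    if df.empty:
        raise ValueError(f"no gametes in stratum {stratum!r}")
    use_fixed = [f for f in fixed
                 if f in df.columns and (stratum == "all" or f != "fid_sex")]
    use_fixed = [f for f in use_fixed if df[f].nunique() > 1 or
                 df[f].dtype.kind not in "OUSb"]

    null = fit_animal_model(df, relationship, response="acc", fixed=use_fixed)
    theta = null.fit.theta
    fids = df["fid"].astype(str)
    levels = sorted(fids.unique())
    K = relationship.subset(levels).matrix
    Z = _incidence(fids, levels)
    comps = [Z @ K @ Z.T, Z @ Z.T, None]
    n = len(df)
    V = _build_v(theta, comps, n)
    cho = linalg.cho_factor(V, check_finite=False)
    Vinv = linalg.cho_solve(cho, np.eye(n), check_finite=False)

    X0, names0 = design_matrix(df, use_fixed)
    y_all = df["acc"].to_numpy(float)

    trans_y: dict = {}
    if trans_mode:
        if not isinstance(acc, CrossoverTable) or acc.per_chromosome.empty:
            raise ValueError("trans_mode needs per-chromosome crossover counts")
        pc = acc.per_chromosome
        key = df[["fid", "offspring"]].astype(str).agg("->".join, axis=1)
        for chrom in panel.chromosomes():
            sub = pc[pc["chrom"] == chrom].copy()
            sub_key = sub[["fid", "offspring"]].astype(str).agg("->".join, axis=1)
            cmap = dict(zip(sub_key, sub["crossovers"]))
            focal = key.map(cmap).fillna(0).to_numpy(float)
            trans_y[chrom] = y_all - focal

    row_of = {i: k for k, i in enumerate(panel.ids)}
    rows = np.array([row_of[f] for f in fids])
    G = panel.genotypes[rows]

    records = []
    chroms = panel.markers["chrom"].to_numpy()
    snps = panel.markers["snp"].astype(str).to_numpy()
    for j in range(panel.n_markers):
        gj = G[:, j]
        ok = gj != MISSING
        classes = np.unique(gj[ok])
        if len(classes) < 2:
            continue
        y = trans_y[chroms[j]] if trans_mode else y_all
        ref = classes[0]  # AA when present, else the lowest observed class
        dummies = [(gj == cl).astype(float) for cl in classes[1:]]
        X = np.column_stack([X0] + dummies)
        if refit_variance:
            sub = df.loc[ok].copy()
            sub["snp_genotype"] = pd.Categorical(gj[ok])
            refit = fit_animal_model(
                sub, relationship, response="acc",
                fixed=use_fixed + ["snp_genotype"],
            )
            gen_cols = [c for c in refit.fit.beta.index
                        if c.startswith("snp_genotype_")]
            wald, dfree, _ = refit.fit.wald_fixed(gen_cols)
            b_map = {c: refit.fit.beta[c] for c in gen_cols}
            s_map = {c: refit.fit.beta_se[c] for c in gen_cols}
            eff = dict.fromkeys(("effect_ab", "effect_bb"), np.nan)
            se_eff = dict.fromkeys(("se_ab", "se_bb"), np.nan)
            for cl in classes[1:]:
                lab = {1: "ab", 2: "bb"}.get(int(cl))
                col = f"snp_genotype_{cl}"
                if lab and col in b_map:
                    eff[f"effect_{lab}"] = float(b_map[col])
                    se_eff[f"se_{lab}"] = float(s_map[col])
            freq_b = float(gj[ok].mean() / 2.0)
            p_a = 1.0 - freq_b
            if 0 < p_a < 1 and np.isfinite(eff["effect_bb"]) and ref == 0:
                vs, prop = snp_variance(
                    p_a,
                    eff["effect_ab"] if np.isfinite(eff["effect_ab"]) else 0.0,
                    eff["effect_bb"], null.v_a,
                )
            else:
                vs, prop = float("nan"), float("nan")
            records.append(
                dict(snp=snps[j], chrom=chroms[j], stratum=stratum,
                     n=int(ok.sum()), classes=len(classes), df=dfree,
                     chi2=wald, p_raw=float(stats.chi2.sf(wald, dfree)),
                     v_snp=vs, prop_va=prop, **eff, **se_eff)
            )
            continue
        if not ok.all():
            Xs, ys = X[ok], y[ok]
            Vs = V[np.ix_(np.flatnonzero(ok), np.flatnonzero(ok))]
            cs = linalg.cho_factor(Vs, check_finite=False)
            VinvX = linalg.cho_solve(cs, Xs, check_finite=False)
            Vinvy = linalg.cho_solve(cs, ys, check_finite=False)
            XtVX = Xs.T @ VinvX
            Xty = Xs.T @ Vinvy
        else:
            VinvX = Vinv @ X
            XtVX = X.T @ VinvX
            Xty = VinvX.T @ y
        try:
            C = np.linalg.inv(XtVX)
        except np.linalg.LinAlgError:
            continue
        b = C @ Xty
        kgen = len(dummies)
        idx = np.arange(X.shape[1] - kgen, X.shape[1])
        bg = b[idx]
        Cg = C[np.ix_(idx, idx)]
        try:
            wald = float(bg @ np.linalg.solve(Cg, bg))
        except np.linalg.LinAlgError:
            continue
        dfree = kgen
        se = np.sqrt(np.clip(np.diag(C), 0, None))
        eff = dict.fromkeys(("effect_ab", "effect_bb"), np.nan)
        se_eff = dict.fromkeys(("se_ab", "se_bb"), np.nan)
        for cl, bi, si in zip(classes[1:], bg, se[idx]):
            lab = {1: "ab", 2: "bb"}.get(int(cl))
            if lab:
                eff[f"effect_{lab}"] = float(bi)
                se_eff[f"se_{lab}"] = float(si)
        freq_b = float(gj[ok].mean() / 2.0)
        p_a = 1.0 - freq_b
        if 0 < p_a < 1 and np.isfinite(eff["effect_bb"]) and ref == 0:
            vs, prop = snp_variance(
                p_a,
                eff["effect_ab"] if np.isfinite(eff["effect_ab"]) else 0.0,
                eff["effect_bb"], null.v_a,
            )
        else:
            vs, prop = float("nan"), float("nan")
        records.append(
            dict(snp=snps[j], chrom=chroms[j], stratum=stratum,
                 n=int(ok.sum()), classes=len(classes), df=dfree,
                 chi2=wald, p_raw=float(stats.chi2.sf(wald, dfree)),
                 v_snp=vs, prop_va=prop, **eff, **se_eff)
        )
    if not records:
        raise ValueError("no testable SNP in this stratum")
    rec = pd.DataFrame(records)
    lam = _lambda_gc(rec["chi2"].to_numpy(), rec["df"].to_numpy())
    applied = lam > 1.0
    if applied:
        chi2_corr = rec["chi2"] / lam
        rec["p"] = stats.chi2.sf(chi2_corr, rec["df"])
    else:
        rec["p"] = rec["p_raw"]
    n_eff, thr = effective_tests(
        panel.genotypes[rows], window=window, alpha=alpha, chrom=chroms,
    )
    return GwasRun(
        records=rec, lambda_gc=lam, lambda_applied=applied,
        n_eff=n_eff, threshold=thr, stratum=stratum, null_model=null,
    )
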