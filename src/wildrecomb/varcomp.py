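"""Genomic relationships and REML animal models for crossover count.

The additive genetic variance of autosomal crossover count (ACC) is
estimated with the animal model

    y = X beta + Z1 a + Zr ur + e,

where ``a`` has covariance V_A * K for a relationship matrix K (genomic or
pedigree-derived) and ``ur`` collects further random effects (by default an
individual-identity "permanent environment" effect for repeated gametes per
focal individual).  Estimation is restricted maximum likelihood by
average-information (AI) iteration with a guarded expectation-maximisation
style fallback step; variance components are constrained non-negative and
flagged when they converge onto the zero boundary.

The genomic relationship matrix uses the standard allele-frequency-weighted
cross-products with the F^III-type inbreeding measure on the diagonal:

    A_jk = mean_m (x_j - 2p)(x_k - 2p) / 2p(1-p)        (j != k)
    A_jj = 1 + F_j,   F_j = mean_m [x^2 - (1+2p)x + 2p^2] / 2p(1-p)
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .pedigree import MISSING, GenotypePanel, Pedigree


# ---------------------------------------------------------------------------
# Genomic relationship matrix
# ---------------------------------------------------------------------------

@dataclass
class GRM:
    """Genomic (or pedigree) relationship matrix over named individuals."""

    matrix: np.ndarray
    ids: list[str]
    fhat: np.ndarray | None = None
    n_markers: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)

    def subset(self, keep_ids) -> "GRM":
        keep_ids = [str(i) for i in keep_ids]
        pos = {i: k for k, i in enumerate(self.ids)}
        idx = np.array([pos[i] for i in keep_ids])
        return GRM(
            matrix=self.matrix[np.ix_(idx, idx)], ids=keep_ids,
            fhat=None if self.fhat is None else self.fhat[idx],
            n_markers=self.n_markers,
        )

    def to_gcta(self, prefix: str) -> None:
        """GCTA-style text triplet (``.grm.gz``) plus ``.grm.id``."""
        with open(f"{prefix}.grm.id", "w") as fh:
            for i in self.ids:
                fh.write(f"FAM\t{i}\n")
        with gzip.open(f"{prefix}.grm.gz", "wt") as fh:
            n = len(self.ids)
            for j in range(n):
                for k in range(j + 1):
                    fh.write(
                        f"{j + 1}\t{k + 1}\t{self.n_markers}\t"
                        f"{self.matrix[j, k]:.6f}\n"
                    )


def compute_grm(
    source, ids=None, freqs=None, adjust: bool = False,
    marker_subset=None,
) -> GRM:
    """Genomic relatedness with F^III inbreeding on the diagonal.

    ``source`` is a GenotypePanel or an individuals x markers matrix of
    B-allele counts (-1 missing).  ``freqs`` overrides the observed allele
    frequencies (e.g. to use base-population frequencies).  ``adjust``
    applies a sampling-error shrinkage of the relationship entries (the
    1/m share of the off-diagonal variance is removed), assuming causal and
    genotyped loci share an allele-frequency spectrum; default off.

    Raises on monomorphic markers: they carry no relationship information
    and make the denominator vanish.
    """
    if isinstance(source, GenotypePanel):
        g = source.genotypes
        ids = list(source.ids)
    else:
        g = np.asarray(source)
        ids = [str(i) for i in (ids if ids is not None else range(len(g)))]
    if marker_subset is not None:
        marker_subset = np.asarray(marker_subset)
        if marker_subset.dtype == bool:
            marker_subset = np.flatnonzero(marker_subset)
        g = g[:, marker_subset]
    g = g.astype(float)
    obs = g != MISSING
    g[~obs] = np.nan
    if freqs is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nanmean(g, axis=0) / 2.0
    else:
        p = np.asarray(freqs, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic marker in GRM computation")
    het = 2.0 * p * (1.0 - p)

    W = (g - 2.0 * p) / np.sqrt(het)
    W[~obs] = 0.0
    M = obs.astype(float)
    N = M @ M.T
    N[N == 0] = np.nan
    A = (W @ W.T) / N

    num = g * g - (1.0 + 2.0 * p) * g + 2.0 * p * p
    fh = np.empty(len(g))
    for i in range(len(g)):
        ok = obs[i]
        fh[i] = np.mean(num[i, ok] / het[ok]) if ok.any() else 0.0
    np.fill_diagonal(A, 1.0 + fh)

    m_mean = float(np.nanmean(N[~np.eye(len(g), dtype=bool)])) if len(g) > 1 else g.shape[1]
    if adjust and len(g) > 2:
        off = A[~np.eye(len(g), dtype=bool)]
        v = float(np.var(off))
        beta = max(0.0, min(1.0, 1.0 - (1.0 / m_mean) / v)) if v > 0 else 1.0
        A = A.copy()
        offmask = ~np.eye(len(g), dtype=bool)
        A[offmask] = A[offmask] * beta
        np.fill_diagonal(A, 1.0 + beta * fh)
    return GRM(matrix=A, ids=ids, fhat=fh, n_markers=g.shape[1])


def pedigree_grm(pedigree: Pedigree) -> GRM:
    """Numerator relationship matrix wrapped in the GRM container."""
    A = pedigree.nrm()
    return GRM(matrix=A.to_numpy(), ids=list(A.index), fhat=None, n_markers=0)


# ---------------------------------------------------------------------------
# REML core
# ---------------------------------------------------------------------------

class REMLError(RuntimeError):
    pass


@dataclass
class REMLResult:
    """Converged REML fit of y = X beta + sum(u_i) + e."""

    names: list[str]
    theta: np.ndarray
    theta_se: np.ndarray
    cov_theta: np.ndarray
    beta: pd.Series
    beta_se: pd.Series
    loglik: float
    converged: bool
    boundary: list[str]
    n: int
    n_params: int
    _xtvinvx_inv: np.ndarray = field(default=None, repr=False)

    @property
    def components(self) -> dict:
        return dict(zip(self.names, self.theta))

    @property
    def v_p(self) -> float:
        return float(self.theta.sum())

    def ratio(self, name: str) -> float:
        return float(self.components[name] / self.v_p)

    def ratio_se(self, name: str) -> float:
        """Delta-method SE of component/V_P."""
        k = self.names.index(name)
        S = self.v_p
        grad = -self.theta[k] / S**2 * np.ones(len(self.theta))
        grad[k] += 1.0 / S
        var = float(grad @ self.cov_theta @ grad)
        return float(np.sqrt(max(var, 0.0)))

    def wald_fixed(self, columns) -> tuple[float, int, float]:
        """Joint Wald chi-square test that the given fixed effects are zero."""
        cols = [c for c in columns if c in self.beta.index]
        if not cols:
            raise KeyError(f"no such fixed effects: {columns}")
        idx = [list(self.beta.index).index(c) for c in cols]
        b = self.beta.values[idx]
        C = self._xtvinvx_inv[np.ix_(idx, idx)]
        chi2 = float(b @ np.linalg.solve(C, b))
        df = len(idx)
        return chi2, df, float(stats.chi2.sf(chi2, df))


def _build_v(theta, v_list, n):
    V = np.zeros((n, n))
    for t, Vi in zip(theta, v_list):
        if Vi is None:
            V[np.diag_indices(n)] += t
        else:
            V += t * Vi
    return V


def _reml_quantities(theta, y, X, v_list):
    """(loglik, P, Py, Vinv, XtVinvX_inv) for a parameter point; None if V
    is not positive definite."""
    n = len(y)
    V = _build_v(theta, v_list, n)
    try:
        c, low = linalg.cho_factor(V, check_finite=False)
    except linalg.LinAlgError:
        return None
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
    Vinv = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    try:
        cx = linalg.cho_factor(XtVinvX, check_finite=False)
    except linalg.LinAlgError:
        return None
    logdet_x = 2.0 * float(np.sum(np.log(np.diag(cx[0]))))
    XtVinvX_inv = linalg.cho_solve(cx, np.eye(X.shape[1]), check_finite=False)
    P = Vinv - VinvX @ XtVinvX_inv @ VinvX.T
    Py = P @ y
    loglik = -0.5 * (logdet_v + logdet_x + float(y @ Py))
    return loglik, P, Py, Vinv, XtVinvX_inv


def reml_loglik(theta, y, X, v_list) -> float:
    """Restricted log-likelihood at a given variance-component vector."""
    q = _reml_quantities(np.asarray(theta, float), y, X, v_list)
    if q is None:
        return -np.inf
    return q[0]


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    components: list[tuple[str, np.ndarray | None]],
    beta_names=None,
    start: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    allow_negative: set | None = None,
) -> REMLResult:
    """AI-REML with EM-style fallback for arbitrary dense covariance terms.

    ``components`` is a list of (name, V_i) with V_i an n x n covariance
    structure (``None`` denotes the identity); a residual identity term must
    be included by the caller (see :func:`fit_animal_model`).  Components are
    constrained non-negative unless named in ``allow_negative`` (used for
    cross-trait covariances).
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X are not conformable")
    names = [c[0] for c in components]
    v_list = [c[1] for c in components]
    k = len(components)
    allow_negative = allow_negative or set()

    ols_beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    var0 = float(np.var(y - X @ ols_beta, ddof=p)) or 1.0
    floor = 1e-10 * var0
    theta = np.full(k, var0 / k) if start is None else np.asarray(start, float).copy()
    for i in range(k):
        if names[i] not in allow_negative:
            theta[i] = max(theta[i], floor)

    q = _reml_quantities(theta, y, X, v_list)
    if q is None:
        raise REMLError("starting point gives a singular covariance matrix")
    loglik, P, Py, Vinv, XtVinvX_inv = q
    converged = False
    AI = np.eye(k)
    for _ in range(max_iter):
        T = np.empty((n, k))
        grad = np.empty(k)
        for i, Vi in enumerate(v_list):
            Ti = Py if Vi is None else Vi @ Py
            T[:, i] = Ti
            trPVi = float(np.trace(P)) if Vi is None else float(np.sum(P * Vi))
            grad[i] = -0.5 * (trPVi - float(Py @ Ti))
        AI = 0.5 * (T.T @ P @ T)
        try:
            delta = np.linalg.solve(AI + 1e-8 * np.eye(k) * np.trace(AI), grad)
        except np.linalg.LinAlgError:
            delta = grad / (np.diag(AI) + 1e-8)

        qp = None
        for _ in range(30):  # step-halving on the AI direction
            prop = theta + delta
            for i in range(k):
                if names[i] not in allow_negative:
                    prop[i] = max(prop[i], floor)
            cand = _reml_quantities(prop, y, X, v_list)
            if cand is not None and cand[0] >= loglik - 1e-10:
                qp = cand
                break
            delta *= 0.5
        if qp is None:
            # EM-flavoured multiplicative fallback keeps components positive
            prop = theta.copy()
            for i, Vi in enumerate(v_list):
                if names[i] in allow_negative:
                    continue
                trPVi = float(np.trace(P)) if Vi is None else float(np.sum(P * Vi))
                num = float(Py @ T[:, i])
                if trPVi > 0 and num > 0:
                    prop[i] = max(theta[i] * num / trPVi, floor)
            qp = _reml_quantities(prop, y, X, v_list)
            if qp is None or qp[0] < loglik - 1e-6 * (1 + abs(loglik)):
                converged = True  # no usable uphill step remains
                break
        moved = float(np.max(np.abs(prop - theta) / (np.abs(theta) + var0 * 1e-3)))
        gain = qp[0] - loglik
        theta = prop
        loglik, P, Py, Vinv, XtVinvX_inv = qp
        if gain < tol * (1 + abs(loglik)) and moved < 1e-4:
            converged = True
            break
    if not converged:
        warnings.warn("REML reached max_iter without meeting tolerance")

    # Boundary polish: a component on a shrinking path can stall short of
    # its true zero-boundary optimum; evaluate the boundary explicitly by
    # refitting without the component and adopt the better solution.
    for i in range(k):
        if (names[i] in allow_negative or v_list[i] is None
                or theta[i] > 0.15 * var0):
            continue
        sub = [c for j, c in enumerate(components) if j != i]
        try:
            subfit = reml_fit(
                y, X, sub, beta_names=beta_names,
                start=np.delete(theta, i), max_iter=max_iter, tol=tol,
                allow_negative=allow_negative,
            )
        except REMLError:  # pragma: no cover - singular sub-model
            continue
        if subfit.loglik > loglik + 1e-9:
            theta = np.insert(subfit.theta, i, floor)
            q = _reml_quantities(theta, y, X, v_list)
            if q is None:  # pragma: no cover
                continue
            loglik, P, Py, Vinv, XtVinvX_inv = q
            converged = converged and subfit.converged

    boundary = [names[i] for i in range(k)
                if names[i] not in allow_negative and theta[i] <= floor * 10]
    try:
        cov_theta = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov_theta = np.full((k, k), np.nan)
    theta_se = np.sqrt(np.clip(np.diag(cov_theta), 0, None))

    VinvX = Vinv @ X
    beta = XtVinvX_inv @ (VinvX.T @ y)
    beta_se = np.sqrt(np.clip(np.diag(XtVinvX_inv), 0, None))
    if beta_names is None:
        beta_names = [f"b{i}" for i in range(p)]
    return REMLResult(
        names=names, theta=theta, theta_se=theta_se, cov_theta=cov_theta,
        beta=pd.Series(beta, index=beta_names),
        beta_se=pd.Series(beta_se, index=beta_names),
        loglik=float(loglik), converged=converged, boundary=boundary,
        n=n, n_params=k, _xtvinvx_inv=XtVinvX_inv,
    )


# ---------------------------------------------------------------------------
# Animal model wrapper
# ---------------------------------------------------------------------------

def design_matrix(df: pd.DataFrame, fixed) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment-coded fixed effects from data-frame columns."""
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for f in fixed:
        s = df[f]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(s.astype(str), prefix=f, drop_first=True)
            for c in d.columns:
                cols.append(d[c].to_numpy(float))
                names.append(c)
        else:
            cols.append(s.to_numpy(float))
            names.append(f)
    return np.column_stack(cols), names


def _incidence(levels: pd.Series, order: list) -> np.ndarray:
    pos = {l: i for i, l in enumerate(order)}
    Z = np.zeros((len(levels), len(order)))
    Z[np.arange(len(levels)), [pos[l] for l in levels]] = 1.0
    return Z


@dataclass
class VarianceEstimate:
    """Variance components, heritability and convergence state of one fit."""

    v_a: float
    v_pe: float
    v_r: float
    v_p: float
    h2: float
    h2_se: float
    e2: float
    se: dict
    loglik: float
    converged: bool
    boundary: list[str]
    extra_components: dict
    fit: REMLResult

    def summary(self) -> pd.Series:
        return pd.Series(
            dict(v_a=self.v_a, v_pe=self.v_pe, v_r=self.v_r, v_p=self.v_p,
                 h2=self.h2, h2_se=self.h2_se, e2=self.e2,
                 loglik=self.loglik)
        )


def fit_animal_model(
    data: pd.DataFrame,
    relationship: GRM,
    response: str = "acc",
    fid_col: str = "fid",
    fixed=("sex",),
    extra_random=(),
    include_additive: bool = True,
    include_permanent_env: bool = True,
    start=None,
) -> VarianceEstimate:
    """Univariate REML animal model of a per-gamete trait.

    One row per gamete; the additive effect covariance is ``relationship``
    over focal individuals, the permanent-environment effect is an
    individual-identity random effect for repeated gametes, and
    ``extra_random`` columns add further identity-covariance effects
    (e.g. birth year).
    """
    df = data.reset_index(drop=True)
    fids = df[fid_col].astype(str)
    levels = sorted(fids.unique())
    K = relationship.subset(levels)
    Z = _incidence(fids, levels)
    ZKZ = Z @ K.matrix @ Z.T

    comps: list[tuple[str, np.ndarray | None]] = []
    if include_additive:
        comps.append(("additive", ZKZ))
    if include_permanent_env:
        comps.append(("permanent_env", Z @ Z.T))
    for col in extra_random:
        lv = sorted(df[col].astype(str).unique())
        Zr = _incidence(df[col].astype(str), lv)
        comps.append((col, Zr @ Zr.T))
    comps.append(("residual", None))

    X, names = design_matrix(df, [f for f in fixed if f in df.columns])
    y = df[response].to_numpy(float)
    fit = reml_fit(y, X, comps, beta_names=names, start=start)

    c = fit.components
    v_a = c.get("additive", 0.0)
    v_pe = c.get("permanent_env", 0.0)
    v_r = c["residual"]
    v_p = fit.v_p
    h2 = v_a / v_p if include_additive else 0.0
    h2_se = fit.ratio_se("additive") if include_additive else float("nan")
    extras = {k: v for k, v in c.items()
              if k not in ("additive", "permanent_env", "residual")}
    return VarianceEstimate(
        v_a=v_a, v_pe=v_pe, v_r=v_r, v_p=v_p, h2=h2, h2_se=h2_se,
        e2=v_r / v_p, se=dict(zip(fit.names, fit.theta_se)),
        loglik=fit.loglik, converged=fit.converged, boundary=fit.boundary,
        extra_components=extras, fit=fit,
    )


def lrt_random_effect(full, reduced, df: int = 1, mixture: bool = False):
    """Likelihood-ratio test between nested REML fits.

    chi2 = 2 (logL_full - logL_reduced); ``mixture`` uses the 50:50
    point-mass/chi-square boundary distribution for a single variance
    component instead of the plain chi-square.
    """
    llf = full.loglik if hasattr(full, "loglik") else float(full)
    llr = reduced.loglik if hasattr(reduced, "loglik") else float(reduced)
    chi2 = 2.0 * (llf - llr)
    if chi2 < -1e-4 * (1 + abs(llf)):
        raise REMLError(
            f"full model log-likelihood {llf:.4f} below reduced {llr:.4f}"
        )
    chi2 = max(chi2, 0.0)
    if mixture and df == 1:
        p = 0.5 * stats.chi2.sf(chi2, 1) + (0.5 if chi2 <= 0 else 0.0)
    else:
        p = stats.chi2.sf(chi2, df)
    return chi2, df, float(p)


# ---------------------------------------------------------------------------
# Bivariate (cross-sex) model
# ---------------------------------------------------------------------------

@dataclass
class BivariateFit:
    constraint: str
    v_a_male: float
    v_a_female: float
    cov_a: float
    r_a: float
    r_a_se: float
    components: dict
    loglik: float
    converged: bool


@dataclass
class BivariateResult:
    free: BivariateFit
    r_a: float
    r_a_se: float
    lrt_vs_zero: tuple
    lrt_vs_one: tuple
    lrt_equal_va: tuple


def _bivariate_structures(df, relationship, fid_col, response, sex_col):
    df = df.reset_index(drop=True)
    male = (df[sex_col].astype(str) == "M").to_numpy()
    fids = df[fid_col].astype(str)
    levels = sorted(fids.unique())
    K = relationship.subset(levels).matrix
    Z = _incidence(fids, levels)
    Zm = Z * male[:, None]
    Zf = Z * (~male)[:, None]
    Am = Zm @ K @ Zm.T
    Af = Zf @ K @ Zf.T
    Amf = Zm @ K @ Zf.T
    C = Amf + Amf.T
    PEm = Zm @ Zm.T
    PEf = Zf @ Zf.T
    Rm = np.diag(male.astype(float))
    Rf = np.diag((~male).astype(float))
    y = df[response].to_numpy(float)
    X = np.column_stack([male.astype(float), (~male).astype(float)])
    names = ["mu_male", "mu_female"]
    return y, X, names, dict(Am=Am, Af=Af, C=C, PEm=PEm, PEf=PEf, Rm=Rm, Rf=Rf)


def fit_bivariate_acc(
    data: pd.DataFrame,
    relationship: GRM,
    constraint: str = "free",
    response: str = "acc",
    fid_col: str = "fid",
    sex_col: str = "fid_sex",
    include_permanent_env: bool = True,
    r_a_fixed_value: float = 0.999,
) -> BivariateFit:
    """Two-trait REML treating male and female ACC as separate traits.

    The cross-sex genetic covariance is r_A * sqrt(V_Am V_Af); constraints:
    ``free`` (unconstrained correlation), ``rA0`` (covariance dropped),
    ``rA1`` (r_A fixed near 1, default 0.999) and ``equalVA`` (common
    additive variance across sexes with free correlation).
    """
    y, X, bnames, S = _bivariate_structures(
        data, relationship, fid_col, response, sex_col
    )
    pe = [("pe_male", S["PEm"]), ("pe_female", S["PEf"])] if include_permanent_env else []

    if constraint in ("free", "rA0"):
        comps = [("va_male", S["Am"]), ("va_female", S["Af"])]
        if constraint == "free":
            comps.append(("cov_a", S["C"]))
        comps += pe + [("res_male", S["Rm"]), ("res_female", S["Rf"])]
        fit = reml_fit(y, X, comps, beta_names=bnames,
                       allow_negative={"cov_a"})
        c = fit.components
        vam, vaf = c["va_male"], c["va_female"]
        cov = c.get("cov_a", 0.0)
        if vam <= 0 or vaf <= 0:
            r_a, r_se = float("nan"), float("nan")
            warnings.warn("a sex-specific V_A is at the zero boundary; "
                          "r_A undefined")
        else:
            r_a = cov / np.sqrt(vam * vaf)
            if constraint == "free":
                i_m = fit.names.index("va_male")
                i_f = fit.names.index("va_female")
                i_c = fit.names.index("cov_a")
                g = np.zeros(len(fit.names))
                g[i_c] = 1.0 / np.sqrt(vam * vaf)
                g[i_m] = -0.5 * cov / (vam ** 1.5 * np.sqrt(vaf))
                g[i_f] = -0.5 * cov / (vaf ** 1.5 * np.sqrt(vam))
                r_se = float(np.sqrt(max(g @ fit.cov_theta @ g, 0.0)))
            else:
                r_a, r_se = 0.0, 0.0
        return BivariateFit(
            constraint=constraint, v_a_male=vam, v_a_female=vaf, cov_a=cov,
            r_a=float(r_a), r_a_se=r_se, components=c, loglik=fit.loglik,
            converged=fit.converged,
        )

    # nonlinear constraints: optimize on a transformed scale with scipy
    var0 = float(np.var(y)) or 1.0

    def unpack(z):
        if constraint == "rA1":
            vam, vaf = np.exp(z[0]) * var0, np.exp(z[1]) * var0
            cov = r_a_fixed_value * np.sqrt(vam * vaf)
            rest = z[2:]
        elif constraint == "equalVA":
            vam = vaf = np.exp(z[0]) * var0
            cov = np.tanh(z[1]) * vam
            rest = z[2:]
        else:
            raise ValueError(f"unknown constraint {constraint!r}")
        theta = [vam, vaf, cov]
        theta += [np.exp(v) * var0 for v in rest]
        return np.array(theta)

    v_list = [S["Am"], S["Af"], S["C"]]
    names = ["va_male", "va_female", "cov_a"]
    for nm, V in pe:
        v_list.append(V)
        names.append(nm)
    v_list += [S["Rm"], S["Rf"]]
    names += ["res_male", "res_female"]
    n_free = 2 + len(pe) + 2

    def negll(z):
        return -reml_loglik(unpack(z), y, X, v_list)

    z0 = np.full(n_free, np.log(0.5 / max(n_free - 1, 1)))
    if constraint == "equalVA":
        z0[1] = np.arctanh(0.5)
    best = optimize.minimize(negll, z0, method="Nelder-Mead",
                             options=dict(maxiter=4000, xatol=1e-6, fatol=1e-9))
    theta = unpack(best.x)
    c = dict(zip(names, theta))
    vam, vaf, cov = c["va_male"], c["va_female"], c["cov_a"]
    r_a = cov / np.sqrt(vam * vaf) if vam > 0 and vaf > 0 else float("nan")
    return BivariateFit(
        constraint=constraint, v_a_male=vam, v_a_female=vaf, cov_a=cov,
        r_a=float(r_a), r_a_se=float("nan"), components=c,
        loglik=float(-best.fun), converged=bool(best.success),
    )


def bivariate_analysis(data, relationship, **kw) -> BivariateResult:
    """Free fit plus the three constrained fits and their LRTs (1 df)."""
    free = fit_bivariate_acc(data, relationship, "free", **kw)
    r0 = fit_bivariate_acc(data, relationship, "rA0", **kw)
    r1 = fit_bivariate_acc(data, relationship, "rA1", **kw)
    eq = fit_bivariate_acc(data, relationship, "equalVA", **kw)
    return BivariateResult(
        free=free, r_a=free.r_a, r_a_se=free.r_a_se,
        lrt_vs_zero=lrt_random_effect(free, r0, df=1),
        lrt_vs_one=lrt_random_effect(free, r1, df=1),
        lrt_equal_va=lrt_random_effect(free, eq, df=1),
    )


# ---------------------------------------------------------------------------
# Reference-panel selection
# ---------------------------------------------------------------------------

def select_reference_panel(A, m: int, ids=None) -> list[str]:
    """Greedy choice of m animals capturing maximal genetic variation.

    At each step the candidate maximising sum(p) with p = A_sel^{-1} c_sel is
    added, where c_sel holds the mean relationship of each selected animal to
    the whole population.  Ties break deterministically by id order;
    candidates producing a singular A_sel are skipped with a warning.
    """
    if isinstance(A, pd.DataFrame):
        ids = list(A.index.astype(str))
        M = A.to_numpy(float)
    elif isinstance(A, GRM):
        ids = list(A.ids)
        M = A.matrix
    else:
        M = np.asarray(A, float)
        ids = [str(i) for i in (ids if ids is not None else range(len(M)))]
    n = len(ids)
    if not 1 <= m <= n:
        raise ValueError("m must be in [1, n]")
    c_all = M.mean(axis=1)
    order = sorted(range(n), key=lambda i: ids[i])
    selected: list[int] = []
    for _ in range(m):
        best_obj, best_i = -np.inf, None
        for i in order:
            if i in selected:
                continue
            sel = selected + [i]
            As = M[np.ix_(sel, sel)]
            try:
                pvec = linalg.solve(As, c_all[sel], assume_a="sym")
            except linalg.LinAlgError:
                warnings.warn(f"candidate {ids[i]} makes A_sel singular; skipped")
                continue
            obj = float(pvec.sum())
            if obj > best_obj + 1e-12:
                best_obj, best_i = obj, i
        if best_i is None:
            warnings.warn("no further candidate improves the objective")
            break
        selected.append(best_i)
    return [ids[i] for i in selected]
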