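"""Recombination-landscape summaries: 1-Mb bin probabilities and regressions.

The probability of crossing over within a bin is the sum of adjacent-interval
recombination fractions falling in it.  An interval spanning a bin boundary
contributes r * N_boundary / N_adjSNP to the left bin, where N_boundary is
the number of bases from the left SNP to the boundary and N_adjSNP the number
of bases to the closest SNP within the adjacent bin; the remainder goes to
the adjacent bin, so bin probabilities conserve the chromosome total exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .linkmap import IntervalRF, LinkageMap

TRANSFORMS = ("linear", "inverse", "quadratic", "cubic", "log")


# ---------------------------------------------------------------------------
# Bin probabilities
# ---------------------------------------------------------------------------

def _allocate_interval(left_bp, right_bp, r, bin_size):
    """Yield (bin_start, probability share) portions of one interval."""
    b0 = int(left_bp // bin_size)
    b1 = int(right_bp // bin_size)
    if b0 == b1:
        yield b0 * bin_size, r
        return
    if b1 - b0 == 1:
        n_boundary = (b0 + 1) * bin_size - left_bp
        n_adjsnp = right_bp - left_bp
        left_share = r * n_boundary / n_adjsnp
        yield b0 * bin_size, left_share
        yield b1 * bin_size, r - left_share
        return
    # interval spanning >2 bins: split proportionally to bin overlap
    total = right_bp - left_bp
    for b in range(b0, b1 + 1):
        lo = max(left_bp, b * bin_size)
        hi = min(right_bp, (b + 1) * bin_size)
        yield b * bin_size, r * (hi - lo) / total


def bin_crossover_probability(
    source,
    bin_size: int = 1_000_000,
    chromosome_lengths: dict | None = None,
    gc_table: pd.DataFrame | None = None,
    strata=("male", "female"),
) -> pd.DataFrame:
    """Crossover probability per (chromosome, bin, sex stratum).

    ``source`` is a LinkageMap (intervals derived per stratum) or a list of
    IntervalRF.  Bins tile each chromosome to its length (from
    ``chromosome_lengths`` in bp, else the last marker).  A ``gc_table`` with
    columns (chrom, bin_start, gc_percent) is merged when given.

    Returns a DataFrame with chrom, bin_start, bin_mid, stratum, prob,
    n_snps, dist_telomere_mb, and gc_percent when available.
    """
    if isinstance(source, LinkageMap):
        intervals = []
        for stratum in strata:
            intervals.extend(source.intervals(stratum))
    else:
        intervals = list(source)

    by_stratum: dict[str, list[IntervalRF]] = {}
    for iv in intervals:
        by_stratum.setdefault(iv.stratum, []).append(iv)

    rows = []
    n_wide = 0
    for stratum, ivs in by_stratum.items():
        chroms: dict = {}
        for iv in ivs:
            chroms.setdefault(iv.chrom, []).append(iv)
            if int(iv.right_bp // bin_size) - int(iv.left_bp // bin_size) > 1:
                n_wide += 1
        for chrom, civs in chroms.items():
            max_bp = max(iv.right_bp for iv in civs)
            length = (
                chromosome_lengths[chrom]
                if chromosome_lengths is not None
                else max_bp
            )
            n_bins = int(np.ceil(length / bin_size))
            prob = np.zeros(n_bins)
            n_snps = np.zeros(n_bins, dtype=int)
            for iv in civs:
                r = 0.0 if np.isnan(iv.r) else iv.r
                for bin_start, share in _allocate_interval(
                    iv.left_bp, iv.right_bp, r, bin_size
                ):
                    prob[int(bin_start // bin_size)] += share
                n_snps[min(int(iv.left_bp // bin_size), n_bins - 1)] += 1
            # count the terminal right SNP of the chromosome once
            n_snps[min(int(civs[-1].right_bp // bin_size), n_bins - 1)] += 1
            for b in range(n_bins):
                mid = (b + 0.5) * bin_size
                rows.append(
                    dict(
                        chrom=chrom, bin_start=b * bin_size, bin_mid=mid,
                        stratum=stratum, prob=prob[b], n_snps=n_snps[b],
                        dist_telomere_mb=min(mid, length - mid) / 1e6,
                    )
                )
    if n_wide:
        warnings.warn(
            f"{n_wide} intervals span more than 2 bins; split proportionally"
        )
    bins = pd.DataFrame(rows)
    if gc_table is not None:
        bins = bins.merge(gc_table, on=["chrom", "bin_start"], how="left")
    return bins


# ---------------------------------------------------------------------------
# Telomere-distance models
# ---------------------------------------------------------------------------

def _distance_terms(x: np.ndarray, transform: str) -> np.ndarray:
    if transform == "linear":
        return x[:, None]
    if transform == "inverse":
        return (1.0 / x)[:, None]
    if transform == "quadratic":
        return np.column_stack([x**2, x])
    if transform == "cubic":
        return np.column_stack([x**3, x**2, x])
    if transform == "log":
        return np.log10(x)[:, None]
    raise ValueError(f"unknown transform {transform!r}")


@dataclass
class TelomereModelFit:
    """AIC-selected model of bin crossover probability vs telomere distance."""

    chosen_transform: str
    aic: dict
    model: object  # statsmodels results for the chosen transform
    ratio_model: object | None = None
    ratio_transform: str | None = None

    @property
    def params(self) -> pd.Series:
        return self.model.params


def fit_telomere_model(
    bins: pd.DataFrame,
    max_distance_mb: float = 60.0,
    transforms=TRANSFORMS,
    include_centromere: bool = False,
) -> TelomereModelFit:
    """Select the telomere-distance transform by AIC and fit sex interactions.

    Gaussian linear models of per-bin crossover probability on each candidate
    transform of distance-to-telomere, with sex main effect and
    sex-by-distance interactions, plus the number of SNPs in the bin and GC
    content when present.  A male/female ratio model (no sex term) is fitted
    with the same candidates.
    """
    df = bins[bins["dist_telomere_mb"] <= max_distance_mb].copy()
    df = df[df["dist_telomere_mb"] > 0]
    strata = sorted(df["stratum"].unique())
    if len(strata) < 2:
        raise ValueError("both sex strata are required")
    male = (df["stratum"] == "male").to_numpy(dtype=float)
    x = df["dist_telomere_mb"].to_numpy()
    y = df["prob"].to_numpy()

    covars = [df["n_snps"].to_numpy(dtype=float)]
    names_cov = ["n_snps"]
    if "gc_percent" in df.columns and df["gc_percent"].notna().all():
        covars.append(df["gc_percent"].to_numpy(dtype=float))
        names_cov.append("gc_percent")
    if include_centromere and "centromere_flag" in df.columns:
        covars.append(df["centromere_flag"].to_numpy(dtype=float))
        names_cov.append("centromere_flag")

    fits, aics = {}, {}
    for tr in transforms:
        terms = _distance_terms(x, tr)
        inter = terms * male[:, None]
        X = np.column_stack([terms, male, inter] + covars)
        names = (
            [f"dist_{tr}{i}" for i in range(terms.shape[1])]
            + ["sex_male"]
            + [f"sexdist_{tr}{i}" for i in range(terms.shape[1])]
            + names_cov
        )
        X = sm.add_constant(pd.DataFrame(X, columns=names))
        try:
            res = sm.OLS(y, X).fit()
        except Exception:  # pragma: no cover - singular design
            continue
        fits[tr] = res
        aics[tr] = float(res.aic)
    if len(fits) < 2:
        raise ValueError("fewer than 2 candidate transforms estimable")
    best = min(aics, key=aics.get)

    # ratio model: male/female probability per bin, no sex term
    wide = df.pivot_table(
        index=["chrom", "bin_start", "dist_telomere_mb"] + (
            ["gc_percent"] if "gc_percent" in names_cov else []
        ),
        columns="stratum", values="prob",
    ).reset_index()
    ratio_model = ratio_tr = None
    if {"male", "female"}.issubset(wide.columns):
        ok = wide["female"] > 0
        xr = wide.loc[ok, "dist_telomere_mb"].to_numpy()
        yr = (wide.loc[ok, "male"] / wide.loc[ok, "female"]).to_numpy()
        r_aics, r_fits = {}, {}
        for tr in transforms:
            Xr = sm.add_constant(_distance_terms(xr, tr))
            try:
                res = sm.OLS(yr, Xr).fit()
            except Exception:  # pragma: no cover
                continue
            r_fits[tr] = res
            r_aics[tr] = float(res.aic)
        if r_fits:
            ratio_tr = min(r_aics, key=r_aics.get)
            ratio_model = r_fits[ratio_tr]

    return TelomereModelFit(
        chosen_transform=best, aic=aics, model=fits[best],
        ratio_model=ratio_model, ratio_transform=ratio_tr,
    )


# ---------------------------------------------------------------------------
# Broad-scale regressions
# ---------------------------------------------------------------------------

def broadscale_regressions(linkmap: LinkageMap) -> dict:
    """Chromosome-level regressions of map length and rate on physical size.

    Fits (i) sex-averaged cM length on Mb length, (ii) cM/Mb on Mb with a
    multiplicative-inverse (1/x) term (and a linear fit for AIC comparison),
    and (iii) male on female chromosome map lengths.  Requires >=3
    chromosomes.
    """
    cl = linkmap.chromosome_lengths()
    if len(cl) < 3:
        raise ValueError("broad-scale regression needs >=3 chromosomes")
    mb = cl["bp_length"].to_numpy() / 1e6
    cm = cl["cm_averaged"].to_numpy()
    rate = cm / mb

    out = {}
    res = sm.OLS(cm, sm.add_constant(mb)).fit()
    out["length"] = dict(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        adj_r2=float(res.rsquared_adj), p=float(res.pvalues[1]), model=res,
    )
    res_inv = sm.OLS(rate, sm.add_constant(1.0 / mb)).fit()
    res_lin = sm.OLS(rate, sm.add_constant(mb)).fit()
    out["rate_inverse"] = dict(
        slope=float(res_inv.params[1]), intercept=float(res_inv.params[0]),
        adj_r2=float(res_inv.rsquared_adj), p=float(res_inv.pvalues[1]),
        aic=float(res_inv.aic), aic_linear=float(res_lin.aic), model=res_inv,
    )
    res_mf = sm.OLS(
        cl["cm_male"].to_numpy(), sm.add_constant(cl["cm_female"].to_numpy())
    ).fit()
    out["male_on_female"] = dict(
        slope=float(res_mf.params[1]), slope_se=float(res_mf.bse[1]),
        intercept=float(res_mf.params[0]), adj_r2=float(res_mf.rsquared_adj),
        p=float(res_mf.pvalues[1]), model=res_mf,
    )
    return out
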