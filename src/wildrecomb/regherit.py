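"""Regional heritability: partitioning V_A into sliding genomic windows.

Each window i is fitted with the model

    y = X beta + Z1 v_i + Z2 nv_i + Zr u_r + e,

where v_i has covariance proportional to a GRM built from the window's SNPs
and nv_i to a GRM from all remaining autosomal markers.  The window term's
significance is a likelihood-ratio test against the model without it; fits
whose regional component converges onto the zero boundary have their
p-value masked (a boundary estimate makes the test uninformative).  Windows
overlap by half their SNP length, so the Bonferroni correction divides the
number of tests by two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import GenotypePanel
from .varcomp import (
    GRM, REMLResult, _incidence, compute_grm, design_matrix, lrt_random_effect,
    reml_fit,
)


@dataclass
class Window:
    window_id: int
    chrom: object
    start_index: int  # global panel marker index range [start, stop)
    stop_index: int
    truncated: bool = False
    whole_chromosome: bool = False

    @property
    def size(self) -> int:
        return self.stop_index - self.start_index


def make_windows(panel: GenotypePanel, size: int, overlap: int | None = None):
    """Sliding windows of ``size`` SNPs overlapping by half (per chromosome).

    The final window of a chromosome is truncated at the chromosome end; a
    chromosome with fewer SNPs than ``size`` yields a single flagged
    whole-chromosome window.
    """
    if size % 2:
        raise ValueError("window size must be even")
    step = overlap if overlap is not None else size // 2
    out: list[Window] = []
    wid = 0
    for chrom in panel.chromosomes():
        sl = panel.chrom_slice(chrom)
        m = sl.stop - sl.start
        if m < size:
            out.append(Window(wid, chrom, sl.start, sl.stop,
                              whole_chromosome=True))
            wid += 1
            continue
        starts = list(range(0, m - size + 1, step))
        last_stop = starts[-1] + size
        for s in starts:
            out.append(Window(wid, chrom, sl.start + s, sl.start + s + size))
            wid += 1
        if last_stop < m:
            out.append(Window(wid, chrom, sl.start + starts[-1] + step,
                              sl.stop, truncated=True))
            wid += 1
    return out


@dataclass
class RegionalWindow:
    """One window's variance partition and LRT."""

    window_id: int
    chrom: object
    start_index: int
    stop_index: int
    median_bp: float
    v_regional: float
    v_rest: float
    v_pe: float
    v_residual: float
    v_p: float
    h2_regional: float
    h2_regional_se: float
    chi2: float
    p: float  # NaN when masked at the boundary
    boundary: bool
    loglik_full: float
    loglik_reduced: float
    fit: REMLResult | None = None


def fit_regional_model(
    window: Window,
    acc: pd.DataFrame,
    panel: GenotypePanel,
    fixed=("fid_sex",),
    include_permanent_env: bool = True,
    founder_freqs: np.ndarray | None = None,
) -> RegionalWindow:
    """Four-component REML for one window (regional, rest, identity, resid).

    ``acc`` is the per-gamete phenotype table (columns fid, fid_sex, acc).
    """
    df = acc.reset_index(drop=True)
    fids = sorted(df["fid"].astype(str).unique())

    idx_all = np.arange(panel.n_markers)
    in_win = (idx_all >= window.start_index) & (idx_all < window.stop_index)
    sub_freqs = None if founder_freqs is None else np.asarray(founder_freqs)
    grm_win = compute_grm(
        panel, marker_subset=in_win,
        freqs=None if sub_freqs is None else sub_freqs[in_win],
    ).subset(fids)
    if np.allclose(grm_win.matrix, 0):
        raise ValueError("regional GRM has rank 0")
    grm_rest = compute_grm(
        panel, marker_subset=~in_win,
        freqs=None if sub_freqs is None else sub_freqs[~in_win],
    ).subset(fids)

    Z = _incidence(df["fid"].astype(str), fids)
    comps = [("regional", Z @ grm_win.matrix @ Z.T),
             ("rest", Z @ grm_rest.matrix @ Z.T)]
    if include_permanent_env:
        comps.append(("permanent_env", Z @ Z.T))
    comps.append(("residual", None))
    use_fixed = [f for f in fixed if f in df.columns and df[f].nunique() > 1]
    X, names = design_matrix(df, use_fixed)
    y = df["acc"].to_numpy(float)

    full = reml_fit(y, X, comps, beta_names=names)
    reduced = reml_fit(y, X, comps[1:], beta_names=names)
    chi2, dfree, p = lrt_random_effect(full, reduced, df=1)
    boundary = "regional" in full.boundary
    if boundary:
        p = float("nan")

    c = full.components
    bp = panel.markers["bp"].iloc[window.start_index: window.stop_index]
    return RegionalWindow(
        window_id=window.window_id, chrom=window.chrom,
        start_index=window.start_index, stop_index=window.stop_index,
        median_bp=float(bp.median()),
        v_regional=c["regional"], v_rest=c["rest"],
        v_pe=c.get("permanent_env", 0.0), v_residual=c["residual"],
        v_p=full.v_p, h2_regional=c["regional"] / full.v_p,
        h2_regional_se=full.ratio_se("regional"),
        chi2=chi2, p=p, boundary=boundary,
        loglik_full=full.loglik, loglik_reduced=reduced.loglik, fit=full,
    )


@dataclass
class RegionalScan:
    table: pd.DataFrame
    threshold: float
    n_windows: int
    window_size: int


def regional_scan(
    panel: GenotypePanel,
    acc: pd.DataFrame,
    size: int = 20,
    alpha: float = 0.05,
    **fit_kw,
) -> RegionalScan:
    """Fit every sliding window and apply the overlap-aware Bonferroni rule.

    threshold = alpha / (n_windows / 2), each genomic region being modelled
    twice by half-overlapping windows.
    """
    windows = make_windows(panel, size)
    rows = []
    for w in windows:
        rw = fit_regional_model(w, acc, panel, **fit_kw)
        rows.append(
            dict(window_id=rw.window_id, chrom=rw.chrom,
                 median_bp=rw.median_bp, v_regional=rw.v_regional,
                 v_rest=rw.v_rest, v_p=rw.v_p, h2_regional=rw.h2_regional,
                 h2_regional_se=rw.h2_regional_se, chi2=rw.chi2, p=rw.p,
                 boundary=rw.boundary)
        )
    n = len(windows)
    return RegionalScan(
        table=pd.DataFrame(rows),
        threshold=alpha / (n / 2.0),
        n_windows=n, window_size=size,
    )
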