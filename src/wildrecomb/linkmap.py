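"""Two-point linkage maps from phase-known gametes.

With grandparental origins resolved per gamete and markers taken in genome
order, the recombination fraction of each adjacent marker interval is the
fraction of gametes informative at both markers whose origins differ — the
sufficient statistic for a phase-known, ordered-marker design.  Fractions are
converted to map distances with the Kosambi function, and markers mapping
>3 cM from both neighbours are iteratively removed as mis-mapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import PhasedGamete
from .pedigree import GenotypePanel

STRATA = ("averaged", "male", "female")

_ORIGIN_MISSING = -9


# ---------------------------------------------------------------------------
# Kosambi map function
# ---------------------------------------------------------------------------

def kosambi_cm(r):
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) in centimorgans."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    out = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(out) if out.ndim == 0 else out


def kosambi_r(cm):
    """Inverse Kosambi: r = tanh(d/50) / 2."""
    cm = np.asarray(cm, dtype=float)
    if np.any(cm < 0):
        raise ValueError("map distance must be non-negative")
    out = 0.5 * np.tanh(cm / 50.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Origin matrices and interval recombination fractions
# ---------------------------------------------------------------------------

def _origin_matrix(
    gametes: list[PhasedGamete], marker_index: dict, n_markers: int, sexes
) -> np.ndarray:
    """Gametes x markers matrix of origins (-9 where uninformative)."""
    rows = [g for g in gametes if g.fid_sex in sexes]
    O = np.full((len(rows), n_markers), _ORIGIN_MISSING, dtype=np.int8)
    for i, g in enumerate(rows):
        # markers removed by map QC no longer appear in marker_index
        pairs = [(marker_index[int(j)], o) for j, o in zip(g.marker_idx, g.origin)
                 if int(j) in marker_index]
        if pairs:
            cols, vals = zip(*pairs)
            O[i, list(cols)] = list(vals)
    return O


@dataclass
class IntervalRF:
    """Recombination fraction of one adjacent-marker interval."""

    chrom: object
    left_snp: str
    right_snp: str
    left_bp: int
    right_bp: int
    r: float  # nan when no informative pair
    n_informative_pairs: int
    stratum: str


def _pair_counts(O: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(n both informative, n discordant) per adjacent column pair."""
    inf = O != _ORIGIN_MISSING
    both = inf[:, :-1] & inf[:, 1:]
    disc = both & (O[:, :-1] != O[:, 1:])
    return both.sum(axis=0), disc.sum(axis=0)


def estimate_interval_rf(
    gametes: list[PhasedGamete],
    panel_or_markers,
    stratum: str = "averaged",
) -> list[IntervalRF]:
    """Adjacent-interval recombination fractions for one sex stratum.

    r-hat = (# gametes with differing origin at the two markers) /
    (# gametes informative at both).  Estimates >= 0.5 are truncated to
    0.4999 with a warning; intervals with no informative pair carry NaN.
    """
    markers = (
        panel_or_markers.markers
        if isinstance(panel_or_markers, GenotypePanel)
        else panel_or_markers
    )
    sexes = {"averaged": ("M", "F", "U"), "male": ("M",), "female": ("F",)}[stratum]
    out: list[IntervalRF] = []
    for chrom, sub in markers.groupby("chrom", sort=False):
        sub = sub.reset_index()
        gidx = {int(j): k for k, j in enumerate(sub["index"])}
        gc = [g for g in gametes if g.chrom == chrom]
        O = _origin_matrix(gc, gidx, len(sub), sexes)
        n_both, n_disc = _pair_counts(O)
        for k in range(len(sub) - 1):
            n, d = int(n_both[k]), int(n_disc[k])
            r = d / n if n else float("nan")
            if n and r >= 0.5:
                warnings.warn(
                    f"interval {sub['snp'][k]}-{sub['snp'][k + 1]}: "
                    f"r={r:.3f} >= 0.5 truncated"
                )
                r = 0.4999
            out.append(
                IntervalRF(
                    chrom=chrom,
                    left_snp=str(sub["snp"][k]), right_snp=str(sub["snp"][k + 1]),
                    left_bp=int(sub["bp"][k]), right_bp=int(sub["bp"][k + 1]),
                    r=r, n_informative_pairs=n, stratum=stratum,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Map construction with the 3-cM marker rule
# ---------------------------------------------------------------------------

@dataclass
class LinkageMap:
    """Per-marker sex-averaged/male/female Kosambi positions.

    ``table`` columns: snp, chrom, bp, cm_averaged, cm_male, cm_female,
    zero_bridged (interval into the marker had no informative pair).
    """

    table: pd.DataFrame
    removed_markers: list[str]

    def chromosome_lengths(self) -> pd.DataFrame:
        return (
            self.table.groupby("chrom", sort=False)
            .agg(
                bp_length=("bp", lambda s: s.max() - s.min()),
                cm_averaged=("cm_averaged", "max"),
                cm_male=("cm_male", "max"),
                cm_female=("cm_female", "max"),
            )
            .reset_index()
        )

    def intervals(self, stratum: str = "averaged") -> list[IntervalRF]:
        """Adjacent-marker intervals with r back-transformed from the map."""
        col = f"cm_{stratum}"
        out = []
        for chrom, sub in self.table.groupby("chrom", sort=False):
            cm = sub[col].to_numpy()
            bp = sub["bp"].to_numpy()
            snp = sub["snp"].to_numpy()
            for k in range(len(sub) - 1):
                out.append(
                    IntervalRF(
                        chrom=chrom, left_snp=str(snp[k]), right_snp=str(snp[k + 1]),
                        left_bp=int(bp[k]), right_bp=int(bp[k + 1]),
                        r=kosambi_r(cm[k + 1] - cm[k]),
                        n_informative_pairs=-1, stratum=stratum,
                    )
                )
        return out

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _cm_positions(rfs: list[IntervalRF]) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative Kosambi cM along one chromosome; NaN intervals bridge 0."""
    r = np.array([iv.r for iv in rfs])
    bridged = np.isnan(r)
    d = np.zeros(len(r))
    d[~bridged] = kosambi_cm(r[~bridged])
    return np.concatenate(([0.0], np.cumsum(d))), np.concatenate(([False], bridged))


def build_map(
    gametes: list[PhasedGamete],
    panel: GenotypePanel,
    max_gap_cm: float = 3.0,
    max_iter: int = 50,
) -> LinkageMap:
    """Estimate the three-stratum linkage map with iterative marker QC.

    A marker whose sex-averaged Kosambi distance to *both* adjacent markers
    exceeds ``max_gap_cm`` is presumed mis-mapped and removed; fractions are
    re-estimated until no such marker remains.  Chromosome-terminal markers
    have a single neighbour and are exempt.
    """
    markers = panel.markers.copy()
    removed: list[str] = []
    for _ in range(max_iter):
        rfs = estimate_interval_rf(gametes, markers, "averaged")
        drop: list[str] = []
        pos = 0
        for chrom, sub in markers.groupby("chrom", sort=False):
            m = len(sub)
            ivs = rfs[pos: pos + m - 1]
            pos += m - 1
            if m < 2:
                raise ValueError(f"chromosome {chrom} has <2 markers")
            d = np.array(
                [kosambi_cm(iv.r) if not np.isnan(iv.r) else 0.0 for iv in ivs]
            )
            for k in range(1, m - 1):
                if d[k - 1] > max_gap_cm and d[k] > max_gap_cm:
                    drop.append(str(sub["snp"].iloc[k]))
        if not drop:
            break
        removed.extend(drop)
        markers = markers[~markers["snp"].astype(str).isin(drop)]

    frames = []
    for chrom, sub in markers.groupby("chrom", sort=False):
        frame = sub[["snp", "chrom", "bp"]].reset_index(drop=True)
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    for stratum in STRATA:
        rfs = estimate_interval_rf(gametes, markers, stratum)
        cms, flags = [], []
        pos = 0
        for chrom, sub in markers.groupby("chrom", sort=False):
            m = len(sub)
            cm, bridged = _cm_positions(rfs[pos: pos + m - 1])
            pos += m - 1
            cms.append(cm)
            flags.append(bridged)
        table[f"cm_{stratum}"] = np.concatenate(cms)
        if stratum == "averaged":
            table["zero_bridged"] = np.concatenate(flags)
    return LinkageMap(table=table, removed_markers=removed)
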