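"""Grandparental-origin phasing, crossover calling and double-crossover QC.

A crossover in the gamete transmitted from a focal individual (FID) to its
offspring is visible as a switch in the grandparental origin (FID-paternal vs
FID-maternal) of the transmitted allele along a chromosome.  Phasing here is
deterministic and single-locus: at each marker the transmitted allele is
resolved from the offspring/mate genotypes and its grandparent of origin from
the FID's parental genotypes; markers where either step is ambiguous are
uninformative.  Apparent double crossovers over very short intervals are
treated as phasing error and removed by two filters applied in fixed order:

1. internal runs of a single informative SNP are recoded as missing;
2. remaining internal runs whose log10 base-pair span lies more than
   ``span_sd`` (default 2.5) standard deviations below the pooled mean
   log10 span are recoded as missing.

Terminal runs (touching a chromosome end) are never span-filtered: only a
segment flanked by the opposite origin on both sides is a double crossover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedigree import MISSING, GenotypePanel, SubPedigree

# Allele codes for the transmitted allele
ALLELE_A = 0
ALLELE_B = 1
UNDETERMINED = -9

# Grandparental origin codes
PATERNAL = 0
MATERNAL = 1
UNKNOWN = -9


# ---------------------------------------------------------------------------
# Single-locus phasing rules
# ---------------------------------------------------------------------------

def transmitted_allele(fid_call: int, offspring_call: int, mate_call: int) -> int:
    """Which allele (A=0, B=1) did the FID transmit to the offspring?

    A homozygous offspring received that allele; a heterozygous offspring
    with a homozygous mate received the allele the mate could not have given.
    The result must be carried by the FID, otherwise the configuration is a
    Mendelian conflict and the call is ``UNDETERMINED``.
    """
    t = UNDETERMINED
    if offspring_call == 0:
        t = ALLELE_A
    elif offspring_call == 2:
        t = ALLELE_B
    elif offspring_call == 1:
        if mate_call == 0:
            t = ALLELE_B
        elif mate_call == 2:
            t = ALLELE_A
    if t == UNDETERMINED:
        return t
    if fid_call == MISSING:
        return UNDETERMINED
    if (fid_call == 0 and t == ALLELE_B) or (fid_call == 2 and t == ALLELE_A):
        return UNDETERMINED
    return t


def _carries(call: int, allele: int) -> bool:
    # a missing genotype may carry any allele
    if call == MISSING:
        return True
    if allele == ALLELE_A:
        return call in (0, 1)
    return call in (1, 2)


def grandparental_origin(
    fid_call: int, transmitted: int, father_call: int, mother_call: int
) -> int:
    """Grandparent of origin of the transmitted allele (FID's father/mother).

    Informative only when the FID is heterozygous.  Of the two assignments of
    {transmitted, other} to {father, mother}, exactly one must be consistent
    with the parental genotypes; otherwise the marker is uninformative.
    """
    if transmitted == UNDETERMINED:
        raise ValueError("transmitted allele must be determined first")
    if fid_call != 1:
        return UNKNOWN
    other = 1 - transmitted
    pat = _carries(father_call, transmitted) and _carries(mother_call, other)
    mat = _carries(father_call, other) and _carries(mother_call, transmitted)
    if pat and not mat:
        return PATERNAL
    if mat and not pat:
        return MATERNAL
    return UNKNOWN


def _phase_vectors(
    g_fid: np.ndarray, g_off: np.ndarray, g_mate: np.ndarray,
    g_father: np.ndarray, g_mother: np.ndarray,
) -> np.ndarray:
    """Vectorized origin assignment over all markers of one subpedigree."""
    t = np.full(g_fid.shape, UNDETERMINED, dtype=np.int8)
    t[g_off == 0] = ALLELE_A
    t[g_off == 2] = ALLELE_B
    het = g_off == 1
    t[het & (g_mate == 0)] = ALLELE_B
    t[het & (g_mate == 2)] = ALLELE_A
    bad = (g_fid == MISSING) | ((g_fid == 0) & (t == ALLELE_B)) | (
        (g_fid == 2) & (t == ALLELE_A)
    )
    t[bad] = UNDETERMINED

    origin = np.full(g_fid.shape, UNKNOWN, dtype=np.int8)
    ok = (g_fid == 1) & (t != UNDETERMINED)
    other = 1 - t

    def carries(g, allele):
        return (g == MISSING) | (g == 1) | (g == np.where(allele == ALLELE_A, 0, 2))

    pat = carries(g_father, t) & carries(g_mother, other)
    mat = carries(g_father, other) & carries(g_mother, t)
    origin[ok & pat & ~mat] = PATERNAL
    origin[ok & mat & ~pat] = MATERNAL
    return origin


# ---------------------------------------------------------------------------
# Phased gametes
# ---------------------------------------------------------------------------

@dataclass
class PhasedGamete:
    """Origin calls at informative markers for one gamete on one chromosome."""

    fid: str
    offspring: str
    fid_sex: str
    chrom: object
    marker_idx: np.ndarray  # global panel indices, strictly increasing
    bp: np.ndarray
    origin: np.ndarray  # PATERNAL/MATERNAL aligned with marker_idx

    def __post_init__(self):
        if len(self.bp) > 1 and not np.all(np.diff(self.bp) > 0):
            raise ValueError("informative markers must strictly increase in bp")
        if len(self.origin) != len(self.marker_idx):
            raise ValueError("origin vector length mismatch")

    @property
    def gamete_id(self) -> str:
        return f"{self.fid}->{self.offspring}"

    def n_crossovers(self) -> int:
        return call_crossovers(self.origin)


def call_crossovers(origin: np.ndarray) -> int:
    """Number of switches in grandparental origin along a chromosome."""
    origin = np.asarray(origin)
    if origin.size == 0:
        raise ValueError("empty origin vector")
    return int(np.count_nonzero(np.diff(origin)))


def phase_gametes(
    subpedigrees: list[SubPedigree], panel: GenotypePanel
) -> list[PhasedGamete]:
    """Assign grandparental origins for every subpedigree and chromosome."""
    gametes: list[PhasedGamete] = []
    bp_all = panel.markers["bp"].to_numpy(np.int64)
    slices = [(c, panel.chrom_slice(c)) for c in panel.chromosomes()]
    for sp in subpedigrees:
        origin = _phase_vectors(
            panel.row(sp.fid), panel.row(sp.offspring), panel.row(sp.mate),
            panel.row(sp.father), panel.row(sp.mother),
        )
        for chrom, sl in slices:
            oc = origin[sl]
            keep = np.flatnonzero(oc != UNKNOWN)
            if keep.size == 0:
                continue
            idx = keep + sl.start
            gametes.append(
                PhasedGamete(
                    fid=sp.fid, offspring=sp.offspring, fid_sex=sp.fid_sex,
                    chrom=chrom, marker_idx=idx, bp=bp_all[idx],
                    origin=oc[keep].astype(np.uint8),
                )
            )
    return gametes


# ---------------------------------------------------------------------------
# Double-crossover filters
# ---------------------------------------------------------------------------

def _runs(origin: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of constant origin as (start, stop) index pairs,
    stop exclusive."""
    if origin.size == 0:
        return []
    change = np.flatnonzero(np.diff(origin)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [origin.size]))
    return list(zip(starts.tolist(), stops.tolist()))


def filter_single_snp_runs(
    gametes: list[PhasedGamete],
) -> tuple[list[PhasedGamete], int]:
    """Delete markers forming internal single-SNP runs (apparent double
    crossovers either side of one SNP).  Applied once; terminal runs kept."""
    out: list[PhasedGamete] = []
    n_removed = 0
    for g in gametes:
        runs = _runs(g.origin)
        drop = np.zeros(len(g.origin), dtype=bool)
        for k, (a, b) in enumerate(runs):
            if 0 < k < len(runs) - 1 and b - a == 1:
                drop[a:b] = True
                n_removed += 1
        if drop.any():
            keep = ~drop
            if not keep.any():
                continue
            g = replace(
                g, marker_idx=g.marker_idx[keep], bp=g.bp[keep],
                origin=g.origin[keep],
            )
        out.append(g)
    return out, n_removed


@dataclass
class DoubleCrossoverFilterStats:
    """Pooled log10 span-distance statistics behind the short-span filter."""

    mean_log10_span: float = float("nan")
    sd_log10_span: float = float("nan")
    threshold_log10: float = float("nan")
    n_double_crossovers: int = 0
    n_single_snp_removed: int = 0
    n_short_span_removed: int = 0
    skipped: bool = False


def _internal_run_spans(g: PhasedGamete) -> list[tuple[int, int, int]]:
    """(start, stop, span_bp) for internal runs; span is the bp distance
    between the informative SNPs immediately flanking the run."""
    runs = _runs(g.origin)
    out = []
    for k, (a, b) in enumerate(runs):
        if 0 < k < len(runs) - 1:
            out.append((a, b, int(g.bp[b] - g.bp[a - 1])))
    return out


def filter_short_double_crossovers(
    gametes: list[PhasedGamete], span_sd: float = 2.5
) -> tuple[list[PhasedGamete], DoubleCrossoverFilterStats]:
    """Remove double-crossover segments with anomalously short spans.

    Span distances of all internal runs are pooled across gametes, sexes and
    chromosomes; runs with log10(span) below ``mean - span_sd * sd`` have all
    their markers recoded as missing.  With fewer than two double crossovers
    in the data set the filter is skipped with a warning.
    """
    spans = []
    for g in gametes:
        spans.extend(s for _, _, s in _internal_run_spans(g))
    stats = DoubleCrossoverFilterStats(n_double_crossovers=len(spans))
    if len(spans) < 2:
        warnings.warn("fewer than 2 double crossovers; span filter skipped")
        stats.skipped = True
        return list(gametes), stats
    log_spans = np.log10(np.asarray(spans, dtype=float))
    stats.mean_log10_span = float(log_spans.mean())
    stats.sd_log10_span = float(log_spans.std(ddof=1))
    stats.threshold_log10 = stats.mean_log10_span - span_sd * stats.sd_log10_span

    out: list[PhasedGamete] = []
    n_removed = 0
    for g in gametes:
        drop = np.zeros(len(g.origin), dtype=bool)
        for a, b, span in _internal_run_spans(g):
            if np.log10(span) < stats.threshold_log10:
                drop[a:b] = True
                n_removed += 1
        if drop.any():
            keep = ~drop
            if not keep.any():
                continue
            g = replace(
                g, marker_idx=g.marker_idx[keep], bp=g.bp[keep],
                origin=g.origin[keep],
            )
        out.append(g)
    stats.n_short_span_removed = n_removed
    return out, stats


# ---------------------------------------------------------------------------
# ACC phenotype table
# ---------------------------------------------------------------------------

@dataclass
class CrossoverTable:
    """Per-gamete crossover phenotypes.

    ``summary`` has one row per gamete (fid, offspring, fid_sex, acc,
    n_informative, informative_length_bp); ``per_chromosome`` one row per
    gamete x chromosome with the chromosome's crossover count.
    """

    summary: pd.DataFrame
    per_chromosome: pd.DataFrame
    filter_stats: DoubleCrossoverFilterStats = field(
        default_factory=DoubleCrossoverFilterStats
    )

    def acc_of(self, fid: str, offspring: str) -> int:
        row = self.summary[
            (self.summary["fid"] == fid) & (self.summary["offspring"] == offspring)
        ]
        return int(row["acc"].iloc[0])

    def to_tsv(self, path) -> None:
        self.summary.to_csv(path, sep="\t", index=False)


def summarize_acc(
    gametes: list[PhasedGamete],
    filter_stats: DoubleCrossoverFilterStats | None = None,
) -> CrossoverTable:
    """Aggregate phased gametes into the ACC phenotype table."""
    per_chrom = []
    for g in gametes:
        per_chrom.append(
            dict(
                fid=g.fid, offspring=g.offspring, fid_sex=g.fid_sex,
                chrom=g.chrom, crossovers=g.n_crossovers(),
                n_informative=len(g.origin),
                informative_length_bp=int(g.bp[-1] - g.bp[0]),
            )
        )
    pc = pd.DataFrame(per_chrom)
    if pc.empty:
        return CrossoverTable(
            summary=pd.DataFrame(
                columns=["fid", "offspring", "fid_sex", "acc",
                         "n_informative", "informative_length_bp"]
            ),
            per_chromosome=pc,
            filter_stats=filter_stats or DoubleCrossoverFilterStats(),
        )
    summary = (
        pc.groupby(["fid", "offspring", "fid_sex"], as_index=False)
        .agg(
            acc=("crossovers", "sum"),
            n_informative=("n_informative", "sum"),
            informative_length_bp=("informative_length_bp", "sum"),
        )
    )
    return CrossoverTable(
        summary=summary, per_chromosome=pc,
        filter_stats=filter_stats or DoubleCrossoverFilterStats(),
    )


def detect_crossovers(
    subpedigrees: list[SubPedigree],
    panel: GenotypePanel,
    span_sd: float = 2.5,
    apply_filters: bool = True,
) -> tuple[list[PhasedGamete], CrossoverTable]:
    """Phase all gametes, apply both QC filters, and tabulate ACC."""
    gametes = phase_gametes(subpedigrees, panel)
    stats = DoubleCrossoverFilterStats()
    if apply_filters:
        gametes, n_single = filter_single_snp_runs(gametes)
        gametes, stats = filter_short_double_crossovers(gametes, span_sd=span_sd)
        stats.n_single_snp_removed = n_single
    return gametes, summarize_acc(gametes, stats)
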