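"""Core haplotypes and haplotype sharing between populations.

A *core haplotype* is a short (default six-SNP) allele sequence adjacent to a
focal SNP that perfectly tags one of the focal alleles: every phased
haplotype carrying the core carries the same focal allele.  Haplotype
sharing between a focal population and a reference population is the
base-pair distance from the core to the first downstream mismatch, computed
over all pairs of core-carrying haplotypes; pairs identical out to the last
compared SNP are censored at that distance and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class HaplotypeSet:
    """Phased haplotypes (rows) over ordered SNPs (columns) for one
    population."""

    label: str
    haplotypes: np.ndarray  # (n_hap, n_snp) of 0/1
    bp: np.ndarray
    snp_names: list[str] | None = None

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if self.haplotypes.shape[1] != len(self.bp):
            raise ValueError("bp vector does not match marker count")
        if len(self.bp) > 1 and not np.all(np.diff(self.bp) > 0):
            raise ValueError("bp must strictly increase")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotypes must be biallelic 0/1")

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @classmethod
    def from_tsv(cls, path, label: str = "") -> "HaplotypeSet":
        """Transposed TSV: rows = SNPs with columns snp, bp, then one column
        per haplotype."""
        df = pd.read_csv(path, sep="\t")
        bp = df["bp"].to_numpy()
        hcols = [c for c in df.columns if c not in ("snp", "bp")]
        return cls(
            label=label or "haplotypes",
            haplotypes=df[hcols].to_numpy().T,
            bp=bp, snp_names=df["snp"].astype(str).tolist(),
        )

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            dict(snp=self.snp_names or [f"snp{i}" for i in range(len(self.bp))],
                 bp=self.bp)
        )
        for h in range(self.n_haplotypes):
            df[f"hap{h}"] = self.haplotypes[h]
        df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class CoreHaplotype:
    """A perfectly tagging allele sequence adjacent to the focal SNP."""

    alleles: tuple
    start_index: int  # first SNP index of the core window
    tagged_allele: int
    n_carriers: int
    purity: float = 1.0

    @property
    def length(self) -> int:
        return len(self.alleles)

    @property
    def stop_index(self) -> int:
        return self.start_index + len(self.alleles)


def find_core_haplotypes(
    focal: HaplotypeSet,
    focal_snp_index: int,
    core_length: int = 6,
    side: str = "proximal",
) -> list[CoreHaplotype]:
    """Distinct core haplotypes perfectly associated with one focal allele.

    The core window holds the ``core_length`` SNPs immediately flanking the
    focal SNP on its ``side`` ("proximal" = lower bp, "distal" = higher bp).
    Cores carried with both focal alleles (tagging purity < 1) are excluded;
    an empty list means no perfectly tagging haplotype exists.
    """
    n_snp = focal.haplotypes.shape[1]
    if not 0 <= focal_snp_index < n_snp:
        raise IndexError("focal SNP outside the region")
    if side == "proximal":
        start = focal_snp_index - core_length
    elif side == "distal":
        start = focal_snp_index + 1
    else:
        raise ValueError("side must be 'proximal' or 'distal'")
    if start < 0 or start + core_length > n_snp:
        raise ValueError("core window falls outside the region")

    window = focal.haplotypes[:, start: start + core_length]
    focal_alleles = focal.haplotypes[:, focal_snp_index]
    out: list[CoreHaplotype] = []
    seen = {}
    for h in range(len(window)):
        key = tuple(int(a) for a in window[h])
        seen.setdefault(key, []).append(int(focal_alleles[h]))
    for key in sorted(seen):
        tags = seen[key]
        if len(set(tags)) == 1:
            out.append(
                CoreHaplotype(
                    alleles=key, start_index=start,
                    tagged_allele=tags[0], n_carriers=len(tags),
                )
            )
    return out


@dataclass
class SharingResult:
    """Pairwise haplotype-sharing distances for one core and one reference
    population."""

    core: CoreHaplotype
    reference_label: str
    distances_bp: np.ndarray  # uncensored pairwise distances
    censored_bp: np.ndarray  # distances of pairs identical to the region end
    n_pairs: int

    @property
    def mean_bp(self) -> float:
        return float(self.distances_bp.mean()) if len(self.distances_bp) else float("nan")

    @property
    def sd_bp(self) -> float:
        return (
            float(self.distances_bp.std(ddof=1))
            if len(self.distances_bp) > 1 else float("nan")
        )

    @property
    def censoring_fraction(self) -> float:
        return len(self.censored_bp) / self.n_pairs if self.n_pairs else float("nan")


def _carriers(hs: HaplotypeSet, core: CoreHaplotype) -> np.ndarray:
    window = hs.haplotypes[:, core.start_index: core.stop_index]
    return np.flatnonzero((window == np.asarray(core.alleles)).all(axis=1))


def haplotype_sharing_length(
    core: CoreHaplotype,
    focal: HaplotypeSet,
    reference: HaplotypeSet,
    direction: str = "downstream",
) -> SharingResult:
    """Sharing distance from a core to the first mismatch, over all pairs.

    For every (focal carrier, reference carrier) pair, SNPs are walked away
    from the core (``downstream`` = increasing bp past the core's last SNP;
    ``upstream`` = decreasing bp before its first SNP); the distance is from
    the core's edge SNP to the first mismatching SNP.  Pairs that match to
    the end of the region contribute the distance to the last compared SNP
    and are reported as censored.  n_pairs = 0 (reference lacks the core) is
    distinct from zero sharing.
    """
    if not np.array_equal(focal.bp, reference.bp):
        raise ValueError("focal and reference sets must share the marker grid")
    fc = _carriers(focal, core)
    rc = _carriers(reference, core)
    if len(fc) == 0:
        raise ValueError("focal set lacks the core haplotype")
    if len(rc) == 0:
        return SharingResult(core, reference.label,
                             np.array([]), np.array([]), 0)

    if direction == "downstream":
        cols = np.arange(core.stop_index, len(focal.bp))
        edge_bp = focal.bp[core.stop_index - 1]
    elif direction == "upstream":
        cols = np.arange(core.start_index - 1, -1, -1)
        edge_bp = focal.bp[core.start_index]
    else:
        raise ValueError("direction must be 'downstream' or 'upstream'")

    F = focal.haplotypes[np.ix_(fc, cols)]
    R = reference.haplotypes[np.ix_(rc, cols)]
    dist, cens = [], []
    for a in F:
        for b in R:
            mism = np.flatnonzero(a != b)
            if len(mism):
                d = abs(int(focal.bp[cols[mism[0]]]) - int(edge_bp))
                dist.append(d)
            else:
                cens.append(abs(int(focal.bp[cols[-1]]) - int(edge_bp)))
    return SharingResult(
        core=core, reference_label=reference.label,
        distances_bp=np.array(dist, dtype=np.int64),
        censored_bp=np.array(cens, dtype=np.int64),
        n_pairs=len(fc) * len(rc),
    )


def sharing_table(
    cores: list[CoreHaplotype],
    focal: HaplotypeSet,
    references: list[HaplotypeSet],
    direction: str = "downstream",
) -> pd.DataFrame:
    """Mean/SD sharing per (core, reference population)."""
    rows = []
    for core in cores:
        for ref in references:
            res = haplotype_sharing_length(core, focal, ref, direction)
            rows.append(
                dict(core="".join(map(str, core.alleles)),
                     tagged_allele=core.tagged_allele,
                     reference=ref.label, n_pairs=res.n_pairs,
                     mean_bp=res.mean_bp, sd_bp=res.sd_bp,
                     censoring_fraction=res.censoring_fraction)
            )
    return pd.DataFrame(rows)
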