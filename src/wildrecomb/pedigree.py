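"""Pedigrees, genotype panels, subpedigree construction and Mendelian QC.

The unit of analysis throughout the package is a *subpedigree*: a five-member
family (focal individual FID, its father and mother, one offspring, and the
offspring's other parent) in which the gamete transmitted from the FID to the
offspring can be phased against the FID's parental genotypes.  This module
builds those units from a population pedigree and applies parent-offspring
Mendelian-consistency quality control before any phasing is attempted.

Genotypes are stored as counts of the B allele (0, 1, 2) with ``-1`` for
missing, in an individuals x markers ``int8`` matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

SEX_MALE = "M"
SEX_FEMALE = "F"
SEX_UNKNOWN = "U"


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

class Pedigree:
    """A population pedigree: one record per individual (id, sire, dam, sex).

    Parameters
    ----------
    records : pandas.DataFrame
        Columns ``id``, ``sire``, ``dam``, ``sex``.  Unknown parents are
        ``None``/NaN; sex is one of ``"M"``, ``"F"``, ``"U"``.

    Raises
    ------
    PedigreeError
        If an individual is its own ancestor, or a sire/dam has a known sex
        inconsistent with its role.
    """

    def __init__(self, records: pd.DataFrame):
        df = records.copy()
        for col in ("id", "sire", "dam", "sex"):
            if col not in df.columns:
                raise PedigreeError(f"pedigree table lacks column {col!r}")
        df["id"] = df["id"].astype(str)
        for col in ("sire", "dam"):
            df[col] = df[col].map(
                lambda v: None if pd.isna(v) or str(v) in ("0", "") else str(v)
            )
        df["sex"] = df["sex"].fillna(SEX_UNKNOWN).astype(str)
        if df["id"].duplicated().any():
            raise PedigreeError("duplicate individual ids in pedigree")
        self.table = df.reset_index(drop=True)
        self._parents = {
            r.id: (r.sire, r.dam) for r in self.table.itertuples()
        }
        self._sex = dict(zip(self.table["id"], self.table["sex"]))
        self._validate()

    def _validate(self) -> None:
        order = self.topological_order()  # raises on cycles
        del order
        for r in self.table.itertuples():
            if r.sire is not None and self._sex.get(r.sire, SEX_UNKNOWN) == SEX_FEMALE:
                raise PedigreeError(f"sire {r.sire} of {r.id} is recorded female")
            if r.dam is not None and self._sex.get(r.dam, SEX_UNKNOWN) == SEX_MALE:
                raise PedigreeError(f"dam {r.dam} of {r.id} is recorded male")

    # -- basic queries ------------------------------------------------------

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    def sex(self, iid: str) -> str:
        return self._sex.get(iid, SEX_UNKNOWN)

    def parents(self, iid: str) -> tuple[str | None, str | None]:
        return self._parents.get(iid, (None, None))

    def founders(self) -> list[str]:
        return [i for i in self.ids if self._parents[i] == (None, None)]

    def parent_offspring_links(self) -> list[tuple[str, str]]:
        """All (parent, offspring) links with the parent recorded."""
        out = []
        for r in self.table.itertuples():
            if r.sire is not None:
                out.append((r.sire, r.id))
            if r.dam is not None:
                out.append((r.dam, r.id))
        return out

    def topological_order(self) -> list[str]:
        """Ids ordered parents-before-offspring (cycle => PedigreeError)."""
        state: dict[str, int] = {}
        order: list[str] = []

        def visit(i: str) -> None:
            st = state.get(i, 0)
            if st == 1:
                raise PedigreeError(f"individual {i} is its own ancestor")
            if st == 2:
                return
            state[i] = 1
            for p in self._parents.get(i, (None, None)):
                if p is not None and p in self._parents:
                    visit(p)
            state[i] = 2
            order.append(i)

        for i in self.ids:
            visit(i)
        return order

    # -- numerator relationship matrix --------------------------------------

    def nrm(self) -> pd.DataFrame:
        """Additive (numerator) relationship matrix by the tabular method."""
        order = self.topological_order()
        idx = {i: k for k, i in enumerate(order)}
        n = len(order)
        A = np.zeros((n, n))
        for i in order:
            k = idx[i]
            s, d = self._parents[i]
            ks = idx.get(s) if s is not None else None
            kd = idx.get(d) if d is not None else None
            f = 0.0 if ks is None or kd is None else 0.5 * A[ks, kd]
            A[k, k] = 1.0 + f
            # off-diagonals with all previously placed individuals
            prev = np.arange(k)
            a = np.zeros(k)
            if ks is not None:
                a += 0.5 * A[ks, prev]
            if kd is not None:
                a += 0.5 * A[kd, prev]
            A[k, prev] = a
            A[prev, k] = a
        out = pd.DataFrame(A, index=order, columns=order)
        return out.loc[self.ids, self.ids]

    # -- IO ------------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path) -> "Pedigree":
        df = pd.read_csv(path, sep="\t", dtype=str)
        df.columns = [c.lower() for c in df.columns]
        return cls(df)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        for col in ("sire", "dam"):
            out[col] = out[col].fillna("0")
        out.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.table)

    def __repr__(self) -> str:
        return f"Pedigree(n={len(self)}, founders={len(self.founders())})"


# ---------------------------------------------------------------------------
# GenotypePanel
# ---------------------------------------------------------------------------

class GenotypePanel:
    """SNP marker map plus an individuals x markers genotype matrix.

    ``markers`` has columns ``snp``, ``chrom``, ``bp``, ``allele_a``,
    ``allele_b`` and is sorted by (chrom, bp); genotypes count copies of the
    B allele with ``-1`` for missing calls.
    """

    def __init__(self, markers: pd.DataFrame, ids: list[str], genotypes: np.ndarray):
        markers = markers.reset_index(drop=True)
        for col in ("snp", "chrom", "bp"):
            if col not in markers.columns:
                raise ValueError(f"marker table lacks column {col!r}")
        if "allele_a" not in markers.columns:
            markers = markers.assign(allele_a="A", allele_b="B")
        if (markers["allele_a"] == markers["allele_b"]).any():
            raise ValueError("marker with identical A and B alleles")
        g = np.asarray(genotypes, dtype=np.int8)
        if g.shape != (len(ids), len(markers)):
            raise ValueError(
                f"genotype matrix shape {g.shape} does not match "
                f"{len(ids)} individuals x {len(markers)} markers"
            )
        for chrom, sub in markers.groupby("chrom", sort=False):
            if not np.all(np.diff(sub["bp"].to_numpy()) >= 0):
                raise ValueError(f"bp positions decrease within chromosome {chrom}")
        self.markers = markers
        self.ids = [str(i) for i in ids]
        self.genotypes = g
        self._row = {i: k for k, i in enumerate(self.ids)}

    # -- queries -------------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def row(self, iid: str) -> np.ndarray:
        return self.genotypes[self._row[str(iid)]]

    def has(self, iid: str) -> bool:
        return str(iid) in self._row

    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.markers["chrom"]))

    def chrom_slice(self, chrom) -> slice:
        mask = (self.markers["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(mask)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def allele_freqs(self) -> np.ndarray:
        """Observed frequency of the B allele per marker (missing excluded)."""
        g = self.genotypes.astype(float)
        g[g == MISSING] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(g, axis=0) / 2.0

    def subset_markers(self, keep: np.ndarray) -> "GenotypePanel":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypePanel(
            self.markers.iloc[keep], self.ids, self.genotypes[:, keep]
        )

    def copy(self) -> "GenotypePanel":
        return GenotypePanel(self.markers.copy(), list(self.ids), self.genotypes.copy())

    # -- IO ------------------------------------------------------------------

    def to_tsv(self, genotype_path, marker_path) -> None:
        self.markers.to_csv(marker_path, sep="\t", index=False)
        df = pd.DataFrame(self.genotypes, columns=self.markers["snp"])
        df.insert(0, "id", self.ids)
        df.to_csv(genotype_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, genotype_path, marker_path) -> "GenotypePanel":
        markers = pd.read_csv(marker_path, sep="\t")
        df = pd.read_csv(genotype_path, sep="\t")
        ids = df["id"].astype(str).tolist()
        g = df.drop(columns="id").to_numpy(dtype=np.int8)
        return cls(markers, ids, g)

    def to_plink(self, prefix: str, pedigree: Pedigree | None = None) -> None:
        """Write PLINK text PED/MAP files (``prefix.ped``, ``prefix.map``)."""
        with open(f"{prefix}.map", "w") as fh:
            for m in self.markers.itertuples():
                fh.write(f"{m.chrom}\t{m.snp}\t0\t{m.bp}\n")
        a = self.markers["allele_a"].to_numpy()
        b = self.markers["allele_b"].to_numpy()
        with open(f"{prefix}.ped", "w") as fh:
            for i, iid in enumerate(self.ids):
                sire = dam = "0"
                sexcode = "0"
                if pedigree is not None and iid in pedigree._parents:
                    s, d = pedigree.parents(iid)
                    sire, dam = s or "0", d or "0"
                    sexcode = {"M": "1", "F": "2"}.get(pedigree.sex(iid), "0")
                g = self.genotypes[i]
                al1 = np.where(g == 0, a, np.where(g == 1, a, np.where(g == 2, b, "0")))
                al2 = np.where(g == 0, a, np.where(g == 1, b, np.where(g == 2, b, "0")))
                row = " ".join(x + " " + y for x, y in zip(al1, al2))
                fh.write(f"FAM {iid} {sire} {dam} {sexcode} -9 {row}\n")

    @classmethod
    def from_plink(cls, prefix: str) -> "GenotypePanel":
        markers = pd.read_csv(
            f"{prefix}.map",
            sep=r"\s+",
            names=["chrom", "snp", "cm", "bp"],
        ).drop(columns="cm")
        ids, rows = [], []
        with open(f"{prefix}.ped") as fh:
            for line in fh:
                parts = line.split()
                ids.append(parts[1])
                alleles = parts[6:]
                rows.append((alleles[0::2], alleles[1::2]))
        m = len(markers)
        # infer A allele as the first non-missing allele seen per marker
        allele_a = np.array(["?"] * m, dtype=object)
        allele_b = np.array(["?"] * m, dtype=object)
        geno = np.full((len(ids), m), MISSING, dtype=np.int8)
        for i, (a1, a2) in enumerate(rows):
            for j in range(m):
                x, y = a1[j], a2[j]
                if x == "0" or y == "0":
                    continue
                for al in (x, y):
                    if allele_a[j] == "?":
                        allele_a[j] = al
                    elif al != allele_a[j] and allele_b[j] == "?":
                        allele_b[j] = al
                geno[i, j] = (x != allele_a[j]) + (y != allele_a[j])
        allele_b[allele_b == "?"] = "B"
        markers = markers.assign(allele_a=allele_a, allele_b=allele_b)
        markers["snp"] = markers["snp"].astype(str)
        return cls(markers[["snp", "chrom", "bp", "allele_a", "allele_b"]], ids, geno)


# ---------------------------------------------------------------------------
# Subpedigrees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubPedigree:
    """Five-member phasing unit around one FID-offspring gamete."""

    fid: str
    offspring: str
    father: str
    mother: str
    mate: str
    fid_sex: str

    @property
    def members(self) -> tuple[str, str, str, str, str]:
        return (self.fid, self.offspring, self.father, self.mother, self.mate)

    @property
    def gamete_id(self) -> str:
        return f"{self.fid}->{self.offspring}"


def build_subpedigrees(
    pedigree: Pedigree, genotyped_ids
) -> tuple[list[SubPedigree], int]:
    """Construct all valid 5-member subpedigrees.

    For every parent-offspring pair in the pedigree, the parent becomes a
    candidate FID; the unit is kept when the FID's own parents, the offspring
    and the offspring's other parent are all genotyped.  Units that would
    contain the same individual twice (e.g. father-daughter matings) are
    discarded.

    Returns
    -------
    (subpedigrees, n_discarded_duplicate)
    """
    genotyped = {str(i) for i in genotyped_ids}
    out: list[SubPedigree] = []
    n_dup = 0
    for off in pedigree.ids:
        sire, dam = pedigree.parents(off)
        if sire is None or dam is None:
            continue
        for fid, mate in ((sire, dam), (dam, sire)):
            gf, gm = pedigree.parents(fid)
            if gf is None or gm is None:
                continue
            members = (fid, off, gf, gm, mate)
            if any(m not in genotyped for m in members):
                continue
            if len(set(members)) < 5:
                n_dup += 1
                continue
            out.append(
                SubPedigree(
                    fid=fid, offspring=off, father=gf, mother=gm,
                    mate=mate, fid_sex=pedigree.sex(fid),
                )
            )
    return out, n_dup


# ---------------------------------------------------------------------------
# Mendelian QC
# ---------------------------------------------------------------------------

@dataclass
class MendelianQCReport:
    pair_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_masked_calls: int = 0
    n_subpedigrees_dropped: int = 0


def mendelian_qc(
    subpedigrees: list[SubPedigree],
    panel: GenotypePanel,
    mismatch_threshold: float = 0.001,
) -> tuple[GenotypePanel, list[SubPedigree], MendelianQCReport]:
    """Mask opposite-homozygote parent-offspring calls; drop bad subpedigrees.

    For every parent-offspring pair appearing in any subpedigree and every
    marker at which the pair shares no allele (one call 0, the other 2), the
    genotype is set missing in both individuals.  Subpedigrees containing a
    parent-offspring pair whose pre-masking mismatch rate (over markers where
    both calls are non-missing) exceeds ``mismatch_threshold`` are discarded.
    """
    if not all(panel.has(m) for sp in subpedigrees for m in sp.members):
        missing = {
            m for sp in subpedigrees for m in sp.members if not panel.has(m)
        }
        raise KeyError(f"individuals absent from genotype panel: {sorted(missing)}")

    pairs: set[tuple[str, str]] = set()
    for sp in subpedigrees:
        pairs.update(
            ((sp.father, sp.fid), (sp.mother, sp.fid),
             (sp.fid, sp.offspring), (sp.mate, sp.offspring))
        )

    clean = panel.copy()
    g = clean.genotypes
    rows = clean._row
    records = []
    bad_pairs: set[tuple[str, str]] = set()
    masks: list[tuple[int, int, np.ndarray]] = []
    for par, off in sorted(pairs):
        rp, ro = rows[par], rows[off]
        gp, go = g[rp], g[ro]
        both = (gp != MISSING) & (go != MISSING)
        mism = both & (np.abs(gp.astype(np.int16) - go.astype(np.int16)) == 2)
        n_comp = int(both.sum())
        n_mism = int(mism.sum())
        rate = n_mism / n_comp if n_comp else 0.0
        records.append(
            dict(parent=par, offspring=off, n_compared=n_comp,
                 n_mismatch=n_mism, rate=rate, dropped=rate > mismatch_threshold)
        )
        if rate > mismatch_threshold:
            bad_pairs.add((par, off))
        masks.append((rp, ro, mism))

    n_masked = 0
    for rp, ro, mism in masks:
        n_masked += int(mism.sum()) * 2
        g[rp, mism] = MISSING
        g[ro, mism] = MISSING

    retained, dropped = [], 0
    for sp in subpedigrees:
        sp_pairs = (
            (sp.father, sp.fid), (sp.mother, sp.fid),
            (sp.fid, sp.offspring), (sp.mate, sp.offspring),
        )
        if any(p in bad_pairs for p in sp_pairs):
            dropped += 1
        else:
            retained.append(sp)

    report = MendelianQCReport(
        pair_table=pd.DataFrame(records),
        n_masked_calls=n_masked,
        n_subpedigrees_dropped=dropped,
    )
    return clean, retained, report
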