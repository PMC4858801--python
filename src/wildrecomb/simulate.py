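"""Gene-dropping meiosis simulator with a configurable ACC architecture.

Founder haplotypes are drawn from population allele frequencies and dropped
through a multi-generation pedigree with explicitly simulated crossovers, so
that every downstream stage — subpedigree phasing, crossover detection,
linkage maps, variance components, association — can be exercised against a
known truth.  Defaults emulate the study system: 26 autosomes at 50K-chip
marker density, sex-specific genetic maps (male total 3748 cM, female
2860 cM, ratio 1.31) with male subtelomeric elevation, obligate crossing
over, and a polygenic ACC architecture with the additive and residual
variances of the published variance decomposition.

Two phenotype pathways are provided.  The mechanistic pathway realises ACC
as actual crossover counts during gene-dropping (its phenotypic variance
therefore includes counting noise on top of the latent architecture).  The
quantitative-genetic pathway (:func:`simulate_acc_phenotype`) draws a
Gaussian ACC phenotype on the same pedigree with an exact
V_A / V_PE / V_R decomposition, for calibrated variance-component and
mapping experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .detect import detect_crossovers
from .pedigree import (
    MISSING, GenotypePanel, Pedigree, build_subpedigrees, mendelian_qc,
)

# Approximate physical lengths (Mb) of 26 sheep-like autosomes
DEFAULT_CHROMOSOME_MB = (
    275, 250, 224, 120, 108, 117, 100, 91, 95, 86, 62, 79, 83,
    63, 81, 71, 72, 68, 60, 51, 50, 51, 62, 42, 45, 44,
)


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the pedigree, genome, maps and ACC architecture.

    Map lengths are per-genome totals in Kosambi-scale cM distributed over
    chromosomes proportionally to physical length; ``acc_mean_male`` /
    ``acc_mean_female`` default to total map length / 100 (the expected
    crossover count) and rescale the maps when set explicitly.
    ``interference_nu`` is the gamma-renewal shape on the cM scale (1 = no
    interference).  ``qtl_marker`` indexes a marker whose B allele adds
    ``qtl_effect`` crossovers per copy to the carrier's gametes (restricted
    to ``qtl_sex_limited`` when given, e.g. ``"F"`` for a female-limited
    locus).
    """

    n_founders: int = 64
    n_generations: int = 3
    offspring_per_pair: int = 3
    chromosome_lengths_bp: tuple = tuple(
        int(mb * 1e6) for mb in DEFAULT_CHROMOSOME_MB
    )
    snp_density_per_mb: float = 16.0
    founder_allele_freq_range: tuple = (0.05, 0.5)
    map_male_cm: float = 3748.0
    map_female_cm: float = 2860.0
    male_subtelomeric_factor: float = 2.5
    subtelomere_mb: float = 18.0
    interference_nu: float = 1.0
    obligate: bool = True
    acc_mean_male: float | None = None
    acc_mean_female: float | None = None
    v_a_acc: float = 4.28
    v_r_acc: float = 25.28
    qtl_marker: int | None = None
    qtl_effect: float = 0.0
    qtl_sex_limited: str | None = None
    genotyping_missing_rate: float = 0.005
    genotyping_error_rate: float = 0.001
    seed: int = 2016

    def __post_init__(self):
        if self.n_founders < 2 or self.n_generations < 1:
            raise ConfigurationError("need >=2 founders and >=1 generation")
        if any(l <= 0 for l in self.chromosome_lengths_bp):
            raise ConfigurationError("chromosome lengths must be positive")
        if self.map_male_cm <= 0 or self.map_female_cm <= 0:
            raise ConfigurationError("map lengths must be positive")
        for rate in (self.genotyping_missing_rate, self.genotyping_error_rate):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError("rates must lie in [0, 1]")
        if self.v_a_acc < 0 or self.v_r_acc < 0:
            raise ConfigurationError("variance components must be >= 0")
        if self.interference_nu <= 0:
            raise ConfigurationError("interference shape must be positive")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosome_lengths_bp)

    def chromosome_cm(self, sex: str) -> np.ndarray:
        """Per-chromosome map lengths (cM) for one parental sex."""
        bp = np.asarray(self.chromosome_lengths_bp, float)
        total = self.map_male_cm if sex == "M" else self.map_female_cm
        mean = self.acc_mean_male if sex == "M" else self.acc_mean_female
        if mean is not None:
            total = 100.0 * mean
        return total * bp / bp.sum()

    def mean_acc(self, sex: str) -> float:
        cm = self.chromosome_cm(sex)
        if self.obligate:
            return float(np.sum(1.0 + np.maximum(0.0, cm / 100.0 - 1.0)))
        return float(cm.sum() / 100.0)


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Discrete-generation pedigree with repeated offspring per pair.

    Founders form generation 0; each later generation pairs the previous
    generation's males and females (monogamous, random pairing) and each
    pair produces ``offspring_per_pair`` offspring of alternating sex, so
    every parent has repeated gametes and sexes stay balanced.
    """
    rng = rng or np.random.default_rng(config.seed)
    rows = []
    gen = []
    for i in range(config.n_founders):
        iid = f"G0_{i:04d}"
        sex = "M" if i % 2 == 0 else "F"
        rows.append(dict(id=iid, sire=None, dam=None, sex=sex))
        gen.append((iid, sex))
    counter = 0
    for g in range(1, config.n_generations):
        males = [i for i, s in gen if s == "M"]
        females = [i for i, s in gen if s == "F"]
        rng.shuffle(males)
        rng.shuffle(females)
        n_pairs = min(len(males), len(females))
        if n_pairs == 0:
            raise ConfigurationError("no mating pair possible")
        nxt = []
        for k in range(n_pairs):
            for o in range(config.offspring_per_pair):
                iid = f"G{g}_{counter:04d}"
                # alternate sexes globally so generations stay balanced
                sex = "M" if counter % 2 == 0 else "F"
                counter += 1
                rows.append(dict(id=iid, sire=males[k], dam=females[k], sex=sex))
                nxt.append((iid, sex))
        gen = nxt
    return Pedigree(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Genetic maps: cumulative cM <-> bp
# ---------------------------------------------------------------------------

def _map_knots(length_bp: int, total_cm: float, sex: str, config: SimConfig):
    """Piecewise-linear cumulative map with male subtelomeric elevation."""
    t = min(config.subtelomere_mb * 1e6, length_bp / 3.0)
    f = config.male_subtelomeric_factor if sex == "M" else 1.0
    mid = length_bp - 2.0 * t
    k = total_cm / (2.0 * f * t + mid)  # baseline cM per bp
    bp_knots = np.array([0.0, t, length_bp - t, float(length_bp)])
    cm_knots = np.array([0.0, f * k * t, f * k * t + k * mid, total_cm])
    return bp_knots, cm_knots


def cm_to_bp(pos_cm, length_bp, total_cm, sex, config) -> np.ndarray:
    bp_knots, cm_knots = _map_knots(length_bp, total_cm, sex, config)
    return np.interp(pos_cm, cm_knots, bp_knots)


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------

def draw_crossover_count(
    rng: np.random.Generator, cm_length: float, obligate: bool = True
) -> int:
    """Crossover count on one chromosome given its (scaled) map length.

    Poisson(cM/100), or with obligate crossing over
    1 + Poisson(max(0, cM/100 - 1)).
    """
    lam = cm_length / 100.0
    if obligate:
        return 1 + int(rng.poisson(max(0.0, lam - 1.0)))
    return int(rng.poisson(lam))


def crossover_positions_cm(
    rng: np.random.Generator, n: int, cm_length: float, nu: float
) -> np.ndarray:
    """Positions of n crossovers on [0, cM] from gamma(nu) spacings.

    nu = 1 gives uniform order statistics (no interference); larger nu makes
    spacings more regular (positive interference).
    """
    if n == 0:
        return np.empty(0)
    w = rng.gamma(nu, 1.0, size=n + 1)
    return cm_length * np.cumsum(w[:-1]) / w.sum()


# ---------------------------------------------------------------------------
# Gene drop
# ---------------------------------------------------------------------------

@dataclass
class TrueMeiosisRecord:
    """Ground truth for one transmitted gamete."""

    parent: str
    offspring: str
    parent_sex: str
    counts: np.ndarray  # per-chromosome crossover counts
    positions_bp: list  # per-chromosome arrays, strictly increasing

    @property
    def acc(self) -> int:
        return int(self.counts.sum())


@dataclass
class GeneDropResult:
    panel: GenotypePanel
    truth: list[TrueMeiosisRecord]
    pedigree: Pedigree
    breeding_values: pd.DataFrame  # id, g (latent polygenic value)
    founder_freqs: np.ndarray
    founder_origins: dict | None = None
    haplotypes: dict | None = None  # kept only when origins are tracked

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dict(fid=t.parent, offspring=t.offspring, parent_sex=t.parent_sex,
                  true_acc=t.acc) for t in self.truth]
        )

    def truth_per_chromosome(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            for c, cnt in enumerate(t.counts):
                rows.append(dict(fid=t.parent, offspring=t.offspring,
                                 chrom=c + 1, true_count=int(cnt)))
        return pd.DataFrame(rows)


def _simulate_markers(config: SimConfig, rng: np.random.Generator):
    markers = []
    freqs = []
    lo, hi = config.founder_allele_freq_range
    for c, length in enumerate(config.chromosome_lengths_bp, start=1):
        m = max(2, int(round(config.snp_density_per_mb * length / 1e6)))
        bp = np.sort(rng.choice(np.arange(1, length, dtype=np.int64),
                                size=m, replace=False))
        for j, b in enumerate(bp):
            markers.append(dict(snp=f"c{c}s{j}", chrom=c, bp=int(b),
                                allele_a="A", allele_b="B"))
        freqs.append(rng.uniform(lo, hi, size=m))
    return pd.DataFrame(markers), np.concatenate(freqs)


def _breeding_values(pedigree: Pedigree, v_a: float, rng) -> dict:
    g = {}
    for iid in pedigree.topological_order():
        s, d = pedigree.parents(iid)
        if s is None or d is None:
            g[iid] = rng.normal(0.0, np.sqrt(v_a)) if v_a > 0 else 0.0
        else:
            mend = rng.normal(0.0, np.sqrt(v_a / 2.0)) if v_a > 0 else 0.0
            g[iid] = 0.5 * (g[s] + g[d]) + mend
    return g


def gene_drop(
    pedigree: Pedigree,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    track_founder_origins: bool = False,
) -> GeneDropResult:
    """Drop founder haplotypes through the pedigree with explicit crossovers.

    Each transmitted gamete is a mosaic of the parent's two haplotypes with
    breakpoints at the recorded true crossover positions; the per-chromosome
    crossover count is drawn from the parent's sex-specific map scaled by the
    parent's latent ACC value (mu_sex + g + qtl + eps) / mu_sex.  Genotypes
    are the sum of the two inherited haplotypes, perturbed by the configured
    missing/error rates.
    """
    rng = rng or np.random.default_rng(config.seed)
    markers, freqs = _simulate_markers(config, rng)
    if np.any((freqs <= 0) | (freqs >= 1)):
        warnings.warn("monomorphic SNP simulated: uninformative marker")
    m_total = len(markers)
    chrom_slices = []
    start = 0
    bp_by_chrom = []
    for c in range(1, config.n_chromosomes + 1):
        sub = markers[markers["chrom"] == c]
        chrom_slices.append(slice(start, start + len(sub)))
        bp_by_chrom.append(sub["bp"].to_numpy(np.int64))
        start += len(sub)

    cm_m = config.chromosome_cm("M")
    cm_f = config.chromosome_cm("F")
    mu = {"M": config.mean_acc("M"), "F": config.mean_acc("F")}

    order = pedigree.topological_order()
    haps: dict[str, np.ndarray] = {}
    origins: dict[str, np.ndarray] = {} if track_founder_origins else None
    g_values = _breeding_values(pedigree, config.v_a_acc, rng)
    qtl_dose: dict[str, int] = {}

    def qtl_shift(iid: str, sex: str) -> float:
        if config.qtl_marker is None or config.qtl_effect == 0.0:
            return 0.0
        if config.qtl_sex_limited and sex != config.qtl_sex_limited:
            return 0.0
        return config.qtl_effect * qtl_dose.get(iid, 0)

    truth: list[TrueMeiosisRecord] = []

    def meiose(parent: str, child: str) -> np.ndarray:
        sex = pedigree.sex(parent)
        cm_len = cm_m if sex == "M" else cm_f
        shift = g_values[parent] + qtl_shift(parent, sex) + rng.normal(
            0.0, np.sqrt(config.v_r_acc) if config.v_r_acc > 0 else 0.0
        )
        scale = max((mu[sex] + shift) / mu[sex], 0.05)
        gam = np.empty(m_total, dtype=np.int8)
        gam_or = np.empty(m_total, dtype=np.int32) if track_founder_origins else None
        counts = np.zeros(config.n_chromosomes, dtype=int)
        pos_all = []
        H = haps[parent]
        O = origins[parent] if track_founder_origins else None
        for c in range(config.n_chromosomes):
            sl = chrom_slices[c]
            total_cm = float(cm_len[c])
            n_xo = draw_crossover_count(rng, total_cm * scale, config.obligate)
            pos_cm = np.sort(crossover_positions_cm(
                rng, n_xo, total_cm, config.interference_nu
            ))
            pos_bp = np.unique(np.round(cm_to_bp(
                pos_cm, config.chromosome_lengths_bp[c], total_cm, sex, config
            )).astype(np.int64))
            counts[c] = len(pos_bp)
            pos_all.append(pos_bp)
            bp = bp_by_chrom[c]
            cut = np.searchsorted(bp, pos_bp, side="right")
            bounds = np.concatenate(([0], cut, [len(bp)]))
            cur = int(rng.integers(2))
            for seg in range(len(bounds) - 1):
                a, b = bounds[seg], bounds[seg + 1]
                gam[sl.start + a: sl.start + b] = H[cur, sl.start + a: sl.start + b]
                if track_founder_origins:
                    gam_or[sl.start + a: sl.start + b] = O[cur, sl.start + a: sl.start + b]
                cur = 1 - cur
        truth.append(TrueMeiosisRecord(
            parent=parent, offspring=child, parent_sex=sex,
            counts=counts, positions_bp=pos_all,
        ))
        if track_founder_origins:
            return gam, gam_or
        return gam

    founder_ids = []
    for k, iid in enumerate(order):
        s, d = pedigree.parents(iid)
        if s is None or d is None:
            h = (rng.random((2, m_total)) < freqs).astype(np.int8)
            haps[iid] = h
            if track_founder_origins:
                fidx = len(founder_ids)
                origins[iid] = np.stack([
                    np.full(m_total, 2 * fidx, dtype=np.int32),
                    np.full(m_total, 2 * fidx + 1, dtype=np.int32),
                ])
            founder_ids.append(iid)
        else:
            if track_founder_origins:
                pg, po = meiose(s, iid)
                mg, mo = meiose(d, iid)
                origins[iid] = np.stack([po, mo])
            else:
                pg = meiose(s, iid)
                mg = meiose(d, iid)
            haps[iid] = np.stack([pg, mg])
        if config.qtl_marker is not None:
            qtl_dose[iid] = int(haps[iid][0, config.qtl_marker]
                                + haps[iid][1, config.qtl_marker])

    ids = pedigree.ids
    geno = np.empty((len(ids), m_total), dtype=np.int8)
    for i, iid in enumerate(ids):
        geno[i] = haps[iid][0] + haps[iid][1]
    if config.genotyping_error_rate > 0:
        err = rng.random(geno.shape) < config.genotyping_error_rate
        if err.any():
            shiftv = rng.integers(1, 3, size=int(err.sum()))
            geno[err] = ((geno[err] + shiftv) % 3).astype(np.int8)
    if config.genotyping_missing_rate > 0:
        miss = rng.random(geno.shape) < config.genotyping_missing_rate
        geno[miss] = MISSING

    panel = GenotypePanel(markers, ids, geno)
    bv = pd.DataFrame(dict(id=list(g_values), g=list(g_values.values())))
    return GeneDropResult(
        panel=panel, truth=truth, pedigree=pedigree,
        breeding_values=bv, founder_freqs=freqs,
        founder_origins=origins,
        haplotypes=haps if track_founder_origins else None,
    )


# ---------------------------------------------------------------------------
# Quantitative-genetic phenotype pathway
# ---------------------------------------------------------------------------

def simulate_acc_phenotype(
    pedigree: Pedigree,
    v_a: float = 4.28,
    v_pe: float = 0.0,
    v_r: float = 25.28,
    mean_male: float = 34.12,
    mean_female: float = 27.00,
    qtl_dose: dict | None = None,
    qtl_effect: float = 0.0,
    qtl_sex_limited: str | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Gaussian ACC phenotypes with an exact variance decomposition.

    One row per pedigree transmission (parent = focal individual); the
    phenotype is mu_sex + a + pe + qtl + e with a ~ pedigree-correlated
    N(0, v_a), pe an individual-level effect and e a per-gamete residual.
    Used where the variance decomposition itself is the study condition.
    """
    rng = rng or np.random.default_rng(seed if seed is not None else 0)
    g = _breeding_values(pedigree, v_a, rng)
    pe = {i: (rng.normal(0.0, np.sqrt(v_pe)) if v_pe > 0 else 0.0)
          for i in pedigree.ids}
    rows = []
    for parent, off in pedigree.parent_offspring_links():
        sex = pedigree.sex(parent)
        mu = mean_male if sex == "M" else mean_female
        q = 0.0
        if qtl_dose is not None and qtl_effect != 0.0:
            if not qtl_sex_limited or sex == qtl_sex_limited:
                q = qtl_effect * qtl_dose.get(parent, 0)
        y = mu + g[parent] + pe[parent] + q + rng.normal(0.0, np.sqrt(v_r))
        rows.append(dict(fid=parent, offspring=off, fid_sex=sex, acc=y))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Detection-validation harness
# ---------------------------------------------------------------------------

def _adjusted_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Adjusted R^2 of the simple regression of y on x."""
    n = len(x)
    if n < 3 or np.var(x) == 0 or np.var(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    r2 = r * r
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


@dataclass
class ValidationReport:
    """Detected-vs-true ACC accuracy across replicate simulations."""

    per_simulation: pd.DataFrame  # sim, n_gametes, adj_r2, slope
    per_gamete: pd.DataFrame  # fid, offspring, n_sims, adj_r2, flagged
    flagged_gametes: list
    config: SimConfig = field(repr=False, default=None)

    @property
    def min_sim_r2(self) -> float:
        return float(self.per_simulation["adj_r2"].min())

    @property
    def mean_sim_r2(self) -> float:
        return float(self.per_simulation["adj_r2"].mean())


def run_detection(
    pedigree: Pedigree, drop: GeneDropResult, span_sd: float = 2.5
) -> pd.DataFrame:
    """Full detection pipeline on one simulated data set; returns the merge
    of detected and true ACC per gamete."""
    subpeds, _ = build_subpedigrees(pedigree, drop.panel.ids)
    if not subpeds:
        raise RuntimeError("no subpedigree could be formed (diagnostics: "
                           f"{len(pedigree)} individuals, "
                           f"{len(pedigree.founders())} founders)")
    clean, kept, _ = mendelian_qc(subpeds, drop.panel)
    gametes, table = detect_crossovers(kept, clean, span_sd=span_sd)
    if table.summary.empty:
        raise RuntimeError("detection produced no informative gamete")
    truth = drop.truth_table()
    merged = table.summary.merge(truth, on=["fid", "offspring"], how="inner")
    return merged


def validation_run(
    config: SimConfig, n_simulations: int = 10, r2_flag_threshold: float = 0.95
) -> ValidationReport:
    """Replicate simulations on one pedigree; regress detected on true ACC.

    Reports adjusted R^2 per simulation (across gametes) and per gamete
    (across simulations); gametes at or below ``r2_flag_threshold`` are
    flagged for removal, mirroring the exclusion of individuals whose ACC
    cannot be measured reliably.
    """
    if n_simulations < 2:
        raise ValueError("need at least 2 simulations")
    rng = np.random.default_rng(config.seed)
    pedigree = simulate_pedigree(config, rng)
    per_sim = []
    per_gam: dict[tuple, list] = {}
    for s in range(n_simulations):
        drop = gene_drop(pedigree, config,
                         np.random.default_rng(config.seed + 1000 + s))
        merged = run_detection(pedigree, drop)
        det = merged["acc"].to_numpy(float)
        tru = merged["true_acc"].to_numpy(float)
        slope = (
            np.cov(det, tru)[0, 1] / np.var(tru) if np.var(tru) > 0 else np.nan
        )
        per_sim.append(dict(sim=s, n_gametes=len(merged),
                            adj_r2=_adjusted_r2(tru, det), slope=slope))
        for f, o, d, t in zip(merged["fid"], merged["offspring"], det, tru):
            per_gam.setdefault((f, o), []).append((t, d))
    gam_rows = []
    for (f, o), pts in per_gam.items():
        arr = np.array(pts)
        r2 = _adjusted_r2(arr[:, 0], arr[:, 1])
        gam_rows.append(dict(fid=f, offspring=o, n_sims=len(pts), adj_r2=r2,
                             flagged=bool(r2 <= r2_flag_threshold)
                             if np.isfinite(r2) else False))
    per_gamete = pd.DataFrame(gam_rows)
    flagged = [
        (r["fid"], r["offspring"]) for _, r in per_gamete.iterrows() if r["flagged"]
    ]
    return ValidationReport(
        per_simulation=pd.DataFrame(per_sim), per_gamete=per_gamete,
        flagged_gametes=flagged, config=config,
    )


# ---------------------------------------------------------------------------
# Config IO (flat key=value)
# ---------------------------------------------------------------------------

def config_to_file(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        for k, v in vars(config).items():
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            fh.write(f"{k}={v}\n")


def config_from_file(path) -> SimConfig:
    kw = {}
    defaults = SimConfig()
    for line in open(path):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        k, v = line.split("=", 1)
        cur = getattr(defaults, k)
        if v == "None":
            kw[k] = None
        elif isinstance(cur, tuple) or (cur is None and "," in v):
            parts = v.split(",")
            kw[k] = tuple(int(x) if "." not in x else float(x) for x in parts)
        elif isinstance(cur, bool):
            kw[k] = v in ("True", "true", "1")
        elif isinstance(cur, int) and not isinstance(cur, bool):
            kw[k] = int(v)
        elif isinstance(cur, float):
            kw[k] = float(v)
        elif cur is None:
            # untyped optional: try int, then float, else keep the string
            try:
                kw[k] = int(v)
            except ValueError:
                try:
                    kw[k] = float(v)
                except ValueError:
                    kw[k] = v
        else:
            kw[k] = v
    return SimConfig(**kw)
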