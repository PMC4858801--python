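"""End-to-end orchestration with flat-file interchange and run manifests.

Stages communicate through TSV files in the output directory, so each stage
can be re-run or tested in isolation; a JSON manifest records the config
snapshot, seed, per-stage counts and a checksum of every file written.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import run_gwas
from .detect import detect_crossovers
from .landscape import bin_crossover_probability, broadscale_regressions
from .linkmap import build_map
from .pedigree import GenotypePanel, Pedigree, build_subpedigrees, mendelian_qc
from .regherit import regional_scan
from .simulate import SimConfig, config_from_file, gene_drop, simulate_pedigree
from .varcomp import fit_animal_model, pedigree_grm

PIPELINE_KEYS = {
    "stage_simulate", "stage_subped", "stage_detect", "stage_map",
    "stage_landscape", "stage_h2", "stage_gwas", "stage_regscan",
    "span_sd", "window_snps", "gwas_window", "alpha", "bin_size",
    "pedigree_file", "genotype_file", "marker_file",
}


@dataclass
class RunManifest:
    seed: int
    config: dict
    stages: list = field(default_factory=list)
    checksums: dict = field(default_factory=dict)
    version: str = __version__
    started: float = field(default_factory=time.time)

    def add_stage(self, name: str, status: str, **counts) -> None:
        self.stages.append(dict(name=name, status=status, counts=counts))

    def add_file(self, path) -> None:
        p = Path(path)
        h = hashlib.sha256(p.read_bytes()).hexdigest()
        self.checksums[p.name] = h

    def write(self, path) -> None:
        payload = dict(
            version=self.version, seed=self.seed, config=self.config,
            stages=self.stages, checksums=self.checksums,
        )
        Path(path).write_text(json.dumps(payload, indent=2, default=str))


def _split_config(path) -> tuple[dict, SimConfig]:
    """Separate pipeline-level keys from simulator keys in a flat file."""
    pipeline = {}
    sim_lines = []
    for line in open(path):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        k, v = s.split("=", 1)
        if k in PIPELINE_KEYS:
            pipeline[k] = v
        else:
            sim_lines.append(s)
    import tempfile, os
    fd, tmp = tempfile.mkstemp(suffix=".cfg")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write("\n".join(sim_lines))
        sim = config_from_file(tmp)
    finally:
        os.unlink(tmp)
    return pipeline, sim


def _flag(pipeline: dict, key: str, default: bool = True) -> bool:
    v = pipeline.get(key)
    if v is None:
        return default
    return v in ("1", "true", "True", "yes")


def run_pipeline(config_path, outdir, seed: int | None = None) -> RunManifest:
    """Execute the stages selected in the config; write TSVs and a manifest.

    Stage order: simulate -> subped -> detect -> map -> landscape -> h2 ->
    gwas -> regscan.  Any stage can be skipped via ``stage_<name>=false``;
    skipping ``simulate`` requires ``pedigree_file``/``genotype_file``/
    ``marker_file`` entries pointing at existing data.  A stage failure
    aborts the run but the partial manifest is still written.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pipeline, sim_cfg = _split_config(config_path)
    if seed is not None:
        sim_cfg = SimConfig(**{**vars(sim_cfg), "seed": int(seed)})
    manifest = RunManifest(seed=sim_cfg.seed, config={
        **pipeline, **{k: str(v) for k, v in vars(sim_cfg).items()}
    })
    try:
        _run_stages(pipeline, sim_cfg, out, manifest)
    finally:
        manifest.write(out / "manifest.json")
    return manifest


def _run_stages(pipeline, sim_cfg, out, manifest):
    span_sd = float(pipeline.get("span_sd", 2.5))
    rng = np.random.default_rng(sim_cfg.seed)

    if _flag(pipeline, "stage_simulate"):
        pedigree = simulate_pedigree(sim_cfg, rng)
        drop = gene_drop(pedigree, sim_cfg, rng)
        panel = drop.panel
        pedigree.to_tsv(out / "pedigree.tsv")
        panel.to_tsv(out / "genotypes.tsv", out / "markers.tsv")
        drop.truth_table().to_csv(out / "truth.tsv", sep="\t", index=False)
        for f in ("pedigree.tsv", "genotypes.tsv", "markers.tsv", "truth.tsv"):
            manifest.add_file(out / f)
        manifest.add_stage("simulate", "complete",
                           individuals=len(pedigree), markers=panel.n_markers)
    else:
        pedigree = Pedigree.from_tsv(pipeline["pedigree_file"])
        panel = GenotypePanel.from_tsv(
            pipeline["genotype_file"], pipeline["marker_file"]
        )
        manifest.add_stage("simulate", "skipped")

    if not _flag(pipeline, "stage_subped"):
        manifest.add_stage("subped", "skipped")
        return
    subpeds, n_dup = build_subpedigrees(pedigree, panel.ids)
    panel, subpeds, qc = mendelian_qc(subpeds, panel)
    qc.pair_table.to_csv(out / "mendelian_qc.tsv", sep="\t", index=False)
    manifest.add_file(out / "mendelian_qc.tsv")
    manifest.add_stage(
        "subped", "complete", built=len(subpeds),
        duplicate_discarded=n_dup, qc_dropped=qc.n_subpedigrees_dropped,
        masked_calls=qc.n_masked_calls,
    )

    if not _flag(pipeline, "stage_detect"):
        manifest.add_stage("detect", "skipped")
        return
    gametes, table = detect_crossovers(subpeds, panel, span_sd=span_sd)
    table.summary.to_csv(out / "crossovers.tsv", sep="\t", index=False)
    table.per_chromosome.to_csv(out / "crossovers_per_chromosome.tsv",
                                sep="\t", index=False)
    manifest.add_file(out / "crossovers.tsv")
    manifest.add_file(out / "crossovers_per_chromosome.tsv")
    manifest.add_stage(
        "detect", "complete", gametes=len(table.summary),
        crossovers=int(table.summary["acc"].sum()),
        single_snp_removed=table.filter_stats.n_single_snp_removed,
        short_span_removed=table.filter_stats.n_short_span_removed,
    )

    linkmap = None
    if _flag(pipeline, "stage_map"):
        linkmap = build_map(gametes, panel)
        linkmap.to_tsv(out / "linkage_map.tsv")
        pd.Series(linkmap.removed_markers, name="snp").to_csv(
            out / "removed_markers.tsv", sep="\t", index=False
        )
        manifest.add_file(out / "linkage_map.tsv")
        manifest.add_file(out / "removed_markers.tsv")
        manifest.add_stage("map", "complete",
                           markers=len(linkmap.table),
                           removed=len(linkmap.removed_markers))
    else:
        manifest.add_stage("map", "skipped")

    if _flag(pipeline, "stage_landscape") and linkmap is not None:
        bins = bin_crossover_probability(
            linkmap, bin_size=int(float(pipeline.get("bin_size", 1_000_000)))
        )
        bins.to_csv(out / "bins.tsv", sep="\t", index=False)
        manifest.add_file(out / "bins.tsv")
        n_chroms = linkmap.table["chrom"].nunique()
        if n_chroms >= 3:  # broad-scale regressions need df
            broad = broadscale_regressions(linkmap)
            pd.DataFrame([
                dict(model=k, **{kk: vv for kk, vv in v.items() if kk != "model"})
                for k, v in broad.items()
            ]).to_csv(out / "broadscale.tsv", sep="\t", index=False)
            manifest.add_file(out / "broadscale.tsv")
        manifest.add_stage("landscape", "complete", bins=len(bins),
                           broadscale=n_chroms >= 3)
    else:
        manifest.add_stage("landscape", "skipped")

    relationship = pedigree_grm(pedigree)
    if _flag(pipeline, "stage_h2"):
        est = fit_animal_model(table.summary, relationship, fixed=("fid_sex",))
        est.summary().to_frame("value").to_csv(out / "h2.tsv", sep="\t")
        manifest.add_file(out / "h2.tsv")
        manifest.add_stage("h2", "complete", h2=round(est.h2, 4),
                           converged=est.converged)
    else:
        manifest.add_stage("h2", "skipped")

    if _flag(pipeline, "stage_gwas"):
        run = run_gwas(
            table, panel, relationship,
            window=int(pipeline.get("gwas_window", 50)),
            alpha=float(pipeline.get("alpha", 0.05)),
        )
        run.records.to_csv(out / "gwas.tsv", sep="\t", index=False)
        manifest.add_file(out / "gwas.tsv")
        manifest.add_stage("gwas", "complete", snps=len(run.records),
                           lambda_gc=round(run.lambda_gc, 4),
                           threshold=run.threshold)
    else:
        manifest.add_stage("gwas", "skipped")

    if _flag(pipeline, "stage_regscan", default=False):
        scan = regional_scan(
            panel, table.summary, size=int(pipeline.get("window_snps", 20)),
            alpha=float(pipeline.get("alpha", 0.05)),
        )
        scan.table.to_csv(out / "regscan.tsv", sep="\t", index=False)
        manifest.add_file(out / "regscan.tsv")
        manifest.add_stage("regscan", "complete", windows=scan.n_windows,
                           threshold=scan.threshold)
    else:
        manifest.add_stage("regscan", "skipped")
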