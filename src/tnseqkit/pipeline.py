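"""End-to-end pipeline stages and their file formats.

Each stage reads and writes plain-text files (FASTA/GFF3/FASTQ/TSV/JSON) so
a run is fully reproducible from its output directory; every table carries a
provenance header with the tool version, seed and config hash. Stage order:

    simulate -> sites -> essential -> clusters -> diffabund

``run_all`` chains the last four over a dataset directory (simulated or
real) and writes a summary report with a library-QC statistics block.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import clusters as clu
from . import diffabund as da
from . import essentiality as ess
from . import io
from . import readproc as rp
from . import simulate as sim
from .models import GeneModel

log = logging.getLogger("tnseqkit")


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s",
                          datefmt="%Y-%m-%dT%H:%M:%S")
    )
    log.handlers[:] = [handler]
    log.setLevel(level.upper())


@dataclass
class PipelineConfig:
    """Paths and knobs for a full run; mirrors the CLI flags."""

    genome: str = "genome.fasta"
    annotation: str = "annotation.gff3"
    sample_sheet: str = "samples.tsv"
    outdir: str = "results"
    oend_marker: str = sim.DEFAULT_OEND_MARKER
    primer_set: Sequence[str] = sim.DEFAULT_PRIMERS
    duplication_length: int = rp.DUP_LEN
    seed_len: int = rp.SEED_LEN
    circular: bool = True
    filter_policy: ess.FilterPolicy = field(default_factory=ess.FilterPolicy)
    n_perm: int = 100_000
    cluster_alpha: float = 0.05
    fdr_alpha: float = 0.1
    reference_condition: str = "input"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        policy = ess.FilterPolicy(**raw.pop("filter_policy", {}))
        return cls(filter_policy=policy, **raw)

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        return io.config_hash(d)


# ------------------------------------------------------------------- simulate

def run_simulate(config: sim.SimulationConfig, outdir: str | Path,
                 conditions: Sequence[str] = ("selection",)) -> dict:
    """Generate a synthetic dataset directory with ground truth.

    Writes genome.fasta, annotation.gff3, samples.tsv, config.yaml,
    reads/<sample>.fastq plus per-read truth sidecars, truth tables and a
    manifest.json with SHA-256 checksums of every file.
    """
    outdir = Path(outdir)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)
    chash = io.config_hash(dataclasses.asdict(config))
    log.info("simulating dataset (seed=%d, hash=%s)", config.seed, chash)

    data = sim.simulate_experiment(config, conditions)
    io.write_fasta(outdir / "genome.fasta", {"chr": data["genome"]})
    io.write_gff3(outdir / "annotation.gff3", data["annotation"])

    pool = data["pools"]["master"]
    io.write_table(outdir / "truth_sites.tsv",
                   pool[["position", "orientation", "gene_id", "abundance"]],
                   seed=config.seed, config_hash=chash)
    fitness_rows = [
        (cond, gid, s)
        for cond, fit in data["truth"].fitness.items()
        for gid, s in sorted(fit.items())
    ]
    io.write_table(outdir / "truth_fitness.tsv",
                   pd.DataFrame(fitness_rows, columns=["condition", "gene_id", "s"]),
                   seed=config.seed, config_hash=chash)

    sheet_rows = []
    for name, (reads, truth) in sorted(data["samples"].items()):
        cond, rep = name.rsplit("_rep", 1)
        fastq = outdir / "reads" / f"{name}.fastq"
        io.write_fastq(fastq, reads)
        io.write_table(outdir / "reads" / f"{name}.truth.tsv", truth,
                       seed=config.seed, config_hash=chash)
        sheet_rows.append((name, cond, int(rep), str(fastq.name)))
    sheet = pd.DataFrame(sheet_rows, columns=["sample", "condition", "replicate", "fastq"])
    io.write_table(outdir / "samples.tsv", sheet, seed=config.seed, config_hash=chash)

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)

    manifest = {
        "config_hash": chash,
        "seed": config.seed,
        "files": {
            str(p.relative_to(outdir)): io.file_sha256(p)
            for p in sorted(outdir.rglob("*")) if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------- sites

def stage_sites(cfg: PipelineConfig, dataset_dir: str | Path,
                outdir: str | Path) -> dict[str, Path]:
    """Process every sample's FASTQ into a unique-site TSV + stats JSON."""
    dataset_dir, outdir = Path(dataset_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = _single_contig(io.read_fasta(dataset_dir / cfg.genome))
    annotation = io.read_annotation(dataset_dir / cfg.annotation)
    aligner = rp.GenomeAligner(genome, cfg.seed_len)
    sheet = io.read_table(dataset_dir / cfg.sample_sheet)

    site_paths: dict[str, Path] = {}
    all_stats = {}
    for row in sheet.itertuples():
        fastq = dataset_dir / "reads" / row.fastq
        reads = io.read_fastq(fastq)
        sites, counts = rp.reads_to_sites(
            reads, aligner, cfg.oend_marker, cfg.primer_set,
            cfg.duplication_length, cfg.circular,
        )
        stats = rp.library_stats(sites, len(genome), annotation, counts)
        log.info("%s: raw=%d filtered=%d mapped=%d unique=%d density=%s",
                 row.sample, counts.n_raw, counts.n_filtered, counts.n_mapped,
                 stats.n_unique_sites, stats.density_bp_per_insertion)
        path = outdir / f"{row.sample}.sites.tsv"
        io.write_table(path, sites, seed=cfg.seed, config_hash=cfg.hash())
        site_paths[row.sample] = path
        all_stats[row.sample] = stats.as_dict()
    with open(outdir / "library_stats.json", "w") as fh:
        json.dump(all_stats, fh, indent=2, sort_keys=True)
    return site_paths


def _single_contig(fasta: Mapping[str, str]) -> str:
    if len(fasta) != 1:
        raise ValueError("expected a single-contig genome FASTA")
    return next(iter(fasta.values()))


def pool_site_tables(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Sum read counts of the same (position, orientation) across samples."""
    merged = pd.concat(tables, ignore_index=True)
    return (
        merged.groupby(["position", "orientation"], as_index=False)["read_count"]
        .sum()
        .sort_values(["position", "orientation"], ignore_index=True)
    )


# ------------------------------------------------------------------ essential

def stage_essential(cfg: PipelineConfig, dataset_dir: str | Path,
                    site_tables: Sequence[pd.DataFrame],
                    outdir: str | Path) -> pd.DataFrame:
    """Essentiality calls from the pooled reference-library site tables."""
    dataset_dir, outdir = Path(dataset_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = io.read_annotation(dataset_dir / cfg.annotation)
    genome = _single_contig(io.read_fasta(dataset_dir / cfg.genome))
    pooled = pool_site_tables(site_tables)
    calls = ess.call_essentiality(pooled, annotation, cfg.filter_policy)
    summary = ess.summarize_calls(calls, annotation, genome)
    log.info("essentiality: %d/%d genes essential (%d%%)",
             summary.n_essential, summary.n_genes, summary.percent_essential)
    io.write_table(outdir / "essentiality_calls.tsv", calls,
                   seed=cfg.seed, config_hash=cfg.hash())
    with open(outdir / "essentiality_summary.json", "w") as fh:
        json.dump(summary.as_dict(), fh, indent=2, sort_keys=True)
    return calls


# ------------------------------------------------------------------- clusters

def stage_clusters(cfg: PipelineConfig, dataset_dir: str | Path,
                   calls: pd.DataFrame, outdir: str | Path) -> dict:
    """Permutation significance of essential-gene runs (protein-coding only,
    genomic order)."""
    dataset_dir, outdir = Path(dataset_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = io.read_annotation(dataset_dir / cfg.annotation)
    protein = [g for g in sorted(annotation, key=lambda g: g.start)
               if g.gene_type == "protein"]
    ess_by_id = dict(zip(calls["gene_id"], calls["essential"]))
    labels = [int(ess_by_id.get(g.gene_id, False)) for g in protein]

    result = clu.cluster_analysis(labels, n_perm=cfg.n_perm,
                                  alpha=cfg.cluster_alpha, seed=cfg.seed)
    frame = clu.clusters_to_frame(result["clusters"], [g.gene_id for g in protein])
    io.write_table(outdir / "clusters.tsv", frame,
                   seed=cfg.seed, config_hash=cfg.hash())
    summary = {
        "n_protein_genes": len(labels),
        "n_essential": int(sum(labels)),
        "n_perm": cfg.n_perm,
        "alpha": cfg.cluster_alpha,
        "pvalues": {str(k): v for k, v in result["pvalues"].items()},
        "min_significant_length": result["min_significant_length"],
    }
    with open(outdir / "clusters_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("clusters: min significant run length = %s",
             result["min_significant_length"])
    return result


# ------------------------------------------------------------------ diffabund

def stage_diffabund(cfg: PipelineConfig, dataset_dir: str | Path,
                    site_tables: Mapping[str, pd.DataFrame],
                    calls: pd.DataFrame, outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Enrichment/depletion per selected condition vs the reference library."""
    dataset_dir, outdir = Path(dataset_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = io.read_annotation(dataset_dir / cfg.annotation)
    by_id = {g.gene_id: g for g in annotation}
    sheet = io.read_table(dataset_dir / cfg.sample_sheet)
    cond_of = dict(zip(sheet["sample"], sheet["condition"]))

    profiles_by_sample = {}
    for sample, table in site_tables.items():
        profiles, _, _ = ess.assign_to_genes(table, annotation)
        profiles_by_sample[sample] = {
            gid: ess.apply_filters(p, cfg.filter_policy, by_id[gid])
            for gid, p in profiles.items()
        }
    essential_ids = set(calls.loc[calls["essential"], "gene_id"])
    counts = da.build_count_matrix(profiles_by_sample, essential_ids)
    io.write_table(outdir / "count_matrix.tsv", counts.reset_index(names="gene_id"),
                   seed=cfg.seed, config_hash=cfg.hash())

    results = {}
    conditions = [c for c in dict.fromkeys(cond_of.values())
                  if c != cfg.reference_condition]
    for condition in conditions:
        keep = [s for s, c in cond_of.items()
                if c in (cfg.reference_condition, condition)]
        res = da.run_differential(
            counts[keep], {s: cond_of[s] for s in keep},
            reference=cfg.reference_condition, treatment=condition,
            alpha=cfg.fdr_alpha,
        )
        path = outdir / f"diffabund_{condition}.tsv"
        io.write_table(path, res.reset_index(), seed=cfg.seed, config_hash=cfg.hash())
        n_sig = int((res["call"] != "ns").sum())
        log.info("diffabund %s: %d/%d genes significant at FDR %.2f",
                 condition, n_sig, len(res), cfg.fdr_alpha)
        results[condition] = res
    return results


# -------------------------------------------------------------------- run all

def run_all(cfg: PipelineConfig, dataset_dir: str | Path,
            outdir: str | Path | None = None) -> dict:
    """Run sites -> essential -> clusters -> diffabund over a dataset
    directory; returns the summary report dict (also written as JSON)."""
    dataset_dir = Path(dataset_dir)
    outdir = Path(outdir) if outdir else dataset_dir / cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("genome", "annotation", "sample_sheet"):
        path = dataset_dir / getattr(cfg, name)
        if not path.exists():
            raise FileNotFoundError(f"{name} file missing: {path}")

    site_paths = stage_sites(cfg, dataset_dir, outdir / "sites")
    site_tables = {s: io.read_table(p) for s, p in site_paths.items()}

    sheet = io.read_table(dataset_dir / cfg.sample_sheet)
    ref_samples = sheet.loc[sheet["condition"] == cfg.reference_condition, "sample"]
    if ref_samples.empty:
        raise ValueError(
            f"reference condition {cfg.reference_condition!r} absent from sample sheet")
    calls = stage_essential(cfg, dataset_dir,
                            [site_tables[s] for s in ref_samples],
                            outdir / "essential")
    cluster_result = stage_clusters(cfg, dataset_dir, calls, outdir / "clusters")
    diff = stage_diffabund(cfg, dataset_dir, site_tables, calls, outdir / "diffabund")

    genome = _single_contig(io.read_fasta(dataset_dir / cfg.genome))
    annotation = io.read_annotation(dataset_dir / cfg.annotation)
    with open(outdir / "sites" / "library_stats.json") as fh:
        library_block = json.load(fh)
    summary = ess.summarize_calls(calls, annotation, genome)
    report = {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "library_stats": library_block,  # Table-1-style block
        "essentiality": summary.as_dict(),
        "min_significant_cluster_length": cluster_result["min_significant_length"],
        "diffabund": {
            cond: {"n_significant": int((res["call"] != "ns").sum()),
                   "n_enriched": int((res["call"] == "enriched").sum()),
                   "n_depleted": int((res["call"] == "depleted").sum()),
                   "n_genes": int(len(res))}
            for cond, res in diff.items()
        },
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
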