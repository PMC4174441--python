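"""End-to-end orchestration: quantify -> enrich -> plots, plus library stats."""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import pysam
import yaml

from . import annotation, enrich, plots, quantify
from .assignment import (
    CONDITIONS,
    DEFAULT_MIN_MAPQ,
    extract_gene_fragments,
    library_size,
)

logger = logging.getLogger(__name__)

REQUIRED_CONDITIONS = ("WT_IP", "WT_TOTAL", "NULL_IP")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    gff: str
    manifest: str  # TSV: path  condition  replicate
    outdir: str
    min_mapq: int = DEFAULT_MIN_MAPQ
    require_proper_pair: bool = False
    mode: str = "contained"  # fragment-to-transcript assignment mode
    epsilon: float = enrich.DEFAULT_EPSILON
    floor: float = enrich.DEFAULT_FLOOR
    cutoff: float = enrich.DEFAULT_CUTOFF
    null_reference: str = "WT_TOTAL"
    plot_genes: list[str] = field(default_factory=list)
    chrom_aliases: dict[str, str] = field(default_factory=dict)
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def read_manifest(path: str) -> pd.DataFrame:
    """Validate the library manifest: required conditions present,
    replicate labels unique within each condition, files on disk."""
    df = pd.read_csv(path, sep="\t")
    missing_cols = {"path", "condition", "replicate"} - set(df.columns)
    if missing_cols:
        raise ValueError(f"manifest lacks columns: {sorted(missing_cols)}")
    for cond in REQUIRED_CONDITIONS:
        if cond not in set(df.condition):
            raise ValueError(f"manifest is missing required condition {cond}")
    unknown = set(df.condition) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown conditions in manifest: {sorted(unknown)}")
    for cond, grp in df.groupby("condition"):
        if grp.replicate.duplicated().any():
            raise ValueError(f"duplicate replicate labels for condition {cond}")
    for p in df.path:
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    return df


def quantify_manifest(
    manifest: pd.DataFrame, genes: list[annotation.GeneModel], config: RunConfig
) -> dict[str, quantify.FPKMTable]:
    """Quantify every library in the manifest and aggregate per condition."""
    tables: dict[str, quantify.FPKMTable] = {}
    for cond, grp in manifest.groupby("condition", sort=True):
        libs = []
        for row in grp.sort_values("replicate").itertuples():
            logger.info("quantifying %s replicate %s", cond, row.replicate)
            libs.append(
                quantify.quantify_library(
                    row.path,
                    genes,
                    condition=cond,
                    replicate=int(row.replicate),
                    min_mapq=config.min_mapq,
                    require_proper_pair=config.require_proper_pair,
                    mode=config.mode,
                )
            )
        tables[cond] = quantify.aggregate_replicates(libs)
    return tables


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Full analysis: returns the ranked table and writes all outputs
    (FPKM tables, ranked table, scatter data, per-gene coverage SVGs,
    metadata sidecar) under ``config.outdir``."""
    manifest = read_manifest(config.manifest)  # validates before any compute
    genes = annotation.apply_chrom_aliases(
        annotation.read_gff(config.gff), config.chrom_aliases
    )
    tx2gene = {t.transcript_id: t.gene_id for g in genes for t in g.transcripts}
    os.makedirs(config.outdir, exist_ok=True)

    tables = quantify_manifest(manifest, genes, config)
    for cond, table in tables.items():
        enrich.write_tsv(
            table.to_frame(tx2gene).rename_axis("transcript_id").reset_index(),
            os.path.join(config.outdir, f"fpkm_{cond}.tsv"),
        )

    records = enrich.build_enrichment_table(
        tables,
        tx2gene,
        epsilon=config.epsilon,
        floor=config.floor,
        cutoff=config.cutoff,
        null_reference=config.null_reference,
    )
    ranked = enrich.rank_table(records, cutoff=config.cutoff)
    enrich.write_tsv(ranked, os.path.join(config.outdir, "ranked_table.tsv"))
    enrich.write_tsv(
        records.reset_index(), os.path.join(config.outdir, "enrichment_records.tsv")
    )
    scatter = enrich.enrichment_scatter(records, epsilon=config.epsilon)
    enrich.write_tsv(scatter, os.path.join(config.outdir, "scatter.tsv"))

    if config.plot_genes:
        plot_genes(config, genes, manifest)

    enrich.write_run_metadata(
        os.path.join(config.outdir, "run_metadata.json"),
        gff=config.gff,
        manifest=config.manifest,
        min_mapq=config.min_mapq,
        require_proper_pair=config.require_proper_pair,
        mode=config.mode,
        epsilon=config.epsilon,
        floor=config.floor,
        cutoff=config.cutoff,
        null_reference=config.null_reference,
        seed=config.seed,
        n_selected=int(records.selected.sum()),
    )
    return ranked


def plot_genes(
    config: RunConfig,
    genes: list[annotation.GeneModel],
    manifest: pd.DataFrame,
    condition: str = "WT_IP",
) -> list[str]:
    """Coverage SVG per requested gene from the IP replicate libraries.

    Per-gene failures are logged, not fatal (the tables of a run are
    still valid when one plot cannot be drawn)."""
    by_id = {g.gene_id: g for g in genes}
    ip = manifest[manifest.condition == condition].sort_values("replicate")
    written: list[str] = []
    for gene_id in config.plot_genes:
        gene = by_id.get(gene_id)
        if gene is None:
            logger.warning("plot requested for unknown gene %r, skipped", gene_id)
            continue
        try:
            profiles = {}
            for row in ip.itertuples():
                with pysam.AlignmentFile(row.path, "rb") as bam:
                    frags = extract_gene_fragments(
                        bam,
                        gene,
                        min_mapq=config.min_mapq,
                        require_proper_pair=config.require_proper_pair,
                    )
                profiles[int(row.replicate)] = plots.coverage_profile(
                    frags, gene_id, gene.region_start, gene.region_end, row.path
                )
            occ = annotation.exon_occurrence(gene)
            out = os.path.join(config.outdir, f"coverage_{gene_id}.svg")
            plots.render_coverage_svg(gene, profiles, occ, out)
            written.append(out)
        except Exception:  # pragma: no cover - per-gene resilience path
            logger.exception("coverage plot failed for gene %s", gene_id)
    return written


def library_stats(manifest: pd.DataFrame, genes: list[annotation.GeneModel]) -> pd.DataFrame:
    """Per-library summary: total records, mapped fragments N, fragments
    assigned to >=1 transcript, unassigned."""
    rows = []
    for row in manifest.itertuples():
        with pysam.AlignmentFile(row.path, "rb") as bam:
            total = sum(1 for _ in bam.fetch(until_eof=True))
            n = library_size(bam)
        lib = quantify.quantify_library(
            row.path, genes, condition=row.condition, replicate=int(row.replicate)
        )
        rows.append(
            {
                "path": row.path,
                "condition": row.condition,
                "replicate": int(row.replicate),
                "total_records": total,
                "mapped_fragments": n,
                "assigned_fragments": lib.n_assigned,
                "unassigned_fragments": lib.n_unassigned,
            }
        )
    return pd.DataFrame(rows)
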