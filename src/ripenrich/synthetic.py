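"""Synthetic RIP-Seq universe: annotation, truth table, aligned reads.

Emulates the full experimental design the pipeline analyses — a
multi-gene, multi-isoform annotation and coordinate-sorted, indexed
BAM libraries for four conditions (WT IP, WT total, null-mutant IP,
null-mutant total) in triplicate — entirely offline, with a truth
table recording every transcript's abundance, enrichment factor and
realized counts so each pipeline stage can be checked against ground
truth.

Sampling model
--------------
Per-transcript relative abundance a_t is log-normal. In input (total
RNA) libraries a transcript's sampling probability is p_t ∝ a_t * L_t
(L_t the exon-model length: longer transcripts shed more fragments, so
FPKM is the recoverable quantity). In the WT IP library a designated
target subset is enriched: the enrichment factor rho_t is defined as
the IP-vs-input fold change of the transcript's *relative* abundance —
a target's IP share is exactly rho_t * p_t, and background transcripts
share the remaining library fraction in proportion to abundance. Thus
log2(rho) is the true log2 enrichment the pipeline should recover.
Null-mutant IP libraries use rho = 1 for every transcript (the beads
pull background proportional to abundance when the protein is absent).

Each library draws its fragment count vector from
Multinomial(n_fragments, shares); fragment start is uniform on the
transcript, fragment length Gaussian clipped to [read_length,
transcript_length]; mate blocks are mapped through the exon chain into
spliced genomic alignments (M/N CIGARs). Target designation is at the
gene level — every isoform of a target gene carries rho — because a
bound protein pulls down a gene's isoforms alike and shared exons make
isoform counts bleed into each other under multi-assignment. Replicate-to-replicate noise
is therefore pure multinomial resampling; there is no sequencing- or
mapping-error model, and base calls are never emitted ('*' SEQ) since
the pipeline does not inspect them.
"""

from __future__ import annotations

import logging
import os
from bisect import bisect_right
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import pysam
import yaml

from .annotation import Exon, GeneModel, TranscriptModel, write_gff
from .assignment import CONDITIONS

logger = logging.getLogger(__name__)


@dataclass
class SimParams:
    """Generator settings; the defaults are the study conditions every
    recovery test and the acceptance run use."""

    seed: int
    n_genes: int = 200
    isoforms_per_gene: tuple[int, int] = (1, 4)
    exons_per_transcript: tuple[int, int] = (2, 8)
    exon_length: tuple[int, int] = (100, 600)
    intron_length: tuple[int, int] = (60, 400)
    intergenic_gap: tuple[int, int] = (1000, 5000)
    n_chromosomes: int = 4
    chromosome_length: int | None = None  # auto-sized when None
    fragment_length_mean: float = 250.0
    fragment_length_sd: float = 50.0
    read_length: int = 75
    n_fragments: int = 200_000
    abundance_mu: float = 0.0  # natural-log scale
    abundance_sigma: float = 1.0
    target_fraction: float = 0.10
    target_fold: float = 4.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("n_genes", "read_length", "n_fragments", "n_chromosomes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.target_fraction < 1:
            raise ValueError("target_fraction must be in [0, 1)")
        if self.target_fold < 0:
            raise ValueError("target_fold must be >= 0")


def _rng(params: SimParams, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=(key,)))


def _sample_gene(
    rng: np.random.Generator, params: SimParams, gene_id: str, chrom: str, start: int
) -> GeneModel:
    """One gene: a skeleton exon chain plus isoform subsets that always
    contain a shared anchor exon (so occurrence shading is exercised)."""
    k = int(rng.integers(params.exons_per_transcript[0], params.exons_per_transcript[1] + 1))
    exon_lens = rng.integers(params.exon_length[0], params.exon_length[1] + 1, size=k)
    intron_lens = rng.integers(params.intron_length[0], params.intron_length[1] + 1, size=max(0, k - 1))
    strand = "+" if rng.random() < 0.5 else "-"
    starts = np.empty(k, dtype=np.int64)
    pos = start
    for i in range(k):
        starts[i] = pos
        pos += int(exon_lens[i])
        if i < k - 1:
            pos += int(intron_lens[i])
    anchor = k // 2
    n_iso = int(rng.integers(params.isoforms_per_gene[0], params.isoforms_per_gene[1] + 1))
    chosen: list[frozenset[int]] = []
    for _ in range(n_iso):
        for _attempt in range(10):
            sel = {anchor} | {i for i in range(k) if i != anchor and rng.random() < 0.75}
            while len(sel) < min(2, k):
                sel.add(min(set(range(k)) - sel))
            fs = frozenset(sel)
            if fs not in chosen:
                chosen.append(fs)
                break
        else:
            chosen.append(fs)  # duplicate isoform tolerated after retries
    gene = GeneModel(gene_id)
    for j, sel in enumerate(chosen, 1):
        exons = [
            Exon(chrom, int(starts[i]), int(starts[i] + exon_lens[i]), strand)
            for i in sorted(sel)
        ]
        gene.transcripts.append(TranscriptModel(f"{gene_id}.T{j}", gene_id, exons))
    return gene


def simulate_annotation(params: SimParams, gff_path: str | None = None) -> list[GeneModel]:
    """Non-overlapping genes packed onto synthetic chromosomes;
    deterministic for a fixed seed. Optionally writes the GFF3."""
    rng = _rng(params, 0)
    genes: list[GeneModel] = []
    per_chrom = -(-params.n_genes // params.n_chromosomes)  # ceil
    width = len(str(params.n_genes))
    for gi in range(params.n_genes):
        chrom = f"chrS{gi // per_chrom + 1}"
        if gi % per_chrom == 0:
            pos = int(rng.integers(*params.intergenic_gap))
        gene = _sample_gene(rng, params, f"SG{gi + 1:0{width}d}", chrom, pos)
        if params.chromosome_length is not None and gene.region_end > params.chromosome_length:
            raise ValueError(
                f"gene {gene.gene_id} ends at {gene.region_end}, beyond the "
                f"{params.chromosome_length} bp chromosome — parameters infeasible"
            )
        genes.append(gene)
        pos = gene.region_end + int(rng.integers(*params.intergenic_gap))
    if gff_path is not None:
        write_gff(genes, gff_path)
    return genes


class _TxLayout:
    """Exon chain of one transcript prepared for coordinate mapping."""

    __slots__ = ("tid", "chrom", "cum", "gstarts", "lens", "length")

    def __init__(self, t: TranscriptModel):
        self.tid = t.transcript_id
        self.chrom = t.chrom
        self.gstarts = [e.start for e in t.exons]
        self.lens = [len(e) for e in t.exons]
        self.cum = [0]
        for ln in self.lens:
            self.cum.append(self.cum[-1] + ln)
        self.length = self.cum[-1]

    def map_interval(self, a: int, b: int) -> list[tuple[int, int]]:
        """Transcript interval [a, b) -> genomic blocks through the chain."""
        i = bisect_right(self.cum, a) - 1
        blocks = []
        while a < b:
            off = a - self.cum[i]
            g0 = self.gstarts[i] + off
            take = min(b - a, self.lens[i] - off)
            blocks.append((g0, g0 + take))
            a += take
            i += 1
        return blocks


def _cigar(blocks: list[tuple[int, int]]) -> str:
    parts = [f"{blocks[0][1] - blocks[0][0]}M"]
    for (ps, pe), (s, e) in zip(blocks, blocks[1:]):
        parts.append(f"{s - pe}N{e - s}M")
    return "".join(parts)


def _library_sam_lines(
    layouts: list[_TxLayout],
    counts: np.ndarray,
    lib_id: str,
    params: SimParams,
    rng: np.random.Generator,
) -> list[str]:
    lines: list[str] = []
    rl = params.read_length
    for layout, c in zip(layouts, counts):
        c = int(c)
        if c == 0:
            continue
        L = layout.length
        flens = np.clip(
            np.rint(rng.normal(params.fragment_length_mean, params.fragment_length_sd, c)),
            rl,
            L,
        ).astype(np.int64)
        starts = (rng.random(c) * (L - flens + 1)).astype(np.int64)
        ends = starts + flens
        rls = np.minimum(rl, flens)
        chrom = layout.chrom
        tid = layout.tid
        for j in range(c):
            b1 = layout.map_interval(int(starts[j]), int(starts[j] + rls[j]))
            b2 = layout.map_interval(int(ends[j] - rls[j]), int(ends[j]))
            name = f"{tid}|{lib_id}|{j}"
            p1 = b1[0][0] + 1
            p2 = b2[0][0] + 1
            tlen = b2[-1][1] - b1[0][0]
            lines.append(
                f"{name}\t99\t{chrom}\t{p1}\t60\t{_cigar(b1)}\t=\t{p2}\t{tlen}\t*\t*\n"
            )
            lines.append(
                f"{name}\t147\t{chrom}\t{p2}\t60\t{_cigar(b2)}\t=\t{p1}\t{-tlen}\t*\t*\n"
            )
    return lines


@dataclass
class SimulatedExperiment:
    """Paths and ground truth of one simulated experiment."""

    outdir: str
    gff_path: str
    manifest: pd.DataFrame  # columns path, condition, replicate
    truth: pd.DataFrame
    truth_path: str
    metadata_path: str
    params: SimParams = field(repr=False, default=None)


def simulate_experiment(
    genes: list[GeneModel],
    params: SimParams,
    outdir: str,
    conditions: tuple[str, ...] = CONDITIONS,
    n_replicates: int = 3,
    gff_path: str | None = None,
) -> SimulatedExperiment:
    """Write sorted+indexed BAMs for each (condition, replicate), the
    truth TSV and a metadata sidecar; returns paths plus the truth
    table. Identical parameters (seed included) give byte-identical
    truth TSV and identical alignment records."""
    os.makedirs(outdir, exist_ok=True)
    if gff_path is None:
        gff_path = os.path.join(outdir, "annotation.gff3")
        write_gff(genes, gff_path)

    all_tx = [t for g in genes for t in g.transcripts]
    layouts_all = [_TxLayout(t) for t in all_tx]
    viable = [lay for lay in layouts_all if lay.length >= params.read_length]
    for lay in layouts_all:
        if lay.length < params.read_length:
            logger.warning(
                "transcript %s (%d bp) shorter than the read length, excluded",
                lay.tid,
                lay.length,
            )
    if not viable:
        raise ValueError("no transcript is at least one read length long")

    rng_ab = _rng(params, 1)
    abundance = rng_ab.lognormal(params.abundance_mu, params.abundance_sigma, len(viable))
    # Targets are whole genes: a bound protein pulls down every isoform of a
    # target gene alike, and shared exons make isoform counts bleed into each
    # other under multi-assignment — enriching all siblings together keeps
    # log2(rho) the recoverable per-transcript enrichment.
    tx2gene_all = {t.transcript_id: t.gene_id for t in all_tx}
    tx_per_gene: dict[str, int] = {}
    for lay in viable:
        gid = tx2gene_all[lay.tid]
        tx_per_gene[gid] = tx_per_gene.get(gid, 0) + 1
    gene_ids = sorted(tx_per_gene)
    n_wanted = int(round(params.target_fraction * len(viable)))
    target_genes: set[str] = set()
    n_target_tx = 0
    if params.target_fold != 1.0 and n_wanted > 0:
        for gid in rng_ab.permutation(gene_ids):
            if n_target_tx >= n_wanted:
                break
            target_genes.add(gid)
            n_target_tx += tx_per_gene[gid]
    rho = np.array(
        [
            params.target_fold if tx2gene_all[lay.tid] in target_genes else 1.0
            for lay in viable
        ]
    )
    n_targets = int((rho > 1).sum())

    lengths = np.array([lay.length for lay in viable], dtype=float)
    p = abundance * lengths
    p /= p.sum()
    # IP composition: target share = rho * input share, exactly; the
    # background is renormalized to fill the remaining library fraction.
    target_mass = float((p * (rho > 1)).sum())
    enriched_mass = float((p * rho * (rho > 1)).sum())
    if enriched_mass >= 1.0:
        raise ValueError("enriched target mass >= 1; reduce target_fraction or target_fold")
    scale_bg = (1.0 - enriched_mass) / (1.0 - target_mass) if target_mass < 1 else 0.0
    q_ip = np.where(rho > 1, rho * p, scale_bg * p)

    chrom_ends: dict[str, int] = {}
    for g in genes:
        chrom_ends[g.chrom] = max(chrom_ends.get(g.chrom, 0), g.region_end)
    header_lines = ["@HD\tVN:1.6\tSO:unsorted\n"] + [
        f"@SQ\tSN:{c}\tLN:{end + 1000}\n" for c, end in sorted(chrom_ends.items())
    ]

    manifest_rows = []
    truth_counts: dict[str, np.ndarray] = {}
    lib_index = 0
    for condition in conditions:
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        shares = q_ip if condition == "WT_IP" else p
        for rep in range(1, n_replicates + 1):
            lib_id = f"{condition}_rep{rep}"
            rng_lib = _rng(params, 10 + lib_index)
            lib_index += 1
            counts = rng_lib.multinomial(params.n_fragments, shares)
            truth_counts[f"count_{lib_id}"] = counts
            sam_path = os.path.join(outdir, f"{lib_id}.sam")
            bam_path = os.path.join(outdir, f"{lib_id}.bam")
            with open(sam_path, "w") as fh:
                fh.writelines(header_lines)
                fh.writelines(
                    _library_sam_lines(viable, counts, lib_id, params, rng_lib)
                )
            pysam.sort("-o", bam_path, sam_path, catch_stdout=False)
            pysam.index(bam_path)
            os.remove(sam_path)
            manifest_rows.append(
                {"path": bam_path, "condition": condition, "replicate": rep}
            )

    truth = pd.DataFrame(
        {
            "transcript_id": [lay.tid for lay in viable],
            "gene_id": [tx2gene_all[lay.tid] for lay in viable],
            "length": [lay.length for lay in viable],
            "abundance": abundance,
            "rho": rho,
            "is_target": rho > 1,
        }
    )
    for col, counts in truth_counts.items():
        truth[col] = counts
    truth = truth.sort_values("transcript_id").reset_index(drop=True)
    truth_path = os.path.join(outdir, "truth.tsv")
    truth.to_csv(truth_path, sep="\t", index=False, float_format="%.10g")

    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(os.path.join(outdir, "manifest.tsv"), sep="\t", index=False)

    metadata_path = os.path.join(outdir, "sim_metadata.yaml")
    with open(metadata_path, "w") as fh:
        yaml.safe_dump(
            {
                "params": asdict(params),
                "conditions": list(conditions),
                "n_replicates": n_replicates,
                "n_transcripts": len(all_tx),
                "n_viable_transcripts": len(viable),
                "n_targets": n_targets,
            },
            fh,
            sort_keys=True,
        )
    return SimulatedExperiment(
        outdir, gff_path, manifest, truth, truth_path, metadata_path, params
    )
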