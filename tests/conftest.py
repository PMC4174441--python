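"""Shared fixtures: hand-built gene models, programmatic BAMs, small
simulations, and independently coded brute-force oracles."""

from __future__ import annotations

import os

import pysam
import pytest

from ripenrich.annotation import Exon, GeneModel, TranscriptModel
from ripenrich.synthetic import SimParams, simulate_annotation, simulate_experiment


# ---------------------------------------------------------------- oracles
def oracle_exon_bases(exons) -> set[int]:
    """Per-base set of a transcript's exon union."""
    bases: set[int] = set()
    for e in exons:
        bases.update(range(e.start, e.end))
    return bases


def oracle_occurrence(gene: GeneModel) -> dict[int, float]:
    """Per-base occurrence fraction over the gene's exonic space."""
    n = len(gene.transcripts)
    counts: dict[int, int] = {}
    for t in gene.transcripts:
        for b in oracle_exon_bases(t.exons):
            counts[b] = counts.get(b, 0) + 1
    return {b: k / n for b, k in counts.items()}


def oracle_assign(fragments, gene: GeneModel, mode: str) -> dict[str, int]:
    """Brute-force per-base fragment-to-transcript assignment."""
    unions = {t.transcript_id: oracle_exon_bases(t.exons) for t in gene.transcripts}
    counts = {tid: 0 for tid in unions}
    for frag in fragments:
        frag_bases = set()
        for s, e in frag.blocks:
            frag_bases.update(range(s, e))
        for tid, union in unions.items():
            if mode == "contained":
                ok = frag_bases <= union
            else:
                ok = bool(frag_bases & union)
            if ok:
                counts[tid] += 1
    return counts


def oracle_library_size(path: str) -> int:
    """Distinct query names with a primary mapped alignment."""
    names = set()
    with pysam.AlignmentFile(path, "rb") as bam:
        for read in bam.fetch(until_eof=True):
            if not (read.is_unmapped or read.is_secondary or read.is_supplementary):
                names.add(read.query_name)
    return len(names)


def oracle_coverage(fragments, region_start: int, region_end: int) -> list[int]:
    depth = [0] * (region_end - region_start)
    for frag in fragments:
        covered = set()
        for s, e in frag.blocks:
            covered.update(range(max(s, region_start), min(e, region_end)))
        for b in covered:
            depth[b - region_start] += 1
    return depth


# ------------------------------------------------------------- BAM helper
def make_bam(path: str, records: list[tuple], references: dict[str, int]) -> str:
    """Write SAM records (name, flag, chrom, pos1, mapq, cigar, rnext,
    pnext, tlen) to a sorted, indexed BAM."""
    sam = str(path) + ".sam"
    with open(sam, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, length in references.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for name, flag, chrom, pos1, mapq, cigar, rnext, pnext, tlen in records:
            fh.write(
                f"{name}\t{flag}\t{chrom}\t{pos1}\t{mapq}\t{cigar}"
                f"\t{rnext}\t{pnext}\t{tlen}\t*\t*\n"
            )
    pysam.sort("-o", str(path), sam, catch_stdout=False)
    pysam.index(str(path))
    os.remove(sam)
    return str(path)


def proper_pair(name, chrom, pos1_r1, cigar_r1, pos1_r2, cigar_r2, mapq=60):
    """Records for one proper pair (both forward-math; flags 99/147)."""
    return [
        (name, 99, chrom, pos1_r1, mapq, cigar_r1, "=", pos1_r2, 0),
        (name, 147, chrom, pos1_r2, mapq, cigar_r2, "=", pos1_r1, 0),
    ]


# --------------------------------------------------------------- fixtures
@pytest.fixture
def two_isoform_gene() -> GeneModel:
    """chr1 gene: T1 has exons [100,200)+[300,400)+[500,600); T2 skips
    the middle exon."""
    g = GeneModel("GX")
    g.transcripts = [
        TranscriptModel(
            "GX.T1",
            "GX",
            [Exon("chr1", 100, 200), Exon("chr1", 300, 400), Exon("chr1", 500, 600)],
        ),
        TranscriptModel("GX.T2", "GX", [Exon("chr1", 100, 200), Exon("chr1", 500, 600)]),
    ]
    return g


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """20-gene, ~20k-fragment experiment, all four conditions x3."""
    d = tmp_path_factory.mktemp("smallsim")
    params = SimParams(seed=101, n_genes=20, n_fragments=20_000)
    genes = simulate_annotation(params, gff_path=str(d / "annotation.gff3"))
    sim = simulate_experiment(genes, params, str(d), gff_path=str(d / "annotation.gff3"))
    return genes, params, sim


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """The full study-condition simulation (~500 transcripts, 10%
    target transcripts at fold 4, 2e5 fragments/library, 4 conditions
    x 3 replicates)."""
    d = tmp_path_factory.mktemp("defaultsim")
    params = SimParams(seed=20)
    genes = simulate_annotation(params, gff_path=str(d / "annotation.gff3"))
    sim = simulate_experiment(genes, params, str(d), gff_path=str(d / "annotation.gff3"))
    return genes, params, sim
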