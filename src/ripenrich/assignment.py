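"""Per-gene fragment extraction from BAM and transcript assignment.

The counting unit is the *fragment* — one sequenced cDNA molecule,
i.e. a read pair pooled into a single set of aligned genomic blocks
(a singleton mate still counts as one fragment). Fragments are
extracted per annotated gene region and assigned to every transcript
whose exon model is compatible with them.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field

import pysam

from .annotation import GeneModel, TranscriptModel

logger = logging.getLogger(__name__)

DEFAULT_MIN_MAPQ = 10

CONDITIONS = ("WT_IP", "WT_TOTAL", "NULL_IP", "NULL_TOTAL")


@dataclass
class FragmentAlignment:
    """One fragment: merged aligned blocks pooled over both mates."""

    fragment_id: str
    chrom: str
    blocks: list[tuple[int, int]]
    mapq_min: int
    is_proper_pair: bool

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    def aligned_bases(self) -> int:
        return sum(e - s for s, e in self.blocks)


@dataclass
class LibraryQuant:
    """Per-library quantification result (filled by the quantify stage)."""

    library_id: str
    condition: str
    replicate: int
    counts: dict[str, int] = field(default_factory=dict)
    n_mapped_fragments: int = 0
    fpkm: dict[str, float] = field(default_factory=dict)
    n_assigned: int = 0
    n_unassigned: int = 0


def _merge_blocks(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    blocks.sort()
    merged: list[tuple[int, int]] = []
    for s, e in blocks:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def _usable(read: pysam.AlignedSegment) -> bool:
    return not (read.is_unmapped or read.is_secondary or read.is_supplementary)


def extract_gene_fragments(
    bam: pysam.AlignmentFile,
    gene: GeneModel,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    require_proper_pair: bool = False,
) -> list[FragmentAlignment]:
    """Fetch every fragment overlapping the gene region.

    Mates are paired by query name and their aligned blocks merged;
    unmapped, secondary and supplementary records are ignored. A mate
    that lies entirely outside the fetch window is retrieved by a
    targeted fetch at its recorded position so the fragment's blocks
    are complete. Fragments failing the MAPQ (min over mates) or
    proper-pair filters are dropped. Requires an indexed BAM; a gene
    chromosome missing from the header yields an empty list.
    """
    if gene.chrom not in bam.references:
        logger.warning("chromosome %r absent from BAM header", gene.chrom)
        return []
    region_start, region_end = gene.region_start, gene.region_end

    per_name: dict[str, list[pysam.AlignedSegment]] = {}
    for read in bam.fetch(gene.chrom, region_start, region_end):
        if _usable(read):
            per_name.setdefault(read.query_name, []).append(read)

    fragments: list[FragmentAlignment] = []
    for name, reads in per_name.items():
        # fetch the mate if it is mapped but outside the window
        first = reads[0]
        if (
            len(reads) == 1
            and first.is_paired
            and not first.mate_is_unmapped
            and first.next_reference_name == gene.chrom
        ):
            mpos = first.next_reference_start
            if not (region_start <= mpos < region_end):
                for cand in bam.fetch(gene.chrom, mpos, mpos + 1):
                    if (
                        cand.query_name == name
                        and _usable(cand)
                        and cand.is_read1 != first.is_read1
                    ):
                        reads.append(cand)
                        break
        blocks: list[tuple[int, int]] = []
        mapq = 255
        proper = True
        for r in reads:
            blocks.extend(r.get_blocks())
            mapq = min(mapq, r.mapping_quality)
            proper = proper and r.is_proper_pair
        blocks = _merge_blocks(blocks)
        if not blocks:
            continue
        if mapq < min_mapq or (require_proper_pair and not proper):
            continue
        if not any(s < region_end and e > region_start for s, e in blocks):
            continue
        fragments.append(FragmentAlignment(name, gene.chrom, blocks, mapq, proper))

    fragments.sort(key=lambda f: (f.start, f.fragment_id))
    return fragments


class _ExonUnion:
    """Merged exon union of a transcript with bisect-based lookups."""

    __slots__ = ("starts", "ends")

    def __init__(self, t: TranscriptModel):
        self.starts = [e.start for e in t.exons]
        self.ends = [e.end for e in t.exons]

    def contains(self, s: int, e: int) -> bool:
        i = bisect_right(self.starts, s) - 1
        return i >= 0 and e <= self.ends[i]

    def overlaps(self, s: int, e: int) -> bool:
        i = bisect_right(self.starts, e - 1) - 1
        return i >= 0 and self.ends[i] > s


def assign_fragments(
    fragments: list[FragmentAlignment],
    gene: GeneModel,
    mode: str = "contained",
) -> tuple[dict[str, int], int]:
    """Count fragments per transcript of one gene.

    ``contained`` (default): a fragment counts for a transcript iff
    every aligned base of every block lies inside the transcript's exon
    union — the strict reading of assigning reads "to the exons".
    ``overlap``: one aligned base inside the union suffices. A fragment
    compatible with k isoforms increments all k counts; fragments
    compatible with none are tallied as unassigned (second return
    value).
    """
    if mode not in ("contained", "overlap"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    unions = [(t.transcript_id, _ExonUnion(t)) for t in gene.transcripts]
    counts = {tid: 0 for tid, _ in unions}
    unassigned = 0
    contained_mode = mode == "contained"
    for frag in fragments:
        hit = False
        for tid, union in unions:
            if contained_mode:
                ok = all(union.contains(s, e) for s, e in frag.blocks)
            else:
                ok = any(union.overlaps(s, e) for s, e in frag.blocks)
            if ok:
                counts[tid] += 1
                hit = True
        if not hit:
            unassigned += 1
    return counts, unassigned


def library_size(bam: pysam.AlignmentFile) -> int:
    """Total mapped fragments N: distinct query names with a primary
    mapped alignment, a pair counted once. This is the "per million
    mapped reads" denominator of FPKM."""
    n = 0
    seen_unpaired: set[str] = set()
    bam.reset()
    for read in bam.fetch(until_eof=True):
        if not _usable(read):
            continue
        if read.is_paired:
            if read.is_read1:
                n += 1
            elif read.mate_is_unmapped:
                # mapped read2 whose read1 never appears as mapped
                n += 1
        else:
            if read.query_name not in seen_unpaired:
                seen_unpaired.add(read.query_name)
                n += 1
    return n
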