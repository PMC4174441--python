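"""Gene/transcript/exon models parsed from GFF3 annotation.

The pipeline quantifies abundance per *exon model*: the union of a
transcript's exons. All coordinates are held 0-based half-open
internally; GFF3 I/O (1-based inclusive) is the only conversion
boundary, so arithmetic against BAM records (0-based) needs no offsets.

Only ``gene``, ``mRNA``/``transcript`` and ``exon`` features enter the
model; everything else in the annotation is ignored. Overlapping exon
records within one transcript are merged so the exon-model length is
well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

_TRANSCRIPT_TYPES = {"mRNA", "transcript"}


@dataclass(frozen=True)
class Exon:
    """A single exonic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid exon interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """One annotated isoform: an ordered, merged chain of exons."""

    transcript_id: str
    gene_id: str
    exons: list[Exon] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.exons:
            self.exons = _merge_exons(self.exons)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def exon_model_length(self) -> int:
        return exon_model_length(self)


@dataclass
class GeneModel:
    """A gene region and the isoforms annotated within it."""

    gene_id: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def region_start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def region_end(self) -> int:
        return max(t.end for t in self.transcripts)


def _merge_exons(exons: Sequence[Exon]) -> list[Exon]:
    """Sort by start and merge overlapping or abutting records."""
    exs = sorted(exons, key=lambda e: (e.start, e.end))
    chroms = {e.chrom for e in exs}
    strands = {e.strand for e in exs}
    if len(chroms) > 1 or len(strands) > 1:
        raise ValueError("exons of one transcript must share chrom and strand")
    merged: list[Exon] = []
    for e in exs:
        if merged and e.start <= merged[-1].end:
            last = merged[-1]
            if e.end > last.end:
                merged[-1] = Exon(last.chrom, last.start, e.end, last.strand)
        else:
            merged.append(e)
    return merged


def exon_model_length(t: TranscriptModel) -> int:
    """Total bases in the union of the transcript's exons.

    This is the length denominator of FPKM ("per kilobase of exon
    model"); exon records are merged before summation.
    """
    if not t.exons:
        raise ValueError(f"transcript {t.transcript_id} has no exons")
    return sum(len(e) for e in _merge_exons(t.exons))


def exon_occurrence(g: GeneModel) -> dict[tuple[int, int], float]:
    """Partition the gene's exonic space by isoform membership.

    Returns maximal disjoint intervals (0-based half-open) mapped to the
    fraction of the gene's transcripts whose exon model contains the
    interval. Used to shade exon rectangles in the coverage figures:
    constitutive exons are drawn at full density, isoform-specific
    exons proportionally lighter.
    """
    n = len(g.transcripts)
    breaks: set[int] = set()
    for t in g.transcripts:
        for e in t.exons:
            breaks.add(e.start)
            breaks.add(e.end)
    edges = sorted(breaks)
    out: dict[tuple[int, int], float] = {}
    for a, b in zip(edges, edges[1:]):
        k = sum(
            1
            for t in g.transcripts
            if any(e.start <= a and b <= e.end for e in t.exons)
        )
        if k:
            out[(a, b)] = k / n
    return out


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff(path: str) -> list[GeneModel]:
    """Parse a GFF3 annotation into gene models.

    Exon features attach to transcripts through their ``Parent``
    attribute (an exon with k parents yields k attachments); transcripts
    link to genes through ``Parent`` or a ``gene_id`` attribute. Lines
    with ``end < start`` and exons with unknown parents are skipped with
    a warning. Raises ``ValueError`` if no gene model can be built.
    """
    tx_gene: dict[str, str] = {}
    tx_exons: dict[str, list[Exon]] = {}
    gene_order: list[str] = []
    seen_genes: set[str] = set()
    pending_exons: list[tuple[str, Exon]] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                logger.warning("%s:%d: not 9 tab-separated fields, skipped", path, lineno)
                continue
            chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attr_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                logger.warning("%s:%d: non-integer coordinates, skipped", path, lineno)
                continue
            if end1 < start1:
                logger.warning("%s:%d: end < start, skipped", path, lineno)
                continue
            # 1-based inclusive -> 0-based half-open
            start, end = start1 - 1, end1
            attrs = _parse_attributes(attr_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid and gid not in seen_genes:
                    seen_genes.add(gid)
                    gene_order.append(gid)
            elif ftype in _TRANSCRIPT_TYPES:
                tid = attrs.get("ID")
                gid = attrs.get("Parent") or attrs.get("gene_id")
                if tid is None or gid is None:
                    logger.warning("%s:%d: transcript without ID/Parent, skipped", path, lineno)
                    continue
                tx_gene[tid] = gid
                tx_exons.setdefault(tid, [])
                if gid not in seen_genes:
                    seen_genes.add(gid)
                    gene_order.append(gid)
            elif ftype == "exon":
                parents = attrs.get("Parent", "")
                if not parents:
                    logger.warning("%s:%d: exon without Parent, skipped", path, lineno)
                    continue
                exon = Exon(chrom, start, end, strand)
                for parent in parents.split(","):
                    pending_exons.append((parent.strip(), exon))

    for parent, exon in pending_exons:
        if parent in tx_exons:
            tx_exons[parent].append(exon)
        else:
            logger.warning("exon with unknown Parent %r, skipped", parent)

    genes: dict[str, GeneModel] = {}
    for tid, exons in tx_exons.items():
        if not exons:
            logger.warning("transcript %r has no exons, dropped", tid)
            continue
        gid = tx_gene[tid]
        genes.setdefault(gid, GeneModel(gid)).transcripts.append(
            TranscriptModel(tid, gid, exons)
        )

    models = [genes[gid] for gid in gene_order if gid in genes]
    if not models:
        raise ValueError(f"no gene models could be built from {path}")
    for g in models:
        g.transcripts.sort(key=lambda t: t.transcript_id)
    return models


def apply_chrom_aliases(
    genes: list[GeneModel], aliases: dict[str, str]
) -> list[GeneModel]:
    """Rename chromosomes in place per an annotation->BAM alias map.

    Matching elsewhere is exact-string; this is the one hook for naming
    drift between an annotation release and the alignment reference.
    """
    if not aliases:
        return genes
    for g in genes:
        for t in g.transcripts:
            t.exons = [
                Exon(aliases.get(e.chrom, e.chrom), e.start, e.end, e.strand)
                for e in t.exons
            ]
    return genes


def write_gff(genes: Iterable[GeneModel], path: str, source: str = "ripenrich") -> None:
    """Write gene models back to GFF3 (the dialect ``read_gff`` accepts)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.region_start + 1}\t{g.region_end}"
                f"\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for t in g.transcripts:
                fh.write(
                    f"{t.chrom}\t{source}\tmRNA\t{t.start + 1}\t{t.end}"
                    f"\t.\t{t.strand}\t.\tID={t.transcript_id};Parent={t.gene_id}\n"
                )
                for i, e in enumerate(t.exons, 1):
                    fh.write(
                        f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}"
                        f"\t.\t{e.strand}\t.\tID={t.transcript_id}.e{i};Parent={t.transcript_id}\n"
                    )
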