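"""FPKM quantification per library and replicate aggregation.

FPKM — fragments per kilobase of exon model per million mapped
fragments — for transcript t in one library is

    FPKM_t = F_t * 1e9 / (L_t * N)

with F_t the fragments assigned to t, L_t the exon-model length in
bases, and N the library's total mapped fragments (genome-wide, not
only assigned ones). Replicate libraries of one condition are
aggregated as the arithmetic mean of per-replicate FPKMs; a
pooled-count mode is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pysam

from .annotation import GeneModel
from .assignment import (
    DEFAULT_MIN_MAPQ,
    LibraryQuant,
    assign_fragments,
    extract_gene_fragments,
    library_size,
)


def fpkm(fragment_count: float, exon_model_length: int, n_mapped: int) -> float:
    """Closed-form FPKM; raises on a non-positive length or library size."""
    if exon_model_length <= 0:
        raise ValueError(f"exon model length must be > 0, got {exon_model_length}")
    if n_mapped <= 0:
        raise ValueError(f"mapped fragment count must be > 0, got {n_mapped}")
    if fragment_count < 0:
        raise ValueError("fragment count must be >= 0")
    return fragment_count * 1e9 / (exon_model_length * n_mapped)


def quantify_library(
    bam_path: str,
    genes: list[GeneModel],
    condition: str = "",
    replicate: int = 1,
    library_id: str | None = None,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    require_proper_pair: bool = False,
    mode: str = "contained",
) -> LibraryQuant:
    """Extract, assign and FPKM-quantify every annotated transcript.

    Runs the per-gene extraction loop over the whole annotation,
    computes N once for the library, and fills an FPKM for every
    transcript (0 when its count is 0).
    """
    lib = LibraryQuant(
        library_id=library_id or bam_path,
        condition=condition,
        replicate=replicate,
    )
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        for gene in genes:
            frags = extract_gene_fragments(
                bam, gene, min_mapq=min_mapq, require_proper_pair=require_proper_pair
            )
            counts, unassigned = assign_fragments(frags, gene, mode=mode)
            lib.counts.update(counts)
            lib.n_unassigned += unassigned
            lib.n_assigned += len(frags) - unassigned
        lib.n_mapped_fragments = library_size(bam)

    lengths = {
        t.transcript_id: t.exon_model_length for g in genes for t in g.transcripts
    }
    n = lib.n_mapped_fragments
    for tid, count in lib.counts.items():
        lib.fpkm[tid] = fpkm(count, lengths[tid], n) if n > 0 else 0.0
    return lib


@dataclass
class FPKMTable:
    """Replicate and mean FPKMs for one condition."""

    condition: str
    replicate_fpkm: pd.DataFrame  # index transcript_id, one column per replicate
    mean_fpkm: pd.Series
    n_replicates: int

    def to_frame(self, tx2gene: dict[str, str] | None = None) -> pd.DataFrame:
        df = self.replicate_fpkm.copy()
        df.insert(0, "condition", self.condition)
        if tx2gene is not None:
            df.insert(0, "gene_id", [tx2gene.get(t, "") for t in df.index])
        df["mean_fpkm"] = self.mean_fpkm
        return df


def aggregate_replicates(
    libs: list[LibraryQuant],
    pooled: bool = False,
    lengths: dict[str, int] | None = None,
) -> FPKMTable:
    """Combine replicate libraries of one condition.

    Default: arithmetic mean of per-replicate FPKMs (replicate values
    retained). ``pooled=True`` instead recomputes FPKM from summed
    counts and summed library sizes; it needs the exon-model
    ``lengths`` map.
    """
    if not libs:
        raise ValueError("need at least one replicate library")
    conditions = {lib.condition for lib in libs}
    if len(conditions) != 1:
        raise ValueError(f"mixed conditions in aggregation: {sorted(conditions)}")
    condition = libs[0].condition
    cols = {f"rep{lib.replicate}": pd.Series(lib.fpkm, dtype=float) for lib in libs}
    df = pd.DataFrame(cols).fillna(0.0).sort_index()
    if pooled:
        if lengths is None:
            raise ValueError("pooled aggregation requires exon-model lengths")
        total_n = sum(lib.n_mapped_fragments for lib in libs)
        pooled_counts = (
            pd.DataFrame({i: pd.Series(lib.counts, dtype=float) for i, lib in enumerate(libs)})
            .fillna(0.0)
            .sum(axis=1)
            .sort_index()
        )
        mean = pd.Series(
            {t: fpkm(c, lengths[t], total_n) for t, c in pooled_counts.items()}
        ).sort_index()
    else:
        mean = df.mean(axis=1)
    return FPKMTable(condition, df, mean, len(libs))


def gene_level_fpkm(table: FPKMTable, tx2gene: dict[str, str]) -> pd.Series:
    """Gene-level roll-up for reporting: max over the gene's transcripts."""
    s = table.mean_fpkm.copy()
    genes = pd.Series({t: tx2gene[t] for t in s.index})
    return s.groupby(genes).max()
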