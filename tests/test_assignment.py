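"""Fragment extraction from BAM and transcript assignment."""

import pysam
import pytest

from ripenrich.assignment import (
    assign_fragments,
    extract_gene_fragments,
    library_size,
)
from ripenrich.annotation import read_gff

from conftest import make_bam, oracle_assign, oracle_library_size, proper_pair

REFS = {"chr1": 10_000, "chr2": 10_000}


def _fetch(bam_path, gene, **kw):
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        return extract_gene_fragments(bam, gene, **kw)


def test_no_reads_on_chrom_gives_empty(tmp_path, two_isoform_gene):
    path = make_bam(tmp_path / "a.bam", proper_pair("q", "chr2", 1, "50M", 61, "50M"), REFS)
    assert _fetch(path, two_isoform_gene) == []


def test_missing_chromosome_warns_and_returns_empty(tmp_path, two_isoform_gene, caplog):
    path = make_bam(tmp_path / "a.bam", proper_pair("q", "chr2", 1, "50M", 61, "50M"),
                    {"chr2": 10_000})
    with caplog.at_level("WARNING"):
        assert _fetch(path, two_isoform_gene) == []
    assert any("absent" in m for m in caplog.messages)


def test_one_pair_pools_both_mates_blocks(tmp_path, two_isoform_gene):
    # mates at 0-based 120..170 and 520..570 (1-based 121/521)
    path = make_bam(tmp_path / "a.bam", proper_pair("frag", "chr1", 121, "50M", 521, "50M"), REFS)
    (frag,) = _fetch(path, two_isoform_gene)
    assert frag.blocks == [(120, 170), (520, 570)]
    assert frag.is_proper_pair and frag.mapq_min == 60


def test_spliced_cigar_yields_split_blocks(tmp_path, two_isoform_gene):
    # read spans the T2 junction: 40M then 300N skip then 10M
    recs = proper_pair("s", "chr1", 161, "40M300N10M", 521, "50M")
    path = make_bam(tmp_path / "a.bam", recs, REFS)
    (frag,) = _fetch(path, two_isoform_gene)
    assert frag.blocks == [(160, 200), (500, 510), (520, 570)]


def test_overlapping_mates_count_bases_once(tmp_path, two_isoform_gene):
    recs = proper_pair("o", "chr1", 121, "50M", 141, "50M")
    path = make_bam(tmp_path / "a.bam", recs, REFS)
    (frag,) = _fetch(path, two_isoform_gene)
    assert frag.blocks == [(120, 190)]


def test_mapq_filter_uses_min_over_mates(tmp_path, two_isoform_gene):
    recs = [
        ("lo", 99, "chr1", 121, 5, "50M", "=", 521, 0),
        ("lo", 147, "chr1", 521, 60, "50M", "=", 121, 0),
    ]
    path = make_bam(tmp_path / "a.bam", recs, REFS)
    assert _fetch(path, two_isoform_gene, min_mapq=10) == []
    assert len(_fetch(path, two_isoform_gene, min_mapq=0)) == 1


def test_secondary_and_unmapped_excluded(tmp_path, two_isoform_gene):
    recs = [
        ("sec", 99 | 0x100, "chr1", 121, 60, "50M", "=", 521, 0),
        ("unm", 4, "chr1", 121, 0, "*", "*", 0, 0),
    ]
    path = make_bam(tmp_path / "a.bam", recs, REFS)
    assert _fetch(path, two_isoform_gene) == []


def test_mate_outside_region_is_recovered(tmp_path, two_isoform_gene):
    """A mate aligned beyond the gene region still contributes its
    blocks to the fragment."""
    recs = proper_pair("far", "chr1", 551, "50M", 901, "50M")
    path = make_bam(tmp_path / "a.bam", recs, REFS)
    (frag,) = _fetch(path, two_isoform_gene)
    assert frag.blocks == [(550, 600), (900, 950)]


def test_shared_exon_fragment_counts_for_both_isoforms(tmp_path, two_isoform_gene):
    path = make_bam(tmp_path / "a.bam", proper_pair("sh", "chr1", 111, "40M", 151, "40M"), REFS)
    frags = _fetch(path, two_isoform_gene)
    counts, unassigned = assign_fragments(frags, two_isoform_gene)
    assert counts == {"GX.T1": 1, "GX.T2": 1} and unassigned == 0


def test_contained_mode_respects_intron_structure(tmp_path):
    """A contiguous block crossing isoform A's intron, but inside the
    retained-intron isoform B, is contained only in B; in overlap mode
    both isoforms count."""
    from ripenrich.annotation import Exon, GeneModel, TranscriptModel

    g = GeneModel("GR")
    g.transcripts = [
        TranscriptModel("GR.A", "GR", [Exon("chr1", 100, 200), Exon("chr1", 400, 500)]),
        TranscriptModel("GR.B", "GR", [Exon("chr1", 100, 500)]),
    ]
    recs = proper_pair("j", "chr1", 181, "50M", 211, "50M")  # block (180, 260)
    path = make_bam(tmp_path / "a.bam", recs, REFS)
    frags = _fetch(path, g)
    contained, _ = assign_fragments(frags, g, mode="contained")
    overlap, _ = assign_fragments(frags, g, mode="overlap")
    assert contained == {"GR.A": 0, "GR.B": 1}
    assert overlap == {"GR.A": 1, "GR.B": 1}


def test_intronic_fragment_is_unassigned(tmp_path, two_isoform_gene):
    path = make_bam(tmp_path / "a.bam", proper_pair("i", "chr1", 211, "40M", 231, "40M"), REFS)
    frags = _fetch(path, two_isoform_gene)
    counts, unassigned = assign_fragments(frags, two_isoform_gene)
    assert sum(counts.values()) == 0 and unassigned == 1


def test_unknown_mode_rejected(two_isoform_gene):
    with pytest.raises(ValueError):
        assign_fragments([], two_isoform_gene, mode="fuzzy")


@pytest.mark.parametrize("mode", ["contained", "overlap"])
def test_simulated_counts_match_brute_force_oracle(small_sim, mode):
    genes, _, sim = small_sim
    bam_path = sim.manifest.path.iloc[0]
    for gene in genes[:6]:
        frags = _fetch(bam_path, gene)
        counts, _ = assign_fragments(frags, gene, mode=mode)
        assert counts == oracle_assign(frags, gene, mode)


def test_contained_counts_never_exceed_overlap(small_sim):
    genes, _, sim = small_sim
    bam_path = sim.manifest.path.iloc[0]
    for gene in genes:
        frags = _fetch(bam_path, gene)
        contained, _ = assign_fragments(frags, gene, mode="contained")
        overlap, _ = assign_fragments(frags, gene, mode="overlap")
        for tid in contained:
            assert contained[tid] <= overlap[tid] <= len(frags)


def test_extraction_matches_simulator_truth(small_sim):
    """Every simulated fragment whose source transcript lies in a gene
    is recovered for that gene (names encode the source)."""
    genes, _, sim = small_sim
    bam_path = sim.manifest.path.iloc[0]
    lib_id = "WT_IP_rep1"
    truth = sim.truth.set_index("transcript_id")
    gene = genes[0]
    tids = {t.transcript_id for t in gene.transcripts}
    expected_n = int(truth.loc[sorted(tids), f"count_{lib_id}"].sum())
    frags = _fetch(bam_path, gene)
    from_gene = [f for f in frags if f.fragment_id.split("|")[0] in tids]
    assert len(from_gene) == expected_n


def test_library_size_empty_bam(tmp_path):
    path = make_bam(tmp_path / "e.bam", [], REFS)
    with pysam.AlignmentFile(path, "rb") as bam:
        assert library_size(bam) == 0


def test_library_size_counts_pairs_once_and_singletons(tmp_path):
    recs = []
    for i in range(30):
        recs += proper_pair(f"p{i}", "chr1", 1 + i, "50M", 201 + i, "50M")
    # singletons: unpaired reads plus a paired read with unmapped mate
    for i in range(7):
        recs.append((f"s{i}", 0, "chr1", 501 + i, 60, "50M", "*", 0, 0))
    recs.append(("half", 0x1 | 0x8 | 0x40, "chr1", 701, 60, "50M", "=", 701, 0))
    path = make_bam(tmp_path / "m.bam", recs, REFS)
    with pysam.AlignmentFile(path, "rb") as bam:
        n = library_size(bam)
    assert n == 38 == oracle_library_size(path)


def test_library_size_matches_oracle_on_simulation(small_sim):
    _, params, sim = small_sim
    path = sim.manifest.path.iloc[0]
    with pysam.AlignmentFile(path, "rb") as bam:
        assert library_size(bam) == oracle_library_size(path) == params.n_fragments
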