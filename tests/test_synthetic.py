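"""Generator contracts: determinism, conservation, mapping-back."""

import os

import pysam
import pytest

from ripenrich.annotation import read_gff
from ripenrich.synthetic import SimParams, simulate_annotation, simulate_experiment

from conftest import oracle_exon_bases


def test_seed_is_mandatory_and_params_validated():
    with pytest.raises(ValueError):
        SimParams(seed=None)
    with pytest.raises(ValueError):
        SimParams(seed=1, n_genes=0)
    with pytest.raises(ValueError):
        SimParams(seed=1, target_fraction=1.5)


def test_single_isoform_gene_occurrence_all_one():
    from ripenrich.annotation import exon_occurrence

    params = SimParams(seed=2, n_genes=1, isoforms_per_gene=(1, 1))
    (gene,) = simulate_annotation(params)
    assert set(exon_occurrence(gene).values()) == {1.0}


def test_genes_do_not_overlap_and_isoforms_share_an_exon():
    params = SimParams(seed=9, n_genes=30)
    genes = simulate_annotation(params)
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for gs in by_chrom.values():
        for a, b in zip(gs, gs[1:]):
            assert a.region_end <= b.region_start
    for g in genes:
        shared = set.intersection(
            *(
                {(e.start, e.end) for e in t.exons}
                for t in g.transcripts
            )
        )
        assert shared, f"{g.gene_id} isoforms share no exon"


def test_infeasible_chromosome_length_raises():
    params = SimParams(seed=1, n_genes=50, n_chromosomes=1, chromosome_length=10_000)
    with pytest.raises(ValueError, match="infeasible"):
        simulate_annotation(params)


def test_annotation_gff_round_trip(tmp_path):
    params = SimParams(seed=5, n_genes=3, isoforms_per_gene=(1, 3))
    path = str(tmp_path / "ann.gff3")
    genes = simulate_annotation(params, gff_path=path)
    back = read_gff(path)
    assert [g.gene_id for g in back] == [g.gene_id for g in genes]
    for g1, g2 in zip(genes, back):
        for t1, t2 in zip(g1.transcripts, g2.transcripts):
            assert [(e.start, e.end) for e in t1.exons] == [
                (e.start, e.end) for e in t2.exons
            ]


def test_same_seed_twice_identical_gff_bytes(tmp_path):
    params = SimParams(seed=33, n_genes=8)
    a, b = str(tmp_path / "a.gff3"), str(tmp_path / "b.gff3")
    simulate_annotation(params, gff_path=a)
    simulate_annotation(params, gff_path=b)
    assert open(a, "rb").read() == open(b, "rb").read()


@pytest.fixture(scope="module")
def tiny_sim(tmp_path_factory):
    d = tmp_path_factory.mktemp("tiny")
    params = SimParams(seed=77, n_genes=6, n_fragments=2000)
    genes = simulate_annotation(params)
    sim = simulate_experiment(
        genes, params, str(d), conditions=("WT_IP", "WT_TOTAL"), n_replicates=2
    )
    return genes, params, sim


def test_counts_conserved_per_library(tiny_sim):
    _, params, sim = tiny_sim
    for col in [c for c in sim.truth.columns if c.startswith("count_")]:
        assert sim.truth[col].sum() == params.n_fragments


def test_realized_counts_match_bam_content(tiny_sim):
    """Generator bookkeeping: the truth table's per-library counts equal
    the fragments actually present in the BAM (names encode the source
    transcript)."""
    _, _, sim = tiny_sim
    row = sim.manifest.iloc[0]
    lib_id = f"{row.condition}_rep{row.replicate}"
    per_tx: dict[str, set] = {}
    with pysam.AlignmentFile(row.path, "rb") as bam:
        for read in bam.fetch(until_eof=True):
            tid = read.query_name.split("|")[0]
            per_tx.setdefault(tid, set()).add(read.query_name)
    truth = sim.truth.set_index("transcript_id")
    for tid, names in per_tx.items():
        assert len(names) == truth.loc[tid, f"count_{lib_id}"]
    assert truth[f"count_{lib_id}"].sum() == sum(len(v) for v in per_tx.values())


def test_fragments_map_back_into_source_exon_union(tiny_sim):
    """Every aligned block of every simulated read lies inside its source
    transcript's exon union (so contained-mode assignment always
    recovers the source transcript)."""
    genes, _, sim = tiny_sim
    unions = {
        t.transcript_id: oracle_exon_bases(t.exons)
        for g in genes
        for t in g.transcripts
    }
    checked = 0
    for path in sim.manifest.path:
        with pysam.AlignmentFile(path, "rb") as bam:
            for read in bam.fetch(until_eof=True):
                tid = read.query_name.split("|")[0]
                for s, e in read.get_blocks():
                    assert set(range(s, e)) <= unions[tid]
                checked += 1
    assert checked > 0


def test_single_transcript_genome_gets_every_fragment(tmp_path):
    params = SimParams(seed=4, n_genes=1, isoforms_per_gene=(1, 1), n_fragments=500)
    genes = simulate_annotation(params)
    sim = simulate_experiment(
        genes, params, str(tmp_path), conditions=("WT_TOTAL",), n_replicates=1
    )
    tid = genes[0].transcripts[0].transcript_id
    assert sim.truth.set_index("transcript_id").loc[tid, "count_WT_TOTAL_rep1"] == 500

    from ripenrich.quantify import quantify_library

    lib = quantify_library(sim.manifest.path.iloc[0], genes)
    assert lib.counts[tid] == 500 and lib.n_mapped_fragments == 500


def test_short_transcript_excluded_with_warning(tmp_path, caplog):
    params = SimParams(
        seed=6,
        n_genes=3,
        isoforms_per_gene=(1, 1),
        exons_per_transcript=(2, 2),
        exon_length=(100, 100),
        read_length=150,  # 200 bp transcripts survive; shrink one below
    )
    genes = simulate_annotation(params)
    # force one transcript under the read length
    from ripenrich.annotation import Exon

    t = genes[0].transcripts[0]
    e0 = t.exons[0]
    t.exons = [Exon(e0.chrom, e0.start, e0.start + 100, e0.strand)]
    with caplog.at_level("WARNING"):
        sim = simulate_experiment(
            genes, params, str(tmp_path), conditions=("WT_TOTAL",), n_replicates=1
        )
    assert any("shorter than the read length" in m for m in caplog.messages)
    assert t.transcript_id not in set(sim.truth.transcript_id)


def test_same_seed_identical_truth_and_records(tmp_path):
    params = SimParams(seed=55, n_genes=5, n_fragments=1500)
    genes = simulate_annotation(params)
    sims = []
    for sub in ("a", "b"):
        d = tmp_path / sub
        sims.append(
            simulate_experiment(genes, params, str(d), conditions=("WT_IP",), n_replicates=1)
        )
    assert (
        open(sims[0].truth_path, "rb").read() == open(sims[1].truth_path, "rb").read()
    )
    views = []
    for sim in sims:
        with pysam.AlignmentFile(sim.manifest.path.iloc[0], "rb") as bam:
            views.append([r.to_string() for r in bam.fetch(until_eof=True)])
    assert views[0] == views[1]
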