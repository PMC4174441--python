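# ripenrich

Identification of the transcripts bound by an RNA-binding protein from
RIP-Seq (RNA immunoprecipitation followed by sequencing), with the qPCR
arithmetic used to validate hits. The design it analyses is the classic
dual-control pull-down: IP and total-RNA (input) libraries from
wild-type lysate, plus the same pair from a null mutant lacking the
protein, each in triplicate. A transcript is called a target when it is
enriched in the wild-type IP **and not** in the null-mutant IP — the
second condition removes RNAs that stick to beads or antibody
nonspecifically.

## Method

For every annotated transcript *t* in every library, abundance is
quantified as FPKM (fragments per kilobase of exon model per million
mapped fragments):

    FPKM_t = F_t · 10⁹ / (L_t · N)

where `F_t` is the number of sequenced fragments (read pairs, counted
once per pair) whose aligned blocks are contained in the transcript's
exon union, `L_t` is the exon-model length (bases in the union of the
transcript's exons) and `N` is the library's total mapped fragments.
Replicates are aggregated as the arithmetic mean of per-replicate
FPKMs. The selection statistic is

    E = log₂((FPKM_IP + ε) / (FPKM_input + ε)),   ε = 0.1

computed once against the wild-type IP (`E_wt`) and once against the
null-mutant IP (`E_null`). A transcript is selected when
`FPKM_input ≥ τ` (abundance floor, default 1), `E_wt ≥ c` and
`E_null < c` (default cutoff c = 1, i.e. 2-fold). Selected transcripts
are ranked by `E_wt` descending. Per-gene figures show the three IP
replicate coverage tracks in red, green and blue over the gene model,
with each exon shaded by the fraction of annotated isoforms containing
it.

The `qpcr` module implements the companion validation arithmetic:
triplicate Ct means, relative quantification by 2^−ΔΔCt against a
reference transcript (e.g. rp49), and RIP recovery as percent of input,
`100 · f · 2^(Ct_input − Ct_IP)` with input aliquot fraction `f`
(0.10 for a 10% input).

Because no public accession exists for the original sequencing data,
the package ships a synthetic-data generator (`ripenrich.synthetic`)
that emulates the full design — multi-isoform annotation, spliced
paired-end alignments for all four conditions in triplicate, a truth
table of abundances and enrichment factors — so the entire analysis is
exercisable and testable offline.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
default synthetic universe (200 genes / ~514 transcripts, 12 libraries
of 200,000 fragments, 10% of transcripts enriched 4-fold in WT IP):

```sh
python analysis/01_simulate.py        # writes scratch/analysis/sim/
python analysis/02_quantify.py        # FPKM tables + results/library_stats.tsv
python analysis/03_enrich.py          # results/ranked_table.tsv + summary
python analysis/04_plot_coverage.py   # results/coverage_<gene>.svg
python analysis/05_qpcr.py            # results/qpcr_percent_input.tsv
```

`03_enrich.py` prints:

```
53 of 514 transcripts selected -> results/ranked_table.tsv
mean log2 enrichment over true targets: 1.999 (truth 2.0)
sensitivity 1.000, specificity 1.000
top of the ranked table:
 rank transcript_id gene_id  log2_enrichment_wt  log2_enrichment_null
    1      SG009.T3   SG009            2.089834              0.100611
    2      SG008.T1   SG008            2.082347             -0.064278
```

Every simulated target gene carries a true log₂ enrichment of 2
(4-fold), so the mean estimate of 1.999 says the FPKM/enrichment chain
is essentially unbiased at this depth, and the selection recovered all
53 targets with no false positives. `E_null` near 0 for the hits shows
the null-mutant filter behaving as a proper negative control.

The same steps are available as a CLI
(`ripenrich simulate|quantify|run|plot|stats|qpcr`) driven by YAML
configs; `ripenrich run --config run.yaml` executes
quantify → enrich → plots in one go and drops a metadata sidecar
recording all parameters.

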