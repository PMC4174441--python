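#!/usr/bin/env python
"""Render coverage figures for the two top-ranked target genes.

Three WT-IP replicate depth tracks (red, green, blue) over the gene
model, exons shaded by the fraction of isoforms containing them.
SVGs go to results/.
"""

import os

import pandas as pd

from ripenrich.annotation import read_gff
from ripenrich.pipeline import RunConfig, plot_genes, read_manifest

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
SIMDIR = os.path.join(ROOT, "scratch", "analysis", "sim")
RESULTS = os.path.join(ROOT, "results")


def main() -> None:
    os.makedirs(RESULTS, exist_ok=True)
    ranked = pd.read_csv(os.path.join(RESULTS, "ranked_table.tsv"), sep="\t")
    top_genes = list(dict.fromkeys(ranked.gene_id))[:2]
    genes = read_gff(os.path.join(SIMDIR, "annotation.gff3"))
    manifest = read_manifest(os.path.join(SIMDIR, "manifest.tsv"))
    cfg = RunConfig(gff="", manifest="", outdir=RESULTS, plot_genes=top_genes)
    written = plot_genes(cfg, genes, manifest)
    for path in written:
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
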