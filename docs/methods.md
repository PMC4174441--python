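# Methods

## Quantification model

The counting unit throughout is the *fragment*: one sequenced cDNA
molecule, i.e. a read pair whose aligned blocks are pooled (bases
covered by both mates count once). A singleton mate — its pair
unmapped — still counts as one fragment. Fragments are extracted per
annotated gene region from a coordinate-sorted, indexed BAM;
unmapped, secondary and supplementary records are ignored, and a mate
aligned outside the gene window is retrieved by a targeted fetch so
fragment blocks are always complete.

Assignment of a fragment to a transcript defaults to **contained**
mode: every aligned base of every block must lie inside the
transcript's exon union. This is the strict reading of assigning reads
"to the exons" of a transcript; the laxer **overlap** mode (one aligned
base suffices) is exposed and tested alongside, and contained-mode
counts can never exceed overlap-mode counts. A fragment compatible
with k isoforms increments all k — there is no fractional allocation
and no isoform deconvolution (a deliberate non-goal; see
*Limitations*). Counting is unstranded, matching random-hexamer
library chemistry. The default mapping-quality floor is 10 (min over
mates), configurable; duplicate marking is not performed.

FPKM for transcript t is `F_t · 1e9 / (L_t · N)` with `L_t` the
exon-model length (overlapping exon records merged before summation,
so L is well defined) and `N` the library's genome-wide mapped
fragments — all distinct fragments with a primary mapped alignment,
not only those assigned to the annotation. Replicates are aggregated
as the arithmetic mean of per-replicate FPKMs, keeping the replicate
values; pooled-count aggregation (summed counts over summed N) is
available behind a flag for users who prefer depth-weighted means.

## Selection statistic and filters

`E = log₂((FPKM_IP + ε)/(FPKM_ref + ε))` with pseudocount ε = 0.1 FPKM
by default. The pseudocount keeps E finite for transcripts absent from
one library; 0.1 is an order of magnitude below the default abundance
floor, so it never dominates a ratio that survives filtering. The
three gates are:

* **floor** — mean input (WT total) FPKM ≥ τ, default 1. Ratios on
  near-zero denominators are noise; the floor formalizes "substantially
  expressed".
* **WT enrichment** — `E_wt ≥ c`, default c = 1 (2-fold). Selection
  uses ≥; the scatter plot's green/red colour classes likewise split
  at `E_wt ≥ 1` (boundary in the enriched class). Both conventions are
  configurable.
* **null filter** — `E_null < c`, where the null-mutant IP is compared
  against WT total by default. A null-mutant *total* library, when
  present, can be chosen as the denominator instead; the default
  avoids requiring one. Applying the same cutoff symmetrically is the
  plainest numeric reading of "enriched in WT and not in the null".

The ranked table contains the selected records sorted by `E_wt`
descending, ties broken lexicographically by transcript id, so reruns
are byte-identical.

## Coverage figures

Per-gene SVGs show up to three replicate depth tracks (fragment-level
depth: mate-overlap collapsed) in fixed red/green/blue order, sharing
one vertical scale per gene so replicates are comparable, above the
gene model. Exon rectangles are shaded with opacity equal to the
fraction of the gene's isoforms containing that exonic interval;
intervals are the maximal segments of constant isoform membership.
Long regions are downsampled to ≤500 polyline segments per track
(max-depth within each bin) to bound file size; rendering uses the
stdlib XML tree, so output bytes are deterministic.

## qPCR arithmetic

Amplification efficiency is fixed at 2.0 (one cycle = one doubling);
efficiency-corrected variants are deliberately omitted. Fold change is
2^−ΔΔCt with within-sample normalization to a reference transcript
and a control sample. Percent input is `100 · f · 2^(Ct_input −
Ct_IP)`: the input aliquot represents a fraction f (default 0.10) of
the IP-equivalent material, so its Ct is shifted by −log₂(1/f) cycles
to stand for 100% input. Error bars aggregate across independent
experiments (mean ± SD); within-run Ct-error propagation is not
attempted. Ct determination from raw fluorescence is instrument-side:
Ct tables are inputs.

## Synthetic data generator

The generator is the package's study design, not a convenience
fixture. Defaults: 200 genes on 4 synthetic chromosomes, 1–4 isoforms
per gene sharing an anchor exon, 2–8 exons of 100–600 bp with 60–400 bp
introns; log-normal relative abundance (ln-scale μ = 0, σ = 1);
fragment length Normal(250, 50) clipped to [read length, transcript
length] (clipping, not resampling — the clipped mass is negligible at
these settings); read length 75; 200,000 fragments per library; four
conditions × 3 replicates; 10% of transcripts designated targets at
ρ = 4. Input-library sampling shares are p_t ∝ a_t·L_t — the length
factor makes FPKM the recoverable quantity. Counts are
Multinomial(N, shares) per library, independent across replicates with
per-library seeds derived from the master seed, so replicate noise is
pure resampling.

Two modelling choices deserve emphasis:

* **ρ is the IP-vs-input fold change of relative abundance.** A target
  transcript's IP share is exactly ρ·p_t; background transcripts are
  scaled to fill the remaining library fraction. Sequencing measures
  composition, so defining ρ on the relative scale makes log₂ρ the
  true value of the pipeline's statistic — simply multiplying weights
  by ρ and renormalizing would depress every share by the same factor
  and make the "true" enrichment depend on the target mass, which is
  not what an enrichment factor should mean. With all ρ = 1 (the null
  experiment) the two formulations coincide.
* **Targets are whole genes.** Every isoform of a target gene carries
  ρ. A protein binds a gene's mRNA isoforms alike, and under
  multi-assignment counting shared exons pool sibling fragments — if
  single isoforms were enriched alone, that pooling would dilute their
  measured enrichment below ρ by construction. The target fraction is
  still honoured as a fraction of transcripts (genes are accumulated
  until the transcript quota is met).

Simulated alignments are spliced (M/N CIGARs mapped through the exon
chain), proper-paired, MAPQ 60, SEQ `*`: there is no sequencing-error,
mapping-error or duplicate model, and no intergenic background. Every
simulated block lies inside its source transcript's exon union
(verified exhaustively in tests), so contained-mode assignment always
recovers the source. Consequently, passing recovery tests demonstrate
the correctness of the counting/normalization/selection chain under
ideal alignment — they say nothing about robustness to misalignment,
soft-clipping, PCR duplicates or annotation errors in real data.

## Problem sizes and numerical choices

Recovery and null-control checks run at the full default scale
(12 × 200k fragments, ~520 transcripts), which completes in a few
minutes on one CPU; oracle-equivalence checks run on ≤1,000-fragment
fixtures where brute-force per-base recomputation is feasible. FPKM
equality versus oracles is asserted to 1e-12 relative (pure floating
arithmetic), integer quantities bitwise. The FPKM-vs-abundance
recovery slope is measured over single-isoform genes only: with
multi-assignment and no deconvolution, a multi-isoform transcript's
count estimates its gene's pooled abundance over shared exons, so a
slope of 1 is only the correct expectation where the count identifies
its own transcript.

## Limitations

No isoform-level abundance deconvolution (EM), no TPM or
effective-length correction, no statistical test or FDR on enrichment
(the selection is a deterministic cutoff), no GO analysis, no BigWig
output. Chromosome matching between GFF and BAM is exact-string, with
an optional alias map in the run configuration for naming drift.
These bounds mirror the scope of the analysis the package implements.
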