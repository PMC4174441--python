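"""log2 IP-vs-input enrichment, the dual-condition filter, and ranking.

The target-selection statistic is the log2 ratio of IP FPKM to input
(total-RNA) FPKM, with a pseudocount so transcripts absent from one
library stay finite:

    E = log2((FPKM_ip + eps) / (FPKM_ref + eps))

A transcript is *selected* when it clears three gates together: an
abundance floor on the input (mean WT total FPKM >= tau, so enrichment
ratios are not driven by near-zero denominators), enrichment in the
wild-type IP (E_wt >= c), and NO enrichment in the null-mutant IP
(E_null < c) — transcripts pulled down without the target protein are
nonspecific background and are filtered out.
"""

from __future__ import annotations

import json
import math
from typing import Mapping

import pandas as pd

from .quantify import FPKMTable

DEFAULT_EPSILON = 0.1
DEFAULT_FLOOR = 1.0
DEFAULT_CUTOFF = 1.0

RANK_COLUMNS = [
    "rank",
    "transcript_id",
    "gene_id",
    "fpkm_wt_ip",
    "fpkm_wt_total",
    "fpkm_null_ip",
    "log2_enrichment_wt",
    "log2_enrichment_null",
]


def log2_enrichment(fpkm_ip: float, fpkm_ref: float, epsilon: float = DEFAULT_EPSILON) -> float:
    """log2((ip + eps) / (ref + eps)); eps must be > 0 if either is 0."""
    if fpkm_ip < 0 or fpkm_ref < 0:
        raise ValueError("FPKM values must be non-negative")
    if epsilon < 0:
        raise ValueError("pseudocount must be non-negative")
    if epsilon == 0 and (fpkm_ip == 0 or fpkm_ref == 0):
        raise ValueError("pseudocount required when an FPKM is zero")
    return math.log2((fpkm_ip + epsilon) / (fpkm_ref + epsilon))


def build_enrichment_table(
    tables: Mapping[str, FPKMTable],
    tx2gene: Mapping[str, str],
    epsilon: float = DEFAULT_EPSILON,
    floor: float = DEFAULT_FLOOR,
    cutoff: float = DEFAULT_CUTOFF,
    null_reference: str = "WT_TOTAL",
) -> pd.DataFrame:
    """One enrichment record per transcript, with filter verdicts.

    ``tables`` must hold FPKMTables for WT_IP, WT_TOTAL and NULL_IP over
    the same transcript universe. The null comparison's denominator is
    WT_TOTAL by default (a null-mutant total library may not exist);
    pass ``null_reference="NULL_TOTAL"`` to use it when provided.
    """
    for cond in ("WT_IP", "WT_TOTAL", "NULL_IP"):
        if cond not in tables:
            raise ValueError(f"missing FPKM table for condition {cond}")
    if null_reference not in tables:
        raise ValueError(f"null reference condition {null_reference} not provided")

    wt_ip = tables["WT_IP"].mean_fpkm
    wt_total = tables["WT_TOTAL"].mean_fpkm
    null_ip = tables["NULL_IP"].mean_fpkm
    null_ref = tables[null_reference].mean_fpkm

    universe = set(wt_ip.index)
    offenders = sorted(
        (set(wt_total.index) ^ universe) | (set(null_ip.index) ^ universe)
    )
    if offenders:
        raise ValueError(f"transcript sets differ between conditions: {offenders}")

    index = wt_ip.sort_index().index
    df = pd.DataFrame(index=index)
    df.index.name = "transcript_id"
    df["gene_id"] = [tx2gene.get(t, "") for t in index]
    df["fpkm_wt_ip"] = wt_ip
    df["fpkm_wt_total"] = wt_total
    df["fpkm_null_ip"] = null_ip
    df["log2_enrichment_wt"] = [
        log2_enrichment(a, b, epsilon) for a, b in zip(df.fpkm_wt_ip, df.fpkm_wt_total)
    ]
    df["log2_enrichment_null"] = [
        log2_enrichment(a, b, epsilon) for a, b in zip(df.fpkm_null_ip, null_ref[index])
    ]
    df["passes_floor"] = df.fpkm_wt_total >= floor
    df["passes_wt"] = df.log2_enrichment_wt >= cutoff
    df["passes_null"] = df.log2_enrichment_null < cutoff
    df["selected"] = df.passes_floor & df.passes_wt & df.passes_null
    return df


def rank_table(records: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Selected records ranked by WT enrichment, descending.

    Ties break lexicographically on transcript_id; the rank column runs
    1..n. Re-running on identical inputs gives byte-identical TSV.
    """
    sel = records[records.selected].copy()
    sel = sel.reset_index().sort_values(
        ["log2_enrichment_wt", "transcript_id"], ascending=[False, True]
    )
    sel.insert(0, "rank", range(1, len(sel) + 1))
    return sel[RANK_COLUMNS + ["passes_floor", "passes_wt", "passes_null"]]


def enrichment_scatter(
    records: pd.DataFrame,
    epsilon: float = DEFAULT_EPSILON,
    class_boundary: float = 1.0,
) -> pd.DataFrame:
    """Scatter data: log2 WT-IP vs log2 WT-total FPKM per transcript.

    One point per transcript with any signal in either library; the
    class column marks points at or above the enrichment boundary
    (boundary value included in the enriched class, matching the
    green/red colouring convention of the enrichment plot).
    """
    if epsilon <= 0:
        raise ValueError("scatter requires a positive pseudocount")
    keep = records[(records.fpkm_wt_ip > 0) | (records.fpkm_wt_total > 0)]
    out = pd.DataFrame(index=keep.index)
    out["log2_fpkm_wt_ip"] = [math.log2(v + epsilon) for v in keep.fpkm_wt_ip]
    out["log2_fpkm_wt_total"] = [math.log2(v + epsilon) for v in keep.fpkm_wt_total]
    out["enriched"] = keep.log2_enrichment_wt >= class_boundary
    return out.reset_index()


def write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_run_metadata(path: str, **params) -> None:
    """JSON sidecar recording the parameters a run used."""
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
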