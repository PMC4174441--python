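"""Recovery metrics against the simulator's truth table."""

from __future__ import annotations

import numpy as np
import pandas as pd


def recovery_metrics(records: pd.DataFrame, truth: pd.DataFrame) -> dict[str, float]:
    """Compare an enrichment table with simulation ground truth.

    Returns the mean estimated log2 enrichment over true targets and
    over background transcripts, selection sensitivity and specificity
    against the truth table, and the selected count.
    """
    m = records.reset_index().merge(truth, on="transcript_id", how="inner")
    targets = m[m.is_target]
    background = m[~m.is_target]
    out = {
        "n_transcripts": float(len(m)),
        "n_targets": float(len(targets)),
        "n_selected": float(m.selected.sum()),
        "mean_log2_enrichment_background": float(
            background.log2_enrichment_wt.mean()
        ),
        "selected_fraction": float(m.selected.mean()),
    }
    if len(targets):
        out["mean_log2_enrichment_targets"] = float(targets.log2_enrichment_wt.mean())
        out["sensitivity"] = float(targets.selected.mean())
    if len(background):
        out["specificity"] = float(1.0 - background.selected.mean())
    return out


def fpkm_recovery_slope(
    fpkm: dict[str, float], truth: pd.DataFrame, genes
) -> float:
    """Slope of log FPKM on log true abundance over single-isoform genes
    (multi-isoform counts pool sibling abundance under multi-assignment,
    so only single-isoform counts identify their own transcript)."""
    solo = {g.transcripts[0].transcript_id for g in genes if len(g.transcripts) == 1}
    t = truth.set_index("transcript_id")
    pts = [
        (np.log(t.loc[tid, "abundance"]), np.log(fpkm[tid]))
        for tid in sorted(solo & set(t.index))
        if fpkm.get(tid, 0.0) > 0
    ]
    x, y = np.array(pts).T
    return float(np.polyfit(x, y, 1)[0])
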