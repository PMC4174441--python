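"""qPCR quantification arithmetic: 2^-ddCt and percent-input.

Ct (cycle threshold) is the PCR cycle at which amplification crosses
threshold; with the assumed doubling per cycle, template copies are
proportional to 2^-Ct. Relative quantification normalises a target's Ct
to a reference transcript (rp49 in the validation experiments) within
each sample, then to a control sample:

    ddCt = (Ct_target,sample - Ct_ref,sample)
         - (Ct_target,control - Ct_ref,control)
    fold change = 2^-ddCt

RIP recovery is expressed as percent of input; the input aliquot is a
fraction f of the IP-equivalent material (f = 0.10 here: 10% total RNA
against the full immunoprecipitate), so the input Ct represents 100%
input after subtracting log2(1/f) cycles:

    percent input = 100 * f * 2^(Ct_input - Ct_ip)

Amplification efficiency is fixed at 2.0 throughout; Ct determination
from raw fluorescence is instrument-side and out of scope — Ct tables
are inputs.
"""

from __future__ import annotations

import math
import statistics

import pandas as pd


def mean_ct(replicates: list[float]) -> tuple[float, float | None]:
    """Arithmetic mean of replicate Ct values; sample SD when n >= 2."""
    vals = [float(v) for v in replicates]
    if not vals:
        raise ValueError("mean_ct needs at least one replicate")
    mean = sum(vals) / len(vals)
    sd = statistics.stdev(vals) if len(vals) >= 2 else None
    return mean, sd


def ddct_fold_change(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative fold change over control by the 2^-ddCt method."""
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_control - ct_ref_control)
    return 2.0 ** (-ddct)


def percent_input(ct_ip: float, ct_input: float, input_fraction: float = 0.10) -> float:
    """IP recovery as percent of total input RNA.

    ``input_fraction`` is the proportion of the material the input
    reaction represents relative to the IP (in (0, 1]); the input Ct is
    adjusted by -log2(1/f) cycles to stand for 100% input.
    """
    if not 0 < input_fraction <= 1:
        raise ValueError(f"input fraction must be in (0, 1], got {input_fraction}")
    return 100.0 * input_fraction * 2.0 ** (ct_input - ct_ip)


def read_ct_table(path: str) -> pd.DataFrame:
    """Read a Ct TSV: sample_id, target_id, then >=1 replicate columns.

    Returns a tidy frame with mean_ct and sd_ct per (sample, target).
    """
    raw = pd.read_csv(path, sep="\t")
    if raw.shape[1] < 3:
        raise ValueError("Ct table needs sample_id, target_id and >=1 Ct column")
    ct_cols = list(raw.columns[2:])
    rows = []
    for _, r in raw.iterrows():
        reps = [float(r[c]) for c in ct_cols if pd.notna(r[c])]
        if not reps or any(v <= 0 for v in reps):
            raise ValueError(
                f"invalid Ct replicates for ({r.iloc[0]}, {r.iloc[1]}): {reps}"
            )
        m, sd = mean_ct(reps)
        rows.append(
            {
                "sample_id": r.iloc[0],
                "target_id": r.iloc[1],
                "mean_ct": m,
                "sd_ct": sd,
                "n_replicates": len(reps),
            }
        )
    return pd.DataFrame(rows)


def _lookup(table: pd.DataFrame, sample: str, target: str) -> float:
    hit = table[(table.sample_id == sample) & (table.target_id == target)]
    if hit.empty:
        raise KeyError(f"no Ct entry for sample={sample!r} target={target!r}")
    return float(hit.mean_ct.iloc[0])


def ddct_table(
    table: pd.DataFrame, control_sample: str, reference_target: str
) -> pd.DataFrame:
    """Fold change over ``control_sample`` for every other (sample, target),
    normalised to ``reference_target`` within each sample."""
    out = []
    for sample in sorted(table.sample_id.unique()):
        if sample == control_sample:
            continue
        for target in sorted(table.target_id.unique()):
            if target == reference_target:
                continue
            fc = ddct_fold_change(
                _lookup(table, sample, target),
                _lookup(table, sample, reference_target),
                _lookup(table, control_sample, target),
                _lookup(table, control_sample, reference_target),
            )
            out.append({"sample_id": sample, "target_id": target, "fold_change": fc})
    return pd.DataFrame(out)


def percent_input_table(
    table: pd.DataFrame,
    ip_sample: str,
    input_sample: str,
    input_fraction: float = 0.10,
) -> pd.DataFrame:
    """Percent input per target for one IP/input sample pair."""
    out = []
    for target in sorted(table.target_id.unique()):
        pct = percent_input(
            _lookup(table, ip_sample, target),
            _lookup(table, input_sample, target),
            input_fraction,
        )
        out.append({"target_id": target, "percent_input": pct})
    return pd.DataFrame(out)


def aggregate_experiments(frames: list[pd.DataFrame], value_col: str) -> pd.DataFrame:
    """Mean +/- SD of a quantification column across independent
    experiment files (across-experiment error bars, not within-run
    Ct-error propagation)."""
    if not frames:
        raise ValueError("no experiment tables to aggregate")
    cat = pd.concat(frames, ignore_index=True)
    keys = [c for c in ("sample_id", "target_id") if c in cat.columns]
    grouped = cat.groupby(keys)[value_col]
    out = grouped.agg(["mean", "std", "count"]).reset_index()
    return out.rename(
        columns={"mean": f"mean_{value_col}", "std": f"sd_{value_col}", "count": "n_experiments"}
    )


def simulate_ct_table(
    targets: dict[str, float],
    rng,
    reference_target: str = "rp49",
    input_fraction: float = 0.10,
    base_ct: float = 24.0,
    noise_sd: float = 0.15,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Synthetic RIP-qPCR Ct table for an IP/input sample pair.

    ``targets`` maps target_id to the true percent-input recovery; the
    reference transcript is added at ~1% recovery (background). Input
    Cts sit near ``base_ct``; IP Cts are derived from the copy-number
    model (copies ~ 2^-Ct) plus Gaussian replicate noise.
    """
    truth = dict(targets)
    truth.setdefault(reference_target, 1.0)
    rows = []
    for target, pct in sorted(truth.items()):
        ct_input = base_ct + rng.normal(0.0, 1.0)
        # percent_input = 100*f*2^(ct_input-ct_ip)  =>  solve for ct_ip
        ct_ip = ct_input - math.log2(pct / (100.0 * input_fraction))
        for sample, ct in (("input", ct_input), ("IP", ct_ip)):
            reps = [ct + rng.normal(0.0, noise_sd) for _ in range(n_replicates)]
            rows.append(
                {"sample_id": sample, "target_id": target}
                | {f"ct{i + 1}": round(v, 3) for i, v in enumerate(reps)}
            )
    return pd.DataFrame(rows)
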