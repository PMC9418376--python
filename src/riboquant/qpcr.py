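"""qPCR statistics: 2^-ddCt quantification, low-dNTP RT drop-off deltas,
generic normalized ratios, and the unpaired t test.

Long-format Cq tables use the columns ``sample``, ``target``, ``condition``
(high / low / n/a), ``replicate``, ``cq``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "delta_delta_ct",
    "rtlp_delta",
    "rtlp_normalized",
    "relative_ratio",
    "unpaired_t",
    "TTestResult",
    "significance_stars",
]


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing columns {missing}")


# ---------------------------------------------------------------------------
# 2^-ddCt
# ---------------------------------------------------------------------------

def delta_delta_ct(
    table: pd.DataFrame,
    reference_target: str,
    calibrator_strain: str,
) -> pd.DataFrame:
    """Relative RNA levels by the 2^-ddCt method.

    Per replicate: dCt = Cq_target - Cq_reference (same sample, replicate);
    ddCt = dCt - mean dCt of the calibrator strain for that target;
    level = 2^-ddCt.  Returns per-(sample, target) mean level, SD, and the
    per-replicate levels as a list column.
    """
    _require_columns(table, ["sample", "target", "replicate", "cq"], "Cq")
    ref = table[table["target"] == reference_target]
    if ref.empty:
        raise ValueError(f"reference target {reference_target!r} not in table")
    ref = ref.rename(columns={"cq": "cq_ref"})[["sample", "replicate", "cq_ref"]]

    tgt = table[table["target"] != reference_target].copy()
    merged = tgt.merge(ref, on=["sample", "replicate"], how="left")
    missing = merged[merged["cq_ref"].isna()]
    if not missing.empty:
        bad = missing[["sample", "target"]].drop_duplicates().to_records(index=False)
        raise ValueError(f"missing reference pairing for {list(bad)}")
    merged["dct"] = merged["cq"] - merged["cq_ref"]

    calib = merged[merged["sample"] == calibrator_strain]
    if calib.empty:
        raise ValueError(f"calibrator strain {calibrator_strain!r} not in table")
    calib_mean = calib.groupby("target")["dct"].mean()

    rows = []
    for (sample, target), sub in merged.groupby(["sample", "target"], sort=False):
        if target not in calib_mean.index:
            raise ValueError(
                f"calibrator {calibrator_strain!r} has no measurements for {target!r}"
            )
        ddct = sub["dct"] - calib_mean[target]
        levels = np.power(2.0, -ddct)
        rows.append(
            {
                "sample": sample,
                "target": target,
                "level": float(levels.mean()),
                "sd": float(levels.std(ddof=1)) if len(levels) > 1 else 0.0,
                "n": len(levels),
                "replicate_levels": list(levels),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Low-dNTP RT drop-off
# ---------------------------------------------------------------------------

def rtlp_delta(table: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate dCq = low-dNTP Cq - high-dNTP Cq per (sample, region).

    Pairing is by replicate id; any (sample, region, replicate) missing one
    of the two conditions is rejected.
    """
    _require_columns(table, ["sample", "target", "condition", "replicate", "cq"], "Cq")
    pivot = table.pivot_table(
        index=["sample", "target", "replicate"], columns="condition",
        values="cq", aggfunc="first",
    )
    for cond in ("low", "high"):
        if cond not in pivot.columns:
            raise ValueError(f"no {cond!r}-dNTP measurements in table")
    unmatched = pivot[pivot["low"].isna() | pivot["high"].isna()]
    if not unmatched.empty:
        raise ValueError(
            f"unmatched dNTP conditions for {list(unmatched.index)}"
        )
    out = pivot.reset_index()[["sample", "target", "replicate"]]
    out["dcq"] = (pivot["low"] - pivot["high"]).to_numpy()
    return out


def rtlp_normalized(
    dcq_table: pd.DataFrame,
    control_region: str,
    calibrator_strain: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize Cq delays to an unmethylated control region and a
    calibrator strain.

    Per strain: ddCq_region = dCq_region - mean(dCq_control) (a delay
    baseline subtraction); relative methylation per region =
    mean(ddCq_strain) / mean(ddCq_calibrator).  Returns
    (per_replicate, summary); a non-positive calibrator mean flags the
    region as non-quantifiable (relative missing).
    """
    _require_columns(dcq_table, ["sample", "target", "replicate", "dcq"], "dCq")
    ctrl = dcq_table[dcq_table["target"] == control_region]
    if ctrl.empty:
        raise ValueError(f"control region {control_region!r} not in table")
    ctrl_mean = ctrl.groupby("sample")["dcq"].mean()

    per_rep = dcq_table.copy()
    missing = set(per_rep["sample"]) - set(ctrl_mean.index)
    if missing:
        raise ValueError(f"control region missing for strains {sorted(missing)}")
    per_rep["ddcq"] = per_rep["dcq"] - per_rep["sample"].map(ctrl_mean)

    if calibrator_strain not in set(per_rep["sample"]):
        raise ValueError(f"calibrator strain {calibrator_strain!r} not in table")

    calib_means = (
        per_rep[per_rep["sample"] == calibrator_strain]
        .groupby("target")["ddcq"].mean()
    )
    rows = []
    for (sample, target), sub in per_rep.groupby(["sample", "target"], sort=False):
        # difference of means (not mean of differences) so the control
        # region's own summary is exactly 0
        mean_ddcq = float(sub["dcq"].mean() - ctrl_mean[sample])
        calib = calib_means.get(target)
        if calib is None:
            raise ValueError(f"calibrator has no measurements for region {target!r}")
        if target == control_region:
            relative, flag = math.nan, "control"
        elif calib <= 0:
            relative, flag = math.nan, "non_quantifiable"
        else:
            relative, flag = mean_ddcq / calib, "ok"
        rows.append(
            {
                "sample": sample,
                "target": target,
                "mean_ddcq": mean_ddcq,
                "relative_methylation": relative,
                "n": len(sub),
                "flag": flag,
            }
        )
    return per_rep, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Generic normalized ratio (e.g. 35S / MRP band intensities)
# ---------------------------------------------------------------------------

def relative_ratio(
    table: pd.DataFrame,
    calibrator: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-replicate value/reference ratios normalized to the calibrator's
    mean ratio.

    ``table`` columns: sample, replicate, value, reference.  Replicates with
    a zero reference are rejected (dropped, counted in the summary's
    ``n_rejected``).
    """
    _require_columns(table, ["sample", "replicate", "value", "reference"], "ratio")
    good = table[table["reference"] != 0].copy()
    n_rejected = len(table) - len(good)
    if good.empty:
        raise ValueError("all replicates have zero reference")
    good["ratio"] = good["value"] / good["reference"]

    calib = good[good["sample"] == calibrator]
    if calib.empty:
        raise ValueError(f"calibrator {calibrator!r} not in table")
    calib_mean = calib["ratio"].mean()
    good["normalized"] = good["ratio"] / calib_mean

    summary = (
        good.groupby("sample")["normalized"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "normalized", "std": "sd", "count": "n"})
    )
    summary["sd"] = summary["sd"].fillna(0.0)
    summary["n_rejected"] = n_rejected
    return good, summary


# ---------------------------------------------------------------------------
# Unpaired t test
# ---------------------------------------------------------------------------

def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    stars: str


def unpaired_t(
    group_a: np.ndarray | list[float],
    group_b: np.ndarray | list[float],
    equal_var: bool = True,
) -> TTestResult:
    """Two-sample two-sided t test (Student by default, Welch optional).

    Zero variance in both groups with equal means returns t = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        df = len(a) + len(b) - 2.0
        if a.mean() == b.mean():
            return TTestResult(0.0, df, 1.0, "ns")
        return TTestResult(math.copysign(math.inf, a.mean() - b.mean()), df, 0.0, "***")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = float(res.df)
    return TTestResult(float(res.statistic), df, float(res.pvalue),
                       significance_stars(float(res.pvalue)))
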