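"""Dual-luciferase fidelity metrics and flow-cytometry translation output."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["fidelity_metric", "translation_output"]


def fidelity_metric(
    records: pd.DataFrame,
    calibrator_strain: str,
) -> pd.DataFrame:
    """Normalized Firefly/Renilla ratios per (strain, reporter class).

    Per replicate r = firefly / renilla; strain value = mean(r of reporter
    rows) / mean(r of control rows); the final metric is further divided by
    the calibrator strain's value for the same class, so the calibrator is
    1.0 by construction.  SD is propagated from the reporter-replicate
    ratios.  A (strain, class) without a control plasmid is rejected
    (excluded, listed in the ``flag`` column of a stub row).
    """
    need = ["strain", "role", "reporter_class", "replicate", "firefly", "renilla"]
    missing = [c for c in need if c not in records.columns]
    if missing:
        raise ValueError(f"luciferase table is missing columns {missing}")
    if (records["firefly"] <= 0).any() or (records["renilla"] <= 0).any():
        raise ValueError("luminescence signals must be positive")

    df = records.copy()
    df["ratio"] = df["firefly"] / df["renilla"]

    rows = []
    for (strain, cls), sub in df.groupby(["strain", "reporter_class"], sort=False):
        rep = sub[sub["role"] == "reporter"]["ratio"]
        ctl = sub[sub["role"] == "control"]["ratio"]
        if ctl.empty or rep.empty:
            rows.append({"strain": strain, "reporter_class": cls, "value": np.nan,
                         "sd": np.nan, "n": 0, "flag": "missing_control"})
            continue
        if len(rep) < 2:
            raise ValueError(
                f"({strain!r}, {cls!r}) has fewer than 2 reporter replicates"
            )
        value = rep.mean() / ctl.mean()
        sd = (rep.std(ddof=1) / ctl.mean()) if len(rep) > 1 else 0.0
        rows.append({"strain": strain, "reporter_class": cls, "value": value,
                     "sd": sd, "n": len(rep), "flag": "ok"})
    out = pd.DataFrame(rows)

    for cls, sub in out.groupby("reporter_class", sort=False):
        calib = sub[(sub["strain"] == calibrator_strain) & (sub["flag"] == "ok")]
        if calib.empty:
            raise ValueError(
                f"calibrator strain {calibrator_strain!r} unavailable for class {cls!r}"
            )
        cval = float(calib["value"].iloc[0])
        sel = out["reporter_class"] == cls
        out.loc[sel, "value"] = out.loc[sel, "value"] / cval
        out.loc[sel, "sd"] = out.loc[sel, "sd"] / cval
    return out


def translation_output(
    events: pd.DataFrame,
    calibrator_strain: str,
    stat: str = "median",
    min_events: int = 1000,
) -> pd.DataFrame:
    """Relative nascent-protein signal from flow-event intensities.

    Per strain: summary = stat(HPG intensities) - background, where
    background is the stat of that strain's cycloheximide-treated control
    set when present (else 0).  Values are reported relative to the
    calibrator strain.  Strains with fewer than ``min_events`` HPG events
    are flagged (and a warning issued) but still reported.
    """
    need = ["strain", "treatment", "intensity"]
    missing = [c for c in need if c not in events.columns]
    if missing:
        raise ValueError(f"flow-event table is missing columns {missing}")
    if (events["intensity"] < 0).any():
        raise ValueError("event intensities must be >= 0")
    if stat not in ("median", "mean"):
        raise ValueError("stat must be 'median' or 'mean'")
    agg = np.median if stat == "median" else np.mean

    rows = []
    for strain, sub in events.groupby("strain", sort=False):
        hpg = sub[sub["treatment"] == "HPG"]["intensity"].to_numpy()
        chx = sub[sub["treatment"] != "HPG"]["intensity"].to_numpy()
        if len(hpg) == 0:
            raise ValueError(f"no HPG-treated events for strain {strain!r}")
        flag = "ok"
        if len(hpg) < min_events:
            warnings.warn(
                f"strain {strain!r}: only {len(hpg)} HPG events (< {min_events})",
                stacklevel=2,
            )
            flag = "low_event_count"
        background = float(agg(chx)) if len(chx) else 0.0
        rows.append({"strain": strain, "signal": float(agg(hpg)) - background,
                     "n_events": len(hpg), "flag": flag})
    out = pd.DataFrame(rows)

    calib = out[out["strain"] == calibrator_strain]
    if calib.empty:
        raise ValueError(f"calibrator strain {calibrator_strain!r} not in table")
    cval = float(calib["signal"].iloc[0])
    if cval == 0:
        raise ValueError("calibrator background-subtracted signal is zero")
    out["relative"] = out["signal"] / cval
    return out
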