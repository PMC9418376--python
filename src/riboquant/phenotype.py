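"""Growth-curve doubling times, inhibitor fold changes, and polysome-profile
peak quantification."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

__all__ = [
    "GrowthFitError",
    "fit_doubling_time",
    "drug_fold_change",
    "Peak",
    "PeakSet",
    "detect_peaks",
    "pm_ratio",
]


class GrowthFitError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Growth
# ---------------------------------------------------------------------------

def _window_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line y = a + b t; returns (slope, intercept, R^2)."""
    tm, ym = t.mean(), y.mean()
    st = t - tm
    sy = y - ym
    sst = float(sy @ sy)
    stt = float(st @ st)
    if stt == 0:
        return 0.0, ym, 0.0
    b = float(st @ sy) / stt
    a = ym - b * tm
    if sst == 0:
        return b, a, 1.0
    ss_res = sst - b * float(st @ sy)
    return b, a, 1.0 - ss_res / sst

def fit_doubling_time(
    curve: pd.DataFrame,
    od_lo: float = 0.1,
    od_hi: float = 0.5,
    r2_min: float = 0.99,
    min_points: int = 5,
) -> float:
    """Doubling time (minutes) from the exponential window of a growth curve.

    The window is the longest contiguous stretch of points with OD inside
    [od_lo, od_hi] fractions of the curve maximum whose ln(OD)-vs-time fit
    reaches R^2 >= r2_min (ties broken by R^2).  T_d = ln2 / slope; a
    non-growing window (slope <= 0) returns inf.
    """
    if "time" not in curve.columns or "od" not in curve.columns:
        raise ValueError("growth curve needs 'time' and 'od' columns")
    t = curve["time"].to_numpy(dtype=float)
    od = curve["od"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time points must be strictly increasing")
    if np.any(od <= 0):
        raise ValueError("OD values must be positive")
    name = str(curve["strain"].iloc[0]) if "strain" in curve.columns else "curve"

    top = od.max()
    in_band = (od >= od_lo * top) & (od <= od_hi * top)
    logod = np.log(od)

    best: tuple[int, float, float] | None = None   # (length, r2, slope)
    n = len(t)
    i = 0
    while i < n:
        if not in_band[i]:
            i += 1
            continue
        j = i
        while j < n and in_band[j]:
            j += 1
        # contiguous run [i, j); scan its sub-windows
        for a in range(i, j - min_points + 1):
            for b_end in range(a + min_points, j + 1):
                slope, _, r2 = _window_fit(t[a:b_end], logod[a:b_end])
                if r2 >= r2_min:
                    cand = (b_end - a, r2, slope)
                    if best is None or cand[:2] > best[:2]:
                        best = cand
        i = j
    if best is None:
        # a shrinking culture never puts a growth window in the OD band;
        # flag it as non-growing rather than failing the fit
        whole_slope, _, _ = _window_fit(t, logod)
        if whole_slope <= 0:
            return math.inf
        raise GrowthFitError(
            f"no exponential window with R^2 >= {r2_min} for {name!r}"
        )
    slope = best[2]
    if slope <= 0:
        return math.inf
    return math.log(2) / slope


def drug_fold_change(
    mutant_td: list[float] | np.ndarray,
    wildtype_td: list[float] | np.ndarray,
) -> tuple[float, list[float]]:
    """Fold change = mean(mutant T_d) / mean(wildtype T_d) in one condition.

    Also returns per-replicate fold changes (each mutant T_d over the
    wildtype mean) for dispersion estimates.
    """
    mut = np.asarray(mutant_td, dtype=float)
    wt = np.asarray(wildtype_td, dtype=float)
    if len(mut) < 1 or len(wt) < 1:
        raise ValueError("need at least one replicate per strain")
    wt_mean = wt.mean()
    if wt_mean <= 0:
        raise ValueError("wildtype mean doubling time must be positive")
    return float(mut.mean() / wt_mean), list(mut / wt_mean)


# ---------------------------------------------------------------------------
# Polysome profiles
# ---------------------------------------------------------------------------

@dataclass
class Peak:
    label: str
    apex_position: float
    apex_index: int
    left_index: int
    right_index: int
    area: float


@dataclass
class PeakSet:
    peaks: list[Peak] = field(default_factory=list)

    def by_label(self, label: str) -> list[Peak]:
        return [p for p in self.peaks if p.label == label]

    def __len__(self) -> int:
        return len(self.peaks)


def _baseline(y: np.ndarray, window: int) -> np.ndarray:
    """Morphological opening (rolling min then max): flat baseline estimate
    that removes peaks narrower than ``window`` samples."""
    eroded = ndimage.minimum_filter1d(y, size=window, mode="nearest")
    return ndimage.maximum_filter1d(eroded, size=window, mode="nearest")


def detect_peaks(
    trace: pd.DataFrame,
    prominence: float | None = None,
    baseline_window: int | None = None,
    smooth: int = 0,
    n_skip: int = 0,
) -> PeakSet:
    """Detect and label gradient-trace peaks.

    Baseline is removed by a rolling-minimum opening; local maxima above the
    prominence threshold (default: 5% of the baseline-subtracted range)
    become peaks with boundaries at the flanking minima.  After skipping
    ``n_skip`` leading peaks (free-RNA region), peaks are labeled in order
    40S, 60S, 80S, then polysome.
    """
    if "position" not in trace.columns or "a260" not in trace.columns:
        raise ValueError("trace needs 'position' and 'a260' columns")
    x = trace["position"].to_numpy(dtype=float)
    y = trace["a260"].to_numpy(dtype=float)
    if len(x) < 16:
        raise ValueError("trace too short (< 16 points)")
    if np.any(np.diff(x) <= 0):
        raise ValueError("trace positions must be strictly increasing")

    if baseline_window is None:
        baseline_window = max(len(y) // 10, 5)
    corrected = y - _baseline(y, baseline_window)
    searched = (
        np.convolve(corrected, np.ones(smooth) / smooth, mode="same")
        if smooth > 1 else corrected
    )
    if prominence is None:
        prominence = 0.05 * float(searched.max() - searched.min())
        if prominence <= 0:
            raise ValueError("no peaks: flat trace")
    apexes, _ = signal.find_peaks(searched, prominence=prominence)
    apexes = apexes[n_skip:] if n_skip else apexes
    if len(apexes) == 0:
        raise ValueError("no peaks detected in trace")
    if len(apexes) < 3:
        raise ValueError(
            f"only {len(apexes)} peaks detected; cannot label the 80S monosome"
        )

    labels = ["40S", "60S", "80S"] + ["polysome"] * (len(apexes) - 3)
    peaks: list[Peak] = []
    for k, apex in enumerate(apexes):
        left = apexes[k - 1] if k > 0 else 0
        lo = left + int(np.argmin(searched[left : apex + 1])) if apex > left else left
        right = apexes[k + 1] if k + 1 < len(apexes) else len(y) - 1
        hi = apex + int(np.argmin(searched[apex : right + 1])) if right > apex else right
        area = float(np.trapezoid(corrected[lo : hi + 1], x[lo : hi + 1]))
        peaks.append(Peak(labels[k], float(x[apex]), int(apex), int(lo), int(hi),
                          max(area, 0.0)))
    return PeakSet(peaks)


def pm_ratio(peaks: PeakSet) -> float:
    """Polysome/monosome ratio: sum of polysome areas over the 80S area."""
    mono = peaks.by_label("80S")
    poly = peaks.by_label("polysome")
    if len(mono) != 1:
        raise ValueError(f"need exactly one 80S peak, found {len(mono)}")
    if not poly:
        raise ValueError("need at least one polysome peak")
    if mono[0].area <= 0:
        raise ValueError("80S (monosome) peak has zero area")
    return sum(p.area for p in poly) / mono[0].area
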