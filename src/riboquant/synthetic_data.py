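"""Synthetic-data generators with machine-readable truth tables.

Each generator emulates the statistical structure one downstream stage
assumes:

* per-molecule alkaline cleavage with methylation-dependent bond protection
  and hard 20-40 nt size selection;
* qPCR Cq values under a fixed amplification efficiency, optionally with
  low-dNTP reverse-transcription drop-off at methylated sites;
* logistic growth sampled on a uniform time grid;
* gradient traces as baseline + Gaussian peaks;
* luminescence tables and log-normal flow-event intensities.

All randomness flows through named substreams of ``config.seed`` (see
``riboquant._rng``), so identical (seed, config) gives identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .config import SimulationConfig, TracePeak
from .io import Read
from .reference import ReferenceSet, TrueMethylationProfile

__all__ = [
    "FragmentationResult",
    "simulate_fragmentation_reads",
    "simulate_cq_table",
    "simulate_rtlp_cq",
    "simulate_growth_curve",
    "simulate_polysome_trace",
    "simulate_luciferase_table",
    "simulate_flow_events",
]


# ---------------------------------------------------------------------------
# Alkaline fragmentation
# ---------------------------------------------------------------------------

@dataclass
class FragmentationResult:
    """Reads plus the planted truth.

    ``site_truth``     planted methylated fraction per site
                       (molecule, position, f).
    ``cleavage_truth`` realized cleavage events per bond
                       (molecule, bond, count); bond i is 3' of nucleotide i.
    """

    reads: list[Read]
    site_truth: pd.DataFrame
    cleavage_truth: pd.DataFrame

    def cleavage_counts(self, molecule: str) -> np.ndarray:
        sel = self.cleavage_truth[self.cleavage_truth["molecule"] == molecule]
        return sel.sort_values("bond")["count"].to_numpy()


def simulate_fragmentation_reads(
    reference: ReferenceSet,
    truth: TrueMethylationProfile,
    config: SimulationConfig,
) -> FragmentationResult:
    """Simulate alkaline fragmentation with methylation protection.

    Per molecule copy, every internal bond i (i = 1..L-1) is cleaved
    independently with probability ``p_cleave`` — except that a copy
    methylated at nucleotide i (with probability f_i, independent per site)
    is never cleaved at bond i.  Maximal uncleaved intervals become
    fragments; those with length inside [fragment_min, fragment_max] are
    emitted verbatim as reads.  The molecule's 5'/3' termini are not
    cleavage events.
    """
    truth.validate_against(reference)
    fp = config.fragmentation
    rng = substream(config.seed, "fragmentation")

    reads: list[Read] = []
    cleav_rows = []
    for mol, seq in reference.items():
        L = len(seq)
        sites = truth.sites(mol)
        counts = np.zeros(L - 1, dtype=np.int64)
        serial = 0
        remaining = fp.n_molecules
        while remaining > 0:
            m = min(fp.chunk_size, remaining)
            remaining -= m
            cut = rng.random((m, L - 1)) < fp.p_cleave
            for pos, f in sites:
                if f > 0 and pos <= L - 1:
                    methylated = rng.random(m) < f
                    cut[methylated, pos - 1] = False
            counts += cut.sum(axis=0)

            # fragment boundaries, vectorized over the chunk
            rows, cols = np.nonzero(cut)
            k = cut.sum(axis=1)                      # cuts per molecule copy
            nfrag = int(k.sum()) + m
            first_slot = np.concatenate(([0], np.cumsum(k + 1)[:-1]))
            last_slot = first_slot + k
            start_b = np.zeros(nfrag, dtype=np.int64)    # bond left of fragment (0 = 5' end)
            end_b = np.full(nfrag, L, dtype=np.int64)    # bond right of fragment (L = 3' end)
            is_first = np.zeros(nfrag, dtype=bool)
            is_first[first_slot] = True
            is_last = np.zeros(nfrag, dtype=bool)
            is_last[last_slot] = True
            bonds = cols + 1                         # 1-based bond indices, row-major
            start_b[~is_first] = bonds
            end_b[~is_last] = bonds

            length = end_b - start_b
            keep = (length >= fp.fragment_min) & (length <= fp.fragment_max)
            for s, e in zip(start_b[keep], end_b[keep]):
                reads.append(Read(f"{mol}:{serial}", seq[s:e], None))
                serial += 1

        cleav_rows.append(
            pd.DataFrame(
                {"molecule": mol, "bond": np.arange(1, L), "count": counts}
            )
        )

    site_truth = truth.table.copy()
    cleavage_truth = pd.concat(cleav_rows, ignore_index=True) if cleav_rows else pd.DataFrame(
        columns=["molecule", "bond", "count"]
    )
    return FragmentationResult(reads, site_truth, cleavage_truth)


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def _cq(level: np.ndarray | float, cq_base: float, efficiency: float) -> np.ndarray | float:
    return cq_base - np.log(level) / np.log(efficiency)


def simulate_cq_table(
    levels: dict[str, dict[str, float]],
    config: SimulationConfig,
    reference_target: str = "reference",
) -> pd.DataFrame:
    """Simulate a long-format Cq table from true relative template levels.

    ``levels`` maps strain -> {target: true level > 0}.  A reference target
    with constant level 1.0 across strains is always included (added if the
    design omits it).  Cq = cq_base - log_E(level) + N(0, noise_sd).
    """
    qp = config.qpcr
    rng = substream(config.seed, "cq_table")
    rows = []
    for strain, targets in levels.items():
        targets = dict(targets)
        targets.setdefault(reference_target, 1.0)
        for target, level in targets.items():
            if not level > 0:
                raise ValueError(
                    f"true level for ({strain!r}, {target!r}) must be positive, got {level}"
                )
            for rep in range(1, qp.n_replicates + 1):
                noise = rng.normal(0.0, qp.noise_sd) if qp.noise_sd > 0 else 0.0
                rows.append(
                    {
                        "sample": strain,
                        "target": target,
                        "condition": "n/a",
                        "replicate": rep,
                        "cq": _cq(level, qp.cq_base, qp.efficiency) + noise,
                    }
                )
    return pd.DataFrame(rows)


def simulate_rtlp_cq(
    regions: dict[str, dict[str, list[tuple[int, float]]]],
    config: SimulationConfig,
) -> pd.DataFrame:
    """Simulate paired high/low-dNTP Cq values per (strain, region).

    ``regions`` maps strain -> {region: [(site, f), ...]}; an empty site list
    is an unmethylated control region.  At high dNTP the template amplifies
    at its full level (1.0); at low dNTP the effective template is multiplied
    by prod(1 - f * dropoff) over the region's sites, delaying Cq.
    """
    qp = config.qpcr
    if not 0 <= qp.dropoff <= 1:
        raise ValueError("dropoff must be in [0, 1]")
    rng = substream(config.seed, "rtlp_cq")
    rows = []
    for strain, regmap in regions.items():
        for region, sites in regmap.items():
            surviving = 1.0
            for _pos, f in sites:
                if not 0 <= f <= 1:
                    raise ValueError(f"methylated fraction {f} outside [0, 1]")
                surviving *= 1.0 - f * qp.dropoff
            if surviving <= 0:
                raise ValueError(
                    f"region ({strain!r}, {region!r}) has zero surviving template at "
                    "low dNTP; reduce f or dropoff"
                )
            for rep in range(1, qp.n_replicates + 1):
                for condition, level in (("high", 1.0), ("low", surviving)):
                    noise = rng.normal(0.0, qp.noise_sd) if qp.noise_sd > 0 else 0.0
                    rows.append(
                        {
                            "sample": strain,
                            "target": region,
                            "condition": condition,
                            "replicate": rep,
                            "cq": _cq(level, qp.cq_base, qp.efficiency) + noise,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Growth, gradient traces, reporters, flow
# ---------------------------------------------------------------------------

def simulate_growth_curve(
    config: SimulationConfig,
    strain: str = "WT",
    condition: str = "none",
    stream_index: int = 0,
) -> pd.DataFrame:
    """Logistic OD600 curve sampled every ``interval`` minutes.

    OD(t) = K / (1 + (K/N0 - 1) * exp(-r t)) with r = ln2 / T_d; carrying
    capacity None (or inf) gives the exact exponential N0 * 2^(t/T_d).
    Noise is multiplicative log-normal: OD * exp(N(0, noise_sd)).
    """
    gp = config.growth
    rng = substream(config.seed, "growth", stream_index)
    t = np.arange(0.0, gp.duration + 0.5 * gp.interval, gp.interval)
    r = math.log(2) / gp.doubling_time
    K = gp.carrying_capacity
    if K is None or math.isinf(K):
        od = gp.n0 * np.exp(r * t)
    else:
        od = K / (1.0 + (K / gp.n0 - 1.0) * np.exp(-r * t))
    if gp.noise_sd > 0:
        od = od * np.exp(rng.normal(0.0, gp.noise_sd, size=od.shape))
    return pd.DataFrame(
        {"time": t, "od": od, "strain": strain, "condition": condition}
    )


def simulate_polysome_trace(
    config: SimulationConfig, stream_index: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gradient A260 trace: baseline + sum of Gaussian peaks + optional noise.

    Returns (trace, truth); truth lists each peak's analytic area
    (height * width * sqrt(2*pi)) and label.
    """
    tp = config.trace
    rng = substream(config.seed, "trace", stream_index)
    x = np.arange(tp.start, tp.stop + 0.5 * tp.step, tp.step)
    y = np.full_like(x, tp.baseline, dtype=float)
    truth_rows = []
    for pk in tp.peaks:
        y += pk.height * np.exp(-0.5 * ((x - pk.center) / pk.width) ** 2)
        truth_rows.append(
            {"label": pk.label, "center": pk.center, "width": pk.width,
             "height": pk.height, "area": pk.area}
        )
    if tp.noise_sd > 0:
        y = y + rng.normal(0.0, tp.noise_sd, size=y.shape)
    trace = pd.DataFrame({"position": x, "a260": y})
    return trace, pd.DataFrame(truth_rows)


def simulate_luciferase_table(
    true_ratios: dict[str, float],
    config: SimulationConfig,
    reporter_class: str = "readthrough",
) -> pd.DataFrame:
    """Simulate a dual-luciferase luminescence table.

    ``true_ratios`` maps strain -> planted normalized fidelity metric (its
    reporter Firefly/Renilla ratio relative to its control plasmid; the
    calibrator strain should be planted at 1.0 for a relative readout).
    Multiplicative log-normal noise with coefficient of variation ``cv`` is
    applied independently to every signal.
    """
    lp = config.luciferase
    rng = substream(config.seed, "luciferase")
    sigma = math.sqrt(math.log(1.0 + lp.cv**2))  # log-normal sd giving CV=cv

    def _noise() -> float:
        return math.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0

    rows = []
    for strain, rho in true_ratios.items():
        if not rho > 0:
            raise ValueError(f"planted ratio for {strain!r} must be positive, got {rho}")
        for role, ratio in (("control", lp.base_ratio), ("reporter", lp.base_ratio * rho)):
            for rep in range(1, lp.n_replicates + 1):
                renilla = lp.renilla_base * _noise()
                firefly = ratio * renilla * _noise()
                rows.append(
                    {
                        "strain": strain,
                        "role": role,
                        "reporter_class": reporter_class,
                        "replicate": rep,
                        "firefly": firefly,
                        "renilla": renilla,
                    }
                )
    return pd.DataFrame(rows)


def simulate_flow_events(
    relative_medians: dict[str, float],
    config: SimulationConfig,
    include_background: bool = False,
    background_median: float = 0.0,
) -> pd.DataFrame:
    """Simulate log-normal flow-cytometry event intensities per strain.

    ``relative_medians`` maps strain -> planted median relative to 1.0 (the
    calibrator should be planted at 1.0).  With ``include_background``, a
    cycloheximide-treated control set with the given (low) median is added
    per strain.
    """
    fp = config.flow
    rng = substream(config.seed, "flow")
    if not fp.min_events <= fp.n_events <= fp.max_events:
        raise ValueError(
            f"n_events={fp.n_events} outside configured bounds "
            f"[{fp.min_events}, {fp.max_events}]"
        )
    frames = []
    for strain, rel in relative_medians.items():
        if not rel > 0:
            raise ValueError(f"planted relative median for {strain!r} must be positive")
        mu = math.log(fp.median * rel)
        intens = np.exp(rng.normal(mu, fp.sigma, size=fp.n_events))
        frames.append(
            pd.DataFrame({"strain": strain, "treatment": "HPG", "intensity": intens})
        )
        if include_background:
            bg = np.exp(rng.normal(math.log(max(background_median, 1e-12)), fp.sigma,
                                   size=fp.n_events))
            frames.append(
                pd.DataFrame(
                    {"strain": strain, "treatment": "HPG+CHX", "intensity": bg}
                )
            )
    return pd.concat(frames, ignore_index=True)
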