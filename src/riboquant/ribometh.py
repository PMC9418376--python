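"""End-coverage 2'-O-methylation scoring.

Pipeline: exact read mapping -> per-bond cleavage-end counts -> per-site
score in [0, 1] from local end depletion in a +/-2-bond window -> band
classification (stable / variable / hypo) -> per-molecule summaries and
condition comparisons.

Conventions
-----------
* Positions are 1-based on the mature rRNA; bond i is 3' of nucleotide i
  (bonds 1..L-1).
* A read aligned to the closed interval [s, e] was created by cleavage at
  bond s-1 (its 5' end) and bond e (its 3' end); ends falling on a molecule
  terminus are not cleavage events and are skipped.
* Score for the site at nucleotide i:
      S_i = clip(1 - n(i) / mean(n(j), j in B), 0, 1)
  where B = {i-2, i-1, i+1, i+2}, clipped to [1, L-1], excluding bonds 3'
  of another annotated site.  Coverage is mean(n(j), j in B).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import AlignmentRecord, Read
from .reference import ModificationAnnotation, ReferenceSet

__all__ = [
    "MappingResult",
    "EndCountProfile",
    "map_reads_exact",
    "count_read_ends",
    "compute_methscore",
    "classify_sites",
    "summarize_classes",
    "compare_conditions",
    "BAND_STABLE",
    "BAND_VARIABLE",
    "BAND_HYPO",
    "BAND_LOW_COVERAGE",
]

BAND_STABLE = "stable"
BAND_VARIABLE = "variable"
BAND_HYPO = "hypo"
BAND_LOW_COVERAGE = "low_coverage"


# ---------------------------------------------------------------------------
# Exact mapping
# ---------------------------------------------------------------------------

@dataclass
class MappingResult:
    alignments: list[AlignmentRecord]
    n_unmapped: int = 0
    n_multi: int = 0

    @property
    def n_mapped(self) -> int:
        return len(self.alignments)


_AMBIGUOUS = object()


def _substring_index(reference: ReferenceSet, lengths: set[int]) -> dict:
    index: dict[str, object] = {}
    for name, seq in reference.items():
        for k in lengths:
            for s in range(len(seq) - k + 1):
                sub = seq[s : s + k]
                if sub in index:
                    index[sub] = _AMBIGUOUS
                else:
                    index[sub] = (name, s + 1)
    return index


def map_reads_exact(reads: Iterable[Read], reference: ReferenceSet) -> MappingResult:
    """Assign each read to its unique exact sense-strand match.

    Reads with zero or multiple exact occurrences across all molecules are
    dropped and counted (``n_unmapped`` / ``n_multi``).
    """
    reads = list(reads)
    if not reads:
        raise ValueError("no reads to map")
    lengths = {len(r.sequence) for r in reads}
    index = _substring_index(reference, lengths)
    result = MappingResult([])
    for r in reads:
        hit = index.get(r.sequence.upper())
        if hit is None:
            result.n_unmapped += 1
        elif hit is _AMBIGUOUS:
            result.n_multi += 1
        else:
            name, start = hit
            result.alignments.append(
                AlignmentRecord(r.id, name, start, start + len(r.sequence) - 1)
            )
    return result


# ---------------------------------------------------------------------------
# End counting
# ---------------------------------------------------------------------------

@dataclass
class EndCountProfile:
    """Cleavage-end counts n(i) for bonds i = 1..L-1 of one molecule."""

    molecule: str
    counts: np.ndarray
    total_reads: int = 0
    terminal_ends_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("end counts must be a 1-D array")
        if np.issubdtype(self.counts.dtype, np.floating):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("end counts must be integral")
        if (self.counts < 0).any():
            raise ValueError("end counts must be non-negative")

    @property
    def length(self) -> int:
        """Molecule length L (counts cover bonds 1..L-1)."""
        return len(self.counts) + 1

    def n(self, bond: int) -> int:
        if not 1 <= bond <= len(self.counts):
            raise IndexError(f"bond {bond} outside 1..{len(self.counts)}")
        return int(self.counts[bond - 1])


def count_read_ends(
    alignments: Iterable[AlignmentRecord],
    reference: ReferenceSet,
) -> dict[str, EndCountProfile]:
    """Accumulate cleavage-end counts from alignments.

    A read on [s, e] increments n(s-1) and n(e); increments at bond 0 or
    bond L (a read touching a terminus) are skipped.  Records outside
    reference bounds are rejected and counted in ``n_rejected`` attached to
    the returned dict.
    """
    profiles = {
        name: EndCountProfile(name, np.zeros(reference.length(name) - 1, dtype=np.int64))
        for name in reference
    }
    n_rejected = 0
    for rec in alignments:
        if rec.molecule not in profiles:
            raise ValueError(f"alignment references unknown molecule {rec.molecule!r}")
        prof = profiles[rec.molecule]
        L = prof.length
        if rec.start < 1 or rec.end > L or rec.start > rec.end:
            n_rejected += 1
            continue
        prof.total_reads += 1
        five = rec.start - 1
        if five >= 1:
            prof.counts[five - 1] += 1
        else:
            prof.terminal_ends_skipped += 1
        three = rec.end
        if three <= L - 1:
            prof.counts[three - 1] += 1
        else:
            prof.terminal_ends_skipped += 1
    for prof in profiles.values():
        prof.n_rejected = n_rejected  # shared tally, for reporting
    return profiles


# ---------------------------------------------------------------------------
# MethScore
# ---------------------------------------------------------------------------

SCORE_COLUMNS = ["molecule", "position", "score", "coverage", "label"]


def _neighbor_bonds(pos: int, length: int, annotated: set[int], window: int) -> list[int]:
    bonds = []
    for j in range(pos - window, pos + window + 1):
        if j == pos or not 1 <= j <= length - 1:
            continue
        if j in annotated:
            continue  # bond 3' of another annotated site: protection leaks into it
        bonds.append(j)
    return bonds


def compute_methscore(
    profiles: dict[str, EndCountProfile] | EndCountProfile,
    annotation: ModificationAnnotation,
    window: int = 2,
    min_cov: float = 10.0,
) -> pd.DataFrame:
    """Score every annotated site from its local end-count depletion.

    Returns a table with columns molecule, position, score, coverage, label.
    Sites whose neighbor set is empty or has zero mean get a missing score
    and the ``low_coverage`` label; sites with coverage below ``min_cov``
    keep their score but are labeled ``low_coverage``.  Other labels are
    left missing until :func:`classify_sites`.
    """
    if isinstance(profiles, EndCountProfile):
        profiles = {profiles.molecule: profiles}
    rows = []
    for mol in annotation.molecules:
        if mol not in profiles:
            raise ValueError(f"no end-count profile for annotated molecule {mol!r}")
        prof = profiles[mol]
        L = prof.length
        positions = annotation.positions(mol)
        annotated = set(positions)
        for pos in positions:
            if not 1 <= pos <= L:
                raise ValueError(f"annotated position {mol}:{pos} outside reference")
            neighbors = _neighbor_bonds(pos, L, annotated, window)
            if not neighbors:
                rows.append((mol, pos, math.nan, math.nan, BAND_LOW_COVERAGE))
                continue
            nb = prof.counts[[j - 1 for j in neighbors]]
            coverage = float(nb.mean())
            if coverage == 0:
                rows.append((mol, pos, math.nan, coverage, BAND_LOW_COVERAGE))
                continue
            n_i = float(prof.counts[pos - 1]) if pos <= L - 1 else 0.0
            score = min(1.0, max(0.0, 1.0 - n_i / coverage))
            label = BAND_LOW_COVERAGE if coverage < min_cov else pd.NA
            rows.append((mol, pos, score, coverage, label))
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def classify_sites(
    table: pd.DataFrame,
    thresholds: tuple[float, float] = (0.4, 0.8),
) -> pd.DataFrame:
    """Assign band labels: score > hi -> stable, lo..hi (inclusive) ->
    variable, < lo -> hypo.  ``low_coverage`` labels are preserved."""
    lo, hi = thresholds
    if not 0 <= lo <= hi <= 1:
        raise ValueError("need 0 <= lo <= hi <= 1")
    out = table.copy()
    out["label"] = out["label"].astype(object)  # may arrive all-NaN/float from disk
    for idx, row in out.iterrows():
        if not pd.isna(row["label"]) and row["label"] == BAND_LOW_COVERAGE:
            continue
        s = row["score"]
        if pd.isna(s):
            out.at[idx, "label"] = BAND_LOW_COVERAGE
        elif s > hi:
            out.at[idx, "label"] = BAND_STABLE
        elif s < lo:
            out.at[idx, "label"] = BAND_HYPO
        else:
            out.at[idx, "label"] = BAND_VARIABLE
    return out


def summarize_classes(table: pd.DataFrame) -> pd.DataFrame:
    """Per-molecule band counts and integer-rounded percentages.

    Percentage denominators are all annotated sites of the molecule, so e.g.
    8 variable of 18 annotated reports 44%.
    """
    bands = [BAND_STABLE, BAND_VARIABLE, BAND_HYPO, BAND_LOW_COVERAGE]
    rows = []
    for mol, sub in table.groupby("molecule", sort=False):
        total = len(sub)
        for band in bands:
            count = int((sub["label"] == band).sum())
            pct = int(round(100.0 * count / total)) if total else 0
            rows.append(
                {"molecule": mol, "band": band, "count": count,
                 "total_sites": total, "percent": pct}
            )
    return pd.DataFrame(rows)


def compare_conditions(
    wt_tables: Sequence[pd.DataFrame],
    mut_tables: Sequence[pd.DataFrame],
) -> pd.DataFrame:
    """Per-site replicate-mean scores and mutant/wildtype relative score.

    Sites labeled ``low_coverage`` in any replicate of either condition are
    flagged and excluded from the means (relative score missing).  A
    wildtype mean of 0 also flags the site (`relative` missing, never 0/0).
    """
    if not wt_tables or not mut_tables:
        raise ValueError("need at least one replicate per condition")

    def _stack(tables: Sequence[pd.DataFrame], name: str) -> pd.DataFrame:
        frames = []
        for i, t in enumerate(tables):
            f = t[SCORE_COLUMNS].copy()
            f["replicate"] = i + 1
            frames.append(f)
        df = pd.concat(frames, ignore_index=True)
        df["condition"] = name
        return df

    wt = _stack(wt_tables, "wt")
    mut = _stack(mut_tables, "mut")
    shared = pd.merge(
        wt[["molecule", "position"]].drop_duplicates(),
        mut[["molecule", "position"]].drop_duplicates(),
        on=["molecule", "position"],
    )
    if shared.empty:
        raise ValueError("no shared annotated sites between conditions")

    both = pd.concat([wt, mut], ignore_index=True)
    rows = []
    for (mol, pos), _ in shared.groupby(["molecule", "position"], sort=False):
        sub = both[(both["molecule"] == mol) & (both["position"] == pos)]
        w = sub[sub["condition"] == "wt"]
        m = sub[sub["condition"] == "mut"]
        low = (
            w["label"].eq(BAND_LOW_COVERAGE).fillna(False).any()
            or m["label"].eq(BAND_LOW_COVERAGE).fillna(False).any()
            or w["score"].isna().any()
            or m["score"].isna().any()
        )
        if low:
            rows.append((mol, pos, math.nan, math.nan, math.nan,
                         len(w), len(m), "low_coverage"))
            continue
        wt_mean = float(w["score"].mean())
        mut_mean = float(m["score"].mean())
        if wt_mean == 0:
            rows.append((mol, pos, wt_mean, mut_mean, math.nan,
                         len(w), len(m), "wt_zero"))
        else:
            rows.append((mol, pos, wt_mean, mut_mean, mut_mean / wt_mean,
                         len(w), len(m), "ok"))
    return pd.DataFrame(
        rows,
        columns=["molecule", "position", "wt_mean", "mut_mean", "relative",
                 "n_wt", "n_mut", "flag"],
    )
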