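"""Reference sequences, modification-site annotations, and simulator truth.

Coordinates are 1-based on the mature rRNA throughout. "Bond i" denotes the
phosphodiester bond 3' of nucleotide i, so a molecule of length L has bonds
1..L-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "ReferenceSet",
    "ModificationAnnotation",
    "TrueMethylationProfile",
    "load_yeast_annotation",
]

_ALPHABET = set("ACGTU")

ANNOTATION_COLUMNS = ["molecule", "position", "base", "guide"]


@dataclass
class ReferenceSet:
    """Named rRNA sequences (e.g. 18S, 25S) with unique names."""

    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("reference set is empty")
        clean: dict[str, str] = {}
        for name, seq in self.sequences.items():
            seq = str(seq).upper()
            bad = set(seq) - _ALPHABET
            if bad:
                raise ValueError(
                    f"reference {name!r} contains non-ACGTU characters: {sorted(bad)}"
                )
            if name in clean:
                raise ValueError(f"duplicate reference name {name!r}")
            clean[name] = seq
        self.sequences = clean

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceSet":
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(seqs)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def items(self):
        return self.sequences.items()

    def length(self, name: str) -> int:
        return len(self.sequences[name])


@dataclass
class ModificationAnnotation:
    """Catalog of 2'-O-methylated positions per molecule.

    ``table`` columns: molecule, position (1-based), base, guide (optional
    snoRNA name, may be missing).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in ("molecule", "position"):
            if col not in df.columns:
                raise ValueError(f"annotation is missing column {col!r}")
        if "base" not in df.columns:
            df["base"] = pd.NA
        if "guide" not in df.columns:
            df["guide"] = pd.NA
        df["position"] = df["position"].astype(int)
        if (df["position"] < 1).any():
            raise ValueError("annotation positions must be >= 1")
        if df.duplicated(["molecule", "position"]).any():
            dup = df[df.duplicated(["molecule", "position"], keep=False)]
            raise ValueError(
                "duplicate (molecule, position) in annotation: "
                f"{dup[['molecule', 'position']].to_records(index=False).tolist()}"
            )
        self.table = df[ANNOTATION_COLUMNS].reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ModificationAnnotation":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def molecules(self) -> list[str]:
        return list(dict.fromkeys(self.table["molecule"]))

    def positions(self, molecule: str) -> list[int]:
        sel = self.table.loc[self.table["molecule"] == molecule, "position"]
        return sorted(int(p) for p in sel)

    def subset(self, molecule: str) -> pd.DataFrame:
        return self.table[self.table["molecule"] == molecule].reset_index(drop=True)

    def validate_against(self, reference: ReferenceSet) -> None:
        """Check every annotated position lies on its molecule and, where a
        base letter is given, matches the reference (T and U equivalent)."""
        for row in self.table.itertuples(index=False):
            if row.molecule not in reference:
                raise ValueError(f"annotated molecule {row.molecule!r} not in reference")
            L = reference.length(row.molecule)
            if not 1 <= row.position <= L:
                raise ValueError(
                    f"annotated position {row.molecule}:{row.position} outside 1..{L}"
                )
            if isinstance(row.base, str):
                ref_base = reference[row.molecule][row.position - 1]
                if ref_base.replace("T", "U") != row.base.replace("T", "U"):
                    raise ValueError(
                        f"annotation base {row.base} at {row.molecule}:{row.position} "
                        f"does not match reference base {ref_base}"
                    )


def load_yeast_annotation() -> ModificationAnnotation:
    """Load the packaged S. cerevisiae 18S/25S ribose-methylation site table
    (18 sites on 18S, 36 on 25S; guide names given where used downstream)."""
    with resources.files("riboquant.data").joinpath("yeast_rrna_nm_sites.tsv").open() as fh:
        return ModificationAnnotation(pd.read_csv(fh, sep="\t"))


@dataclass
class TrueMethylationProfile:
    """Simulator ground truth: methylated fraction f per annotated site.

    ``table`` columns: molecule, position (1-based), f in [0, 1].
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in ("molecule", "position", "f"):
            if col not in df.columns:
                raise ValueError(f"truth profile is missing column {col!r}")
        df["position"] = df["position"].astype(int)
        df["f"] = df["f"].astype(float)
        if ((df["f"] < 0) | (df["f"] > 1)).any():
            raise ValueError("methylated fractions f must lie in [0, 1]")
        if df.duplicated(["molecule", "position"]).any():
            raise ValueError("duplicate (molecule, position) in truth profile")
        self.table = df.reset_index(drop=True)

    @classmethod
    def from_mapping(cls, sites: Mapping[str, Mapping[int, float]]) -> "TrueMethylationProfile":
        rows = [
            {"molecule": mol, "position": pos, "f": f}
            for mol, d in sites.items()
            for pos, f in d.items()
        ]
        return cls(pd.DataFrame(rows, columns=["molecule", "position", "f"]))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TrueMethylationProfile":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def validate_against(self, reference: ReferenceSet) -> None:
        for row in self.table.itertuples(index=False):
            if row.molecule not in reference:
                raise ValueError(f"truth molecule {row.molecule!r} not in reference")
            L = reference.length(row.molecule)
            if not 1 <= row.position <= L:
                raise ValueError(
                    f"methylated position {row.molecule}:{row.position} outside "
                    f"reference bounds 1..{L}"
                )

    def sites(self, molecule: str) -> list[tuple[int, float]]:
        sel = self.table[self.table["molecule"] == molecule]
        return [(int(r.position), float(r.f)) for r in sel.itertuples(index=False)]

    def to_annotation(self, reference: ReferenceSet | None = None) -> ModificationAnnotation:
        df = self.table[["molecule", "position"]].copy()
        if reference is not None:
            df["base"] = [
                reference[m][p - 1] for m, p in zip(df["molecule"], df["position"])
            ]
        return ModificationAnnotation(df)
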