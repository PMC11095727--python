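"""Variant and assay-dataset containers.

A variant is a set of point substitutions applied to a wildtype amino-acid
sequence.  Substitution strings follow the ProteinGym convention
``"A23G"`` (wildtype residue, 1-based position, mutant residue), with
multiple substitutions joined by colons (``"A23G:T45K"``) and the empty
string denoting the wildtype itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical amino acids in alphabetical one-letter order.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Canonical encoding alphabet: 20 amino acids, gap, unknown (d_aa = 22).
#: The order is frozen so one-hot columns are reproducible across runs.
DEFAULT_ALPHABET = AA20 + "-X"


@dataclass(frozen=True)
class Substitution:
    """A single point substitution ``wt_aa`` → ``mut_aa`` at a 1-based position."""

    wt_aa: str
    position: int
    mut_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"mutant residue equals wildtype at {self.position}")

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass(frozen=True)
class Variant:
    """An ordered set of substitutions relative to a wildtype.

    Positions are strictly increasing; degree 0 is the wildtype itself.
    """

    substitutions: tuple[Substitution, ...] = ()

    def __post_init__(self) -> None:
        positions = [s.position for s in self.substitutions]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("substitution positions must be strictly increasing")

    @property
    def degree(self) -> int:
        """Number of substitutions (mutation degree, the *k* in kM)."""
        return len(self.substitutions)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(s.position for s in self.substitutions)

    def validate(self, wildtype: str) -> None:
        """Check every substitution against the wildtype sequence."""
        L = len(wildtype)
        for s in self.substitutions:
            if not 1 <= s.position <= L:
                raise ValueError(f"position {s.position} outside [1, {L}]")
            if wildtype[s.position - 1] != s.wt_aa:
                raise ValueError(
                    f"wildtype mismatch at {s.position}: sequence has "
                    f"{wildtype[s.position - 1]!r}, substitution says {s.wt_aa!r}"
                )

    def apply(self, wildtype: str) -> str:
        """Return the mutated full-length sequence."""
        self.validate(wildtype)
        seq = list(wildtype)
        for s in self.substitutions:
            seq[s.position - 1] = s.mut_aa
        return "".join(seq)

    def __str__(self) -> str:
        return ":".join(str(s) for s in self.substitutions)


def parse_variant(mutant: str) -> Variant:
    """Parse a colon-separated substitution string ("A23G:T45K"; "" = wildtype)."""
    mutant = mutant.strip()
    if not mutant:
        return Variant()
    subs = []
    for token in mutant.split(":"):
        token = token.strip()
        if len(token) < 3:
            raise ValueError(f"malformed substitution {token!r}")
        wt_aa, pos_str, mut_aa = token[0], token[1:-1], token[-1]
        if not pos_str.isdigit():
            raise ValueError(f"malformed substitution {token!r}")
        for aa in (wt_aa, mut_aa):
            if not (aa.isalpha() or aa in "-"):
                raise ValueError(f"malformed substitution {token!r}")
        subs.append(Substitution(wt_aa, int(pos_str), mut_aa))
    subs.sort(key=lambda s: s.position)
    return Variant(tuple(subs))


@dataclass
class AssayDataset:
    """Variants with real-valued assay labels and optional acquisition rounds."""

    variants: list[Variant]
    labels: np.ndarray
    round_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=float)
        if len(self.labels) != len(self.variants):
            raise ValueError("labels and variants length mismatch")
        if self.round_index is not None:
            self.round_index = np.asarray(self.round_index, dtype=int)
            if len(self.round_index) != len(self.variants):
                raise ValueError("round_index length mismatch")
            if np.any(self.round_index < 0):
                raise ValueError("round_index entries must be non-negative")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def degrees(self) -> np.ndarray:
        return np.array([v.degree for v in self.variants], dtype=int)

    def subset(self, indices: Sequence[int] | np.ndarray) -> "AssayDataset":
        idx = np.asarray(indices, dtype=int)
        rounds = None if self.round_index is None else self.round_index[idx]
        return AssayDataset(
            [self.variants[i] for i in idx], self.labels[idx], rounds
        )

    def to_frame(self) -> pd.DataFrame:
        data = {
            "mutant": [str(v) for v in self.variants],
            "fitness": self.labels,
        }
        if self.round_index is not None:
            data["round"] = self.round_index
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AssayDataset":
        variants = [parse_variant(m) for m in df["mutant"].fillna("")]
        rounds = df["round"].to_numpy() if "round" in df.columns else None
        return cls(variants, df["fitness"].to_numpy(dtype=float), rounds)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AssayDataset":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False,
                                          na_values=[], dtype={"mutant": str}))


def write_wildtype_fasta(wildtype: str, path: str | Path, name: str = "WT") -> None:
    record = SeqRecord(Seq(wildtype), id=name, description="wildtype sequence")
    SeqIO.write([record], str(path), "fasta")


def read_wildtype_fasta(path: str | Path) -> str:
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq)
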