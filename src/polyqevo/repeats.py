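"""Maximal glutamine-stretch detection and codon-composition statistics.

A Q stretch is a maximal run of consecutive glutamines, counted in a
non-nested way: "QQQQ" is one stretch of length four, not nested shorter
runs. Glutamine is encoded only by CAA and CAG under the standard code, so
for unambiguous records every stretch satisfies n_CAA + n_CAG == length.

Purity classes follow the four-way scheme used for orthologous regions:
all-CAG, all-CAA, a CAG/CAA mix, or a run containing interrupting non-Q
codons (reachable only for merged aligned regions, where non-Q residues may
sit between the first and last glutamine).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .io import GeneRecord

Q_CODONS = ("CAA", "CAG")


class PurityClass(enum.Enum):
    PURE_CAG = "PURE_CAG"
    MIX_CAG_CAA = "MIX_CAG_CAA"
    MIX_WITH_OTHER = "MIX_WITH_OTHER"
    PURE_CAA = "PURE_CAA"


@dataclass(frozen=True)
class QStretch:
    """One maximal glutamine run with its codon composition.

    Coordinates are 0-based half-open on the protein.
    """

    protein_id: str
    species: str
    start: int
    end: int
    codon_run: tuple[str, ...]
    ambiguous: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_CAA(self) -> int:
        return sum(c == "CAA" for c in self.codon_run)

    @property
    def n_CAG(self) -> int:
        return sum(c == "CAG" for c in self.codon_run)


def find_q_stretches(record: GeneRecord) -> list[QStretch]:
    """Return every maximal run of consecutive Q in the protein, in order.

    Runs of length 1 and above are all reported. Stretches inherit the
    record's ambiguity flag so codon tallies can exclude them downstream.
    """
    seq = record.protein_seq
    out: list[QStretch] = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == "Q":
            j = i
            while j < n and seq[j] == "Q":
                j += 1
            out.append(QStretch(record.protein_id, record.species, i, j,
                                record.codons[i:j], ambiguous=record.ambiguous))
            i = j
        else:
            i += 1
    return out


def classify_purity(codon_run: Sequence[str]) -> PurityClass:
    """Classify a codon run containing at least one glutamine codon."""
    run = list(codon_run)
    if not any(c in Q_CODONS for c in run):
        raise ValueError("codon run contains no glutamine codon")
    if all(c == "CAG" for c in run):
        return PurityClass.PURE_CAG
    if all(c == "CAA" for c in run):
        return PurityClass.PURE_CAA
    if any(c not in Q_CODONS for c in run):
        return PurityClass.MIX_WITH_OTHER
    return PurityClass.MIX_CAG_CAA


def max_codon_run(codon_run: Sequence[str], target: str) -> int:
    """Length of the longest block of consecutive ``target`` codons."""
    best = cur = 0
    for c in codon_run:
        cur = cur + 1 if c == target else 0
        best = max(best, cur)
    return best


def stretch_table(stretches: Iterable[QStretch]) -> pd.DataFrame:
    """Tabulate stretches with 1-based inclusive coordinates."""
    rows = []
    for s in stretches:
        rows.append({
            "protein_id": s.protein_id,
            "species": s.species,
            "start_1based": s.start + 1,
            "end_1based": s.end,
            "length": s.length,
            "n_CAA": s.n_CAA,
            "n_CAG": s.n_CAG,
            "purity": classify_purity(s.codon_run).value,
            "max_run_CAG": max_codon_run(s.codon_run, "CAG"),
            "max_run_CAA": max_codon_run(s.codon_run, "CAA"),
            "ambiguous": int(s.ambiguous),
        })
    cols = ["protein_id", "species", "start_1based", "end_1based", "length",
            "n_CAA", "n_CAG", "purity", "max_run_CAG", "max_run_CAA",
            "ambiguous"]
    return pd.DataFrame(rows, columns=cols)


def write_stretch_table(stretches: Iterable[QStretch],
                        path: str | Path) -> None:
    stretch_table(stretches).to_csv(path, sep="\t", index=False)
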