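"""Ortholog-group alignment, codon back-translation and polyQ region calls.

The multiple protein alignment is a deterministic center-star construction:
every non-reference member is globally aligned to the reference (affine-gap
Needleman–Wunsch, BLOSUM62, gap open 10 / extend 0.5) and the pairwise
alignments are merged on reference coordinates, insertions left-aligned.
This is not a full progressive aligner, but orthologous polyQ blocks only
need column-consistent correspondence to the reference, which the
center-star merge guarantees; an external aligner callable can be hooked in
for users who want T-Coffee-grade gap placement.

An orthologous polyQ region is seeded by any member's pure glutamine run of
length >= 4, mapped to alignment columns; overlapping seeds are merged, and
each region is extended over any flanking column in which some member still
carries a glutamine. The merged glutamine length of a member counts all its
Q residues in the region interval, including glutamines separated by
interrupting residues: QQQQPQQQQ counts 8, QQQQQQQQQ counts 9.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io import GeneRecord, OrthologGroup
from .repeats import Q_CODONS, classify_purity, max_codon_run

GAP = "-"

#: signature of an external alignment engine: takes the sequences in order,
#: returns equal-length gapped rows. Used in place of the built-in merge.
ExternalAligner = Callable[[Sequence[str]], Sequence[str]]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def pairwise_align(a: str, b: str) -> tuple[str, str, float]:
    """Optimal global affine-gap alignment of two protein sequences.

    Returns the two gapped rows and the alignment score.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aln = _ALIGNER.align(a, b)[0]
    return aln[0], aln[1], aln.score


@dataclass(frozen=True)
class ProteinMSA:
    """Equal-length gapped protein rows for one ortholog group."""

    group_id: str
    species: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("MSA rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, species: str) -> str:
        return self.rows[self.species.index(species)]

    def ungapped(self, species: str) -> str:
        return self.row(species).replace(GAP, "")

    def residue_columns(self, species: str) -> list[int]:
        """Alignment column of each ungapped residue, in sequence order."""
        return [i for i, ch in enumerate(self.row(species)) if ch != GAP]


@dataclass(frozen=True)
class CodonMSA:
    """Same row/column structure as the protein MSA; non-gap cells carry
    that residue's codon, gap cells carry None."""

    group_id: str
    species: tuple[str, ...]
    rows: tuple[tuple[str | None, ...], ...]

    def row(self, species: str) -> tuple[str | None, ...]:
        return self.rows[self.species.index(species)]


def align_group(group: OrthologGroup,
                divergence: Mapping[str, float],
                external: ExternalAligner | None = None) -> ProteinMSA:
    """Build the group's protein MSA.

    Member order in the MSA is by increasing divergence to the reference
    (ties by species code); the reference species (divergence 0) is the
    center of the star. ``external`` substitutes the alignment engine but
    must honour the same contract (ungapping each row reproduces the input).
    """
    order = sorted(group.members,
                   key=lambda sp: (divergence.get(sp, float("inf")), sp))
    seqs = [group.members[sp].protein_seq for sp in order]
    if any(not s for s in seqs):
        raise ValueError(f"group {group.group_id}: empty sequence")
    if external is not None:
        rows = tuple(external(seqs))
    elif len(seqs) == 1:
        rows = (seqs[0],)
    else:
        rows = _center_star(seqs)
    msa = ProteinMSA(group.group_id, tuple(order), rows)
    for sp in order:
        if msa.ungapped(sp) != group.members[sp].protein_seq:
            raise AssertionError("alignment does not reproduce input sequence")
    return msa


def _center_star(seqs: Sequence[str]) -> tuple[str, ...]:
    """Merge pairwise alignments against seqs[0] on its coordinates."""
    center = seqs[0]
    n = len(center)
    # per sequence: insertion blocks before each center position (index 0..n)
    # and the character aligned to each center residue
    parsed = []
    max_ins = [0] * (n + 1)
    for seq in seqs[1:]:
        crow, srow, _ = pairwise_align(center, seq)
        ins: list[list[str]] = [[] for _ in range(n + 1)]
        aligned = [GAP] * n
        ci = 0
        for cch, sch in zip(crow, srow):
            if cch == GAP:
                if sch != GAP:
                    ins[ci].append(sch)
            else:
                aligned[ci] = sch
                ci += 1
        parsed.append((ins, aligned))
        for i in range(n + 1):
            max_ins[i] = max(max_ins[i], len(ins[i]))

    def build(ins: list[list[str]], aligned: list[str]) -> str:
        parts = []
        for i in range(n):
            block = "".join(ins[i])
            parts.append(block + GAP * (max_ins[i] - len(block)))
            parts.append(aligned[i])
        block = "".join(ins[n])
        parts.append(block + GAP * (max_ins[n] - len(block)))
        return "".join(parts)

    rows = [build([[] for _ in range(n + 1)], list(center))]
    for ins, aligned in parsed:
        rows.append(build(ins, aligned))
    return tuple(rows)


def backtranslate(msa: ProteinMSA, group: OrthologGroup) -> CodonMSA:
    """Attach each residue's codon to its alignment cell."""
    rows = []
    for sp in msa.species:
        record = group.members[sp]
        row = msa.row(sp)
        if len(row) - row.count(GAP) != len(record.codons):
            raise ValueError(f"{sp}: residue/codon count mismatch")
        it = iter(record.codons)
        rows.append(tuple(next(it) if ch != GAP else None for ch in row))
    return CodonMSA(msa.group_id, msa.species, tuple(rows))


@dataclass(frozen=True)
class RegionMember:
    """One species' view of an aligned polyQ region."""

    species: str
    merged_q_length: int
    codon_run: tuple[str, ...]  # trimmed to first..last glutamine codon
    ambiguous: bool

    @property
    def n_CAA(self) -> int:
        return sum(c == "CAA" for c in self.codon_run)

    @property
    def n_CAG(self) -> int:
        return sum(c == "CAG" for c in self.codon_run)


@dataclass(frozen=True)
class AlignedRegion:
    """A column interval of the MSA covering one orthologous polyQ."""

    group_id: str
    region_id: str
    c_start: int  # 0-based half-open alignment columns
    c_end: int
    members: Mapping[str, RegionMember]


def _q_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal Q runs of a (gapped or ungapped) string, 0-based half-open,
    in residue coordinates of the ungapped sequence."""
    runs = []
    i = 0
    ungapped = seq.replace(GAP, "")
    n = len(ungapped)
    while i < n:
        if ungapped[i] == "Q":
            j = i
            while j < n and ungapped[j] == "Q":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def delineate_regions(msa: ProteinMSA, min_seed: int = 4) -> list[AlignedRegion]:
    """Call independent orthologous polyQ regions on the alignment.

    Seeds are members' pure Q runs of length >= ``min_seed`` mapped to
    their column spans; overlapping seeds merge; each interval extends over
    adjacent columns while any member carries a glutamine there, and
    intervals that meet after extension merge into one region.
    """
    col_has_q = [False] * msa.n_columns
    seed_spans: list[tuple[int, int]] = []
    for sp in msa.species:
        cols = msa.residue_columns(sp)
        row_ungapped = msa.ungapped(sp)
        for i, ch in enumerate(row_ungapped):
            if ch == "Q":
                col_has_q[cols[i]] = True
        for a, b in _q_runs(row_ungapped):
            if b - a >= min_seed:
                seed_spans.append((cols[a], cols[b - 1] + 1))
    if not seed_spans:
        return []

    # merge overlapping seeds, extend through Q-bearing columns, re-merge
    spans = _merge_spans(seed_spans)
    changed = True
    while changed:
        changed = False
        extended = []
        for a, b in spans:
            while a > 0 and col_has_q[a - 1]:
                a -= 1
            while b < msa.n_columns and col_has_q[b]:
                b += 1
            extended.append((a, b))
        merged = _merge_spans(extended)
        if merged != spans:
            changed = True
        spans = merged

    regions = []
    for k, (a, b) in enumerate(spans, start=1):
        regions.append(AlignedRegion(msa.group_id, f"{msa.group_id}_r{k}",
                                     a, b, {}))
    return regions


def _merge_spans(spans: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for a, b in sorted(spans):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def annotate_region(region: AlignedRegion, msa: ProteinMSA, codon_msa: CodonMSA,
                    group: OrthologGroup) -> AlignedRegion:
    """Fill per-member merged lengths and trimmed codon runs for a region."""
    members = {}
    for sp in msa.species:
        row = msa.row(sp)[region.c_start:region.c_end]
        codons = codon_msa.row(sp)[region.c_start:region.c_end]
        residues = [(ch, cd) for ch, cd in zip(row, codons) if ch != GAP]
        q_idx = [i for i, (ch, _) in enumerate(residues) if ch == "Q"]
        merged = len(q_idx)
        if q_idx:
            run = tuple(cd for _, cd in residues[q_idx[0]:q_idx[-1] + 1]
                        if cd is not None)
        else:
            run = ()
        members[sp] = RegionMember(sp, merged, run,
                                   group.members[sp].ambiguous)
    return AlignedRegion(region.group_id, region.region_id, region.c_start,
                         region.c_end, members)


def call_regions(group: OrthologGroup, divergence: Mapping[str, float],
                 min_seed: int = 4,
                 external: ExternalAligner | None = None,
                 ) -> tuple[ProteinMSA, CodonMSA, list[AlignedRegion]]:
    """Align, back-translate and delineate one group end to end."""
    msa = align_group(group, divergence, external=external)
    codon_msa = backtranslate(msa, group)
    regions = [annotate_region(r, msa, codon_msa, group)
               for r in delineate_regions(msa, min_seed=min_seed)]
    return msa, codon_msa, regions


def merged_q_length(region: AlignedRegion, species: str) -> int:
    return region.members[species].merged_q_length


def region_table(regions: Sequence[AlignedRegion]) -> pd.DataFrame:
    """Per-region, per-species table (1-based inclusive column interval)."""
    rows = []
    for r in regions:
        for sp, m in r.members.items():
            has_q = any(c in Q_CODONS for c in m.codon_run)
            rows.append({
                "group_id": r.group_id,
                "region_id": r.region_id,
                "c_start_1based": r.c_start + 1,
                "c_end_1based": r.c_end,
                "species": sp,
                "merged_q_length": m.merged_q_length,
                "purity": classify_purity(m.codon_run).value if has_q else "",
                "n_CAA": m.n_CAA,
                "n_CAG": m.n_CAG,
                "max_run_CAG": max_codon_run(m.codon_run, "CAG"),
                "max_run_CAA": max_codon_run(m.codon_run, "CAA"),
            })
    cols = ["group_id", "region_id", "c_start_1based", "c_end_1based",
            "species", "merged_q_length", "purity", "n_CAA", "n_CAG",
            "max_run_CAG", "max_run_CAA"]
    return pd.DataFrame(rows, columns=cols)


def write_msa_fasta(msa: ProteinMSA, group: OrthologGroup,
                    path: str | Path) -> None:
    with open(path, "w") as fh:
        for sp in msa.species:
            fh.write(f">{group.members[sp].protein_id} {sp}\n")
            fh.write(msa.row(sp) + "\n")
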