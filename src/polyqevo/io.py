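"""Reading and validation of pipeline inputs.

Inputs are paired protein/CDS FASTA files per species, a tab-separated
ortholog table (``group_id  species  protein_id``), a species configuration
(``species_code  divergence_myr``, reference species at 0 Myr) and an
optional disease-panel table. Every record entering the pipeline is checked
for CDS/protein consistency: the coding sequence (after stripping one
terminal stop codon) must be exactly three nucleotides per residue and must
translate to the peptide under the standard genetic code.

Coordinates are 0-based half-open internally; user-facing tables are
1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_FORWARD = standard_dna_table.forward_table  # codon -> amino acid, stops excluded
_STOPS = set(standard_dna_table.stop_codons)
_UNAMBIGUOUS = set("ACGT")

#: reason codes for excluded / flagged records
LENGTH_MISMATCH = "LENGTH_MISMATCH"
TRANSLATION_MISMATCH = "TRANSLATION_MISMATCH"
AMBIGUOUS_NT = "AMBIGUOUS_NT"


@dataclass(frozen=True)
class GeneRecord:
    """One validated protein with its coding sequence, split into codons.

    ``ambiguous`` marks records containing non-ACGT nucleotides inside a
    codon; such records are kept for length-based analyses but excluded
    from CAA/CAG tallies.
    """

    protein_id: str
    species: str
    protein_seq: str
    cds_seq: str
    codons: tuple[str, ...]
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if len(self.codons) != len(self.protein_seq):
            raise ValueError("codons and protein_seq length differ")


@dataclass(frozen=True)
class SpeciesConfig:
    """A species code and its divergence time (Myr) to the reference."""

    species_code: str
    divergence_myr: float


@dataclass(frozen=True)
class OrthologGroup:
    """One ortholog set: one GeneRecord per configured species."""

    group_id: str
    members: Mapping[str, GeneRecord]  # species code -> record

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.members)


@dataclass
class FastaPairResult:
    """Outcome of reading one protein/CDS FASTA pair.

    input count == len(records) + len(excluded) + len(unmatched)
    (record conservation).
    """

    records: list[GeneRecord] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)
    unmatched: list[str] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return len(self.records) + len(self.excluded) + len(self.unmatched)


def validate_record(protein_id: str, species: str, protein_seq: str,
                    cds_seq: str) -> GeneRecord | tuple[str, str]:
    """Validate one protein/CDS pair.

    Returns a GeneRecord on success, or ``(protein_id, reason)`` on
    rejection. A single terminal stop codon is tolerated and stripped;
    internal stops or any codon translating to the wrong residue reject the
    record; ambiguous nucleotides flag it instead.
    """
    protein_seq = "".join(protein_seq.split()).upper()
    cds_seq = "".join(cds_seq.split()).upper().replace("U", "T")
    n = len(protein_seq)
    if len(cds_seq) == 3 * n + 3 and cds_seq[-3:] in _STOPS:
        cds_seq = cds_seq[:-3]
    if len(cds_seq) != 3 * n:
        return (protein_id, LENGTH_MISMATCH)
    codons = tuple(cds_seq[i:i + 3] for i in range(0, 3 * n, 3))
    ambiguous = False
    for codon, aa in zip(codons, protein_seq):
        if not set(codon) <= _UNAMBIGUOUS:
            ambiguous = True
            continue
        if _FORWARD.get(codon) != aa:
            return (protein_id, TRANSLATION_MISMATCH)
    return GeneRecord(protein_id, species, protein_seq, cds_seq, codons,
                      ambiguous=ambiguous)


def read_fasta_pair(protein_path: str | Path, cds_path: str | Path,
                    species: str) -> FastaPairResult:
    """Read a protein FASTA and its matching CDS FASTA for one species.

    Records are matched by the header token before the first whitespace.
    Identifiers present in only one of the two files are skipped with a
    warning; records failing validation are excluded with a reason code.
    """
    proteins = {r.id: str(r.seq) for r in SeqIO.parse(str(protein_path), "fasta")}
    cds = {r.id: str(r.seq) for r in SeqIO.parse(str(cds_path), "fasta")}
    result = FastaPairResult()
    for pid in list(proteins) + [c for c in cds if c not in proteins]:
        if pid not in proteins or pid not in cds:
            logger.warning("%s: id %r present in only one file, skipped",
                           species, pid)
            result.unmatched.append(pid)
            continue
        out = validate_record(pid, species, proteins[pid], cds[pid])
        if isinstance(out, GeneRecord):
            if out.ambiguous:
                logger.warning("%s/%s: %s (kept for length analyses)",
                               species, pid, AMBIGUOUS_NT)
            result.records.append(out)
        else:
            logger.warning("%s/%s: excluded (%s)", species, pid, out[1])
            result.excluded.append(out)
    return result


def write_fasta(records: Iterable[GeneRecord], protein_path: str | Path,
                cds_path: str | Path) -> None:
    """Write GeneRecords back out as a protein/CDS FASTA pair."""
    records = list(records)
    SeqIO.write((SeqRecord(Seq(r.protein_seq), id=r.protein_id, description="")
                 for r in records), str(protein_path), "fasta")
    SeqIO.write((SeqRecord(Seq(r.cds_seq), id=r.protein_id, description="")
                 for r in records), str(cds_path), "fasta")


def read_species_config(path: str | Path) -> list[SpeciesConfig]:
    """Read the species table; exactly one species must sit at 0 Myr."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["species_code", "divergence_myr"],
                     comment="#", dtype={"species_code": str})
    cfg = [SpeciesConfig(str(r.species_code), float(r.divergence_myr))
           for r in df.itertuples()]
    codes = [c.species_code for c in cfg]
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate species codes in species config")
    n_ref = sum(1 for c in cfg if c.divergence_myr == 0)
    if n_ref != 1:
        raise ValueError(f"species config must have exactly one reference "
                         f"(divergence 0), found {n_ref}")
    if any(c.divergence_myr < 0 for c in cfg):
        raise ValueError("negative divergence time")
    return cfg


def reference_species(cfg: Sequence[SpeciesConfig]) -> str:
    return next(c.species_code for c in cfg if c.divergence_myr == 0)


def divergence_map(cfg: Sequence[SpeciesConfig]) -> dict[str, float]:
    return {c.species_code: c.divergence_myr for c in cfg}


@dataclass
class OrthologTableResult:
    groups: list[OrthologGroup]
    n_dropped_incomplete: int


def read_ortholog_table(path: str | Path, species_set: Sequence[str],
                        records_by_species: Mapping[str, Mapping[str, GeneRecord]],
                        ) -> OrthologTableResult:
    """Assemble complete ortholog groups from the mapping table.

    Groups missing any configured species (after record validation) are
    dropped and counted. When a species contributes several candidate
    proteins to one group, the longest protein is chosen, ties broken by
    lexicographically smallest protein id.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"group_id", "species", "protein_id"}
    if not required <= set(df.columns):
        raise ValueError(f"ortholog table must have columns {sorted(required)}")
    unknown = set(df["species"]) - set(species_set)
    if unknown:
        raise ValueError(f"unknown species code(s) in ortholog table: "
                         f"{sorted(unknown)}")
    groups: list[OrthologGroup] = []
    n_dropped = 0
    for gid, sub in df.groupby("group_id", sort=True):
        members: dict[str, GeneRecord] = {}
        for sp in species_set:
            candidates = [
                records_by_species.get(sp, {}).get(pid)
                for pid in sub.loc[sub["species"] == sp, "protein_id"]
            ]
            candidates = [c for c in candidates if c is not None]
            if not candidates:
                break
            members[sp] = min(candidates,
                              key=lambda r: (-len(r.protein_seq), r.protein_id))
        if len(members) == len(species_set):
            groups.append(OrthologGroup(str(gid), members))
        else:
            n_dropped += 1
    logger.info("ortholog table: %d complete groups, %d dropped as incomplete",
                len(groups), n_dropped)
    return OrthologTableResult(groups, n_dropped)


@dataclass(frozen=True)
class PanelEntry:
    """A reference protein with the 1-based coordinates of its
    disease-associated Q stretch."""

    protein_id: str
    disease: str
    q_start: int  # 1-based inclusive
    q_end: int    # 1-based inclusive


def read_panel_table(path: str | Path) -> list[PanelEntry]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "disease": str})
    required = {"protein_id", "disease", "q_start", "q_end"}
    if not required <= set(df.columns):
        raise ValueError(f"panel table must have columns {sorted(required)}")
    entries = [PanelEntry(str(r.protein_id), str(r.disease), int(r.q_start),
                          int(r.q_end)) for r in df.itertuples()]
    for e in entries:
        if not 1 <= e.q_start <= e.q_end:
            raise ValueError(f"panel entry {e.protein_id}: bad coordinates "
                             f"{e.q_start}-{e.q_end}")
    return entries
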