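"""Synthetic primate-like ortholog sets with planted polyQ structure.

The generator embodies the evolutionary picture the analysis is built to
detect: glutamine codon usage depends on stretch length, and long pure CAG
runs destabilize a stretch through replication slippage. Each ortholog
group starts from an ancestral protein containing background glutamine
stretches (about ten single Q, one QQ and 0.1 QQQ per protein) and one
planted polyQ seed. The ancestor evolves along a star of branches scaled
by divergence time; per slippage round a stretch expands with probability
p_exp = min(cap, slip_rate * r^slip_exponent) where r is its longest
consecutive-CAG run, and contracts with a fixed fraction of that. An
expansion duplicates a randomly chosen codon in place (slippage copies a
neighbour), so CAG-rich stretches both grow and stay CAG-rich; a
contraction deletes a uniformly chosen codon. Background residues never
mutate — orthology is by construction, not inference.

Glutamine codons are drawn CAG with probability theta(bin of the ancestral
stretch length): defaults 0.70 for lengths 1-3, 0.80 for 4-8 and 0.77
above 8, the pattern seen across primate proteomes. Long planted stretches
may carry one non-glutamine interrupting codon (a proline), producing
merged regions whose purity class is MIX_WITH_OTHER.

A separate small panel of groups emulates disease-associated proteins:
high CAG content (theta 0.92), long reference stretches, and
contraction-biased evolution so distant species carry shorter versions,
with occasional missing orthologs.

Everything is driven by one seedable generator; the same seed yields
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .io import GeneRecord, OrthologGroup, PanelEntry, SpeciesConfig, write_fasta
from .repeats import max_codon_run
from .stability import classify_stability

#: 12 primate-like species with divergence times (Myr) to the reference,
#: spanning the ~74 Myr of the primate radiation.
DEFAULT_SPECIES: tuple[tuple[str, float], ...] = (
    ("hsa", 0.0), ("ptr", 6.7), ("ggo", 9.1), ("pab", 15.8), ("nle", 20.2),
    ("mmul", 29.4), ("csa", 29.4), ("pan", 29.4), ("cja", 43.2),
    ("csy", 69.0), ("oga", 74.0), ("mmur", 74.0),
)

# background amino-acid frequencies (glutamine excluded: every Q is planted)
_BG_AA = "ACDEFGHIKLMNPRSTVWY"
_BG_W = np.array([0.080, 0.020, 0.052, 0.068, 0.040, 0.072, 0.023, 0.060,
                  0.059, 0.100, 0.022, 0.042, 0.050, 0.053, 0.081, 0.055,
                  0.069, 0.013, 0.031])
_BG_W = _BG_W / _BG_W.sum()

_SYNONYMS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _SYNONYMS.setdefault(_aa, ())
    _SYNONYMS[_aa] = _SYNONYMS[_aa] + (_codon,)
_SYNONYMS = {aa: tuple(sorted(cs)) for aa, cs in _SYNONYMS.items()}

_PROLINE_CODONS = ("CCA", "CCC", "CCG", "CCT")


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults are the study conditions."""

    species: tuple[tuple[str, float], ...] = DEFAULT_SPECIES
    n_groups: int = 300
    seed: int = 42
    # background stretch spectrum: expected stretches per protein by length
    stretch_rates: tuple[tuple[int, float], ...] = ((1, 10.0), (2, 1.0),
                                                    (3, 0.1))
    # CAG probability per glutamine codon, by ancestral stretch-length bin
    theta_1_3: float = 0.70
    theta_4_8: float = 0.80
    theta_gt8: float = 0.77
    # planted polyQ seed
    polyq_len_min: int = 4
    polyq_len_max: int = 13
    interruption_rate: float = 0.05  # one proline inside planted length > 8
    # spacers between stretches
    spacer_min: int = 5
    spacer_max: int = 40
    # slippage model
    rounds_per_myr: float = 0.18
    slip_rate: float = 2.4e-5
    slip_exponent: float = 5.5
    slip_cap: float = 0.8
    contraction_ratio: float = 0.95
    # disease-like panel
    n_panel: int = 9
    theta_panel: float = 0.92
    panel_len_min: int = 9
    panel_len_max: int = 23
    panel_contract_rate: float = 0.35  # per round at 74 Myr, scales with t
    panel_expand_rate: float = 0.03
    panel_dropout: float = 0.1

    def theta(self, length: int) -> float:
        if length <= 3:
            return self.theta_1_3
        return self.theta_4_8 if length <= 8 else self.theta_gt8

    def validate(self) -> None:
        probs = [self.theta_1_3, self.theta_4_8, self.theta_gt8,
                 self.interruption_rate, self.slip_cap,
                 self.contraction_ratio, self.theta_panel,
                 self.panel_contract_rate, self.panel_expand_rate,
                 self.panel_dropout]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_groups < 1 or self.polyq_len_min < 4:
            raise ValueError("need n_groups >= 1 and polyq_len_min >= 4")
        if self.polyq_len_max < self.polyq_len_min:
            raise ValueError("empty planted length range")
        codes = [sp for sp, _ in self.species]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate species codes")
        if sum(1 for _, t in self.species if t == 0) != 1:
            raise ValueError("exactly one reference species (0 Myr) required")


# ---------------------------------------------------------------------------
# ancestral proteins

@dataclass
class _Segment:
    kind: str                  # "bg" | "q"
    codons: list[str]
    planted: bool = False      # the polyQ seed segment


def _sample_bg_segment(rng: np.random.Generator, length: int) -> _Segment:
    residues = rng.choice(list(_BG_AA), size=length, p=_BG_W)
    codons = [_SYNONYMS[aa][rng.integers(len(_SYNONYMS[aa]))]
              for aa in residues]
    return _Segment("bg", codons)


def _sample_q_codons(rng: np.random.Generator, length: int,
                     theta: float) -> list[str]:
    return ["CAG" if rng.random() < theta else "CAA" for _ in range(length)]


def _sample_polyq_codons(rng: np.random.Generator, length: int,
                         theta: float) -> list[str]:
    """Planted polyQ codons with a stratified CAG count.

    The number of CAG codons is length * theta rounded stochastically, the
    arrangement uniform; per-region CAG content then scatters tightly
    around theta while run structure still varies. A side effect matching
    real primate polyQ: all-CAA regions essentially never occur.
    """
    expected = length * theta
    n_cag = int(expected) + (1 if rng.random() < expected - int(expected)
                             else 0)
    n_cag = min(n_cag, length)
    codons = ["CAG"] * n_cag + ["CAA"] * (length - n_cag)
    rng.shuffle(codons)
    return codons


def _build_ancestor(rng: np.random.Generator, cfg: SimConfig,
                    planted_len: int | None,
                    theta_planted: float | None = None) -> list[_Segment]:
    stretches: list[_Segment] = []
    for length, rate in cfg.stretch_rates:
        for _ in range(rng.poisson(rate)):
            stretches.append(_Segment(
                "q", _sample_q_codons(rng, length, cfg.theta(length))))
    if planted_len is not None:
        theta = cfg.theta(planted_len) if theta_planted is None else theta_planted
        codons = _sample_polyq_codons(rng, planted_len, theta)
        if (planted_len > 8 and theta_planted is None
                and rng.random() < cfg.interruption_rate):
            pos = int(rng.integers(1, planted_len - 1))
            codons[pos] = _PROLINE_CODONS[rng.integers(4)]
        stretches.append(_Segment("q", codons, planted=True))
    rng.shuffle(stretches)
    segments: list[_Segment] = []
    for s in stretches:
        segments.append(_sample_bg_segment(
            rng, int(rng.integers(cfg.spacer_min, cfg.spacer_max + 1))))
        segments.append(s)
    segments.append(_sample_bg_segment(
        rng, int(rng.integers(cfg.spacer_min, cfg.spacer_max + 1))))
    return segments


# ---------------------------------------------------------------------------
# branch evolution

def _longest_run_span(codons: Sequence[str], target: str) -> tuple[int, int]:
    """First maximal block of consecutive ``target`` codons, half-open."""
    best = (0, 0)
    i = 0
    n = len(codons)
    while i < n:
        if codons[i] == target:
            j = i
            while j < n and codons[j] == target:
                j += 1
            if j - i > best[1] - best[0]:
                best = (i, j)
            i = j
        else:
            i += 1
    return best


def _slip_round(codons: list[str], cfg: SimConfig,
                rng: np.random.Generator) -> list[str]:
    if not codons:
        return codons
    run = max_codon_run(codons, "CAG")
    p_exp = min(cfg.slip_cap, cfg.slip_rate * run ** cfg.slip_exponent)
    if rng.random() < p_exp:
        # slippage acts inside the run that drives it: duplicate a codon of
        # the longest CAG block (falling back to anywhere if there is none)
        a, b = _longest_run_span(codons, "CAG")
        i = int(rng.integers(a, b)) if b > a else int(rng.integers(len(codons)))
        codons = codons[:i] + [codons[i]] + codons[i:]
    if codons and rng.random() < p_exp * cfg.contraction_ratio:
        a, b = _longest_run_span(codons, "CAG")
        i = int(rng.integers(a, b)) if b > a else int(rng.integers(len(codons)))
        codons = codons[:i] + codons[i + 1:]
    return codons


def _evolve_segments(segments: Sequence[_Segment], t_myr: float,
                     cfg: SimConfig, rng: np.random.Generator,
                     panel: bool = False) -> list[_Segment]:
    out = []
    for seg in segments:
        if seg.kind != "q":
            out.append(seg)
            continue
        codons = list(seg.codons)
        rounds = int(rng.poisson(cfg.rounds_per_myr * t_myr))
        for _ in range(rounds):
            if panel and seg.planted:
                scale = t_myr / 74.0
                if codons and rng.random() < cfg.panel_contract_rate * scale:
                    i = int(rng.integers(len(codons)))
                    codons = codons[:i] + codons[i + 1:]
                if codons and rng.random() < cfg.panel_expand_rate:
                    i = int(rng.integers(len(codons)))
                    codons = codons[:i] + [codons[i]] + codons[i:]
            else:
                codons = _slip_round(codons, cfg, rng)
        out.append(_Segment(seg.kind, codons, planted=seg.planted))
    return out


def _to_record(segments: Sequence[_Segment], protein_id: str,
               species: str) -> GeneRecord:
    codons = [c for seg in segments for c in seg.codons]
    protein = "".join(standard_dna_table.forward_table[c] for c in codons)
    return GeneRecord(protein_id, species, protein, "".join(codons),
                      tuple(codons))


def _planted_stats(segments: Sequence[_Segment]) -> tuple[int, int, int, str]:
    for seg in segments:
        if seg.planted:
            n_q = sum(c in ("CAA", "CAG") for c in seg.codons)
            n_caa = sum(c == "CAA" for c in seg.codons)
            n_cag = sum(c == "CAG" for c in seg.codons)
            return n_q, n_caa, n_cag, ",".join(seg.codons)
    return 0, 0, 0, ""


# ---------------------------------------------------------------------------
# dataset

@dataclass
class SimulatedDataset:
    config: SimConfig
    species_config: list[SpeciesConfig]
    records: dict[str, list[GeneRecord]]        # species -> main proteome
    groups: list[OrthologGroup]
    truth: pd.DataFrame
    panel_records: dict[str, list[GeneRecord]]  # species -> panel orthologs
    panel_groups: list[OrthologGroup]
    panel_entries: list[PanelEntry]

    def write(self, outdir: str | Path) -> None:
        """Emit the full file set the pipeline reads, plus the truth table."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "species.tsv", "w") as fh:
            for sc in self.species_config:
                fh.write(f"{sc.species_code}\t{sc.divergence_myr}\n")
        rows = [{"group_id": g.group_id, "species": sp,
                 "protein_id": g.members[sp].protein_id}
                for g in self.groups for sp in g.species]
        pd.DataFrame(rows).to_csv(outdir / "orthologs.tsv", sep="\t",
                                  index=False)
        for sp, recs in self.records.items():
            write_fasta(recs, outdir / f"{sp}_prot.fa", outdir / f"{sp}_cds.fa")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        if self.panel_groups:
            rows = [{"group_id": g.group_id, "species": sp,
                     "protein_id": g.members[sp].protein_id}
                    for g in self.panel_groups for sp in g.species]
            pd.DataFrame(rows).to_csv(outdir / "panel_orthologs.tsv",
                                      sep="\t", index=False)
            for sp, recs in self.panel_records.items():
                write_fasta(recs, outdir / f"{sp}_panel_prot.fa",
                            outdir / f"{sp}_panel_cds.fa")
            pd.DataFrame([{"protein_id": e.protein_id, "disease": e.disease,
                           "q_start": e.q_start, "q_end": e.q_end}
                          for e in self.panel_entries]).to_csv(
                outdir / "panel.tsv", sep="\t", index=False)


def simulate_dataset(config: SimConfig | None = None) -> SimulatedDataset:
    """Generate a complete synthetic data set (see module docstring)."""
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    species_config = [SpeciesConfig(sp, t) for sp, t in cfg.species]
    divergence = {sp: t for sp, t in cfg.species}
    reference = next(sp for sp, t in cfg.species if t == 0)

    records: dict[str, list[GeneRecord]] = {sp: [] for sp, _ in cfg.species}
    groups: list[OrthologGroup] = []
    truth_rows: list[dict] = []
    for g in range(1, cfg.n_groups + 1):
        gid = f"G{g:04d}"
        planted_len = int(rng.integers(cfg.polyq_len_min,
                                       cfg.polyq_len_max + 1))
        ancestor = _build_ancestor(rng, cfg, planted_len)
        members: dict[str, GeneRecord] = {}
        lengths: dict[str, int] = {}
        member_stats = {}
        for sp, t in cfg.species:
            segs = _evolve_segments(ancestor, t, cfg, rng)
            rec = _to_record(segs, f"{gid}_{sp}", sp)
            records[sp].append(rec)
            members[sp] = rec
            n_q, n_caa, n_cag, codon_str = _planted_stats(segs)
            lengths[sp] = n_q
            member_stats[sp] = (n_q, n_caa, n_cag, codon_str)
        stab = classify_stability(lengths, divergence, region_id=gid)
        for sp, _ in cfg.species:
            n_q, n_caa, n_cag, codon_str = member_stats[sp]
            truth_rows.append({
                "group_id": gid, "region_ordinal": 1, "species": sp,
                "planted_length": n_q, "ancestral_length": planted_len,
                "n_CAA": n_caa, "n_CAG": n_cag,
                "is_stable": int(stab.is_stable),
                "assigned_length": stab.assigned_length,
                "planted_codons": codon_str,
            })
        groups.append(OrthologGroup(gid, members))

    panel_records: dict[str, list[GeneRecord]] = {sp: [] for sp, _ in cfg.species}
    panel_groups: list[OrthologGroup] = []
    panel_entries: list[PanelEntry] = []
    for p in range(1, cfg.n_panel + 1):
        gid = f"P{p:02d}"
        planted_len = int(rng.integers(cfg.panel_len_min,
                                       cfg.panel_len_max + 1))
        ancestor = _build_ancestor(rng, cfg, planted_len,
                                   theta_planted=cfg.theta_panel)
        members = {}
        for sp, t in cfg.species:
            if sp != reference and rng.random() < cfg.panel_dropout:
                continue
            segs = _evolve_segments(ancestor, t, cfg, rng, panel=True)
            rec = _to_record(segs, f"{gid}_{sp}", sp)
            panel_records[sp].append(rec)
            members[sp] = rec
        panel_groups.append(OrthologGroup(gid, members))
        # anchor from the (unevolved) reference protein
        pos = 0
        for seg in ancestor:
            if seg.planted:
                break
            pos += len(seg.codons)
        panel_entries.append(PanelEntry(f"{gid}_{reference}",
                                        f"synthetic_polyQ_disease_{p}",
                                        pos + 1, pos + planted_len))

    truth = pd.DataFrame(truth_rows)
    return SimulatedDataset(cfg, species_config, records, groups, truth,
                            panel_records, panel_groups, panel_entries)


# ---------------------------------------------------------------------------
# worked example

def worked_example_fixture() -> tuple[OrthologGroup, dict[str, float]]:
    """A 2-member group: QQQQPQQQQ (CAGx4, CCA, CAGx4) aligned with
    QQQQQQQQQ (CAGx9) inside identical flanks.

    Through the align -> delineate -> count path the two members yield
    merged glutamine lengths 8 and 9 and purity classes MIX_WITH_OTHER and
    PURE_CAG.
    """
    flank_l = [("M", "ATG"), ("S", "TCT"), ("T", "ACT"), ("L", "CTG"),
               ("K", "AAA"), ("E", "GAA")]
    flank_r = [("G", "GGT"), ("A", "GCT"), ("R", "CGT"), ("V", "GTT"),
               ("N", "AAT"), ("D", "GAT")]
    inner_a = [("Q", "CAG")] * 4 + [("P", "CCA")] + [("Q", "CAG")] * 4
    inner_b = [("Q", "CAG")] * 9

    def build(pid: str, sp: str, inner) -> GeneRecord:
        pairs = flank_l + inner + flank_r
        protein = "".join(aa for aa, _ in pairs)
        codons = tuple(c for _, c in pairs)
        return GeneRecord(pid, sp, protein, "".join(codons), codons)

    group = OrthologGroup("WORKED", {
        "hsa": build("WORKED_hsa", "hsa", inner_a),
        "ptr": build("WORKED_ptr", "ptr", inner_b),
    })
    return group, {"hsa": 0.0, "ptr": 6.7}
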