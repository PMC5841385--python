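"""Coordinate-anchored analysis of disease-associated polyQ stretches.

Each panel entry names a reference protein and the 1-based coordinates of
the one disease-associated glutamine stretch in it (proteins carrying
several stretches contribute only the pathogenic one, anchored by its
coordinates). Ortholog sets here may be incomplete — species with no
ortholog are simply absent — and an available member is accepted only if
its aligned span covers the anchored columns: by default the member's
first..last residue columns must overlap at least half of the anchor
columns, so fragments ending before the stretch are rejected while
near-complete orthologs survive a terminal gap.

Reported per member: merged glutamine length over the anchored columns and
the CAG percentage of its glutamine codons there. Normal/pathological
length ranges, when known, are annotations only and never enter the
computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io import GeneRecord, OrthologGroup, PanelEntry
from .regions import (GAP, AlignedRegion, RegionMember, annotate_region,
                      align_group, backtranslate)
from .stability import mann_whitney_u
from .usage import cag_fraction


@dataclass(frozen=True)
class PanelMemberResult:
    species: str
    accepted: bool
    merged_q_length: int
    n_CAA: int
    n_CAG: int

    @property
    def cag_pct(self) -> float | None:
        if not self.accepted or self.n_CAA + self.n_CAG == 0:
            return None
        return cag_fraction(self.n_CAG, self.n_CAA)


@dataclass(frozen=True)
class PanelEntryResult:
    entry: PanelEntry
    members: Mapping[str, PanelMemberResult]


def validate_entry(entry: PanelEntry, reference: GeneRecord) -> None:
    """The reference protein must be glutamine across the anchored span."""
    seq = reference.protein_seq
    if entry.q_end > len(seq):
        raise ValueError(f"{entry.protein_id}: anchor {entry.q_start}-"
                         f"{entry.q_end} exceeds protein length {len(seq)}")
    span = seq[entry.q_start - 1:entry.q_end]
    if set(span) != {"Q"}:
        raise ValueError(f"{entry.protein_id}: anchored span "
                         f"{entry.q_start}-{entry.q_end} is not all Q "
                         f"(got {span!r})")


def analyze_panel_entry(entry: PanelEntry, group: OrthologGroup,
                        divergence: Mapping[str, float],
                        reference_species: str,
                        min_coverage: float = 0.5) -> PanelEntryResult:
    """Anchor the disease stretch on the group alignment and score members.

    ``min_coverage`` is the fraction of anchor columns a member's aligned
    span must overlap to be accepted.
    """
    if reference_species not in group.members:
        raise ValueError("reference member missing from group")
    ref = group.members[reference_species]
    validate_entry(entry, ref)
    msa = align_group(group, divergence)
    codon_msa = backtranslate(msa, group)
    ref_cols = msa.residue_columns(reference_species)
    anchor_cols = ref_cols[entry.q_start - 1:entry.q_end]
    c_start, c_end = anchor_cols[0], anchor_cols[-1] + 1
    region = annotate_region(
        AlignedRegion(group.group_id, f"{group.group_id}_panel", c_start,
                      c_end, {}), msa, codon_msa, group)
    n_anchor = c_end - c_start
    members = {}
    for sp in msa.species:
        row = msa.row(sp)
        res_cols = msa.residue_columns(sp)
        if res_cols:
            span_lo, span_hi = res_cols[0], res_cols[-1] + 1
            overlap = max(0, min(span_hi, c_end) - max(span_lo, c_start))
        else:
            overlap = 0
        accepted = overlap >= min_coverage * n_anchor
        m: RegionMember = region.members[sp]
        members[sp] = PanelMemberResult(
            species=sp, accepted=accepted,
            merged_q_length=m.merged_q_length if accepted else 0,
            n_CAA=m.n_CAA if (accepted and not m.ambiguous) else 0,
            n_CAG=m.n_CAG if (accepted and not m.ambiguous) else 0)
    return PanelEntryResult(entry, members)


def panel_result_table(results: Sequence[PanelEntryResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for sp, m in res.members.items():
            rows.append({"protein_id": res.entry.protein_id,
                         "disease": res.entry.disease, "species": sp,
                         "accepted": int(m.accepted),
                         "merged_q_length": m.merged_q_length,
                         "n_CAA": m.n_CAA, "n_CAG": m.n_CAG,
                         "cag_pct": m.cag_pct if m.cag_pct is not None
                         else ""})
    return pd.DataFrame(rows, columns=["protein_id", "disease", "species",
                                       "accepted", "merged_q_length",
                                       "n_CAA", "n_CAG", "cag_pct"])


def panel_summary(results: Sequence[PanelEntryResult]) -> pd.DataFrame:
    """Per-species pooled CAG percentage and length list over the panel.

    Only accepted members contribute. Lengths are serialized as a
    comma-joined list so the distribution stays inspectable in the TSV.
    """
    if not results:
        raise ValueError("no panel results to summarize")
    pooled: dict[str, list[int]] = {}
    lengths: dict[str, list[int]] = {}
    for res in results:
        for sp, m in res.members.items():
            if not m.accepted:
                continue
            c = pooled.setdefault(sp, [0, 0])
            c[0] += m.n_CAA
            c[1] += m.n_CAG
            lengths.setdefault(sp, []).append(m.merged_q_length)
    rows = []
    for sp in sorted(pooled):
        n_caa, n_cag = pooled[sp]
        rows.append({"species": sp, "n_entries": len(lengths[sp]),
                     "mean_length": round(
                         sum(lengths[sp]) / len(lengths[sp]), 2),
                     "lengths": ",".join(map(str, lengths[sp])),
                     "n_CAA": n_caa, "n_CAG": n_cag,
                     "cag_pct": cag_fraction(n_cag, n_caa)
                     if n_caa + n_cag else ""})
    return pd.DataFrame(rows, columns=["species", "n_entries", "mean_length",
                                       "lengths", "n_CAA", "n_CAG",
                                       "cag_pct"])


def close_vs_distant_lengths(results: Sequence[PanelEntryResult],
                             divergence: Mapping[str, float],
                             split_myr: float = 30.0):
    """Rank-sum contrast of panel lengths in close vs distant species."""
    close, distant = [], []
    for res in results:
        for sp, m in res.members.items():
            if not m.accepted:
                continue
            (close if divergence[sp] <= split_myr else
             distant).append(m.merged_q_length)
    return mann_whitney_u(close, distant)
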