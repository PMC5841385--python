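"""Length-stability classification of orthologous polyQ regions.

A region is stable-in-length when at least half of the ortholog set members
share the modal merged length (multiplicity >= n/2, read literally, so 6 of
12 suffices). The assigned length is the modal length; when several lengths
tie at the maximal multiplicity, the tied length carried by the species
closest in evolution to the reference wins — the reference itself
(divergence 0 Myr) dominates any tie it participates in. Members whose
region is entirely gapped count as length 0, which is what feeds the 0-3
reference bin of the length-difference profiles: such regions exist in the
data set only because some other ortholog carries a polyQ there.

The stable/unstable x short/long codon-usage contrast and the rank-sum test
on it mirror the downstream comparisons of CAG enrichment; no
multiple-testing correction is applied (single raw P values are reported).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .regions import AlignedRegion
from .usage import cag_fraction, ref_bin

SU_CLASSES = ["4-8S", "4-8U", ">8S", ">8U"]


@dataclass(frozen=True)
class StabilityRecord:
    region_id: str
    lengths: Mapping[str, int]  # species -> merged Q length (0 = absent)
    is_stable: bool
    assigned_length: int

    @property
    def length_bin(self) -> str:
        return ref_bin(self.assigned_length)


@dataclass(frozen=True)
class RankSumResult:
    """Two-sided Mann-Whitney U outcome."""

    U: float
    p_value: float
    n1: int
    n2: int
    method: str  # "exact" | "asymptotic"
    sidedness: str = "two-sided"


def classify_stability(lengths: Mapping[str, int],
                       divergence: Mapping[str, float],
                       region_id: str = "") -> StabilityRecord:
    """Apply the at-least-half rule and the proximity tie-break.

    ``lengths`` must cover >= 2 members; every species present must have a
    divergence time. A final deterministic tie-break (two tied lengths held
    at identical divergence) prefers the smaller length.
    """
    if len(lengths) < 2:
        raise ValueError("need at least two members to classify stability")
    n = len(lengths)
    mult = Counter(lengths.values())
    max_mult = max(mult.values())
    is_stable = 2 * max_mult >= n
    tied = [ln for ln, m in mult.items() if m == max_mult]
    if len(tied) == 1:
        assigned = tied[0]
    else:
        def closeness(ln: int) -> tuple[float, int]:
            d = min(divergence[sp] for sp, v in lengths.items() if v == ln)
            return (d, ln)
        assigned = min(tied, key=closeness)
    return StabilityRecord(region_id, dict(lengths), is_stable, assigned)


def classify_regions(regions: Iterable[AlignedRegion],
                     divergence: Mapping[str, float]) -> list[StabilityRecord]:
    return [classify_stability(
        {sp: m.merged_q_length for sp, m in r.members.items()},
        divergence, region_id=r.region_id) for r in regions]


def length_difference_profile(records: Sequence[StabilityRecord],
                              reference: str) -> pd.DataFrame:
    """Signed length differences (other - reference) per reference bin.

    One row per record x non-reference species, grouped by the bin (0-3,
    4-8, >8) of the reference member's length in that record.
    """
    rows = []
    for rec in records:
        if reference not in rec.lengths:
            raise ValueError(f"reference {reference!r} missing from "
                             f"record {rec.region_id}")
        ref_len = rec.lengths[reference]
        for sp, ln in rec.lengths.items():
            if sp == reference:
                continue
            rows.append({"region_id": rec.region_id, "reference": reference,
                         "species": sp, "ref_length": ref_len,
                         "ref_bin": ref_bin(ref_len), "diff": ln - ref_len})
    return pd.DataFrame(rows, columns=["region_id", "reference", "species",
                                       "ref_length", "ref_bin", "diff"])


def all_length_difference_profiles(records: Sequence[StabilityRecord],
                                   species: Sequence[str]) -> pd.DataFrame:
    """Repeat the difference profile with every species as reference."""
    frames = [length_difference_profile(records, sp) for sp in species]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def stability_rates(records: Sequence[StabilityRecord]) -> pd.DataFrame:
    """Percentage of stable regions per assigned length."""
    rows = []
    by_len: dict[int, list[bool]] = {}
    for rec in records:
        by_len.setdefault(rec.assigned_length, []).append(rec.is_stable)
    for ln in sorted(by_len):
        flags = by_len[ln]
        rows.append({"assigned_length": ln, "n_total": len(flags),
                     "n_stable": sum(flags),
                     "pct_stable": round(100.0 * sum(flags) / len(flags), 2)})
    return pd.DataFrame(rows, columns=["assigned_length", "n_total",
                                       "n_stable", "pct_stable"])


def su_class(record: StabilityRecord) -> str | None:
    """4-8S / 4-8U / >8S / >8U, or None for assigned lengths below 4."""
    if record.assigned_length < 4:
        return None
    bin_lab = "4-8" if record.assigned_length <= 8 else ">8"
    return bin_lab + ("S" if record.is_stable else "U")


def su_codon_usage(records: Sequence[StabilityRecord],
                   regions: Sequence[AlignedRegion]) -> pd.DataFrame:
    """Pooled CAA/CAG counts per species x stability/length class.

    The class comes from the record's assigned length bin and stability
    flag; counts pool each member's glutamine codons in the region, with
    ambiguous records excluded from tallies. Empty classes are omitted.
    """
    by_id = {r.region_id: r for r in regions}
    counts: dict[tuple[str, str], list[int]] = {}
    for rec in records:
        cls = su_class(rec)
        if cls is None or rec.region_id not in by_id:
            continue
        for sp, m in by_id[rec.region_id].members.items():
            if m.ambiguous:
                continue
            key = (sp, cls)
            c = counts.setdefault(key, [0, 0])
            c[0] += m.n_CAA
            c[1] += m.n_CAG
    rows = []
    for (sp, cls), (n_caa, n_cag) in sorted(counts.items()):
        if n_caa + n_cag == 0:
            continue
        rows.append({"species": sp, "su_class": cls, "n_CAA": n_caa,
                     "n_CAG": n_cag, "cag_pct": cag_fraction(n_cag, n_caa)})
    return pd.DataFrame(rows, columns=["species", "su_class", "n_CAA",
                                       "n_CAG", "cag_pct"])


def su_region_fractions(records: Sequence[StabilityRecord],
                        regions: Sequence[AlignedRegion],
                        cls: str) -> list[float]:
    """Per-region pooled CAG fractions for one S/U class (the default
    sampling unit for the rank-sum contrast)."""
    by_id = {r.region_id: r for r in regions}
    out = []
    for rec in records:
        if su_class(rec) != cls or rec.region_id not in by_id:
            continue
        n_caa = n_cag = 0
        for m in by_id[rec.region_id].members.values():
            if m.ambiguous:
                continue
            n_caa += m.n_CAA
            n_cag += m.n_CAG
        if n_caa + n_cag:
            out.append(cag_fraction(n_cag, n_caa))
    return out


def mann_whitney_u(sample_a: Sequence[float],
                   sample_b: Sequence[float]) -> RankSumResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when n1*n2 <= 400 and the pooled
    sample is tie-free, otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    exact = no_ties and a.size * b.size <= 400
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=True)
    return RankSumResult(U=float(res.statistic), p_value=float(res.pvalue),
                         n1=int(a.size), n2=int(b.size),
                         method="exact" if exact else "asymptotic")
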