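"""Proteome-level codon-usage profiles of glutamine stretches.

Percentages are ratios of pooled codon counts within a length bin (ratio of
sums, not mean of per-stretch ratios) and are reported to two decimals with
round-half-even, matching the convention of per-proteome codon-frequency
tables (e.g. 35.28 CAG vs 13.66 CAA per 1,000 codons pools to 72.09% CAG).

Three binning schemes are used:

* ``fine`` — exact lengths 1..8 plus ">8" (per-length profiles),
* ``coarse`` — "1-3", "4-8", ">8" (short stretch vs short/long polyQ),
* ``ref`` — "0-3", "4-8", ">8" (reference-length binning, allows 0 for
  orthologs whose region is absent).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .repeats import QStretch

FINE_LABELS = ["1", "2", "3", "4", "5", "6", "7", "8", ">8"]
COARSE_LABELS = ["1-3", "4-8", ">8"]
REF_LABELS = ["0-3", "4-8", ">8"]


def fine_bin(length: int) -> str:
    if length < 1:
        raise ValueError("fine binning needs length >= 1")
    return str(length) if length <= 8 else ">8"


def coarse_bin(length: int) -> str:
    if length < 1:
        raise ValueError("coarse binning needs length >= 1")
    if length <= 3:
        return "1-3"
    return "4-8" if length <= 8 else ">8"


def ref_bin(length: int) -> str:
    if length < 0:
        raise ValueError("negative length")
    if length <= 3:
        return "0-3"
    return "4-8" if length <= 8 else ">8"


_SCHEMES = {"fine": (fine_bin, FINE_LABELS), "coarse": (coarse_bin, COARSE_LABELS)}


def cag_fraction(n_cag: int | float, n_caa: int | float) -> float:
    """Percentage of CAG among glutamine codons, to two decimals.

    Raises if both counts are zero (the percentage is undefined).
    """
    if n_cag < 0 or n_caa < 0:
        raise ValueError("negative codon count")
    total = n_cag + n_caa
    if total == 0:
        raise ValueError("cag_fraction undefined for zero counts")
    return round(100.0 * n_cag / total, 2)


def profile_proteome(stretches: Iterable[QStretch], n_proteins: int,
                     scheme: str = "fine",
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Length-binned codon usage and per-length stretch frequencies.

    All stretches must come from one species. Codon counts are pooled
    within each bin before the ratio is taken; stretches from ambiguous
    records contribute to the frequency table but not to codon counts.

    Returns ``(usage, freq)``: usage has columns species/bin/n_CAA/n_CAG/
    cag_pct, freq has species/length/n_stretches/stretches_per_protein.
    """
    if n_proteins <= 0:
        raise ValueError("n_proteins must be positive")
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown binning scheme {scheme!r}")
    binner, labels = _SCHEMES[scheme]
    stretches = list(stretches)
    species = {s.species for s in stretches}
    if len(species) > 1:
        raise ValueError("profile_proteome expects stretches from one species")
    sp = species.pop() if species else ""

    counts: dict[str, list[int]] = {lab: [0, 0] for lab in labels}
    freq: dict[int, int] = {}
    for s in stretches:
        freq[s.length] = freq.get(s.length, 0) + 1
        if not s.ambiguous:
            b = counts[binner(s.length)]
            b[0] += s.n_CAA
            b[1] += s.n_CAG
    usage_rows = []
    for lab in labels:
        n_caa, n_cag = counts[lab]
        if n_caa + n_cag == 0:
            continue
        usage_rows.append({"species": sp, "bin": lab, "n_CAA": n_caa,
                           "n_CAG": n_cag,
                           "cag_pct": cag_fraction(n_cag, n_caa)})
    freq_rows = [{"species": sp, "length": ln, "n_stretches": k,
                  "stretches_per_protein": k / n_proteins}
                 for ln, k in sorted(freq.items())]
    usage_cols = ["species", "bin", "n_CAA", "n_CAG", "cag_pct"]
    freq_cols = ["species", "length", "n_stretches", "stretches_per_protein"]
    return (pd.DataFrame(usage_rows, columns=usage_cols),
            pd.DataFrame(freq_rows, columns=freq_cols))


def bin_contrast(usage: pd.DataFrame) -> pd.DataFrame:
    """Per-species (CAG% in 1-3, CAG% in 4-8) pairs from a coarse table.

    Species missing either bin are omitted with a warning column absent;
    species where the 4-8 value falls below the 1-3 value are flagged.
    """
    rows = []
    for sp, sub in usage.groupby("species", sort=True):
        by_bin = dict(zip(sub["bin"], sub["cag_pct"]))
        if "1-3" not in by_bin or "4-8" not in by_bin:
            continue
        x, y = by_bin["1-3"], by_bin["4-8"]
        rows.append({"species": sp, "cag_1_3": x, "cag_4_8": y,
                     "flagged": int(y < x)})
    return pd.DataFrame(rows, columns=["species", "cag_1_3", "cag_4_8",
                                       "flagged"])


def pool_usage(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-species usage tables into one frame."""
    if not tables:
        return pd.DataFrame(columns=["species", "bin", "n_CAA", "n_CAG",
                                     "cag_pct"])
    return pd.concat(tables, ignore_index=True)
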