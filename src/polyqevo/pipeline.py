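"""End-to-end pipeline stages over a data directory.

The data directory layout is the one the simulator writes and matches what
a user would export from a proteome database:

* ``species.tsv`` — species_code <tab> divergence_myr (reference at 0),
* ``<sp>_prot.fa`` / ``<sp>_cds.fa`` — per-species proteome pair,
* ``orthologs.tsv`` — group_id / species / protein_id,
* optionally ``panel.tsv`` (+ ``panel_orthologs.tsv`` and
  ``<sp>_panel_prot.fa`` / ``<sp>_panel_cds.fa`` when the panel proteins
  live in separate files).

Each stage writes TSV tables into a fresh versioned run directory
(``run_001``, ``run_002``, ...) so outputs are never silently overwritten,
plus a ``summary.txt`` with the record/group funnel counts. All outputs
are plain text and deterministic for a fixed input and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as qio
from . import regions as qregions
from . import repeats as qrepeats
from . import stability as qstab
from . import usage as qusage
from .panel import (analyze_panel_entry, close_vs_distant_lengths,
                    panel_result_table, panel_summary)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    data_dir: Path
    out_dir: Path
    coverage: float = 0.5
    min_seed: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        self.data_dir = Path(self.data_dir)
        self.out_dir = Path(self.out_dir)
        if not self.data_dir.is_dir():
            raise FileNotFoundError(f"data directory {self.data_dir} not found")


def make_run_dir(out_dir: Path) -> Path:
    """Next free ``run_NNN`` directory under out_dir."""
    out_dir.mkdir(parents=True, exist_ok=True)
    n = 1
    while (out_dir / f"run_{n:03d}").exists():
        n += 1
    run = out_dir / f"run_{n:03d}"
    run.mkdir()
    return run


@dataclass
class LoadedData:
    species_config: list[qio.SpeciesConfig]
    records: dict[str, list[qio.GeneRecord]]
    n_excluded: dict[str, int] = field(default_factory=dict)

    @property
    def divergence(self) -> dict[str, float]:
        return qio.divergence_map(self.species_config)

    @property
    def reference(self) -> str:
        return qio.reference_species(self.species_config)

    def by_id(self) -> dict[str, dict[str, qio.GeneRecord]]:
        return {sp: {r.protein_id: r for r in recs}
                for sp, recs in self.records.items()}


def load_proteomes(data_dir: Path, suffix: str = "") -> LoadedData:
    """Read species config and every per-species FASTA pair.

    ``suffix`` selects an alternative file family (e.g. ``panel_``).
    """
    cfg = qio.read_species_config(data_dir / "species.tsv")
    records: dict[str, list[qio.GeneRecord]] = {}
    n_excluded: dict[str, int] = {}
    for sc in cfg:
        sp = sc.species_code
        prot = data_dir / f"{sp}_{suffix}prot.fa"
        cds = data_dir / f"{sp}_{suffix}cds.fa"
        if not prot.exists():
            raise FileNotFoundError(f"missing proteome file {prot}")
        result = qio.read_fasta_pair(prot, cds, sp)
        records[sp] = result.records
        n_excluded[sp] = len(result.excluded) + len(result.unmatched)
    return LoadedData(cfg, records, n_excluded)


def run_profile(config: RunConfig) -> Path:
    """Per-proteome stretch frequencies, length-binned CAG usage and the
    short-vs-polyQ cross-species contrast."""
    data = load_proteomes(config.data_dir)
    run = make_run_dir(config.out_dir)
    usage_fine, usage_coarse, freqs, all_stretches = [], [], [], []
    for sc in data.species_config:
        sp = sc.species_code
        recs = data.records[sp]
        if not recs:
            raise ValueError(f"empty proteome for species {sp}")
        stretches = [s for r in recs for s in qrepeats.find_q_stretches(r)]
        all_stretches.extend(stretches)
        fine, freq = qusage.profile_proteome(stretches, len(recs), "fine")
        coarse, _ = qusage.profile_proteome(stretches, len(recs), "coarse")
        usage_fine.append(fine)
        usage_coarse.append(coarse)
        freqs.append(freq)
    qrepeats.write_stretch_table(all_stretches, run / "stretches.tsv")
    pd.concat(freqs, ignore_index=True).to_csv(
        run / "stretch_frequencies.tsv", sep="\t", index=False)
    qusage.pool_usage(usage_fine).to_csv(run / "usage_by_length.tsv",
                                         sep="\t", index=False)
    coarse = qusage.pool_usage(usage_coarse)
    coarse.to_csv(run / "usage_coarse.tsv", sep="\t", index=False)
    contrast = qusage.bin_contrast(coarse)
    div = data.divergence
    contrast.insert(1, "divergence_myr",
                    [div[sp] for sp in contrast["species"]])
    contrast.to_csv(run / "bin_contrast.tsv", sep="\t", index=False)
    _write_summary(run, [
        ("species", len(data.species_config)),
        ("records_retained", sum(len(r) for r in data.records.values())),
        ("records_excluded", sum(data.n_excluded.values())),
        ("stretches_total", len(all_stretches)),
    ])
    return run


def run_orthology(config: RunConfig) -> Path:
    """Ortholog regions, stability calls, length differences and the
    stable/unstable codon-usage contrast."""
    data = load_proteomes(config.data_dir)
    table = qio.read_ortholog_table(config.data_dir / "orthologs.tsv",
                                    [c.species_code
                                     for c in data.species_config],
                                    data.by_id())
    div = data.divergence
    all_regions = []
    for group in table.groups:
        _, _, regs = qregions.call_regions(group, div,
                                           min_seed=config.min_seed)
        all_regions.extend(regs)
    records = qstab.classify_regions(all_regions, div)
    run = make_run_dir(config.out_dir)
    qregions.region_table(all_regions).to_csv(run / "regions.tsv", sep="\t",
                                              index=False)
    pd.DataFrame([{
        "region_id": r.region_id, "is_stable": int(r.is_stable),
        "assigned_length": r.assigned_length, "length_bin": r.length_bin,
        **{f"len_{sp}": r.lengths[sp] for sp in sorted(r.lengths)},
    } for r in records]).to_csv(run / "stability.tsv", sep="\t", index=False)
    species = [c.species_code for c in data.species_config]
    qstab.all_length_difference_profiles(records, species).to_csv(
        run / "length_differences.tsv", sep="\t", index=False)
    qstab.stability_rates(records).to_csv(run / "stability_rates.tsv",
                                          sep="\t", index=False)
    su = qstab.su_codon_usage(records, all_regions)
    su.to_csv(run / "su_usage.tsv", sep="\t", index=False)
    test_rows = []
    short_s = qstab.su_region_fractions(records, all_regions, "4-8S")
    short_u = qstab.su_region_fractions(records, all_regions, "4-8U")
    if short_s and short_u:
        res = qstab.mann_whitney_u(short_s, short_u)
        test_rows.append({"comparison": "4-8S_vs_4-8U_region_cag_pct",
                          "U": res.U, "p_value": res.p_value, "n1": res.n1,
                          "n2": res.n2, "method": res.method})
    pd.DataFrame(test_rows, columns=["comparison", "U", "p_value", "n1",
                                     "n2", "method"]).to_csv(
        run / "rank_sum_tests.tsv", sep="\t", index=False)
    n_with_region = len({r.region_id.rsplit("_r", 1)[0] for r in all_regions})
    _write_summary(run, [
        ("groups_complete", len(table.groups)),
        ("groups_dropped_incomplete", table.n_dropped_incomplete),
        ("groups_with_polyq_region", n_with_region),
        ("independent_regions", len(all_regions)),
        ("regions_stable", sum(r.is_stable for r in records)),
    ])
    return run


def run_panel(config: RunConfig) -> Path:
    """Coordinate-anchored analysis of the disease-like panel."""
    panel_path = config.data_dir / "panel.tsv"
    entries = qio.read_panel_table(panel_path)
    suffix = "panel_" if (config.data_dir / "panel_orthologs.tsv").exists() \
        else ""
    data = load_proteomes(config.data_dir, suffix=suffix)
    table_path = config.data_dir / (f"{suffix}orthologs.tsv"
                                    if suffix else "orthologs.tsv")
    df = pd.read_csv(table_path, sep="\t", dtype=str)
    by_id = data.by_id()
    ref = data.reference
    div = data.divergence
    # assemble groups without the completeness requirement: the panel
    # accepts whatever orthologs exist, the coverage rule filters fragments
    groups = {}
    for gid, sub in df.groupby("group_id", sort=True):
        members = {}
        for sp in [c.species_code for c in data.species_config]:
            cands = [by_id.get(sp, {}).get(pid)
                     for pid in sub.loc[sub["species"] == sp, "protein_id"]]
            cands = [c for c in cands if c is not None]
            if cands:
                members[sp] = min(cands, key=lambda r: (-len(r.protein_seq),
                                                        r.protein_id))
        groups[str(gid)] = qio.OrthologGroup(str(gid), members)
    ref_to_group = {g.members[ref].protein_id: g for g in groups.values()
                    if ref in g.members}
    results = []
    for entry in entries:
        if entry.protein_id not in ref_to_group:
            logger.warning("panel entry %s: no group with that reference "
                           "protein, skipped", entry.protein_id)
            continue
        results.append(analyze_panel_entry(entry,
                                           ref_to_group[entry.protein_id],
                                           div, ref,
                                           min_coverage=config.coverage))
    run = make_run_dir(config.out_dir)
    panel_result_table(results).to_csv(run / "panel_results.tsv", sep="\t",
                                       index=False)
    if results:
        panel_summary(results).to_csv(run / "panel_summary.tsv", sep="\t",
                                      index=False)
        res = close_vs_distant_lengths(results, div)
        pd.DataFrame([{"comparison": "close_vs_distant_lengths", "U": res.U,
                       "p_value": res.p_value, "n1": res.n1, "n2": res.n2,
                       "method": res.method}]).to_csv(
            run / "rank_sum_tests.tsv", sep="\t", index=False)
    else:
        logger.warning("no panel entries could be analyzed")
    n_accepted = sum(m.accepted for r in results for m in r.members.values())
    _write_summary(run, [
        ("panel_entries", len(entries)),
        ("entries_analyzed", len(results)),
        ("members_accepted", n_accepted),
    ])
    return run


def _write_summary(run: Path, counts: list[tuple[str, int]]) -> None:
    with open(run / "summary.txt", "w") as fh:
        for name, value in counts:
            fh.write(f"{name}\t{value}\n")
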