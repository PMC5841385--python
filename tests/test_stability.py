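"""Stability classification, difference profiles and the rank-sum test."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from polyqevo.regions import AlignedRegion, RegionMember
from polyqevo.stability import (StabilityRecord, all_length_difference_profiles,
                                classify_stability, length_difference_profile,
                                mann_whitney_u, stability_rates, su_class,
                                su_codon_usage)

TWELVE = {f"s{i}": float(i) for i in range(12)}  # s0 is the reference


class TestClassifyStability:
    def test_majority_is_stable(self):
        lengths = {f"s{i}": (5 if i < 7 else 10 + i) for i in range(12)}
        rec = classify_stability(lengths, TWELVE)
        assert rec.is_stable and rec.assigned_length == 5

    def test_exactly_half_counts_as_stable(self):
        lengths = {f"s{i}": (4 if i < 6 else 20 + i) for i in range(12)}
        rec = classify_stability(lengths, TWELVE)
        assert rec.is_stable and rec.assigned_length == 4

    def test_modal_tie_resolved_by_reference_proximity(self):
        lengths = {"s0": 9, "s1": 7, "s2": 7, "s3": 9}
        lengths.update({f"s{i}": 20 + i for i in range(4, 12)})
        rec = classify_stability(lengths, TWELVE)
        assert not rec.is_stable
        assert rec.assigned_length == 9  # tied, but held by the reference

    def test_two_member_literal_rule(self):
        # multiplicity 1 >= n/2 for n=2: stable even with unequal lengths
        rec = classify_stability({"s0": 8, "s1": 9}, TWELVE)
        assert rec.is_stable and rec.assigned_length == 8

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classify_stability({"s0": 4}, TWELVE)

    def test_matches_rule_table_oracle_exhaustively(self):
        """All length assignments for n <= 5 members over a small length
        domain, compared to an independently written rule evaluation."""
        div = {"a": 0.0, "b": 1.0, "c": 2.0, "d": 3.0, "e": 4.0}
        for n in (2, 3, 4, 5):
            species = list(div)[:n]
            for combo in itertools.product([1, 2, 3], repeat=n):
                lengths = dict(zip(species, combo))
                rec = classify_stability(lengths, div)
                counts = Counter(combo)
                top = max(counts.values())
                assert rec.is_stable == (top >= n / 2)
                candidates = sorted(
                    (min(div[sp] for sp in species if lengths[sp] == ln), ln)
                    for ln, m in counts.items() if m == top)
                assert rec.assigned_length == candidates[0][1]

    def test_order_invariance(self, rng):
        for _ in range(50):
            vals = rng.integers(0, 6, size=8)
            lengths = {f"s{i}": int(v) for i, v in enumerate(vals)}
            rec1 = classify_stability(lengths, TWELVE)
            items = list(lengths.items())
            rng.shuffle(items)
            rec2 = classify_stability(dict(items), TWELVE)
            assert (rec1.is_stable, rec1.assigned_length) == \
                   (rec2.is_stable, rec2.assigned_length)


def make_record(region_id, lengths, stable=None, assigned=None):
    rec = classify_stability(lengths, {sp: float(i) for i, sp in
                                       enumerate(lengths)}, region_id)
    if stable is None:
        return rec
    return StabilityRecord(region_id, lengths, stable, assigned)


class TestLengthDifferenceProfile:
    def test_perfect_stability(self):
        rec = make_record("r1", {"ref": 5, "a": 5, "b": 5})
        df = length_difference_profile([rec], "ref")
        assert list(df["diff"]) == [0, 0]
        assert set(df["ref_bin"]) == {"4-8"}

    def test_short_reference_with_polyq_ortholog(self):
        rec = make_record("r1", {"ref": 2, "a": 6, "b": 2})
        df = length_difference_profile([rec], "ref")
        assert sorted(df["diff"]) == [0, 4]
        assert set(df["ref_bin"]) == {"0-3"}

    def test_counts_and_no_self_difference(self):
        recs = [make_record(f"r{i}", {"x": i, "y": i + 1, "z": 0})
                for i in range(5)]
        df = all_length_difference_profiles(recs, ["x", "y", "z"])
        assert len(df) == 5 * 2 * 3  # records x (n_species - 1) x references
        assert not ((df["species"] == df["reference"]).any())

    def test_planted_spread_ordering_recovered(self, rng):
        """Differences around a 4-8 reference planted tighter than >8."""
        recs = []
        for i in range(120):
            base = 6 if i % 2 == 0 else 12
            sd = 0.5 if base == 6 else 2.5
            lengths = {"ref": base}
            for j in range(5):
                lengths[f"o{j}"] = max(0, base + int(round(rng.normal(0, sd))))
            recs.append(make_record(f"r{i}", lengths))
        df = length_difference_profile(recs, "ref")
        spread = df.groupby("ref_bin")["diff"].std()
        assert spread["4-8"] < spread[">8"]


def region_with(region_id, per_species_runs):
    members = {sp: RegionMember(sp, sum(c in ("CAA", "CAG") for c in run),
                                tuple(run), False)
               for sp, run in per_species_runs.items()}
    return AlignedRegion("g", region_id, 0, 1, members)


class TestStabilityRates:
    def test_all_stable_at_length(self):
        recs = [make_record(f"r{i}", {"a": 4, "b": 4, "c": 4})
                for i in range(3)]
        df = stability_rates(recs)
        assert df.loc[df.assigned_length == 4, "pct_stable"].item() == 100.0

    def test_absent_lengths_omitted(self):
        recs = [make_record("r1", {"a": 4, "b": 4})]
        assert list(stability_rates(recs)["assigned_length"]) == [4]


class TestSuCodonUsage:
    def test_single_stable_pure_region(self):
        region = region_with("r1", {"a": ["CAG"] * 4, "b": ["CAG"] * 4})
        rec = make_record("r1", {"a": 4, "b": 4})
        df = su_codon_usage([rec], [region])
        assert set(df["su_class"]) == {"4-8S"}
        assert (df["cag_pct"] == 100.0).all()

    def test_class_counts_conserve_members(self, rng):
        regions, recs = [], []
        for i in range(30):
            n = int(rng.integers(4, 12))
            runs = {sp: ["CAG" if rng.random() < 0.8 else "CAA"
                         for _ in range(n)] for sp in ("a", "b", "c")}
            regions.append(region_with(f"r{i}", runs))
            recs.append(make_record(f"r{i}", {sp: n for sp in runs}))
        df = su_codon_usage(recs, regions)
        total = df["n_CAA"].sum() + df["n_CAG"].sum()
        expect = sum(m.n_CAA + m.n_CAG for r in regions
                     for m in r.members.values()
                     if su_class(dict(zip([c.region_id for c in recs],
                                          recs))[r.region_id]) is not None)
        assert total == expect

    def test_planted_su_theta_ordering_recovered(self, rng):
        """theta(4-8U)=0.92 vs theta(4-8S)=0.80 planted per species:
        the recovered ordering holds in nearly every species."""
        species = [f"s{i}" for i in range(12)]
        regions, recs = [], []
        for i in range(300):
            unstable = i % 2 == 0
            theta = 0.92 if unstable else 0.80
            n = int(rng.integers(4, 9))
            runs = {sp: ["CAG" if rng.random() < theta else "CAA"
                         for _ in range(n)] for sp in species}
            regions.append(region_with(f"r{i}", runs))
            lengths = {sp: n for sp in species}
            if unstable:  # break the modal majority artificially
                for j, sp in enumerate(species):
                    lengths[sp] = n + j % 7
            recs.append(make_record(f"r{i}", lengths))
        df = su_codon_usage(recs, regions)
        wide = df.pivot(index="species", columns="su_class",
                        values="cag_pct")
        assert (wide["4-8U"] > wide["4-8S"]).sum() >= 11

    def test_recomputation_from_region_tables(self, rng):
        regions, recs = [], []
        for i in range(20):
            n = int(rng.integers(4, 15))
            runs = {sp: ["CAG" if rng.random() < 0.8 else "CAA"
                         for _ in range(n)] for sp in ("a", "b")}
            regions.append(region_with(f"r{i}", runs))
            recs.append(make_record(f"r{i}", {"a": n, "b": n}))
        df = su_codon_usage(recs, regions)
        by_id = {r.region_id: r for r in regions}
        for _, row in df.iterrows():
            n_caa = sum(by_id[rec.region_id].members[row.species].n_CAA
                        for rec in recs if su_class(rec) == row.su_class)
            assert n_caa == row.n_CAA


def permutation_pvalue(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all assignments."""
    pooled = sorted(a + b)
    n1 = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    u_mirror = len(a) * len(b) - u_obs
    lo, hi = min(u_obs, u_mirror), max(u_obs, u_mirror)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        sa = [pooled[i] for i in combo]
        sb = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = sum(1 for x in sa for y in sb if x > y)
        total += 1
        if u <= lo or u >= hi:
            count += 1
    return count / total


class TestMannWhitneyU:
    def test_identical_samples(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.U == 4.5
        assert res.p_value > 0.9

    def test_fully_separated_small_samples(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.U == 0
        assert res.p_value == pytest.approx(1 / 3)
        assert res.method == "exact"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_exact_p_matches_permutation_enumeration(self, rng):
        for _ in range(100):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 6))
            pooled = rng.permutation(100)[:n1 + n2]  # distinct -> no ties
            a = [float(x) for x in pooled[:n1]]
            b = [float(x) for x in pooled[n1:]]
            res = mann_whitney_u(a, b)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(permutation_pvalue(a, b))

    def test_exact_mode_type_i_error_bounded(self, rng):
        """Under a permutation null the exact test is valid at alpha=.05."""
        rejections = 0
        reps = 10_000
        for _ in range(reps):
            pooled = rng.permutation(50)[:8].astype(float)
            res = mann_whitney_u(pooled[:4], pooled[4:])
            if res.p_value <= 0.05:
                rejections += 1
        assert rejections / reps <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / reps)
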