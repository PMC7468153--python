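"""Amplicon processing chain: filters, pairing rule, clustering oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lakebiogeo import amplicon
from lakebiogeo.errors import DegenerateDataError, ValidationError


def rec(v9, its, lake, count):
    return {"v9_seq": v9, "its_seq": its, "lake_id": lake, "count": count}


def frame(*rows):
    return pd.DataFrame(list(rows))


def random_records(rng, n=60):
    seqs = ["".join(rng.choice(list("ACGT"), size=20)) for _ in range(8)]
    rows = [
        rec(
            str(rng.choice(seqs)),
            str(rng.choice(seqs)),
            f"L{rng.integers(3)}",
            int(rng.integers(1, 50)),
        )
        for _ in range(n)
    ]
    return frame(*rows)


class TestDereplicate:
    def test_merges_identical_records(self):
        r = rec("AAAA", "CCCC", "L1", 1)
        out = amplicon.dereplicate(frame(r, r, r, rec("AAAA", "GGGG", "L1", 4)))
        assert len(out) == 2
        assert sorted(out["count"]) == [3, 4]

    def test_length_variants_stay_distinct(self):
        out = amplicon.dereplicate(
            frame(rec("AAAA", "CCCC", "L1", 1), rec("AAAA", "CCCCC", "L1", 1))
        )
        assert len(out) == 2

    def test_same_sequences_different_lakes_distinct(self):
        out = amplicon.dereplicate(
            frame(rec("AAAA", "CCCC", "L1", 2), rec("AAAA", "CCCC", "L2", 3))
        )
        assert len(out) == 2

    def test_read_conservation_on_random_fixtures(self, rng):
        records = random_records(rng)
        out = amplicon.dereplicate(records)
        assert out["count"].sum() == records["count"].sum()

    def test_empty_input_is_empty_output(self):
        out = amplicon.dereplicate(pd.DataFrame(columns=list(amplicon.RECORD_COLUMNS)))
        assert len(out) == 0


class TestPairFilter:
    def test_most_abundant_v9_wins(self):
        out = amplicon.pair_filter(
            frame(rec("AAAA", "TTTT", "L1", 120), rec("GGGG", "TTTT", "L1", 7))
        )
        assert set(out["v9_seq"]) == {"AAAA"}

    def test_abundance_summed_across_lakes(self):
        # B wins on the cross-lake total (5+5 > 6) even though A peaks in one lake
        out = amplicon.pair_filter(
            frame(
                rec("AAAA", "TTTT", "L1", 6),
                rec("GGGG", "TTTT", "L1", 5),
                rec("GGGG", "TTTT", "L2", 5),
            )
        )
        assert set(out["v9_seq"]) == {"GGGG"}

    def test_single_pairing_unchanged(self):
        records = frame(rec("AAAA", "TTTT", "L1", 3))
        out = amplicon.pair_filter(records)
        pd.testing.assert_frame_equal(out, records)

    def test_tie_breaks_to_lexicographically_smallest(self):
        out = amplicon.pair_filter(
            frame(rec("GGGG", "TTTT", "L1", 5), rec("AAAA", "TTTT", "L1", 5))
        )
        assert set(out["v9_seq"]) == {"AAAA"}

    def test_its_to_v9_is_a_function(self, rng):
        out = amplicon.pair_filter(amplicon.dereplicate(random_records(rng, 120)))
        assert (out.groupby("its_seq")["v9_seq"].nunique() == 1).all()


class TestClusterV9:
    def test_prefix_identity_groups(self):
        a = "A" * 150 + "GGGGGGGGGG"
        b = "A" * 150 + "TTTTTTTTTT"  # differs only after base 150
        c = "A" * 2 + "C" + "A" * 147  # differs at base 3
        records = frame(rec(a, "T", "L1", 1), rec(b, "T", "L2", 1), rec(c, "T", "L1", 1))
        ids = amplicon.cluster_v9(records)
        assert ids.iloc[0] == ids.iloc[1]
        assert ids.iloc[0] != ids.iloc[2]

    def test_short_sequences_group_by_full_length(self):
        records = frame(rec("AAAA", "T", "L1", 1), rec("AAAA", "G", "L2", 1))
        ids = amplicon.cluster_v9(records)
        assert ids.iloc[0] == ids.iloc[1]

    def test_matches_prefix_dictionary_oracle(self, rng):
        records = random_records(rng, 80)
        ids = amplicon.cluster_v9(records, prefix_len=10)
        oracle = records["v9_seq"].str[:10]
        # same partition: ids equal iff prefixes equal
        for (i, a), (j, b) in itertools.combinations(enumerate(oracle), 2):
            assert (ids.iloc[i] == ids.iloc[j]) == (a == b)


class TestFilterSamples:
    def test_median_cutoff_arithmetic(self):
        totals = pd.Series({"a": 100_000, "b": 100_460, "c": 120_000, "d": 10_000})
        kept = amplicon.filter_samples(totals, fraction=0.15)
        # median 100,230 -> cutoff 15,034.5 -> only d dropped
        assert kept == ["a", "b", "c"]

    def test_all_equal_totals_all_retained(self):
        totals = pd.Series({"a": 5, "b": 5, "c": 5})
        assert amplicon.filter_samples(totals) == ["a", "b", "c"]

    def test_all_excluded_is_an_error(self):
        with pytest.raises(DegenerateDataError):
            amplicon.filter_samples(pd.Series(dtype=float))


class TestFilterLowAbundance:
    def test_boundary_strictly_less_than(self):
        # lake totals 1,000,000: 9 reads removed, 10 reads (== threshold) kept
        filler = rec("AAAA", "CCCC", "L1", 1_000_000 - 19)
        records = frame(filler, rec("AAAA", "GGGG", "L1", 9), rec("AAAA", "TTTT", "L1", 10))
        out = amplicon.filter_low_abundance(records, min_fraction=1e-5)
        assert set(out["its_seq"]) == {"CCCC", "TTTT"}

    def test_removal_is_per_lake(self):
        records = frame(
            rec("AAAA", "GGGG", "L1", 5),
            rec("AAAA", "CCCC", "L1", 999_995),
            rec("AAAA", "GGGG", "L2", 5),  # lake total 5 -> threshold tiny -> kept
        )
        out = amplicon.filter_low_abundance(records, min_fraction=1e-5)
        kept = set(zip(out["its_seq"], out["lake_id"]))
        assert ("GGGG", "L2") in kept and ("GGGG", "L1") not in kept

    def test_output_subset_of_input(self, rng):
        records = amplicon.dereplicate(random_records(rng))
        out = amplicon.filter_low_abundance(records, min_fraction=0.05)
        merged = out.merge(records, on=list(amplicon.RECORD_COLUMNS), how="left", indicator=True)
        assert (merged["_merge"] == "both").all()


def brute_force_components(variants, d):
    """All-pairs Levenshtein + union-find oracle (dynamic-programming DP)."""

    def lev(a, b):
        m, n = len(a), len(b)
        prev = list(range(n + 1))
        for i in range(1, m + 1):
            cur = [i] + [0] * n
            for j in range(1, n + 1):
                cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (a[i - 1] != b[j - 1]))
            prev = cur
        return prev[n]

    variants = sorted(set(variants))
    parent = list(range(len(variants)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(len(variants)):
        for j in range(i + 1, len(variants)):
            if lev(variants[i], variants[j]) <= d:
                parent[find(i)] = find(j)
    comps = {}
    for i, v in enumerate(variants):
        comps.setdefault(find(i), []).append(v)
    return sorted((sorted(c) for c in comps.values()), key=lambda c: c[0])


class TestSwarmCluster:
    def test_chain_linkage(self):
        swarms = amplicon.swarm_cluster(["AAAA", "AAAT", "AATT", "CCCC"], d=1)
        assert swarms == [["AAAA", "AAAT", "AATT"], ["CCCC"]]

    def test_all_far_apart_all_singletons(self):
        swarms = amplicon.swarm_cluster(["AAAA", "CCCC", "GGGG"], d=1)
        assert swarms == [["AAAA"], ["CCCC"], ["GGGG"]]

    def test_indels_count_toward_distance(self):
        swarms = amplicon.swarm_cluster(["AAAA", "AAAAA"], d=1)
        assert len(swarms) == 1

    def test_negative_d_rejected(self):
        with pytest.raises(ValidationError):
            amplicon.swarm_cluster(["AAAA"], d=-1)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 40))
            variants = [
                "".join(rng.choice(list("ACGT"), size=int(rng.integers(4, 10))))
                for _ in range(n)
            ]
            assert amplicon.swarm_cluster(variants, d=1) == brute_force_components(variants, 1)

    def test_partition_property(self, rng):
        variants = ["".join(rng.choice(list("ACG"), size=5)) for _ in range(30)]
        swarms = amplicon.swarm_cluster(variants, d=1)
        flat = [v for s in swarms for v in s]
        assert sorted(flat) == sorted(set(variants))


class TestPipeline:
    def test_empty_records_empty_table(self):
        table, report = amplicon.process_amplicons(
            pd.DataFrame(columns=list(amplicon.RECORD_COLUMNS))
        )
        assert len(table.df) == 0

    def test_presence_view_matches_hand_enumeration(self):
        v9 = "A" * 150
        records = frame(
            rec(v9, "TTTTT", "L1", 40),
            rec(v9, "TTTTA", "L1", 30),  # same swarm as TTTTT (distance 1)
            rec(v9, "GGGGG", "L2", 30),  # own swarm
        )
        table, _ = amplicon.process_amplicons(records)
        sets = table.presence_sets("swarm")
        assert sorted(map(sorted, sets.values())) == [["L1"], ["L2"]]
        assert table.total_reads() == 100

    def test_record_order_invariance(self, rng):
        records = amplicon.dereplicate(random_records(rng, 100))
        table1, _ = amplicon.process_amplicons(records)
        shuffled = records.sample(frac=1.0, random_state=7).reset_index(drop=True)
        table2, _ = amplicon.process_amplicons(shuffled)
        pd.testing.assert_frame_equal(
            table1.df.reset_index(drop=True), table2.df.reset_index(drop=True)
        )

    def test_metazoa_excluded_with_annotations(self):
        v9a, v9b = "A" * 150, "C" * 150
        records = frame(rec(v9a, "TTTTT", "L1", 10), rec(v9b, "GGGGG", "L1", 10))
        table, _ = amplicon.process_amplicons(
            records, annotations_by_prefix={v9a: "Metazoa", v9b: "Chrysophyceae"}
        )
        assert set(table.df["taxon_group"]) == {"Chrysophyceae"}
        assert len(table.presence_sets("v9")) == 1
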