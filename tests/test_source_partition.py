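"""Exact-match source partitioning, percentile inclusion filter, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sewagesense import (
    ASVTable,
    SourceDatabase,
    SourceRecord,
    category_relative_abundance,
    exact_match,
    partition,
    river_percentile,
    sewage_inclusion_filter,
    sewage_proportion,
)
from conftest import (
    brute_force_partition,
    brute_force_percentile,
    make_table,
    random_dna,
    random_partition_instance,
)


class TestExactMatch:
    def test_identity_and_near_miss(self):
        rng = np.random.default_rng(0)
        seq = random_dna(rng, 60)
        db = SourceDatabase([SourceRecord("fw_0", seq, "freshwater")])
        assert exact_match(seq, db) == "fw_0"
        mutated = ("A" if seq[0] != "A" else "C") + seq[1:]
        assert exact_match(mutated, db) is None

    def test_case_insensitive(self):
        db = SourceDatabase([SourceRecord("fw_0", "ACGTACGT", "freshwater")])
        assert exact_match("acgtacgt", db) == "fw_0"

    def test_ambiguous_bases_rejected(self):
        db = SourceDatabase([SourceRecord("fw_0", "ACGTACGT", "freshwater")])
        with pytest.raises(ValueError):
            exact_match("ACGTACGN", db)

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(1)
        # short sequences so collisions actually occur
        refs = [random_dna(rng, 6) for _ in range(300)]
        unique = list(dict.fromkeys(refs))
        db = SourceDatabase(
            [SourceRecord(f"r{i}", s, "freshwater") for i, s in enumerate(unique)])
        queries = [random_dna(rng, 6) for _ in range(300)]
        for q in queries:
            brute = next((f"r{i}" for i, s in enumerate(unique) if s == q), None)
            assert exact_match(q, db) == brute


class TestRiverPercentile:
    def test_constant_vector(self):
        seqs = {"a": "ACGT" * 5}
        counts = {f"s{i}": {"a": 1} for i in range(4)}
        table = make_table(counts, seqs)
        # relative abundance is 1.0 in every sample (single-ASV table)
        assert river_percentile("a", table, 5) == pytest.approx(1.0)

    def test_absent_asv_is_zero(self):
        seqs = {"a": "ACGT" * 5, "b": "TTTT" * 5}
        counts = {f"s{i}": {"a": 10, "b": 0} for i in range(5)}
        table = make_table(counts, seqs)
        assert river_percentile("b", table, 5) == 0.0

    def test_hand_interpolation_oracle(self):
        # relative abundances (0, 0, 0.002, 0.004, 0.01) across 5 samples
        rel = [0.0, 0.0, 0.002, 0.004, 0.01]
        seqs = {"a": "ACGT" * 5, "pad": "TGCA" * 5}
        counts = {f"s{i}": {"a": int(r * 1000), "pad": 1000 - int(r * 1000)}
                  for i, r in enumerate(rel)}
        table = make_table(counts, seqs)
        expected = brute_force_percentile(rel, 5)
        assert river_percentile("a", table, 5) == pytest.approx(expected, rel=1e-12)
        # by hand: h = 0.05 * 4 = 0.2 between two zeros -> 0
        assert expected == 0.0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12),
           st.floats(0, 100))
    def test_matches_manual_order_statistics(self, rel, q):
        assert np.percentile(rel, q) == pytest.approx(
            brute_force_percentile(rel, q), abs=1e-12)

    def test_zero_total_samples_excluded(self):
        seqs = {"a": "ACGT" * 5, "b": "TGCA" * 5}
        counts = {"s0": {"a": 1, "b": 1}, "s1": {"a": 0, "b": 0}}
        table = make_table(counts, seqs)
        assert river_percentile("a", table, 50) == pytest.approx(0.5)


class TestInclusionFilter:
    @pytest.mark.parametrize("p5,p95,expected", [
        (0.0001, 0.01, True),
        (0.01, 0.01, False),   # strict inequality at the boundary
        (0.05, 0.01, False),
    ])
    def test_rule(self, p5, p95, expected):
        assert sewage_inclusion_filter(p5, p95) is expected

    def test_missing_p95_rejected(self):
        with pytest.raises(ValueError):
            sewage_inclusion_filter(0.1, None)


class TestPartition:
    def test_freshwater_precedence_over_sewer(self):
        rng = np.random.default_rng(2)
        seq = random_dna(rng, 40)
        other = random_dna(rng, 40)
        fw = SourceDatabase([SourceRecord("fw_0", seq, "freshwater")])
        sw = SourceDatabase([SourceRecord("sw_0", seq, "sewer", 0.9)])
        table = make_table({"s0": {"a": 5, "b": 5}}, {"a": seq, "b": other})
        st_db = SourceDatabase([], source="human_stool")
        part = partition(table, fw, sw, st_db)
        row = part.assignments.set_index("asv_id").loc["a"]
        assert row["category"] == "freshwater"

    def test_stool_match_passing_filter_is_human_fecal(self, toy_table, toy_databases):
        fw, sw, st_db = toy_databases
        part = partition(toy_table, fw, sw, st_db)
        cats = part.category_of()
        assert cats["a_hf"] == "human_fecal"
        assert cats["a_sw"] == "sewer"
        assert cats["a_fw"] == "freshwater"
        assert cats["a_un"] == "uncategorized"

    def test_failed_filter_falls_to_uncategorized(self):
        rng = np.random.default_rng(3)
        seq = random_dna(rng, 40)
        sw = SourceDatabase([SourceRecord("sw_0", seq, "sewer", 0.001)])
        fw = SourceDatabase([], source="freshwater")
        st_db = SourceDatabase([], source="human_stool")
        # ASV at 50% relative abundance in every sample: p5 = 0.5 >= 0.001
        table = make_table({"s0": {"a": 5, "b": 5}, "s1": {"a": 5, "b": 5}},
                           {"a": seq, "b": random_dna(rng, 40)})
        cats = partition(table, fw, sw, st_db).category_of()
        assert cats["a"] == "uncategorized"

    def test_freshwater_flag_column_path(self):
        rng = np.random.default_rng(4)
        seqs = {"a": random_dna(rng, 40), "b": random_dna(rng, 40)}
        table = make_table({"s0": {"a": 3, "b": 7}}, seqs)
        empty = lambda src: SourceDatabase([], source=src)
        flags = pd.Series({"a": True, "b": False})
        cats = partition(table, empty("freshwater"), empty("sewer"),
                         empty("human_stool"), freshwater_flags=flags).category_of()
        assert cats["a"] == "freshwater"
        assert cats["b"] == "uncategorized"

    def test_duplicate_asv_sequences_flagged(self):
        rng = np.random.default_rng(5)
        seq = random_dna(rng, 40)
        counts = pd.DataFrame({"a": [1], "b": [1]}, index=["s0"])
        table = ASVTable(counts=counts, sequences={"a": seq, "b": seq})
        empty = lambda src: SourceDatabase([], source=src)
        with pytest.raises(ValueError, match="duplicate"):
            partition(table, empty("freshwater"), empty("sewer"),
                      empty("human_stool"))

    def test_partition_is_complete_and_disjoint(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            table, fw, sw, st_db = random_partition_instance(rng)
            part = partition(table, fw, sw, st_db)
            assert sorted(part.assignments["asv_id"]) == sorted(table.asv_ids)
            assert not part.assignments["asv_id"].duplicated().any()

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            table, fw, sw, st_db = random_partition_instance(rng)
            part = partition(table, fw, sw, st_db)
            brute = brute_force_partition(table, fw, sw, st_db)
            got = {r.asv_id: (r.category, r.reference_id)
                   for r in part.assignments.itertuples()}
            assert got == brute

    def test_filter_monotonicity_raising_abundance(self):
        """Raising an ASV's abundance everywhere can only exclude, not include."""
        rng = np.random.default_rng(8)
        seq = random_dna(rng, 40)
        other = random_dna(rng, 40)
        sw = SourceDatabase([SourceRecord("sw_0", seq, "sewer", 0.3)])
        fw = SourceDatabase([], source="freshwater")
        st_db = SourceDatabase([], source="human_stool")
        status = []
        for a_count in (1, 10, 40, 90, 99):
            table = make_table(
                {"s0": {"a": a_count, "b": 100 - a_count},
                 "s1": {"a": a_count, "b": 100 - a_count}},
                {"a": seq, "b": other})
            cats = partition(table, fw, sw, st_db).category_of()
            status.append(cats["a"] == "sewer")
        # included (True) can only switch to excluded (False), never back
        assert status == sorted(status, reverse=True)


class TestSummaries:
    def test_toy_category_proportions(self, toy_table, toy_databases):
        fw, sw, st_db = toy_databases
        part = partition(toy_table, fw, sw, st_db)
        props = category_relative_abundance(toy_table, part)
        row = props.loc["s1"]
        assert row["freshwater"] == pytest.approx(0.70)
        assert row["sewer"] == pytest.approx(0.25)
        assert row["human_fecal"] == pytest.approx(0.05)
        assert row["uncategorized"] == pytest.approx(0.0)
        assert props.sum(axis=1).round(9).eq(1.0).all()

    def test_toy_sewage_proportion(self, toy_table, toy_databases):
        fw, sw, st_db = toy_databases
        part = partition(toy_table, fw, sw, st_db)
        sp = sewage_proportion(toy_table, part)
        assert sp["s1"] == pytest.approx(0.30)
        assert sp["s2"] == pytest.approx(0.0)
        only_sewer = sewage_proportion(toy_table, part, include_human_fecal=False)
        assert only_sewer["s1"] == pytest.approx(0.25)

    def test_all_freshwater_sample(self):
        rng = np.random.default_rng(9)
        seq = random_dna(rng, 40)
        fw = SourceDatabase([SourceRecord("fw_0", seq, "freshwater")])
        empty = lambda src: SourceDatabase([], source=src)
        table = make_table({"s0": {"a": 10}}, {"a": seq})
        part = partition(table, fw, empty("sewer"), empty("human_stool"))
        props = category_relative_abundance(table, part)
        assert props.loc["s0"].tolist() == pytest.approx([1.0, 0.0, 0.0, 0.0])
        assert sewage_proportion(table, part)["s0"] == 0.0

    def test_zero_total_sample_reported_missing(self):
        rng = np.random.default_rng(10)
        seqs = {"a": random_dna(rng, 40)}
        counts = pd.DataFrame({"a": [5, 0]}, index=["s0", "s1"])
        table = ASVTable(counts=counts, sequences=seqs)
        empty = lambda src: SourceDatabase([], source=src)
        part = partition(table, empty("freshwater"), empty("sewer"),
                         empty("human_stool"))
        props = category_relative_abundance(table, part)
        assert props.loc["s1"].isna().all()
        assert not props.loc["s0"].isna().any()
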