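import numpy as np
import pandas as pd
import pytest

from blankgate.decontam import (blank_otu_set, decontam_report,
                                remove_contaminants, to_percent_abundance)
from blankgate.io import Metadata, OtuTable

from conftest import random_counts_table


@pytest.fixture()
def table_with_blank():
    data = pd.DataFrame(
        # blank B1 sees OTUs a and c
        [[2, 0, 1, 0],
         [5, 5, 0, 10],
         [1, 2, 3, 4]],
        index=["B1", "S1", "S2"], columns=["a", "b", "c", "d"])
    meta = Metadata.from_records([
        {"sample_id": "B1", "volume_ml": 0, "is_blank": True,
         "blank_type": "filtered-water"},
        {"sample_id": "S1", "volume_ml": 500, "is_blank": False},
        {"sample_id": "S2", "volume_ml": 100, "is_blank": False},
    ])
    return OtuTable(data, unit="counts"), meta


class TestBlankOtuSet:
    def test_single_blank(self, table_with_blank):
        table, meta = table_with_blank
        assert blank_otu_set(table, meta) == {"a", "c"}

    def test_all_zero_blank_gives_empty_set(self, table_with_blank):
        table, meta = table_with_blank
        zeroed = table.data.copy()
        zeroed.loc["B1"] = 0
        assert blank_otu_set(OtuTable(zeroed), meta) == frozenset()

    def test_min_count_knob(self, table_with_blank):
        table, meta = table_with_blank
        assert blank_otu_set(table, meta, min_count=2) == {"a"}

    def test_no_blanks_is_error(self, table_with_blank):
        table, _ = table_with_blank
        meta = Metadata.from_records(
            [{"sample_id": s, "volume_ml": 1, "is_blank": False}
             for s in table.sample_ids])
        with pytest.raises(ValueError, match="blank"):
            blank_otu_set(table, meta)


class TestRemoveContaminants:
    def test_removes_blank_otus_and_blank_samples(self, table_with_blank):
        table, meta = table_with_blank
        clean = remove_contaminants(table, meta)
        assert clean.sample_ids == ["S1", "S2"]
        assert clean.otu_ids == ["b", "d"]
        # surviving values are untouched
        assert clean.data.at["S1", "d"] == 10

    def test_no_shared_otus_leaves_subtable_unchanged(self):
        data = pd.DataFrame([[3, 0], [0, 0], [1, 2]],
                            index=["S1", "B1", "S2"], columns=["a", "b"])
        meta = Metadata.from_records([
            {"sample_id": "S1", "volume_ml": 100, "is_blank": False},
            {"sample_id": "B1", "volume_ml": 0, "is_blank": True,
             "blank_type": "unused-filter"},
            {"sample_id": "S2", "volume_ml": 100, "is_blank": False},
        ])
        clean = remove_contaminants(OtuTable(data), meta)
        assert clean.data.equals(data.loc[["S1", "S2"]])

    def test_everything_contaminant_warns_and_empties(self, table_with_blank):
        table, meta = table_with_blank
        hot = table.data.copy()
        hot.loc["B1"] = 1  # blank sees every OTU
        with pytest.warns(UserWarning, match="zero reads"):
            clean = remove_contaminants(OtuTable(hot), meta)
        assert clean.otu_ids == []

    def test_set_identity_against_two_pass_scan(self, rng):
        # retained OTUs == all observed OTUs minus blank-observed OTUs
        for _ in range(30):
            table, meta = random_counts_table(rng, n_samples=8, n_otus=15,
                                              max_count=4, with_blanks=2)
            clean = remove_contaminants(table, meta)
            blanks = meta.blank_ids
            observed_in_blank = {
                o for o in table.otu_ids
                if any(table.data.at[b, o] > 0 for b in blanks)}
            expected = [o for o in table.otu_ids if o not in observed_in_blank]
            assert clean.otu_ids == expected

    def test_idempotent(self, rng):
        table, meta = random_counts_table(rng, n_samples=8, n_otus=15,
                                          max_count=4, with_blanks=2)
        once = remove_contaminants(table, meta)
        twice_data = once.data  # no blanks remain, so re-applying the OTU
        # filter against the same blank set must not change anything
        contaminants = blank_otu_set(table, meta)
        again = twice_data.drop(columns=[c for c in twice_data.columns
                                         if c in contaminants])
        assert again.equals(once.data)

    def test_per_sample_read_conservation(self, rng):
        for _ in range(20):
            table, meta = random_counts_table(rng, n_samples=7, n_otus=12,
                                              max_count=6, with_blanks=1)
            clean = remove_contaminants(table, meta)
            contaminants = blank_otu_set(table, meta)
            for sid in clean.sample_ids:
                removed = sum(table.data.at[sid, o] for o in contaminants)
                assert (table.data.loc[sid].sum() - clean.data.loc[sid].sum()
                        == removed)


class TestPercentAbundance:
    def test_hand_example(self):
        table = OtuTable(pd.DataFrame([[2, 3, 5]], index=["S1"],
                                      columns=["a", "b", "c"]))
        percent = to_percent_abundance(table)
        assert percent.unit == "percent"
        assert list(percent.data.loc["S1"]) == [20.0, 30.0, 50.0]

    def test_single_otu_sample(self):
        table = OtuTable(pd.DataFrame([[7]], index=["S1"], columns=["a"]))
        assert to_percent_abundance(table).data.at["S1", "a"] == 100.0

    def test_rows_sum_to_100(self, rng):
        table = random_counts_table(rng, n_samples=10, n_otus=30)
        sums = to_percent_abundance(table).values().sum(axis=1)
        assert np.allclose(sums, 100.0, atol=1e-9)

    def test_zero_row_names_sample(self):
        table = OtuTable(pd.DataFrame([[0, 0], [1, 1]],
                                      index=["EMPTY", "S"], columns=["a", "b"]))
        with pytest.raises(ValueError, match="EMPTY"):
            to_percent_abundance(table)


class TestReport:
    def test_no_removal_gives_zero_fractions(self, table_with_blank):
        table, _ = table_with_blank
        report = decontam_report(table, table)
        assert (report.per_sample["contaminant_fraction_otus"] == 0).all()
        assert (report.per_sample["contaminant_fraction_sequences"] == 0).all()

    def test_hand_arithmetic(self):
        before = OtuTable(pd.DataFrame([[3, 3, 2, 2]], index=["S1"],
                                       columns=list("abcd")))
        after = OtuTable(pd.DataFrame([[2, 2]], index=["S1"], columns=list("cd")))
        row = decontam_report(before, after).per_sample.loc["S1"]
        assert row["sequences_before"] == 10
        assert row["sequences_after"] == 4
        assert row["otus_after"] == 2
        assert row["contaminant_fraction_sequences"] == pytest.approx(0.6)
        assert row["contaminant_fraction_otus"] == pytest.approx(0.5)

    def test_unknown_sample_in_after_is_error(self, table_with_blank):
        table, _ = table_with_blank
        extra = OtuTable(pd.DataFrame([[1]], index=["GHOST"], columns=["a"]))
        with pytest.raises(ValueError, match="GHOST"):
            decontam_report(table, extra)

    def test_dataset_totals(self, table_with_blank):
        table, meta = table_with_blank
        clean = remove_contaminants(table, meta)
        totals = decontam_report(table, clean).totals
        assert totals["distinct_otus_before"] == 4
        assert totals["distinct_otus_after"] == 2
        assert totals["min_sequences_after"] == 6.0   # S2 keeps b=2, d=4
        assert totals["max_sequences_after"] == 15.0  # S1 keeps b=5, d=10
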