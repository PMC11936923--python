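"""Parsing, deduplication and primary-suspect selection."""
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from faersignal.faers_io import (
    concat_quarters,
    deduplicate,
    match_drug_rows,
    normalize_name,
    read_quarter,
    select_primary_suspect,
)
from faersignal.store import load_store, write_store

from conftest import write_quarter


class TestReadQuarter:
    def test_parses_wellformed_rows(self, quarter_dir):
        raw = read_quarter(quarter_dir, "2022Q1")
        assert len(raw.demo) == 2
        assert len(raw.drug) == 3
        row = raw.demo.set_index("primaryid").loc["1001"]
        assert row["sex"] == "F"
        assert row["fda_dt"] == 20230105
        assert row["event_dt"] == 20221215 and row["event_dt_prec"] == "day"
        # month-precision event date is retained with its tag
        row2 = raw.demo.set_index("primaryid").loc["1002"]
        assert row2["event_dt"] == 20221101 and row2["event_dt_prec"] == "month"

    def test_missing_required_table_is_fatal(self, tmp_path):
        write_quarter(
            tmp_path,
            demo=["primaryid$caseid$fda_dt", "1$C1$20230101"],
            drug=["primaryid$caseid$drug_seq$role_cod$drugname", "1$C1$1$PS$X"],
        )
        with pytest.raises(FileNotFoundError, match="REAC"):
            read_quarter(tmp_path, "2022Q1")

    def test_malformed_rows_counted_not_silent(self, tmp_path):
        write_quarter(
            tmp_path,
            demo=[
                "primaryid$caseid$fda_dt",
                "1$C1$20230101",
                "2$C2$20230101$EXTRA$FIELDS",  # wrong field count
                "3$C3$20230101",
            ],
            drug=["primaryid$caseid$drug_seq$role_cod$drugname", "1$C1$1$PS$X"],
            reac=["primaryid$caseid$pt", "1$C1$Headache"],
        )
        raw = read_quarter(tmp_path, "2022Q1")
        assert len(raw.demo) == 2
        assert raw.log["bad_rows"]["DEMO"] == 1

    def test_unparseable_date_sets_field_absent(self, tmp_path):
        write_quarter(
            tmp_path,
            demo=["primaryid$caseid$event_dt$fda_dt", "1$C1$20231399$20230101"],
            drug=["primaryid$caseid$drug_seq$role_cod$drugname", "1$C1$1$PS$X"],
            reac=["primaryid$caseid$pt", "1$C1$Headache"],
        )
        raw = read_quarter(tmp_path, "2022Q1")
        assert len(raw.demo) == 1  # row retained
        assert pd.isna(raw.demo["event_dt"].iloc[0])

    def test_store_round_trip_preserves_fields(self, quarter_dir, tmp_path):
        raw = read_quarter(quarter_dir, "2022Q1")
        write_store(raw, tmp_path / "store")
        back = load_store(tmp_path / "store")
        for col in ("primaryid", "caseid", "sex", "occr_country"):
            assert list(back.demo[col].fillna("")) == list(raw.demo[col].fillna(""))
        assert list(back.demo["fda_dt"]) == list(raw.demo["fda_dt"])
        assert list(back.demo["event_dt_prec"]) == list(raw.demo["event_dt_prec"])


class TestConcatQuarters:
    def _quarter(self, tmp_path, tag, n):
        d = tmp_path / tag
        d.mkdir()
        write_quarter(
            d,
            demo=["primaryid$caseid$fda_dt"] + [f"{tag}{i}$C{tag}{i}$20230101" for i in range(n)],
            drug=["primaryid$caseid$drug_seq$role_cod$drugname", f"{tag}0$C{tag}0$1$PS$X"],
            reac=["primaryid$caseid$pt", f"{tag}0$C{tag}0$Headache"],
            tag=tag,
        )
        return read_quarter(d, "2022Q1")

    def test_union_of_rows(self, tmp_path):
        q1 = self._quarter(tmp_path, "a", 3)
        q2 = self._quarter(tmp_path, "b", 2)
        both = concat_quarters([q1, q2])
        assert len(both.demo) == 5

    def test_single_quarter_identity(self, tmp_path):
        q1 = self._quarter(tmp_path, "a", 3)
        assert concat_quarters([q1]) is q1

    def test_no_implicit_dedup(self, tmp_path):
        q1 = self._quarter(tmp_path, "a", 2)
        both = concat_quarters([q1, q1])
        assert len(both.demo) == 4  # same primaryids retained twice

    def test_inconsistent_columns_fatal(self, tmp_path):
        q1 = self._quarter(tmp_path, "a", 1)
        q2 = self._quarter(tmp_path, "b", 1)
        q2.tables["DEMO"] = q2.tables["DEMO"].rename(columns={"caseid": "case_id"})
        with pytest.raises(ValueError, match="case_id"):
            concat_quarters([q1, q2])


def _demo(rows):
    return pd.DataFrame(rows, columns=["primaryid", "caseid", "fda_dt"])


class TestDeduplicate:
    def test_latest_fda_dt_wins(self):
        out = deduplicate(_demo([("10", "C1", 20230101), ("11", "C1", 20230301)]))
        assert list(out["primaryid"]) == ["11"]

    def test_tie_broken_by_highest_primaryid(self):
        out = deduplicate(_demo([("100", "C1", 20230101), ("200", "C1", 20230101)]))
        assert list(out["primaryid"]) == ["200"]

    def test_tie_break_is_numeric_for_digit_ids(self):
        # lexicographically "99" > "100" but numerically 100 wins
        out = deduplicate(_demo([("99", "C1", 20230101), ("100", "C1", 20230101)]))
        assert list(out["primaryid"]) == ["100"]

    def test_unique_input_unchanged(self):
        df = _demo([("1", "C1", 20230101), ("2", "C2", 20230201)])
        out = deduplicate(df)
        pd.testing.assert_frame_equal(out, df)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.integers(1, 30),  # caseid pool -> forces duplicates
                st.integers(1, 10**6),  # primaryid
                st.integers(20220101, 20221230),
            ),
            min_size=1,
            max_size=60,
        )
    )
    def test_idempotent_and_counts_distinct_caseids(self, rows):
        df = _demo([(str(p), f"C{c}", d) for c, p, d in rows])
        once = deduplicate(df)
        assert len(once) == df["caseid"].nunique()
        pd.testing.assert_frame_equal(deduplicate(once), once)


class TestSelectPrimarySuspect:
    drug = pd.DataFrame(
        [
            ("1", "1", "PS", "Vabysmo", None),
            ("2", "1", "C", "FARICIMAB", None),
            ("3", "1", "PS", "aspirin", "FARICIMAB  "),
            ("4", "1", "PS", "Other drug", "OTHER"),
        ],
        columns=["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"],
    )

    def test_brand_name_match_case_insensitive(self):
        assert select_primary_suspect(self.drug, ["VABYSMO"]) == {"1"}

    def test_role_mismatch_excluded(self):
        # report 2 names the drug but only as concomitant
        assert "2" not in select_primary_suspect(self.drug, ["FARICIMAB"])

    def test_prod_ai_matches_too(self):
        assert select_primary_suspect(self.drug, ["FARICIMAB"]) == {"3"}

    def test_empty_pattern_list_fatal(self):
        with pytest.raises(ValueError):
            select_primary_suspect(self.drug, [])

    def test_empty_table_gives_empty_set(self):
        empty = self.drug.iloc[0:0]
        assert select_primary_suspect(empty, ["VABYSMO"]) == set()

    def test_substring_mode(self):
        rows = match_drug_rows(self.drug, ["FARICI"], substring=True)
        assert set(rows["primaryid"]) == {"3"}

    def test_name_normalization_collapses_whitespace(self):
        assert normalize_name("  blinded   Faricimab ") == "BLINDED FARICIMAB"
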