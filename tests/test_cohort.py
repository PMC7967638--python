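import textwrap

import pandas as pd
import pytest

from prenatal_risk.cohort import (
    CategoryCountTable,
    CodedVariable,
    PregnancyRecord,
    build_count_table,
    load_cohort_csv,
    load_municipality_config,
    merge_small_not_answered,
    recode_frame,
    recode_record,
    write_cohort_csv,
)


def make_record(**overrides):
    base = dict(
        household_id="H1",
        municipality_id="M1",
        marital_status="married",
        maternal_age_years=30,
        gestational_weeks_at_registration=8,
        pregnancy_progress="good",
        birth_order="first",
        abortion_history="no",
        infertility_treatment="no",
        feeling_at_pregnancy="happy",
        return_to_parents_home="yes",
        has_helper="yes",
        worries_anxiety="no",
        smoking="no",
        passive_smoking="no",
        alcohol="no",
        disease_history="no",
        mental_illness_history="no",
        depressive_symptoms="no",
        outcome_rccrc=False,
    )
    base.update(overrides)
    return PregnancyRecord(**base)


class TestRecode:
    @pytest.mark.parametrize(
        "age,band",
        [(17, "<20"), (19, "<20"), (20, "20-24"), (24, "20-24"),
         (25, "25-39"), (39, "25-39"), (40, ">=40")],
    )
    def test_age_bands_are_half_open(self, age, band):
        assert recode_record(make_record(maternal_age_years=age))["maternal_age"] == band

    @pytest.mark.parametrize(
        "weeks,late", [(11, "no"), (12, "yes"), (20, "yes"), ("not_answered", "not_answered")]
    )
    def test_registration_at_twelve_weeks_counts_as_late(self, weeks, late):
        rec = make_record(gestational_weeks_at_registration=weeks)
        assert recode_record(rec)["late_registration"] == late

    @pytest.mark.parametrize(
        "feeling", ["unexpected_puzzled", "dont_know_what_to_do", "no_feeling", "other"]
    )
    def test_unintended_unhappy_feelings_pool(self, feeling):
        rec = make_record(feeling_at_pregnancy=feeling)
        assert recode_record(rec)["feeling_at_pregnancy"] == "unexpected_other"

    def test_smoking_label_shortens(self):
        rec = make_record(smoking="stopped_after_confirmation")
        assert recode_record(rec)["smoking"] == "stopped"

    def test_recode_is_deterministic(self):
        rec = make_record(maternal_age_years=22, smoking="yes")
        assert recode_record(rec) == recode_record(rec)

    @pytest.mark.parametrize("age", [-1, 75])
    def test_implausible_age_rejected(self, age):
        with pytest.raises(ValueError, match="age"):
            recode_record(make_record(maternal_age_years=age))

    def test_unknown_enum_label_rejected(self):
        with pytest.raises(ValueError, match="unknown label"):
            recode_record(make_record(smoking="sometimes"))

    def test_frame_recode_matches_per_record(self):
        records = [
            make_record(household_id=f"H{i}", maternal_age_years=18 + 5 * i,
                        smoking=s, feeling_at_pregnancy=f)
            for i, (s, f) in enumerate(
                [("no", "happy"), ("yes", "no_feeling"),
                 ("stopped_after_confirmation", "unexpected_happy")]
            )
        ]
        frame = pd.DataFrame([vars(r) for r in records])
        recoded = recode_frame(frame)
        for i, rec in enumerate(records):
            expected = recode_record(rec)
            for var, cat in expected.items():
                assert recoded.loc[i, var] == cat


class TestMergeRule:
    def table(self, na_total, na_events=0):
        return CategoryCountTable(
            "abortion_history",
            (("no", 100, 2), ("yes", 20, 1), ("not_answered", na_total, na_events)),
        )

    def test_small_cell_folds_into_reference(self):
        merged = merge_small_not_answered(self.table(3, 1))
        assert merged.rows[0] == ("no/not_answered", 103, 3)
        assert len(merged.rows) == 2
        assert (merged.n_total, merged.n_events) == (123, 4)

    def test_cell_at_threshold_is_kept(self):
        assert merge_small_not_answered(self.table(5)) == self.table(5)

    def test_empty_cell_is_left_alone(self):
        assert merge_small_not_answered(self.table(0)) == self.table(0)

    def test_not_investigated_is_never_merged(self):
        table = CategoryCountTable(
            "worries_anxiety", (("no", 100, 2), ("not_investigated", 2, 0))
        )
        assert merge_small_not_answered(table) == table

    def test_threshold_is_a_parameter(self):
        assert len(merge_small_not_answered(self.table(6), threshold=10).rows) == 2


class TestCountTable:
    def test_counts_match_hand_tally(self):
        # 10 records: 4 smokers-who-stopped (1 event), 1 active smoker, 5 never
        records = (
            [make_record(household_id=f"A{i}", smoking="stopped_after_confirmation",
                         outcome_rccrc=(i == 0)) for i in range(4)]
            + [make_record(household_id="B0", smoking="yes")]
            + [make_record(household_id=f"C{i}") for i in range(5)]
        )
        frame = recode_frame(pd.DataFrame([vars(r) for r in records]))
        table = build_count_table(
            frame, CodedVariable("smoking", ("no", "stopped", "yes", "not_answered"))
        )
        assert table.rows == (("no", 5, 0), ("stopped", 4, 1), ("yes", 1, 0))
        assert (table.n_total, table.n_events) == (10, 1)

    def test_single_event_free_record(self):
        frame = recode_frame(pd.DataFrame([vars(make_record())]))
        table = build_count_table(frame, CodedVariable("alcohol", ("no", "yes")))
        assert table.rows == (("no", 1, 0),)

    def test_empty_cohort_rejected(self):
        frame = recode_frame(pd.DataFrame([vars(make_record())]))
        with pytest.raises(ValueError, match="empty"):
            build_count_table(frame.iloc[:0], CodedVariable("alcohol", ("no", "yes")))

    def test_tabulate_then_merge_equals_merge_then_tabulate(self):
        records = [make_record(household_id=f"H{i}") for i in range(8)] + [
            make_record(household_id="H9", abortion_history="not_answered",
                        outcome_rccrc=True)
        ]
        frame = recode_frame(pd.DataFrame([vars(r) for r in records]))
        coded = CodedVariable("abortion_history", ("no", "yes", "not_answered"))
        tabulate_then_merge = merge_small_not_answered(build_count_table(frame, coded))
        relabeled = frame.copy()
        relabeled["abortion_history"] = relabeled["abortion_history"].replace(
            {"not_answered": "no"}
        )
        merge_then_tabulate = build_count_table(relabeled, coded)
        assert tabulate_then_merge.rows[0][1:] == merge_then_tabulate.rows[0][1:]
        assert tabulate_then_merge.n_events == merge_then_tabulate.n_events


class TestFixture:
    def test_every_table_sums_to_the_cohort(self, published_counts):
        assert len(published_counts) == 17
        for table in published_counts.values():
            assert (table.n_total, table.n_events) == (893, 11)

    def test_smoking_rows_as_published(self, published_counts):
        assert published_counts["smoking"].rows == (
            ("no/not_answered", 776, 6), ("stopped", 94, 3), ("yes", 23, 2)
        )

    def test_marital_rows_as_published(self, published_counts):
        assert published_counts["marital_status"].rows == (
            ("married", 423, 2), ("unmarried", 27, 2),
            ("not_answered", 26, 1), ("not_investigated", 417, 6),
        )


class TestCohortCsv:
    def test_blank_cells_become_not_answered_or_not_investigated(self, tmp_path):
        csv = tmp_path / "cohort.csv"
        frame = pd.DataFrame([vars(make_record(household_id="H1", municipality_id="M1")),
                              vars(make_record(household_id="H2", municipality_id="M2"))])
        frame.loc[0, "worries_anxiety"] = ""
        frame.loc[1, "worries_anxiety"] = ""
        frame.to_csv(csv, index=False)
        config_path = tmp_path / "muni.yaml"
        config_path.write_text("M2: [worries_anxiety]\n")
        cohort = load_cohort_csv(csv, load_municipality_config(config_path))
        assert cohort.loc[0, "worries_anxiety"] == "not_answered"
        assert cohort.loc[1, "worries_anxiety"] == "not_investigated"

    def test_roundtrip_preserves_records(self, tmp_path):
        frame = pd.DataFrame([vars(make_record())]).astype(str)
        path = tmp_path / "out.csv"
        write_cohort_csv(frame, path)
        back = load_cohort_csv(path)
        assert back.loc[0, "marital_status"] == "married"
        assert back.loc[0, "outcome_rccrc"] == False  # noqa: E712

    def test_municipality_config_rejects_unknown_variable(self, tmp_path):
        path = tmp_path / "muni.yaml"
        path.write_text("M1: [shoe_size]\n")
        with pytest.raises(ValueError, match="unknown variables"):
            load_municipality_config(path)
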