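"""Schema intake: parsing, validation/exclusion, and name classification."""

import io

import pytest
from hypothesis import given, strategies as st

from rxuse import (canonical_name, classify_medicine, read_survey,
                   validate_encounter, write_survey)
from rxuse.data_model import (SurveyFormatError, is_parenteral_form,
                              parse_bool, survey_to_frame)

from conftest import enc, med

LONG_HEADER = ("encounter_id,district,pharmacy_category,outlet_id,"
               "medicine_name,form,prescribed_by_generic,is_antibiotic,"
               "is_injection,on_eml,dispensed,labelled\n")


def long_csv(rows):
    return io.StringIO(LONG_HEADER + "\n".join(rows) + "\n")


class TestCanonicalization:
    @pytest.mark.parametrize("raw, expected", [
        ("Atorvastatin 20mg", "atorvastatin"),
        ("  CO-AMOXYCLAV  625 mg ", "co-amoxyclav"),
        ("insulin 30/70 100iu/ml", "insulin 30/70"),
        ("paracetamol 125mg/5ml", "paracetamol"),
        ("vitamin  c", "vitamin c"),
        ("losartan", "losartan"),
    ])
    def test_strips_dose_and_normalizes(self, raw, expected):
        assert canonical_name(raw) == expected

    @given(st.text(alphabet="abcdefghijklmnopqrstuvwxyz"
                            "ABCDEFGHIJKLMNOPQRSTUVWXYZ -",
                   min_size=1, max_size=30))
    def test_idempotent_and_case_insensitive(self, name):
        canon = canonical_name(name)
        assert canonical_name(canon) == canon
        assert canonical_name(name.upper()) == canon


class TestClassification:
    def test_inn_match_sets_generic_flag(self, toy_refs):
        rec = classify_medicine("Atorvastatin 20mg", "tablet", toy_refs)
        assert rec.prescribed_by_generic
        assert rec.generic_name == "atorvastatin"
        assert rec.on_eml and not rec.is_antibiotic

    def test_brand_resolves_via_map_but_is_not_generic(self, toy_refs):
        rec = classify_medicine("Panadol", "tablet", toy_refs)
        assert not rec.prescribed_by_generic
        assert rec.generic_name == "paracetamol"
        assert rec.on_eml

    def test_antibiotic_resolved_on_generic_name(self, toy_refs):
        assert classify_medicine("co-amoxyclav", "tablet",
                                 toy_refs).is_antibiotic
        assert classify_medicine("Augmentin", "tablet",
                                 toy_refs).is_antibiotic

    def test_injection_from_list_and_form_token(self, toy_refs):
        assert classify_medicine("insulin", "injection", toy_refs).is_injection
        assert classify_medicine("paracetamol", "IV infusion",
                                 toy_refs).is_injection
        assert not classify_medicine("paracetamol", "tablet",
                                     toy_refs).is_injection
        assert is_parenteral_form("prefilled pen")

    def test_unresolvable_brand_keeps_empty_generic(self, toy_refs, caplog):
        with caplog.at_level("WARNING"):
            rec = classify_medicine("Mysterium", "tablet", toy_refs)
        assert rec.generic_name == ""
        assert not rec.on_eml and not rec.prescribed_by_generic
        assert any("Mysterium" in r.message for r in caplog.records)

    def test_classification_case_insensitive(self, toy_refs):
        a = classify_medicine("ATORVASTATIN 10MG", "TABLET", toy_refs)
        b = classify_medicine("atorvastatin 10mg", "tablet", toy_refs)
        assert (a.prescribed_by_generic, a.generic_name, a.on_eml) == \
               (b.prescribed_by_generic, b.generic_name, b.on_eml)

    def test_antibiotics_must_be_subset_of_inn(self):
        from rxuse import ReferenceLists
        with pytest.raises(ValueError, match="missing from INN"):
            ReferenceLists(inn={"a"}, antibiotics={"b"})


class TestValidation:
    def test_complete_encounter_is_valid(self):
        ok, reason = validate_encounter(enc(meds=[med(), med(), med()]))
        assert ok and reason is None

    @pytest.mark.parametrize("encounter, reason", [
        (enc(meds=[]), "no medicines"),
        (enc(meds=[med(name=" ")]), "empty medicine name"),
        (enc(meds=[med()], district=""), "missing district or category"),
        (enc(meds=[med(dispensed=None, labelled=None)]),
         "missing dispensed flag"),
        (enc(meds=[med(dispensed=False, labelled=True)]),
         "labelled without dispensed"),
        (enc(meds=[med(name=f"m{i}", generic=f"m{i}") for i in range(13)]),
         "more than 12 medicines"),
    ])
    def test_exclusion_reasons(self, encounter, reason):
        ok, got = validate_encounter(encounter)
        assert not ok and got == reason

    def test_exclusion_log_carries_encounter_id(self):
        from rxuse import validate_dataset
        bad = enc("E9", meds=[med(dispensed=False, labelled=True)])
        ds = validate_dataset([enc("E1"), bad])
        assert ds.exclusion_log == [("E9", "labelled without dispensed")]
        assert ds.excluded_count == 1 and ds.n_encounters == 1


class TestReadSurvey:
    def test_two_table_layout_round_counts(self, tmp_path):
        (tmp_path / "enc.csv").write_text(
            "encounter_id,district,pharmacy_category,outlet_id\n"
            "E1,Colombo,private,O1\nE2,Colombo,private,O1\n"
            "E3,Galle,state_owned,O2\n")
        meds = ["E1,paracetamol,tablet,1,0,0,1,1,1"] * 3 + \
               ["E2,losartan,tablet,1,0,0,1,1,1"] * 2 + \
               ["E3,aspirin,tablet,1,0,0,1,1,1"] * 2
        (tmp_path / "med.csv").write_text(
            "encounter_id,medicine_name,form,prescribed_by_generic,"
            "is_antibiotic,is_injection,on_eml,dispensed,labelled\n"
            + "\n".join(meds) + "\n")
        ds = read_survey((tmp_path / "enc.csv", tmp_path / "med.csv"),
                         layout="two_table")
        assert ds.n_encounters == 3
        assert ds.n_medicines == 7

    def test_blank_encounter_id_logged_rest_parsed(self):
        ds = read_survey(long_csv([
            "E1,Colombo,private,O1,paracetamol,tablet,1,0,0,1,1,1",
            ",Colombo,private,O1,aspirin,tablet,1,0,0,1,1,1",
            "E2,Colombo,private,O1,losartan,tablet,1,0,0,1,1,1",
        ]))
        assert ds.n_encounters == 2
        assert ("<blank>", "blank encounter_id") in ds.exclusion_log

    def test_missing_mandatory_column_names_it(self):
        src = io.StringIO("encounter_id,district,outlet_id,medicine_name,"
                          "dispensed,labelled\nE1,C,O1,x,1,1\n")
        with pytest.raises(SurveyFormatError, match="pharmacy_category"):
            read_survey(src)

    def test_unknown_category_label_lists_accepted(self):
        src = long_csv(["E1,Colombo,hospital,O1,x,tablet,1,0,0,1,1,1"])
        with pytest.raises(SurveyFormatError) as err:
            read_survey(src)
        assert "hospital" in str(err.value)
        assert "private" in str(err.value)

    def test_flags_derived_when_columns_absent(self, toy_refs):
        src = io.StringIO(
            "encounter_id,district,pharmacy_category,outlet_id,"
            "medicine_name,form,dispensed,labelled\n"
            "E1,Colombo,private,O1,Panadol,tablet,yes,no\n")
        ds = read_survey(src, refs=toy_refs)
        m = ds.encounters[0].medicines[0]
        assert m.generic_name == "paracetamol" and m.on_eml
        assert m.dispensed is True and m.labelled is False

    def test_flags_absent_without_refs_is_hard_error(self):
        src = io.StringIO(
            "encounter_id,district,pharmacy_category,outlet_id,"
            "medicine_name,form,dispensed,labelled\n"
            "E1,Colombo,private,O1,Panadol,tablet,1,1\n")
        with pytest.raises(SurveyFormatError, match="reference lists"):
            read_survey(src)

    def test_boolean_variants_accepted_and_emitted_as_01(self, small_dataset):
        assert parse_bool("Yes") and parse_bool("TRUE") and parse_bool(1)
        assert parse_bool("no") is False and parse_bool("0") is False
        assert parse_bool("") is None
        frame = survey_to_frame(small_dataset)
        assert set(frame["dispensed"].unique()) <= {"0", "1"}


class TestRoundTrip:
    def test_write_read_round_trip(self, small_dataset):
        buf = io.StringIO()
        write_survey(small_dataset, buf)
        buf.seek(0)
        again = read_survey(buf)
        assert again.n_encounters == small_dataset.n_encounters
        assert again.exclusion_log == []
        for a, b in zip(again.encounters, small_dataset.encounters):
            assert a.encounter_id == b.encounter_id
            assert a.district == b.district
            assert a.pharmacy_category == b.pharmacy_category
            for ma, mb in zip(a.medicines, b.medicines):
                assert ma.name_as_written == mb.name_as_written
                assert (ma.prescribed_by_generic, ma.is_antibiotic,
                        ma.is_injection, ma.on_eml, ma.dispensed,
                        ma.labelled) == \
                       (mb.prescribed_by_generic, mb.is_antibiotic,
                        mb.is_injection, mb.on_eml, mb.dispensed, mb.labelled)

    def test_valid_plus_excluded_partition_input(self, default_survey):
        dataset, truth = default_survey
        assert dataset.n_encounters + dataset.excluded_count == \
            truth["n_encounters"]
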