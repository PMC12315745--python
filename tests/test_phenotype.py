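"""Subject-document deconstruction, table regeneration, aliases, provenance."""

import random

import pandas as pd
import pytest

from bidscurate.fixtures import random_phenotype_study
from bidscurate.phenotype import (
    AliasCollisionError,
    ConflictingValueError,
    ParticipantPhenoDocument,
    PhenotypeError,
    SourceRecord,
    UnknownVariableError,
    VariableDictionary,
    VariableSpec,
    count_document_cells,
    count_table_cells,
    deconstruct_tables,
    generate_tables,
    harmonize_dictionaries,
    read_documents,
    write_documents,
    write_phenotype_tables,
)


def _spec(name, level, vtype="string", **kw):
    return VariableSpec(name, level, vtype, **kw)


class TestDeconstruct:
    def test_two_tables_three_participants_two_visits(self, toy_dictionary, toy_tables):
        docs = deconstruct_tables(toy_tables, toy_dictionary, "participant_id", "visit")
        assert sorted(docs) == ["P001", "P002", "P003"]
        for doc in docs.values():
            assert sorted(doc.sessions) == ["01", "02"]
        assert count_document_cells(docs) == count_table_cells(
            toy_tables, "participant_id", "visit")

    def test_alias_column_stored_under_canonical(self, toy_dictionary, toy_tables):
        docs = deconstruct_tables(toy_tables, toy_dictionary, "participant_id", "visit")
        assert docs["P001"].demographics["sex"] == "F"
        assert "gender" not in docs["P001"].demographics

    def test_provenance_original_name_resolves(self, toy_dictionary, toy_tables):
        # visits.tsv carries 'motor_total', declared as the original name of motor_score
        docs = deconstruct_tables(toy_tables, toy_dictionary, "participant_id", "visit")
        assert docs["P002"].sessions["02"]["motor_score"] == 33

    def test_empty_table_set(self, toy_dictionary):
        assert deconstruct_tables([], toy_dictionary, "participant_id") == {}

    def test_unknown_column_rejected_naming_it(self, toy_dictionary, toy_tables):
        toy_tables[0]["mystery"] = 1
        with pytest.raises(UnknownVariableError, match="mystery"):
            deconstruct_tables(toy_tables, toy_dictionary, "participant_id", "visit")

    def test_conflicting_demographic_rejected(self, toy_dictionary, toy_tables):
        extra = pd.DataFrame({"participant_id": ["P001"], "age": [99.0]})
        with pytest.raises(ConflictingValueError, match="P001.*age"):
            deconstruct_tables(toy_tables + [extra], toy_dictionary,
                               "participant_id", "visit")

    def test_conflicting_session_value_rejected(self, toy_dictionary, toy_tables):
        dup = toy_tables[1].iloc[[0]].copy()
        dup["motor_total"] = 999
        with pytest.raises(ConflictingValueError, match="P001"):
            deconstruct_tables(toy_tables + [dup], toy_dictionary,
                               "participant_id", "visit")

    def test_session_variable_without_session_column(self, toy_dictionary, toy_tables):
        visits = toy_tables[1].drop(columns=["visit"])
        with pytest.raises(PhenotypeError, match="session"):
            deconstruct_tables([visits], toy_dictionary, "participant_id", "visit")


class TestGenerate:
    def test_alias_request_honored_in_header(self, toy_dictionary, toy_tables):
        docs = deconstruct_tables(toy_tables, toy_dictionary, "participant_id", "visit")
        via_alias = generate_tables(docs, toy_dictionary, ["gender"])["participants"]
        via_canon = generate_tables(docs, toy_dictionary, ["sex"])["participants"]
        assert list(via_alias.columns) == ["participant_id", "gender"]
        assert via_alias["gender"].tolist() == via_canon["sex"].tolist()

    def test_missing_cell_is_na_row_present(self, toy_dictionary, toy_tables, tmp_path):
        docs = deconstruct_tables(toy_tables, toy_dictionary, "participant_id", "visit")
        sess = generate_tables(docs, toy_dictionary)["sessions"]
        row = sess[(sess.participant_id == "P003") & (sess.session_id == "02")]
        assert len(row) == 1 and pd.isna(row["motor_score"].iloc[0])
        write_phenotype_tables({"sessions": sess}, tmp_path, toy_dictionary)
        text = (tmp_path / "sessions.tsv").read_text()
        assert "n/a" in text

    def test_unresolvable_request_lists_near_matches(self, toy_dictionary):
        with pytest.raises(UnknownVariableError, match="motor"):
            generate_tables({}, toy_dictionary, ["motor_scor"])

    def test_empty_documents_yield_headers(self, toy_dictionary):
        out = generate_tables({}, toy_dictionary, ["sex", "motor_score"])
        assert list(out["participants"].columns) == ["participant_id", "sex"]
        assert out["participants"].empty and out["sessions"].empty

    def test_categorical_code_validated_at_generation(self, toy_dictionary):
        doc = ParticipantPhenoDocument("P001", demographics={"sex": "X"})
        with pytest.raises(PhenotypeError, match="accepted codes"):
            generate_tables({"P001": doc}, toy_dictionary, ["sex"])

    def test_domain_sharding(self, toy_dictionary, toy_tables):
        docs = deconstruct_tables(toy_tables, toy_dictionary, "participant_id", "visit")
        out = generate_tables(docs, toy_dictionary,
                              domains={"motor": ["motor_score"],
                                       "cognition": ["cognitive_score"]})
        assert set(out) == {"participants", "motor", "cognition"}
        assert "cognitive_score" not in out["motor"].columns


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(10))
    def test_random_study_round_trip_and_conservation(self, seed):
        rng = random.Random(seed)
        tables, dictionary, idc, sesc = random_phenotype_study(rng)
        docs = deconstruct_tables(tables, dictionary, idc, sesc)
        assert count_document_cells(docs) == count_table_cells(tables, idc, sesc)
        regenerated = generate_tables(docs, dictionary)
        docs2 = deconstruct_tables(list(regenerated.values()), dictionary,
                                   "participant_id", "session_id")
        assert docs2 == docs

    def test_disk_round_trip_via_tsv(self, toy_dictionary, toy_tables, tmp_path):
        docs = deconstruct_tables(toy_tables, toy_dictionary, "participant_id", "visit")
        write_phenotype_tables(generate_tables(docs, toy_dictionary),
                               tmp_path, toy_dictionary)
        reread = []
        for name in ("participants", "sessions"):
            df = pd.read_csv(tmp_path / f"{name}.tsv", sep="\t",
                             na_values=["n/a"], dtype={"participant_id": str,
                                                       "session_id": str})
            reread.append(df)
        docs2 = deconstruct_tables(reread, toy_dictionary,
                                   "participant_id", "session_id")
        assert docs2 == docs

    def test_update_locality(self, toy_dictionary, toy_tables):
        docs = deconstruct_tables(toy_tables, toy_dictionary, "participant_id", "visit")
        full = generate_tables(docs, toy_dictionary)
        reduced_docs = {k: v for k, v in docs.items() if k != "P002"}
        reduced = generate_tables(reduced_docs, toy_dictionary)
        for name in full:
            kept = full[name][full[name].participant_id != "P002"].reset_index(drop=True)
            pd.testing.assert_frame_equal(kept, reduced[name].reset_index(drop=True),
                                          check_dtype=False)

    def test_document_disk_round_trip(self, toy_dictionary, toy_tables, tmp_path):
        docs = deconstruct_tables(toy_tables, toy_dictionary, "participant_id", "visit")
        write_documents(docs, tmp_path)
        assert read_documents(tmp_path) == docs


class TestAlias:
    def test_add_alias_resolves(self):
        d = VariableDictionary("S", [_spec("sex", "demographic")])
        d.add_alias("sex", "gender")
        assert d.resolve("gender") == "sex"

    def test_alias_equal_to_canonical_rejected(self):
        d = VariableDictionary("S", [_spec("sex", "demographic")])
        with pytest.raises(AliasCollisionError, match="sex"):
            d.add_alias("sex", "sex")

    def test_duplicate_alias_rejected_naming_owner(self):
        d = VariableDictionary("S", [_spec("sex", "demographic")])
        d.add_alias("sex", "gender")
        with pytest.raises(AliasCollisionError, match="sex"):
            d.add_alias("sex", "gender")

    def test_alias_colliding_with_other_entry(self):
        d = VariableDictionary("S", [_spec("sex", "demographic"),
                                     _spec("age", "demographic", "real")])
        with pytest.raises(AliasCollisionError, match="age"):
            d.add_alias("sex", "age")


def _study(label, names, level_map=None, files=None):
    specs = []
    for n in names:
        specs.append(VariableSpec(
            n, (level_map or {}).get(n, "demographic"),
            provenance=[SourceRecord(label, (files or {}).get(n, f"{label}.tsv"), n)]))
    return VariableDictionary(label, specs)


class TestHarmonize:
    def test_merge_shared_variables(self):
        a = _study("A", ["sex", "age", "tapA"])
        b = _study("B", ["sex", "age", "tapB"])
        eq = {("A", "sex"): "sex", ("B", "sex"): "sex",
              ("A", "age"): "age", ("B", "age"): "age"}
        merged = harmonize_dictionaries([a, b], eq)
        assert len(merged) == 4
        assert len(merged) == len(a) + len(b) - 2
        assert {p.source_study for p in merged.entries["sex"].provenance} == {"A", "B"}

    def test_merged_provenance_lists_both_source_files(self):
        a = _study("A", ["sex"], files={"sex": "formA.tsv"})
        b = _study("B", ["gendercode"], files={"gendercode": "formB.tsv"})
        merged = harmonize_dictionaries(
            [a, b], {("A", "sex"): "sex", ("B", "gendercode"): "sex"})
        files = {p.source_file for p in merged.entries["sex"].provenance}
        assert files == {"formA.tsv", "formB.tsv"}
        # the superseded canonical name survives as an alias
        assert merged.resolve("gendercode") == "sex"

    def test_empty_equivalence_disjoint_union(self):
        a = _study("A", ["x1", "x2"])
        b = _study("B", ["y1"])
        merged = harmonize_dictionaries([a, b], {})
        assert len(merged) == 3

    def test_undeclared_name_clash_rejected(self):
        with pytest.raises(PhenotypeError, match="declared equivalence"):
            harmonize_dictionaries([_study("A", ["sex"]), _study("B", ["sex"])], {})

    def test_level_mismatch_rejected(self):
        a = _study("A", ["score"], level_map={"score": "demographic"})
        b = _study("B", ["score"], level_map={"score": "session"})
        with pytest.raises(PhenotypeError, match="level"):
            harmonize_dictionaries([a, b], {("A", "score"): "score",
                                            ("B", "score"): "score"})

    def test_never_exceeds_disjoint_union_and_associative(self):
        a, b, c = _study("A", ["u", "v"]), _study("B", ["w"]), _study("C", ["z"])
        left = harmonize_dictionaries(
            [harmonize_dictionaries([a, b], {}), c], {})
        right = harmonize_dictionaries(
            [a, harmonize_dictionaries([b, c], {})], {})
        assert len(left) == len(right) == 4
        assert set(left.entries) == set(right.entries)


class TestDocumentInvariants:
    def test_variable_in_both_sections_rejected(self):
        with pytest.raises(PhenotypeError, match="both"):
            ParticipantPhenoDocument("P1", demographics={"x": 1},
                                     sessions={"01": {"x": 2}})

    def test_empty_participant_id_rejected(self):
        with pytest.raises(PhenotypeError):
            ParticipantPhenoDocument("")

    def test_source_record_fields_non_empty(self):
        with pytest.raises(PhenotypeError):
            SourceRecord("A", "", "x")
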