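import pandas as pd
import pytest

from bidscurate.fixtures import FixtureSpec, default_planted_identifiers, make_fixture
from bidscurate.phenotype import SourceRecord, VariableDictionary, VariableSpec


@pytest.fixture(scope="session")
def clean_bids(tmp_path_factory):
    """A small valid dataset: 3 subjects x 2 sessions, T1w+bold, one QC failure."""
    out = tmp_path_factory.mktemp("clean") / "bids"
    spec = FixtureSpec(n_subjects=3, sessions_per_subject=2, n_qc_failures=1, seed=7)
    manifest = make_fixture(spec, out)
    return out, manifest


@pytest.fixture(scope="session")
def planted_bids(tmp_path_factory):
    """Same shape, but with one identifier planted per scrub category."""
    out = tmp_path_factory.mktemp("planted") / "bids"
    spec = FixtureSpec(n_subjects=3, sessions_per_subject=2, seed=11,
                       planted_identifiers=default_planted_identifiers())
    manifest = make_fixture(spec, out)
    return out, manifest


@pytest.fixture()
def toy_dictionary():
    study = "STUDYA"
    return VariableDictionary(study, [
        VariableSpec("age", "demographic", "real",
                     provenance=[SourceRecord(study, "demo.tsv", "age")]),
        VariableSpec("sex", "demographic", "categorical", aliases={"gender"},
                     accepted_codes={"F": "female", "M": "male"},
                     provenance=[SourceRecord(study, "demo.tsv", "sex")]),
        VariableSpec("motor_score", "session", "integer",
                     provenance=[SourceRecord(study, "visits.tsv", "motor_total")]),
        VariableSpec("cognitive_score", "session", "real",
                     provenance=[SourceRecord(study, "visits.tsv", "sdmt")]),
    ])


@pytest.fixture()
def toy_tables():
    demo = pd.DataFrame({
        "participant_id": ["P001", "P002", "P003"],
        "age": [41.5, 52.0, 36.2],
        "gender": ["F", "M", "F"],
    })
    demo.attrs["source_file"] = "demo.tsv"
    visits = pd.DataFrame({
        "participant_id": ["P001", "P001", "P002", "P002", "P003", "P003"],
        "visit": [1, 2, 1, 2, 1, 2],
        "motor_total": [10, 12, 30, 33, 5, None],
        "sdmt": [50.0, 48.5, 30.0, None, 55.0, 54.0],
    })
    visits.attrs["source_file"] = "visits.tsv"
    return [demo, visits]
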