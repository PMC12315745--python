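"""Date anchoring, time quantization, recoding, scrubbing, and auditing."""

import datetime as dt
import json
import random

import pytest
from hypothesis import given, settings, strategies as st

from bidscurate.deid import (
    AnchoringError,
    CodeSpaceExhausted,
    DeidError,
    EventDate,
    RecodingMap,
    RecodingMaps,
    ScrubPolicy,
    anchor_dates,
    audit_dataset,
    quantize_time,
    scrub_dataset,
    scrub_sidecar,
)


class TestAnchorDates:
    def test_baseline_and_follow_up_offsets(self):
        events = [
            EventDate("P1", "screening", "2010-03-05", is_baseline=True),
            EventDate("P1", "visit1", "2010-03-19"),
            EventDate("P1", "prescreen", "2010-02-26"),
        ]
        offsets = anchor_dates(events)
        assert offsets[("P1", "screening")] == 0
        assert offsets[("P1", "visit1")] == 14
        assert offsets[("P1", "prescreen")] == -7

    @pytest.mark.parametrize("n_baselines", [0, 2])
    def test_baseline_cardinality_enforced(self, n_baselines):
        events = [EventDate("P9", f"e{i}", "2010-01-01", is_baseline=i < n_baselines)
                  for i in range(3)]
        with pytest.raises(AnchoringError, match="P9"):
            anchor_dates(events)

    @given(st.lists(st.dates(min_value=dt.date(1990, 1, 1),
                             max_value=dt.date(2030, 1, 1)),
                    min_size=2, max_size=8))
    @settings(max_examples=100, derandomize=True)
    def test_pairwise_intervals_preserved(self, dates):
        events = [EventDate("PX", f"e{i}", d, is_baseline=i == 0)
                  for i, d in enumerate(dates)]
        offsets = anchor_dates(events)
        for i, di in enumerate(dates):
            for j, dj in enumerate(dates):
                assert (offsets[("PX", f"e{i}")] - offsets[("PX", f"e{j}")]
                        == (di - dj).days)


class TestQuantizeTime:
    @pytest.mark.parametrize("raw,expected", [
        ("14:37:00", "14:30:00"),
        ("09:00:00", "09:00:00"),
        ("11:52:30", "12:00:00"),   # exact 7.5-minute tie rounds up
        ("23:52:30", "00:00:00"),   # wraps past midnight
        ("23:52:29", "23:45:00"),
        ("00:07:29", "00:00:00"),
        ("00:07:30", "00:15:00"),
    ])
    def test_examples(self, raw, expected):
        assert quantize_time(raw) == expected

    def test_time_objects_round_trip_type(self):
        assert quantize_time(dt.time(14, 37)) == dt.time(14, 30)

    @given(st.times())
    @settings(max_examples=300, derandomize=True)
    def test_bound_and_grid(self, t):
        q = quantize_time(t)
        assert q.minute in (0, 15, 30, 45) and q.second == 0 and q.microsecond == 0
        seconds = lambda x: x.hour * 3600 + x.minute * 60 + x.second + x.microsecond / 1e6
        diff = abs(seconds(q) - seconds(t))
        assert min(diff, 86400 - diff) <= 450.0

    def test_idempotent(self):
        for h in range(0, 24, 3):
            on_grid = dt.time(h, 45)
            assert quantize_time(on_grid) == on_grid


class TestRecode:
    def test_institution_gets_letter_code(self):
        m = RecodingMap("institution", seed=3)
        code = m.recode("Hopital_de_la_Pitie_Salpetriere")
        assert m.is_code(code) and code.startswith("Institution ")

    def test_stability_and_injectivity(self):
        m = RecodingMap("institution", seed=1)
        a1 = m.recode("site_a")
        b = m.recode("site_b")
        assert m.recode("site_a") == a1 and a1 != b
        assert m.recode(a1) == a1  # already-coded values pass through

    def test_insertion_order_determinism(self):
        codes = []
        for _ in range(2):
            m = RecodingMap("scanner_serial", seed=5)
            codes.append([m.recode(v) for v in ["s3", "s1", "s2"]])
        assert codes[0] == codes[1]

    def test_sorted_input_mode_is_order_independent(self):
        m1 = RecodingMap("institution", seed=9)
        m2 = RecodingMap("institution", seed=9)
        m1.recode_all(["c", "a", "b"], sorted_input=True)
        m2.recode_all(["b", "c", "a"], sorted_input=True)
        assert m1.forward == m2.forward

    def test_participant_id_grammar(self):
        m = RecodingMap("participant_id", seed=2, prefix="T", width=5)
        code = m.recode("original-subject-417")
        assert m.is_code(code) and len(code) == 6 and code[0] == "T"

    def test_code_space_exhaustion(self):
        m = RecodingMap("participant_id", seed=0, prefix="X", width=1)
        for i in range(10):
            m.recode(f"v{i}")
        with pytest.raises(CodeSpaceExhausted, match="capacity"):
            m.recode("one-too-many")

    def test_empty_value_rejected(self):
        with pytest.raises(DeidError):
            RecodingMap("institution").recode("")

    def test_maps_persistence_round_trip(self, tmp_path):
        maps = RecodingMaps.with_seed(4)
        maps.institution.recode("somewhere")
        maps.save(tmp_path / "maps.json")
        again = RecodingMaps.load(tmp_path / "maps.json")
        assert again.institution.recode("somewhere") == maps.institution.forward["somewhere"]


class TestScrubSidecar:
    @pytest.fixture()
    def maps(self):
        return RecodingMaps.with_seed(0)

    def test_institution_recoded_time_quantized(self, maps):
        meta = {"InstitutionName": "Hopital_de_la_Pitie_Salpetriere",
                "AcquisitionTime": "14:37:00", "RepetitionTime": 2.0}
        out, audit = scrub_sidecar(meta, ScrubPolicy(), maps)
        assert out["InstitutionName"].startswith("Institution ")
        assert out["AcquisitionTime"] == "14:30:00"
        assert out["RepetitionTime"] == 2.0
        assert {a[0] for a in audit} == {"InstitutionName", "AcquisitionTime"}

    def test_date_anchored_to_study_day(self, maps):
        meta = {"AcquisitionDate": "2010-03-19", "AcquisitionDateTime": "2010-03-05T10:00:00"}
        out, _ = scrub_sidecar(meta, ScrubPolicy(), maps, anchor="2010-03-05")
        assert out["AcquisitionDate"] == 14
        assert out["AcquisitionDateTime"] == 0

    def test_removed_fields_absent_and_audited(self, maps):
        out, audit = scrub_sidecar({"PatientName": "Doe^Jane", "EchoTime": 0.03},
                                   ScrubPolicy(), maps)
        assert "PatientName" not in out and ("PatientName", "removed") in audit

    def test_unparseable_transform_drops_field(self, maps):
        out, audit = scrub_sidecar({"AcquisitionTime": "not a time"}, ScrubPolicy(), maps)
        assert "AcquisitionTime" not in out
        assert ("AcquisitionTime", "dropped-unparseable") in audit

    def test_date_without_anchor_dropped_not_kept(self, maps):
        out, audit = scrub_sidecar({"AcquisitionDate": "2010-03-19"}, ScrubPolicy(), maps)
        assert "AcquisitionDate" not in out
        assert ("AcquisitionDate", "dropped-unparseable") in audit

    def test_idempotence(self, maps):
        meta = {"InstitutionName": "Somewhere General", "AcquisitionTime": "08:11:03",
                "AcquisitionDate": "2011-06-01", "PatientName": "X",
                "DeviceSerialNumber": "SN-778", "Untouched": "value"}
        once, _ = scrub_sidecar(meta, ScrubPolicy(), maps, anchor="2011-05-01")
        twice, audit = scrub_sidecar(once, ScrubPolicy(), maps, anchor="2011-05-01")
        assert twice == once and audit == []

    def test_remove_transform_overlap_rejected(self):
        with pytest.raises(DeidError, match="both"):
            ScrubPolicy(remove_fields=["AcquisitionTime"],
                        transform_fields={"AcquisitionTime": "quantize_time"})


class TestAudit:
    def test_clean_fixture_has_no_findings(self, clean_bids):
        root, _ = clean_bids
        assert audit_dataset(root) == []

    def test_planted_identifiers_all_found_no_false_positives(self, planted_bids):
        root, manifest = planted_bids
        found = {(f.path, f.field) for f in audit_dataset(root)}
        planted = {(p["path"], p["field"]) for p in manifest.planted_identifiers}
        assert found == planted  # recall and precision both 1.0

    def test_station_name_detected(self, tmp_path):
        p = tmp_path / "sub-T00001" / "ses-01" / "anat"
        p.mkdir(parents=True)
        (p / "sub-T00001_ses-01_T1w.json").write_text(
            json.dumps({"StationName": "MRI-PARIS-01"}))
        findings = audit_dataset(tmp_path)
        assert any(f.field == "StationName" for f in findings)

    def test_date_inside_comment_detected(self, tmp_path):
        p = tmp_path / "sub-T00001" / "ses-01" / "anat"
        p.mkdir(parents=True)
        (p / "sub-T00001_ses-01_T1w.json").write_text(
            json.dumps({"ScanComments": "rescheduled from 2010-03-05"}))
        findings = audit_dataset(tmp_path)
        assert any(f.kind == "date" for f in findings)

    def test_unreadable_json_reported_not_fatal(self, tmp_path):
        p = tmp_path / "sub-T00001" / "ses-01" / "anat"
        p.mkdir(parents=True)
        (p / "sub-T00001_ses-01_T1w.json").write_text("{broken")
        findings = audit_dataset(tmp_path)
        assert [f.kind for f in findings] == ["unverifiable"]


class TestScrubDataset:
    def test_full_dataset_scrub_then_audit_clean_and_idempotent(self, tmp_path, planted_bids):
        import shutil

        src, manifest = planted_bids
        root = tmp_path / "bids"
        shutil.copytree(src, root)
        policy = ScrubPolicy(
            remove_fields=list(ScrubPolicy().remove_fields) + ["ScanComments"],
            transform_fields=ScrubPolicy().transform_fields)
        maps = RecodingMaps.with_seed(1)
        rows = scrub_dataset(root, policy, maps, baselines=manifest.baseline_dates)
        assert rows  # every planted identifier produced an action
        assert audit_dataset(root) == []
        rows2 = scrub_dataset(root, policy, maps, baselines=manifest.baseline_dates)
        assert rows2 == []

    def test_interval_preservation_on_fixture_calendar(self, clean_bids):
        _, manifest = clean_bids
        events = manifest.event_dates()
        offsets = anchor_dates(events)
        by_pid = {}
        for e in events:
            by_pid.setdefault(e.participant_id, []).append(e)
        for pid, evs in by_pid.items():
            for a in evs:
                for b in evs:
                    assert (offsets[(pid, a.event_label)] - offsets[(pid, b.event_label)]
                            == (a.calendar_date - b.calendar_date).days)
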