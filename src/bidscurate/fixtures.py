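"""Self-contained toy studies for exercising every curation operation.

:func:`make_fixture` writes a miniature but structurally valid dataset —
subject/session folders, minimal NIfTI volumes with sidecar JSON,
``participants.tsv``, wide phenotype source tables with a variable
dictionary, per-subject phenotype documents — plus a ground-truth
manifest recording the expected roster, the planted identifying metadata,
the planted structural defects, the phenotype cell count, and every
participant's visit calendar.  Downstream modules are tested against the
manifest as an exact oracle.

Image payloads are minimal 4x4x4 int16 volumes: Level-1 curation never
reads voxel data, so content is irrelevant and trees stay desk-scale.
Trees are byte-identical for a given spec and seed (gzip streams are
written with a zeroed timestamp).
"""

from __future__ import annotations

import datetime as dt
import gzip
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from ._util import atomic_write_json, atomic_write_text
from .cohort import CandidateParticipant
from .deid import EventDate
from .layout import DATATYPE_BY_SUFFIX, BidsName, DatasetRoster, mark_qc_fail
from .phenotype import (
    SourceRecord,
    VariableDictionary,
    VariableSpec,
    count_table_cells,
    deconstruct_tables,
    write_documents,
)

__all__ = [
    "FixtureSpec",
    "GroundTruthManifest",
    "FixtureError",
    "make_fixture",
    "make_multistudy_fixture",
    "default_planted_identifiers",
    "random_phenotype_study",
    "random_candidate_pool",
]

GROUPS = ("control", "premanifest", "manifest")
_GRID_MINUTES = (0, 15, 30, 45)


class FixtureError(ValueError):
    pass


@dataclass
class FixtureSpec:
    """Parameters of one toy study."""

    n_subjects: int = 3
    sessions_per_subject: int | Sequence[int] = 2
    modalities: dict[str, int] = field(default_factory=lambda: {"T1w": 1, "bold": 1})
    n_qc_failures: int = 0
    planted_identifiers: list[tuple[str, object, str]] | None = None
    planted_defects: tuple[str, ...] = ()
    phenotype: bool = True
    study_label: str = "TOY"
    subject_prefix: str = "T"
    subject_start: int = 1
    seed: int = 0

    def __post_init__(self):
        for suffix in self.modalities:
            if suffix not in DATATYPE_BY_SUFFIX:
                raise FixtureError(f"unknown modality suffix {suffix!r}")
        bad = set(self.planted_defects) - {
            "orphan_sidecar", "bad_filename", "missing_sidecar", "unlisted_subject"}
        if bad:
            raise FixtureError(f"unknown defect kinds {sorted(bad)}")

    def subject_ids(self) -> list[str]:
        return [f"{self.subject_prefix}{i:05d}"
                for i in range(self.subject_start, self.subject_start + self.n_subjects)]

    def session_counts(self) -> list[int]:
        if isinstance(self.sessions_per_subject, int):
            return [self.sessions_per_subject] * self.n_subjects
        counts = list(self.sessions_per_subject)
        if len(counts) != self.n_subjects:
            raise FixtureError("per-subject session list length != n_subjects")
        return counts

    @classmethod
    def from_file(cls, path: Path | str) -> "FixtureSpec":
        import yaml

        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        if "planted_defects" in d:
            d["planted_defects"] = tuple(d["planted_defects"])
        if d.get("planted_identifiers"):
            d["planted_identifiers"] = [tuple(x) for x in d["planted_identifiers"]]
        return cls(**d)


def default_planted_identifiers() -> list[tuple[str, object, str]]:
    """One identifier per category the scrub conventions must catch."""
    return [
        ("InstitutionName", "Hopital_de_la_Pitie_Salpetriere", "institution"),
        ("InstitutionAddress", "47 Boulevard de l'Hopital, Paris", "institution"),
        ("DeviceSerialNumber", "SN-001234", "scanner_serial"),
        ("StationName", "MRI-PARIS-01", "scanner_serial"),
        ("AcquisitionDateTime", "2010-03-05T14:37:12", "date"),
        ("AcquisitionTime", "14:37:12", "sub-quarter-hour-time"),
        ("ScanComments", "baseline visit on 2010-03-05", "date-in-comment"),
        ("PatientName", "Doe^Jane", "identifying-field"),
    ]


@dataclass
class GroundTruthManifest:
    """What a generated fixture is known to contain."""

    roster: DatasetRoster
    phenotype_cell_count: int = 0
    baseline_dates: dict[str, str] = field(default_factory=dict)
    events: list[dict] = field(default_factory=list)
    planted_identifiers: list[dict] = field(default_factory=list)
    planted_defects: list[dict] = field(default_factory=list)
    qc_failed_files: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def event_dates(self) -> list[EventDate]:
        return [EventDate(e["participant_id"], e["event_label"],
                          e["calendar_date"], e["is_baseline"]) for e in self.events]

    def to_dict(self) -> dict:
        return {
            "roster": self.roster.to_dict(),
            "phenotype_cell_count": self.phenotype_cell_count,
            "baseline_dates": dict(self.baseline_dates),
            "events": list(self.events),
            "planted_identifiers": list(self.planted_identifiers),
            "planted_defects": list(self.planted_defects),
            "qc_failed_files": list(self.qc_failed_files),
            "extra": dict(self.extra),
        }

    def save(self, path: Path | str) -> None:
        atomic_write_json(path, self.to_dict())

    @classmethod
    def load(cls, path: Path | str) -> "GroundTruthManifest":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(roster=DatasetRoster.from_dict(d["roster"]),
                   phenotype_cell_count=d["phenotype_cell_count"],
                   baseline_dates=d["baseline_dates"], events=d["events"],
                   planted_identifiers=d["planted_identifiers"],
                   planted_defects=d["planted_defects"],
                   qc_failed_files=d["qc_failed_files"], extra=d.get("extra", {}))


def _write_nifti(path: Path, nprng: np.random.Generator) -> None:
    data = nprng.integers(0, 100, size=(4, 4, 4), dtype=np.int16)
    raw = nib.Nifti1Image(data, np.eye(4)).to_bytes()
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        with gzip.GzipFile(fileobj=fh, mode="wb", mtime=0) as gz:
            gz.write(raw)


def _clean_sidecar(rng: random.Random, study_day: int) -> dict:
    return {
        "Manufacturer": "SyntheticImaging",
        "RepetitionTime": 2.0,
        "EchoTime": 0.03,
        "AcquisitionTime": f"{rng.randrange(8, 18):02d}:{rng.choice(_GRID_MINUTES):02d}:00",
        "StudyDay": study_day,
    }


def _phenotype_dictionary(study_label: str) -> VariableDictionary:
    src = lambda f, orig: [SourceRecord(study_label, f, orig)]
    return VariableDictionary(study_label, [
        VariableSpec("age", "demographic", "real",
                     provenance=src("demographics.tsv", "age")),
        VariableSpec("sex", "demographic", "categorical", aliases={"gender"},
                     accepted_codes={"F": "female", "M": "male"},
                     provenance=src("demographics.tsv", "sex")),
        VariableSpec("cag", "demographic", "integer",
                     provenance=src("demographics.tsv", "cag")),
        VariableSpec("motor_score", "session", "integer",
                     provenance=src("visits.tsv", "motor_total")),
        VariableSpec("cognitive_score", "session", "real",
                     provenance=src("visits.tsv", "sdmt")),
    ])


def _make_phenotype(rng: random.Random, plan_sessions: Mapping[str, list[str]],
                    study_label: str) -> tuple[list[pd.DataFrame], VariableDictionary, dict]:
    """Wide source tables + dictionary + per-subject demographic record."""
    demo_rows, visit_rows, per_subject = [], [], {}
    for pid in sorted(plan_sessions):
        age = round(rng.uniform(20.0, 70.0), 1)
        sex = rng.choice(["F", "M"])
        cag = rng.randrange(15, 51)
        group = rng.choice(GROUPS)
        per_subject[pid] = {"age": age, "sex": sex, "cag": cag, "group": group}
        demo_rows.append({"participant_id": pid, "age": age, "sex": sex, "cag": cag})
        for ses in plan_sessions[pid]:
            visit_rows.append({
                "participant_id": pid,
                "visit": ses,
                "motor_total": rng.randrange(0, 125) if rng.random() > 0.15 else None,
                "sdmt": round(rng.uniform(10, 60), 1) if rng.random() > 0.15 else None,
            })
    demo = pd.DataFrame(demo_rows)
    demo.attrs["source_file"] = "demographics.tsv"
    visits = pd.DataFrame(visit_rows)
    visits.attrs["source_file"] = "visits.tsv"
    return [demo, visits], _phenotype_dictionary(study_label), per_subject


def _materialize(
    out_dir: Path,
    study_label: str,
    plan_sessions: Mapping[str, list[str]],
    modalities_for: Mapping[tuple[str, str], dict[str, int]],
    n_qc_failures: int,
    seed: int,
    phenotype: bool,
    planted_identifiers: list[tuple[str, object, str]] | None,
    planted_defects: Sequence[str],
    extra: dict | None = None,
) -> GroundTruthManifest:
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        raise FixtureError(f"output directory {out_dir} is not empty")
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    nprng = np.random.default_rng(seed)

    atomic_write_json(out_dir / "dataset_description.json",
                      {"Name": study_label, "BIDSVersion": "1.8.0"})

    # visit calendar: baseline plus roughly-annual follow-ups with jitter
    baselines: dict[str, str] = {}
    events: list[dict] = []
    study_day: dict[tuple[str, str], int] = {}
    for pid in sorted(plan_sessions):
        base = dt.date(2009, 1, 1) + dt.timedelta(days=rng.randrange(0, 1461))
        baselines[pid] = base.isoformat()
        for k, ses in enumerate(plan_sessions[pid]):
            offset = 0 if k == 0 else 365 * k + rng.randrange(-30, 31)
            date = base + dt.timedelta(days=offset)
            events.append({"participant_id": pid, "event_label": f"ses-{ses}",
                           "calendar_date": date.isoformat(), "is_baseline": k == 0})
            study_day[(pid, ses)] = offset

    # scan plan, then QC-failure assignment, then writing
    scans: list[tuple[str, str, BidsName]] = []
    for pid in sorted(plan_sessions):
        for ses in plan_sessions[pid]:
            for suffix, runs in sorted(modalities_for[(pid, ses)].items()):
                for run in range(1, runs + 1):
                    ents = (("run", f"{run:02d}"),) if runs > 1 else ()
                    scans.append((pid, ses, BidsName(subject=pid, suffix=suffix,
                                                     session=ses, entities=ents)))
    if n_qc_failures > len(scans):
        raise FixtureError(f"n_qc_failures {n_qc_failures} exceeds {len(scans)} scans")
    failed_idx = set(rng.sample(range(len(scans)), n_qc_failures))

    scan_counts: dict[str, int] = {}
    qc_failed_files: list[str] = []
    sidecar_paths: list[Path] = []
    for i, (pid, ses, name) in enumerate(scans):
        qc_failed = i in failed_idx
        final = name.with_qc(qc_failed)
        datatype = DATATYPE_BY_SUFFIX[name.suffix]
        folder = out_dir / f"sub-{pid}" / f"ses-{ses}" / datatype
        img = folder / final.render()
        _write_nifti(img, nprng)
        sidecar = folder / final.with_qc(qc_failed).render().replace(".nii.gz", ".json")
        atomic_write_json(sidecar, _clean_sidecar(rng, study_day[(pid, ses)]))
        sidecar_paths.append(sidecar)
        if qc_failed:
            qc_failed_files.append(str(img.relative_to(out_dir)))
        else:
            scan_counts[name.suffix] = scan_counts.get(name.suffix, 0) + 1

    # phenotype: wide source tables, dictionary, per-subject documents
    cell_count = 0
    groups: dict[str, int] = {}
    participants_rows = []
    if phenotype:
        tables, dictionary, per_subject = _make_phenotype(rng, plan_sessions, study_label)
        src_dir = out_dir / "sourcedata" / "phenotype"
        src_dir.mkdir(parents=True, exist_ok=True)
        for df in tables:
            atomic_write_text(src_dir / df.attrs["source_file"],
                              df.to_csv(sep="\t", index=False, na_rep="n/a"))
        dictionary.save(src_dir / "dictionary.json")
        cell_count = count_table_cells(tables, "participant_id", "visit")
        docs = deconstruct_tables(tables, dictionary, "participant_id", "visit")
        write_documents(docs, out_dir)
        for pid in sorted(plan_sessions):
            rec = per_subject[pid]
            groups[rec["group"]] = groups.get(rec["group"], 0) + 1
            participants_rows.append({"participant_id": f"sub-{pid}", "age": rec["age"],
                                      "sex": rec["sex"], "group": rec["group"]})
    else:
        participants_rows = [{"participant_id": f"sub-{pid}"} for pid in sorted(plan_sessions)]
    atomic_write_text(out_dir / "participants.tsv",
                      pd.DataFrame(participants_rows).to_csv(sep="\t", index=False,
                                                             na_rep="n/a"))

    # planted identifying metadata, one sidecar per identifier
    planted: list[dict] = []
    if planted_identifiers:
        if not sidecar_paths:
            raise FixtureError("cannot plant identifiers: fixture has no sidecars")
        hosts = sorted(sidecar_paths)
        for k, (fld, value, kind) in enumerate(planted_identifiers):
            host = hosts[k % len(hosts)]
            with open(host, encoding="utf-8") as fh:
                meta = json.load(fh)
            meta[fld] = value
            atomic_write_json(host, meta)
            planted.append({"path": str(host.relative_to(out_dir)),
                            "field": fld, "value": value, "kind": kind})

    # deliberately planted structural defects
    n_participants = len(plan_sessions)
    n_sessions = sum(len(v) for v in plan_sessions.values())
    defects: list[dict] = []
    first_pid = sorted(plan_sessions)[0]
    first_ses = plan_sessions[first_pid][0]
    anat = out_dir / f"sub-{first_pid}" / f"ses-{first_ses}" / "anat"
    for kind in planted_defects:
        if kind == "orphan_sidecar":
            suffix = next(s for s in ("PDw", "T2w", "FLAIR")
                          if s not in modalities_for[(first_pid, first_ses)])
            p = anat / f"sub-{first_pid}_ses-{first_ses}_{suffix}.json"
            atomic_write_json(p, {"Manufacturer": "SyntheticImaging"})
            defects.append({"kind": kind, "path": str(p.relative_to(out_dir))})
        elif kind == "bad_filename":
            p = anat / "scan_final.nii.gz"
            p.parent.mkdir(parents=True, exist_ok=True)
            _write_nifti(p, nprng)
            defects.append({"kind": kind, "path": str(p.relative_to(out_dir))})
        elif kind == "missing_sidecar":
            victim = sorted(sidecar_paths)[0]
            victim.unlink()
            defects.append({"kind": kind, "path": str(victim.relative_to(out_dir))})
        elif kind == "unlisted_subject":
            pid = "ZZ99999"
            folder = out_dir / f"sub-{pid}" / "ses-01" / "anat"
            name = BidsName(subject=pid, suffix="T1w", session="01")
            _write_nifti(folder / name.render(), nprng)
            atomic_write_json(folder / name.render().replace(".nii.gz", ".json"),
                              _clean_sidecar(rng, 0))
            defects.append({"kind": kind, "path": f"sub-{pid}"})
            n_participants += 1
            n_sessions += 1
            scan_counts["T1w"] = scan_counts.get("T1w", 0) + 1

    roster = DatasetRoster(
        dataset_label=study_label,
        n_participants=n_participants,
        n_sessions=n_sessions,
        scans_by_modality=dict(sorted(scan_counts.items())),
        group_counts=dict(sorted(groups.items())),
    )
    manifest = GroundTruthManifest(
        roster=roster,
        phenotype_cell_count=cell_count,
        baseline_dates=baselines,
        events=events,
        planted_identifiers=planted,
        planted_defects=defects,
        qc_failed_files=sorted(qc_failed_files),
        extra=dict(extra or {}),
    )
    manifest.save(out_dir / "sourcedata" / "manifest.json")
    return manifest


def make_fixture(spec: FixtureSpec, out_dir: Path | str) -> GroundTruthManifest:
    """Generate one toy study under ``out_dir`` (must be empty or absent)."""
    ids = spec.subject_ids()
    counts = spec.session_counts()
    plan_sessions = {pid: [f"{k:02d}" for k in range(1, c + 1)]
                     for pid, c in zip(ids, counts)}
    modalities_for = {(pid, ses): dict(spec.modalities)
                      for pid, sessions in plan_sessions.items() for ses in sessions}
    return _materialize(Path(out_dir), spec.study_label, plan_sessions, modalities_for,
                        spec.n_qc_failures, spec.seed, spec.phenotype,
                        spec.planted_identifiers, spec.planted_defects)


def make_multistudy_fixture(
    spec_a: FixtureSpec,
    spec_b: FixtureSpec,
    carryover_fraction: float,
    out_dir: Path | str,
    session_labels_a: Sequence[str] | None = None,
    session_labels_b: Sequence[str] | None = None,
) -> GroundTruthManifest:
    """Two formally separate studies combined into one dataset.

    A fraction of study-B subjects are carried over from study A: their
    folders merge and their study-B sessions continue study A's numbering.
    Fresh study-B subjects get their own folders numbered from 01.
    """
    if not 0.0 <= carryover_fraction <= 1.0:
        raise FixtureError("carryover_fraction must be within [0, 1]")
    if not isinstance(spec_a.sessions_per_subject, int) or not isinstance(
            spec_b.sessions_per_subject, int):
        raise FixtureError("multistudy fixtures need integer sessions_per_subject")
    m_a, m_b = spec_a.sessions_per_subject, spec_b.sessions_per_subject
    labels_a = list(session_labels_a or (f"{k:02d}" for k in range(1, m_a + 1)))
    labels_b = list(session_labels_b or (f"{k:02d}" for k in range(m_a + 1, m_a + m_b + 1)))
    if set(labels_a) & set(labels_b):
        raise FixtureError(
            f"session-label collision on merge: {sorted(set(labels_a) & set(labels_b))}")

    ids_a = spec_a.subject_ids()
    n_carry = round(carryover_fraction * spec_b.n_subjects)
    if n_carry > spec_a.n_subjects:
        raise FixtureError("more carryover subjects than study A has")
    carry = ids_a[:n_carry]
    n_new = spec_b.n_subjects - n_carry
    start_new = spec_a.subject_start + spec_a.n_subjects
    ids_b_new = [f"{spec_a.subject_prefix}{i:05d}"
                 for i in range(start_new, start_new + n_new)]

    plan_sessions: dict[str, list[str]] = {pid: list(labels_a) for pid in ids_a}
    modalities_for: dict[tuple[str, str], dict[str, int]] = {
        (pid, ses): dict(spec_a.modalities) for pid in ids_a for ses in labels_a}
    for pid in carry:
        plan_sessions[pid] += list(labels_b)
        for ses in labels_b:
            modalities_for[(pid, ses)] = dict(spec_b.modalities)
    for pid in ids_b_new:
        own = [f"{k:02d}" for k in range(1, m_b + 1)]
        plan_sessions[pid] = own
        for ses in own:
            modalities_for[(pid, ses)] = dict(spec_b.modalities)

    label = f"{spec_a.study_label}+{spec_b.study_label}"
    extra = {"study_a": spec_a.study_label, "study_b": spec_b.study_label,
             "carryover_subjects": carry, "n_carryover": n_carry}
    return _materialize(Path(out_dir), label, plan_sessions, modalities_for,
                        spec_a.n_qc_failures + spec_b.n_qc_failures, spec_a.seed,
                        spec_a.phenotype, None, (), extra=extra)


# ---------------------------------------------------------------------------
# in-memory random study generators for property testing

_WORDS = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta")


def random_phenotype_study(rng: random.Random):
    """A random small study: wide tables + dictionary, for round-trip checks.

    Column headers are drawn at random from canonical names, aliases, and
    provenance original names so resolution paths are all exercised.
    Returns ``(tables, dictionary, id_column, session_column)``.
    """
    study = "RND"
    n_demo = rng.randrange(1, 4)
    n_sess = rng.randrange(1, 4)
    specs: list[VariableSpec] = []
    headers: dict[str, list[str]] = {}
    for i in range(n_demo + n_sess):
        level = "demographic" if i < n_demo else "session"
        vtype = rng.choice(["integer", "real", "categorical", "string"])
        name = f"var{i}"
        aliases = {f"alias{i}"} if rng.random() < 0.5 else set()
        codes = {"A": "a", "B": "b", "C": "c"} if vtype == "categorical" else None
        orig = f"orig{i}"
        specs.append(VariableSpec(name, level, vtype, aliases=aliases,
                                  accepted_codes=codes,
                                  provenance=[SourceRecord(study, "raw.tsv", orig)]))
        headers[name] = [name, orig] + sorted(aliases)
    dictionary = VariableDictionary(study, specs)

    def value_for(spec: VariableSpec):
        if rng.random() < 0.2:
            return None
        if spec.value_type == "integer":
            return rng.randrange(0, 100)
        if spec.value_type == "real":
            return round(rng.uniform(0, 100), 2)
        if spec.value_type == "categorical":
            return rng.choice(sorted(spec.accepted_codes))
        return rng.choice(_WORDS)

    pids = [f"P{i:03d}" for i in range(1, rng.randrange(2, 7))]
    sessions = [f"{k:02d}" for k in range(1, rng.randrange(2, 5))]
    demo_specs, sess_specs = specs[:n_demo], specs[n_demo:]

    demo_cols = {s.canonical_name: rng.choice(headers[s.canonical_name]) for s in demo_specs}
    demo_rows = [{"participant_id": pid,
                  **{demo_cols[s.canonical_name]: value_for(s) for s in demo_specs}}
                 for pid in pids]
    demo = pd.DataFrame(demo_rows)
    demo.attrs["source_file"] = "demo.tsv"
    tables = [demo]
    if sess_specs:
        sess_cols = {s.canonical_name: rng.choice(headers[s.canonical_name])
                     for s in sess_specs}
        rows = [{"participant_id": pid, "visit": ses,
                 **{sess_cols[s.canonical_name]: value_for(s) for s in sess_specs}}
                for pid in pids for ses in sessions]
        visits = pd.DataFrame(rows)
        visits.attrs["source_file"] = "visits.tsv"
        tables.append(visits)
    return tables, dictionary, "participant_id", "visit"


def random_candidate_pool(rng: random.Random, n: int,
                          sites: Sequence[str] = ("S1", "S2"),
                          statuses: Sequence[str] = GROUPS) -> list[CandidateParticipant]:
    """Random cohort-selection pool with varied strata."""
    return [
        CandidateParticipant(
            participant_id=f"P{i:03d}",
            site=rng.choice(list(sites)),
            sex=rng.choice(["F", "M"]),
            clinical_status=rng.choice(list(statuses)),
            age=round(rng.uniform(21.0, 69.0), 1),
        )
        for i in range(1, n + 1)
    ]
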