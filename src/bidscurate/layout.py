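"""BIDS filename grammar, QC marking, tree validation, and roster accounting.

The filename grammar covers the entity subset used by Level-1 curation
(``sub``, ``ses``, ``acq``, ``run`` plus a scan-type suffix) and one
deliberate extension to the BIDS standard: scans that failed quality
control carry a ``BAD`` prefix on their suffix
(``sub-X_ses-01_run-01_BADT1w.nii.gz``).  Marked scans stay in the dataset
but are excluded from roster counts, acting as a first barrier against
their accidental use by automated pipelines.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ._util import atomic_write_json

__all__ = [
    "BidsName",
    "BidsNameError",
    "QCRecord",
    "DatasetRoster",
    "Violation",
    "parse_bids_name",
    "build_name",
    "mark_qc_fail",
    "unmark_qc_fail",
    "validate_tree",
    "summarize_roster",
    "aggregate_rosters",
]

#: canonical rendering order of entities that follow sub/ses
ENTITY_ORDER = ("acq", "run")

#: datatype folder for each recognized suffix
DATATYPE_BY_SUFFIX = {
    "T1w": "anat",
    "T2w": "anat",
    "FLAIR": "anat",
    "PDw": "anat",
    "bold": "func",
    "dwi": "dwi",
    "swi": "swi",
    "pet": "pet",
}

#: modality families used in summary tables (sMRI rows stay per-suffix)
MODALITY_GROUP = {
    "T1w": "sMRI",
    "T2w": "sMRI",
    "FLAIR": "sMRI",
    "PDw": "sMRI",
    "bold": "fMRI",
    "dwi": "DWI",
    "swi": "SWI",
    "pet": "PET",
}

_VALUE_RE = re.compile(r"^[A-Za-z0-9]+$")
_TOKEN_RE = re.compile(r"^([a-z]+)-([A-Za-z0-9]+)$")
_SPLIT_EXT_RE = re.compile(r"^([^.]+)(\..+)?$")

#: files tolerated at the dataset root alongside sub-* folders
_IGNORED_TOP = {
    "dataset_description.json",
    "participants.tsv",
    "participants.json",
    "README",
    "README.md",
    "CHANGES",
    ".bidsignore",
}
_IGNORED_DIRS = {"sourcedata", "derivatives", "code", "phenotype"}


class BidsNameError(ValueError):
    """Raised for filenames that violate the naming grammar."""


@dataclass(frozen=True)
class BidsName:
    """Parsed or to-be-rendered BIDS filename.

    ``entities`` holds key/value pairs beyond subject and session (e.g.
    ``acq``, ``run``) as an ordered tuple of pairs; rendering places
    ``acq`` and ``run`` in canonical order, any extra entities after them
    in the given order.
    """

    subject: str
    suffix: str
    session: str | None = None
    entities: tuple[tuple[str, str], ...] = ()
    qc_failed: bool = False
    extension: str = ".nii.gz"

    def __post_init__(self):
        if not self.subject or not _VALUE_RE.match(self.subject):
            raise BidsNameError(f"illegal subject label {self.subject!r}")
        if self.session is not None and not _VALUE_RE.match(self.session):
            raise BidsNameError(f"illegal session label {self.session!r}")
        if not self.suffix or not _VALUE_RE.match(self.suffix):
            raise BidsNameError(f"illegal suffix {self.suffix!r}")
        seen = set()
        for key, value in self.entities:
            if key in ("sub", "ses"):
                raise BidsNameError(f"entity {key!r} must use the dedicated field")
            if not re.match(r"^[a-z]+$", key) or not _VALUE_RE.match(value):
                raise BidsNameError(f"illegal entity {key}-{value}")
            if key in seen:
                raise BidsNameError(f"duplicate entity {key!r}")
            seen.add(key)
        if self.extension and not self.extension.startswith("."):
            raise BidsNameError(f"extension must start with '.': {self.extension!r}")

    @property
    def entity_dict(self) -> dict[str, str]:
        return dict(self.entities)

    def render(self) -> str:
        parts = [f"sub-{self.subject}"]
        if self.session is not None:
            parts.append(f"ses-{self.session}")
        ents = dict(self.entities)
        for key in ENTITY_ORDER:
            if key in ents:
                parts.append(f"{key}-{ents.pop(key)}")
        for key, value in self.entities:
            if key in ents:
                parts.append(f"{key}-{value}")
        parts.append(("BAD" if self.qc_failed else "") + self.suffix)
        return "_".join(parts) + self.extension

    def with_qc(self, qc_failed: bool) -> "BidsName":
        return dataclasses.replace(self, qc_failed=qc_failed)


def parse_bids_name(filename: str | Path) -> BidsName:
    """Parse a filename into a :class:`BidsName`; raises :class:`BidsNameError`."""
    name = Path(filename).name
    m = _SPLIT_EXT_RE.match(name)
    if not m:
        raise BidsNameError(f"cannot split extension of {name!r}")
    base, extension = m.group(1), m.group(2) or ""
    tokens = base.split("_")
    if len(tokens) < 2:
        raise BidsNameError(f"{name!r} has no entity tokens before the suffix")
    suffix_tok = tokens[-1]
    if not _VALUE_RE.match(suffix_tok):
        raise BidsNameError(f"illegal suffix token {suffix_tok!r} in {name!r}")
    qc_failed = suffix_tok.startswith("BAD") and len(suffix_tok) > 3
    suffix = suffix_tok[3:] if qc_failed else suffix_tok
    subject = None
    session = None
    entities: list[tuple[str, str]] = []
    for tok in tokens[:-1]:
        tm = _TOKEN_RE.match(tok)
        if not tm:
            raise BidsNameError(f"malformed entity token {tok!r} in {name!r}")
        key, value = tm.group(1), tm.group(2)
        if key == "sub":
            if subject is not None:
                raise BidsNameError(f"duplicate sub- entity in {name!r}")
            subject = value
        elif key == "ses":
            if session is not None:
                raise BidsNameError(f"duplicate ses- entity in {name!r}")
            session = value
        else:
            entities.append((key, value))
    if subject is None:
        raise BidsNameError(f"{name!r} lacks the leading sub- entity")
    if tokens[0] != f"sub-{subject}":
        raise BidsNameError(f"sub- entity must come first in {name!r}")
    return BidsName(
        subject=subject,
        suffix=suffix,
        session=session,
        entities=tuple(entities),
        qc_failed=qc_failed,
        extension=extension,
    )


def build_name(parts: BidsName) -> str:
    """Render a :class:`BidsName` to its canonical filename string."""
    return parts.render()


def mark_qc_fail(name: str) -> str:
    """Mark a filename as QC-failed by prefixing its suffix with ``BAD``."""
    parsed = parse_bids_name(name)
    if parsed.qc_failed:
        raise BidsNameError(f"{name!r} is already marked as QC-failed")
    return parsed.with_qc(True).render()


def unmark_qc_fail(name: str) -> str:
    """Inverse of :func:`mark_qc_fail`."""
    parsed = parse_bids_name(name)
    if not parsed.qc_failed:
        raise BidsNameError(f"{name!r} is not marked as QC-failed")
    return parsed.with_qc(False).render()


@dataclass(frozen=True)
class QCRecord:
    """Manual quality-control rating on a 1-5 ordinal scale (1-2 fail, 3-5 pass)."""

    target: str
    rating: int
    comment: str = ""
    rater: str = ""
    duration_seconds: float | None = None

    def __post_init__(self):
        if self.rating not in (1, 2, 3, 4, 5):
            raise ValueError(f"rating must be 1..5, got {self.rating!r}")

    @property
    def passed(self) -> bool:
        return self.rating >= 3


@dataclass
class DatasetRoster:
    """Per-dataset accounting of participants, sessions, and usable scans.

    QC-failed scans are excluded from ``scans_by_modality``.  Group counts
    may sum to less than ``n_participants`` because phenotype-only
    participants (no imaging) can be left ungrouped.
    """

    dataset_label: str
    n_participants: int = 0
    n_sessions: int = 0
    scans_by_modality: dict[str, int] = field(default_factory=dict)
    group_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for label, n in [("n_participants", self.n_participants), ("n_sessions", self.n_sessions)]:
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"{label} must be a non-negative integer, got {n!r}")
        for d in (self.scans_by_modality, self.group_counts):
            for k, v in d.items():
                if not isinstance(v, int) or v < 0:
                    raise ValueError(f"count for {k!r} must be a non-negative integer")
        if sum(self.group_counts.values()) > self.n_participants:
            raise ValueError(
                f"group counts of {self.dataset_label!r} sum to more than n_participants"
            )

    @property
    def group_total(self) -> int:
        return sum(self.group_counts.values())

    def group_sum(self, keys: Iterable[str]) -> int:
        """Sum of a subset of group counts (e.g. all gene-carrier strata)."""
        return sum(self.group_counts[k] for k in keys)

    def to_dict(self) -> dict:
        return {
            "dataset_label": self.dataset_label,
            "n_participants": self.n_participants,
            "n_sessions": self.n_sessions,
            "scans_by_modality": dict(self.scans_by_modality),
            "group_counts": dict(self.group_counts),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DatasetRoster":
        return cls(
            dataset_label=d["dataset_label"],
            n_participants=int(d["n_participants"]),
            n_sessions=int(d["n_sessions"]),
            scans_by_modality={k: int(v) for k, v in d.get("scans_by_modality", {}).items()},
            group_counts={k: int(v) for k, v in d.get("group_counts", {}).items()},
        )

    def save(self, path: Path | str) -> None:
        atomic_write_json(path, self.to_dict())

    @classmethod
    def load(cls, path: Path | str) -> "DatasetRoster":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"quantity": "participants", "count": self.n_participants},
            {"quantity": "sessions", "count": self.n_sessions},
        ]
        for suffix in sorted(self.scans_by_modality):
            rows.append({"quantity": f"scans[{suffix}]", "count": self.scans_by_modality[suffix]})
        for grp in sorted(self.group_counts):
            rows.append({"quantity": f"group[{grp}]", "count": self.group_counts[grp]})
        return pd.DataFrame(rows)


def aggregate_rosters(rosters: Iterable[DatasetRoster], label: str = "combined") -> DatasetRoster:
    """Component-wise sum of disjoint dataset rosters."""
    rosters = list(rosters)
    labels = [r.dataset_label for r in rosters]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate dataset labels: {dupes}")
    total = DatasetRoster(dataset_label=label)
    for r in rosters:
        total.n_participants += r.n_participants
        total.n_sessions += r.n_sessions
        for k, v in r.scans_by_modality.items():
            total.scans_by_modality[k] = total.scans_by_modality.get(k, 0) + v
        for k, v in r.group_counts.items():
            total.group_counts[k] = total.group_counts.get(k, 0) + v
    return total


@dataclass(frozen=True)
class Violation:
    path: str
    rule: str
    message: str


def _is_image(p: Path) -> bool:
    return p.name.endswith(".nii.gz") or p.name.endswith(".nii")


def _image_base(p: Path) -> str:
    name = p.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return name[: -len(ext)]
    return p.stem


def _participants_column(root: Path) -> list[str] | None:
    tsv = root / "participants.tsv"
    if not tsv.exists():
        return None
    df = pd.read_csv(tsv, sep="\t", dtype=str)
    if "participant_id" not in df.columns:
        return []
    return [str(v) for v in df["participant_id"].dropna()]


def validate_tree(bids_root: Path | str) -> list[Violation]:
    """Check a dataset tree against the Level-1 naming conventions.

    Reported violations: filenames that fail the grammar, subject/session
    labels that do not match their folder, images lacking a sidecar JSON,
    orphan sidecars, unexpected root entries, and mismatches between
    subject folders and ``participants.tsv``.
    """
    root = Path(bids_root)
    violations: list[Violation] = []
    subj_dirs = sorted(p for p in root.iterdir() if p.is_dir() and p.name.startswith("sub-"))
    for entry in sorted(root.iterdir()):
        if entry.name.startswith("."):
            continue
        if entry.is_dir() and (entry.name.startswith("sub-") or entry.name in _IGNORED_DIRS):
            continue
        if entry.is_file() and entry.name in _IGNORED_TOP:
            continue
        violations.append(Violation(str(entry.relative_to(root)), "unexpected-entry",
                                    "entry does not belong at the dataset root"))

    for subj_dir in subj_dirs:
        label = subj_dir.name[len("sub-"):]
        if not _VALUE_RE.match(label):
            violations.append(Violation(subj_dir.name, "grammar", "illegal subject folder label"))
            continue
        for f in sorted(subj_dir.rglob("*")):
            if not f.is_file():
                continue
            rel = str(f.relative_to(root))
            try:
                parsed = parse_bids_name(f.name)
            except BidsNameError as exc:
                violations.append(Violation(rel, "grammar", str(exc)))
                continue
            if parsed.subject != label:
                violations.append(Violation(rel, "subject-mismatch",
                                            f"file subject {parsed.subject!r} != folder {label!r}"))
            ses_parents = [p.name for p in f.relative_to(subj_dir).parents
                           if p.name.startswith("ses-")]
            if ses_parents:
                folder_ses = ses_parents[0][len("ses-"):]
                if parsed.session != folder_ses:
                    violations.append(Violation(rel, "session-mismatch",
                                                f"file session {parsed.session!r} != folder {folder_ses!r}"))
            if _is_image(f):
                sidecar = f.parent / (_image_base(f) + ".json")
                if not sidecar.exists():
                    violations.append(Violation(rel, "missing-sidecar",
                                                "image has no sidecar JSON"))
            elif f.suffix == ".json" and parsed.suffix != "phenotype":
                images = [f.parent / (f.stem + ext) for ext in (".nii.gz", ".nii")]
                if not any(img.exists() for img in images):
                    violations.append(Violation(rel, "orphan-sidecar",
                                                "sidecar JSON has no matching image"))

    listed = _participants_column(root)
    if listed is not None:
        on_disk = {d.name for d in subj_dirs}
        listed_set = set(listed)
        for missing in sorted(listed_set - on_disk):
            violations.append(Violation("participants.tsv", "missing-subject-folder",
                                        f"{missing} listed but no folder on disk"))
        for extra in sorted(on_disk - listed_set):
            violations.append(Violation(extra, "unlisted-subject",
                                        f"{extra} on disk but absent from participants.tsv"))
    return violations


def summarize_roster(source: Path | str | Mapping, dataset_label: str | None = None) -> DatasetRoster:
    """Count participants, sessions, and usable scans.

    ``source`` is either a BIDS root directory or an already-tabulated
    manifest mapping (the printed accounting of a published dataset).
    Sessions are ``ses-*`` folders containing at least one file; scans are
    counted per suffix and QC-failed (``BAD``) scans are excluded.
    """
    if isinstance(source, Mapping):
        roster = DatasetRoster.from_dict(source)
        if dataset_label is not None:
            roster.dataset_label = dataset_label
        return roster

    root = Path(source)
    label = dataset_label or root.name
    subj_dirs = sorted(p for p in root.iterdir() if p.is_dir() and p.name.startswith("sub-"))
    n_sessions = 0
    scans: dict[str, int] = {}
    for subj_dir in subj_dirs:
        for ses_dir in sorted(p for p in subj_dir.iterdir()
                              if p.is_dir() and p.name.startswith("ses-")):
            if any(f.is_file() for f in ses_dir.rglob("*")):
                n_sessions += 1
        for f in subj_dir.rglob("*"):
            if f.is_file() and _is_image(f):
                try:
                    parsed = parse_bids_name(f.name)
                except BidsNameError:
                    continue
                if not parsed.qc_failed:
                    scans[parsed.suffix] = scans.get(parsed.suffix, 0) + 1

    groups: dict[str, int] = {}
    tsv = root / "participants.tsv"
    if tsv.exists():
        df = pd.read_csv(tsv, sep="\t", dtype=str)
        if "group" in df.columns:
            groups = {str(k): int(v) for k, v in df["group"].dropna().value_counts().items()}
    return DatasetRoster(
        dataset_label=label,
        n_participants=len(subj_dirs),
        n_sessions=n_sessions,
        scans_by_modality=dict(sorted(scans.items())),
        group_counts=dict(sorted(groups.items())),
    )
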