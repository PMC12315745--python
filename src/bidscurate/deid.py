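"""Pseudonymization of dataset metadata.

Identifying information is any value that narrows the search for a
participant: calendar dates, precise scan times, scanning facility,
scanner serial numbers, raw participant identifiers.  The transforms here
implement the Level-1 conventions:

* calendar dates become integer *study days* (day 0 = the participant's
  screening/baseline visit; pre-baseline events are negative);
* times of day are rounded to the nearest quarter hour (ties round up,
  wrapping past midnight to 00:00);
* institutions, scanner serials, and participant IDs receive consistent
  pseudonymous codes drawn from a seed-shuffled label sequence
  ("Institution Y" style), recorded in an append-only re-linkage map kept
  outside the distributed dataset.

:func:`scrub_sidecar` applies a configurable policy to one metadata map;
:func:`audit_dataset` sweeps a dataset tree for residual identifiers.
"""

from __future__ import annotations

import datetime as dt
import json
import random
import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from ._util import atomic_write_json

__all__ = [
    "EventDate",
    "RecodingMap",
    "RecodingMaps",
    "ScrubPolicy",
    "Finding",
    "DeidError",
    "AnchoringError",
    "CodeSpaceExhausted",
    "anchor_dates",
    "quantize_time",
    "scrub_sidecar",
    "scrub_dataset",
    "audit_dataset",
]

_QUARTER_US = 15 * 60 * 1_000_000
_DAY_US = 24 * 60 * 60 * 1_000_000


class DeidError(ValueError):
    pass


class AnchoringError(DeidError):
    pass


class CodeSpaceExhausted(DeidError):
    pass


@dataclass(frozen=True)
class EventDate:
    """A dated study event for one participant (visit, screening, scan)."""

    participant_id: str
    event_label: str
    calendar_date: dt.date
    is_baseline: bool = False

    def __post_init__(self):
        if isinstance(self.calendar_date, str):
            object.__setattr__(self, "calendar_date", dt.date.fromisoformat(self.calendar_date))
        if not isinstance(self.calendar_date, dt.date):
            raise DeidError(f"calendar_date must be a date, got {self.calendar_date!r}")


def anchor_dates(events: Iterable[EventDate]) -> dict[tuple[str, str], int]:
    """Replace calendar dates with study-day offsets from each baseline.

    Every participant must have exactly one baseline event; offsets are
    exact calendar-day differences, so pairwise intervals are preserved.
    """
    by_pid: dict[str, list[EventDate]] = {}
    for e in events:
        by_pid.setdefault(e.participant_id, []).append(e)
    offsets: dict[tuple[str, str], int] = {}
    for pid, evs in by_pid.items():
        baselines = [e for e in evs if e.is_baseline]
        if len(baselines) != 1:
            raise AnchoringError(
                f"participant {pid!r} has {len(baselines)} baseline events (need exactly 1)"
            )
        day0 = baselines[0].calendar_date
        for e in evs:
            offsets[(pid, e.event_label)] = (e.calendar_date - day0).days
    return offsets


def _parse_time(value) -> int:
    """Time-of-day to microseconds since midnight."""
    if isinstance(value, dt.time):
        t = value
    elif isinstance(value, str):
        try:
            t = dt.time.fromisoformat(value)
        except ValueError as exc:
            raise DeidError(f"not a time of day: {value!r}") from exc
    else:
        raise DeidError(f"not a time of day: {value!r}")
    return ((t.hour * 60 + t.minute) * 60 + t.second) * 1_000_000 + t.microsecond


def quantize_time(t: dt.time | str):
    """Round a time of day to the nearest quarter hour.

    Ties (exactly 7.5 minutes) round up; 23:52:30 and later wrap to
    00:00:00.  Returns the same type it was given (``HH:MM:SS`` for
    strings).
    """
    us = _parse_time(t)
    q = ((us + _QUARTER_US // 2) // _QUARTER_US) * _QUARTER_US % _DAY_US
    seconds = q // 1_000_000
    out = dt.time(seconds // 3600, (seconds % 3600) // 60, seconds % 60)
    return out.strftime("%H:%M:%S") if isinstance(t, str) else out


_LETTERS = string.ascii_uppercase
_CATEGORIES = ("institution", "scanner_serial", "participant_id")
_CODE_LABEL = {"institution": "Institution", "scanner_serial": "Scanner"}


def _letter_sequence(seed: int):
    rng = random.Random(seed)
    singles = list(_LETTERS)
    rng.shuffle(singles)
    yield from singles
    for a in singles:
        for b in singles:
            yield a + b


@dataclass
class RecodingMap:
    """Deterministic, append-only map from identifying values to codes.

    Institutions and scanner serials receive letter codes
    (``Institution A`` ... then two-letter codes, 702 in total);
    participant IDs receive a fixed study prefix plus a zero-padded index
    (``T00042``).  Codes are drawn from a seed-shuffled sequence, so the
    assignment is deterministic given ``(seed, insertion order)``; use
    :meth:`recode_all` with ``sorted_input=True`` for an order-independent
    assignment.  Recoding an already-assigned code returns it unchanged.
    """

    category: str
    seed: int = 0
    forward: dict[str, str] = field(default_factory=dict)
    prefix: str = "T"
    width: int = 5

    def __post_init__(self):
        if self.category not in _CATEGORIES:
            raise DeidError(f"unknown recoding category {self.category!r}")
        codes = list(self.forward.values())
        if len(set(codes)) != len(codes):
            raise DeidError("forward map is not injective")

    # -- code grammar ------------------------------------------------------
    def is_code(self, value: str) -> bool:
        if self.category == "participant_id":
            return bool(re.fullmatch(re.escape(self.prefix) + r"\d{%d}" % self.width, value))
        label = _CODE_LABEL[self.category]
        return bool(re.fullmatch(re.escape(label) + r" [A-Z]{1,2}", value))

    @property
    def capacity(self) -> int:
        if self.category == "participant_id":
            return 10 ** self.width
        return len(_LETTERS) + len(_LETTERS) ** 2

    def _next_code(self) -> str:
        used = set(self.forward.values())
        if len(used) >= self.capacity:
            raise CodeSpaceExhausted(
                f"{self.category} code space exhausted (capacity {self.capacity})"
            )
        if self.category == "participant_id":
            rng = random.Random(self.seed)
            while True:
                cand = f"{self.prefix}{rng.randrange(self.capacity):0{self.width}d}"
                if cand not in used:
                    return cand
        label = _CODE_LABEL[self.category]
        for letters in _letter_sequence(self.seed):
            code = f"{label} {letters}"
            if code not in used:
                return code
        raise CodeSpaceExhausted(f"{self.category} code space exhausted")

    def recode(self, value: str) -> str:
        """Return the stable code for ``value``, assigning one if new."""
        if not isinstance(value, str) or not value:
            raise DeidError(f"cannot recode empty value {value!r}")
        if value in self.forward:
            return self.forward[value]
        if self.is_code(value):
            return value
        code = self._next_code()
        self.forward[value] = code
        return code

    def recode_all(self, values: Iterable[str], sorted_input: bool = False) -> dict[str, str]:
        vals = sorted(set(values)) if sorted_input else list(values)
        return {v: self.recode(v) for v in vals}

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "seed": self.seed,
            "forward": dict(self.forward),
            "prefix": self.prefix,
            "width": self.width,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RecodingMap":
        return cls(category=d["category"], seed=int(d["seed"]),
                   forward=dict(d.get("forward", {})),
                   prefix=d.get("prefix", "T"), width=int(d.get("width", 5)))


@dataclass
class RecodingMaps:
    """The three per-category maps used when scrubbing one study."""

    institution: RecodingMap
    scanner_serial: RecodingMap
    participant_id: RecodingMap

    @classmethod
    def with_seed(cls, seed: int, prefix: str = "T") -> "RecodingMaps":
        base = seed % (2 ** 31 - 3)
        return cls(
            institution=RecodingMap("institution", seed=base),
            scanner_serial=RecodingMap("scanner_serial", seed=base + 1),
            participant_id=RecodingMap("participant_id", seed=base + 2, prefix=prefix),
        )

    def save(self, path: Path | str) -> None:
        atomic_write_json(path, {
            "institution": self.institution.to_dict(),
            "scanner_serial": self.scanner_serial.to_dict(),
            "participant_id": self.participant_id.to_dict(),
        })

    @classmethod
    def load(cls, path: Path | str) -> "RecodingMaps":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(*(RecodingMap.from_dict(d[k])
                     for k in ("institution", "scanner_serial", "participant_id")))


TRANSFORM_NAMES = ("anchor_date", "quantize_time", "recode_institution", "recode_serial")

DEFAULT_REMOVE_FIELDS = [
    "PatientName",
    "PatientID",
    "PatientBirthDate",
    "PerformingPhysicianName",
    "ReferringPhysicianName",
    "InstitutionalDepartmentName",
]

DEFAULT_TRANSFORM_FIELDS = {
    "AcquisitionDate": "anchor_date",
    "AcquisitionDateTime": "anchor_date",
    "AcquisitionTime": "quantize_time",
    "InstitutionName": "recode_institution",
    "InstitutionAddress": "recode_institution",
    "DeviceSerialNumber": "recode_serial",
    "StationName": "recode_serial",
}


@dataclass
class ScrubPolicy:
    """Which metadata fields to drop and which to transform."""

    remove_fields: list[str] = field(default_factory=lambda: list(DEFAULT_REMOVE_FIELDS))
    transform_fields: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_TRANSFORM_FIELDS))

    def __post_init__(self):
        overlap = set(self.remove_fields) & set(self.transform_fields)
        if overlap:
            raise DeidError(f"fields cannot be both removed and transformed: {sorted(overlap)}")
        for f_, t in self.transform_fields.items():
            if t not in TRANSFORM_NAMES:
                raise DeidError(f"unknown transform {t!r} for field {f_!r}")

    @classmethod
    def from_file(cls, path: Path | str) -> "ScrubPolicy":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        return cls(remove_fields=list(d.get("remove_fields", [])),
                   transform_fields=dict(d.get("transform_fields", {})))


def _parse_any_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    if isinstance(value, str):
        s = value.replace("T", " ")
        try:
            return dt.datetime.fromisoformat(s).date() if " " in s else dt.date.fromisoformat(s)
        except ValueError as exc:
            raise DeidError(f"unparseable date {value!r}") from exc
    raise DeidError(f"unparseable date {value!r}")


def _apply_transform(rule: str, value, maps: RecodingMaps, anchor: dt.date | None):
    if rule == "anchor_date":
        if isinstance(value, int):  # already a study day
            return value
        if anchor is None:
            raise DeidError("no baseline anchor available for date anchoring")
        return (_parse_any_date(value) - anchor).days
    if rule == "quantize_time":
        return quantize_time(value)
    if rule == "recode_institution":
        return maps.institution.recode(str(value))
    if rule == "recode_serial":
        return maps.scanner_serial.recode(str(value))
    raise DeidError(f"unknown transform {rule!r}")


def scrub_sidecar(
    metadata: Mapping,
    policy: ScrubPolicy,
    maps: RecodingMaps,
    anchor: dt.date | str | None = None,
) -> tuple[dict, list[tuple[str, str]]]:
    """Apply a scrub policy to one sidecar metadata map.

    Returns the scrubbed map and an audit list of ``(field, action)`` for
    every change.  Fields whose transform fails (unparseable date/time)
    are dropped, never kept raw.  Applying the same policy twice is a
    no-op.
    """
    if isinstance(anchor, str):
        anchor = dt.date.fromisoformat(anchor)
    out: dict = {}
    audit: list[tuple[str, str]] = []
    for key, value in metadata.items():
        if key in policy.remove_fields:
            audit.append((key, "removed"))
            continue
        rule = policy.transform_fields.get(key)
        if rule is None:
            out[key] = value
            continue
        try:
            new = _apply_transform(rule, value, maps, anchor)
        except DeidError:
            audit.append((key, "dropped-unparseable"))
            continue
        out[key] = new
        if new != value:
            audit.append((key, rule))
    return out, audit


def scrub_dataset(
    bids_root: Path | str,
    policy: ScrubPolicy,
    maps: RecodingMaps,
    baselines: Mapping[str, dt.date | str] | None = None,
) -> list[tuple[str, str, str]]:
    """Scrub every sidecar JSON under the subject folders, in place.

    ``baselines`` maps participant labels to baseline dates for the
    ``anchor_date`` transform.  Returns audit rows ``(path, field,
    action)``.
    """
    from .layout import parse_bids_name, BidsNameError

    root = Path(bids_root)
    baselines = dict(baselines or {})
    rows: list[tuple[str, str, str]] = []
    for f in sorted(root.glob("sub-*/**/*.json")):
        try:
            parsed = parse_bids_name(f.name)
        except BidsNameError:
            continue
        if parsed.suffix == "phenotype":
            continue
        anchor = baselines.get(parsed.subject)
        with open(f, encoding="utf-8") as fh:
            meta = json.load(fh)
        scrubbed, audit = scrub_sidecar(meta, policy, maps, anchor)
        if audit:
            atomic_write_json(f, scrubbed)
        rel = str(f.relative_to(root))
        rows.extend((rel, fld, action) for fld, action in audit)
    return rows


@dataclass(frozen=True)
class Finding:
    """One residual-identifier hit from :func:`audit_dataset`."""

    path: str
    field: str
    kind: str
    detail: str = ""


_DATE_RE = re.compile(r"\b\d{4}-\d{2}-\d{2}\b|\b\d{1,2}/\d{1,2}/\d{4}\b")
_TIME_RE = re.compile(r"\b(\d{1,2}):(\d{2})(?::(\d{2})(?:\.\d+)?)?\b")

#: fields whose very presence is a finding
ALWAYS_IDENTIFYING_FIELDS = frozenset(DEFAULT_REMOVE_FIELDS)
#: fields allowed only with pseudonymous-code values
_CODED_FIELD_CATEGORY = {
    "InstitutionName": "institution",
    "InstitutionAddress": "institution",
    "DeviceSerialNumber": "scanner_serial",
    "StationName": "scanner_serial",
}
_AUDIT_SKIP_DIRS = {"sourcedata", "derivatives", "code"}


def _iter_leaves(obj, prefix=""):
    if isinstance(obj, Mapping):
        for k, v in obj.items():
            yield from _iter_leaves(v, f"{prefix}{k}." if not prefix else f"{prefix}{k}.")
    elif isinstance(obj, (list, tuple)):
        for v in obj:
            yield from _iter_leaves(v, prefix)
    else:
        yield prefix.rstrip("."), obj


def _off_grid_time(text: str) -> str | None:
    for m in _TIME_RE.finditer(text):
        minute = int(m.group(2))
        second = int(m.group(3)) if m.group(3) else 0
        if minute % 15 != 0 or second != 0:
            return m.group(0)
    return None


def audit_dataset(bids_root: Path | str) -> list[Finding]:
    """Scan JSON metadata for residual identifying information.

    Flags: fields from the identifying-name list; institution/serial
    fields whose value is not a pseudonymous code; any string containing a
    calendar-date pattern; any time-of-day with sub-quarter-hour
    precision.  Unreadable files are reported as unverifiable rather than
    silently skipped.
    """
    root = Path(bids_root)
    code_maps = {cat: RecodingMap(cat) for cat in ("institution", "scanner_serial")}
    findings: list[Finding] = []
    for f in sorted(root.rglob("*.json")):
        relparts = f.relative_to(root).parts
        if relparts and relparts[0] in _AUDIT_SKIP_DIRS:
            continue
        rel = str(f.relative_to(root))
        try:
            with open(f, encoding="utf-8") as fh:
                meta = json.load(fh)
        except (OSError, json.JSONDecodeError) as exc:
            findings.append(Finding(rel, "", "unverifiable", str(exc)))
            continue
        for key_path, value in _iter_leaves(meta):
            leaf = key_path.split(".")[-1]
            if leaf in ALWAYS_IDENTIFYING_FIELDS:
                findings.append(Finding(rel, key_path, "identifying-field"))
            cat = _CODED_FIELD_CATEGORY.get(leaf)
            if cat and isinstance(value, str) and not code_maps[cat].is_code(value):
                findings.append(Finding(rel, key_path, "uncoded-value", value))
            if isinstance(value, str):
                dm = _DATE_RE.search(value)
                if dm:
                    findings.append(Finding(rel, key_path, "date", dm.group(0)))
                tm = _off_grid_time(value)
                if tm:
                    findings.append(Finding(rel, key_path, "sub-quarter-hour-time", tm))
    return findings
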