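"""Subject-level hierarchical phenotype storage.

Wide per-study phenotype tables are *deconstructed* into one JSON document
per participant, stored next to that participant's imaging data.  Each
document has a ``demographics`` section for visit-invariant values (ID,
age at baseline, sex, gene status, ...) and a ``sessions`` section keyed
by visit label for scores collected repeatedly.  A
:class:`VariableDictionary` carries, for every canonical variable, its
aliases (e.g. ``gender`` resolving to ``sex``), the accepted categorical
codes, and the provenance of each value: source study, source file or
form, and original variable name.

Tables are *regenerated* from the documents on demand: a participants
table for demographics plus per-domain session tables, with missing cells
encoded as ``n/a``.  Because documents live in the subject folder,
updating the dataset is just adding or removing a folder and regenerating
the tables.
"""

from __future__ import annotations

import difflib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from ._util import atomic_write_json, atomic_write_text

__all__ = [
    "SourceRecord",
    "VariableSpec",
    "VariableDictionary",
    "ParticipantPhenoDocument",
    "PhenotypeError",
    "UnknownVariableError",
    "AliasCollisionError",
    "ConflictingValueError",
    "deconstruct_tables",
    "generate_tables",
    "harmonize_dictionaries",
    "count_table_cells",
    "count_document_cells",
    "write_documents",
    "read_documents",
    "write_phenotype_tables",
]

SCHEMA_VERSION = "1.0"
MISSING = "n/a"  # BIDS missing-value marker in emitted tables

LEVELS = ("demographic", "session")
VALUE_TYPES = ("string", "integer", "real", "categorical", "date-offset")


class PhenotypeError(ValueError):
    pass


class UnknownVariableError(PhenotypeError):
    def __init__(self, name: str, candidates: Sequence[str] = ()):
        self.name = name
        self.near_matches = difflib.get_close_matches(name, candidates, n=3)
        hint = f"; did you mean {self.near_matches}?" if self.near_matches else ""
        super().__init__(f"unknown variable {name!r}{hint}")


class AliasCollisionError(PhenotypeError):
    pass


class ConflictingValueError(PhenotypeError):
    pass


@dataclass(frozen=True)
class SourceRecord:
    """Where a variable's values came from."""

    source_study: str
    source_file: str
    original_variable_name: str

    def __post_init__(self):
        for f_ in ("source_study", "source_file", "original_variable_name"):
            if not getattr(self, f_):
                raise PhenotypeError(f"SourceRecord.{f_} must be non-empty")

    def to_dict(self) -> dict:
        return {"source_study": self.source_study, "source_file": self.source_file,
                "original_variable_name": self.original_variable_name}

    @classmethod
    def from_dict(cls, d: Mapping) -> "SourceRecord":
        return cls(d["source_study"], d["source_file"], d["original_variable_name"])


@dataclass
class VariableSpec:
    canonical_name: str
    level: str
    value_type: str = "string"
    aliases: set[str] = field(default_factory=set)
    accepted_codes: dict[str, str] | None = None
    provenance: list[SourceRecord] = field(default_factory=list)

    def __post_init__(self):
        if not self.canonical_name:
            raise PhenotypeError("canonical_name must be non-empty")
        if self.level not in LEVELS:
            raise PhenotypeError(f"level must be one of {LEVELS}, got {self.level!r}")
        if self.value_type not in VALUE_TYPES:
            raise PhenotypeError(f"value_type must be one of {VALUE_TYPES}")
        self.aliases = set(self.aliases)
        if self.canonical_name in self.aliases:
            raise PhenotypeError(f"{self.canonical_name!r} cannot be its own alias")

    def cast(self, value):
        """Coerce a raw table cell to this variable's scalar type."""
        if self.value_type in ("integer", "date-offset"):
            iv = int(value)
            if isinstance(value, float) and value != iv:
                raise PhenotypeError(
                    f"{self.canonical_name}: non-integral value {value!r}")
            return iv
        if self.value_type == "real":
            return float(value)
        return str(value)

    def validate_code(self, value) -> None:
        if self.accepted_codes is not None and str(value) not in self.accepted_codes:
            raise PhenotypeError(
                f"{self.canonical_name}: value {value!r} not among accepted codes "
                f"{sorted(self.accepted_codes)}")

    def to_dict(self) -> dict:
        return {
            "canonical_name": self.canonical_name,
            "level": self.level,
            "value_type": self.value_type,
            "aliases": sorted(self.aliases),
            "accepted_codes": self.accepted_codes,
            "provenance": [p.to_dict() for p in self.provenance],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "VariableSpec":
        return cls(
            canonical_name=d["canonical_name"],
            level=d["level"],
            value_type=d.get("value_type", "string"),
            aliases=set(d.get("aliases", [])),
            accepted_codes=d.get("accepted_codes"),
            provenance=[SourceRecord.from_dict(p) for p in d.get("provenance", [])],
        )


class VariableDictionary:
    """Canonical variable names, aliases, codes, and provenance for a study.

    Aliases are global: no alias may equal any other entry's canonical
    name or alias, so every name resolves to exactly one variable.
    """

    def __init__(self, study_label: str, entries: Iterable[VariableSpec] = ()):
        self.study_label = study_label
        self.entries: dict[str, VariableSpec] = {}
        for spec in entries:
            self.add(spec)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        try:
            self.resolve(name)
            return True
        except UnknownVariableError:
            return False

    def _name_owner(self) -> dict[str, str]:
        owner: dict[str, str] = {}
        for spec in self.entries.values():
            owner[spec.canonical_name] = spec.canonical_name
            for a in spec.aliases:
                owner[a] = spec.canonical_name
        return owner

    def add(self, spec: VariableSpec) -> None:
        owner = self._name_owner()
        for name in {spec.canonical_name, *spec.aliases}:
            if name in owner:
                raise AliasCollisionError(
                    f"name {name!r} already used by variable {owner[name]!r}")
        self.entries[spec.canonical_name] = spec

    def resolve(self, name: str) -> str:
        """Return the canonical name for ``name`` (itself or an alias)."""
        owner = self._name_owner()
        if name in owner:
            return owner[name]
        raise UnknownVariableError(name, sorted(owner))

    def resolve_column(self, column: str, source_study: str | None = None) -> str:
        """Resolve a table column: canonical name, alias, or provenance original name."""
        owner = self._name_owner()
        if column in owner:
            return owner[column]
        for spec in self.entries.values():
            for rec in spec.provenance:
                if rec.original_variable_name == column and (
                        source_study is None or rec.source_study == source_study):
                    return spec.canonical_name
        raise UnknownVariableError(column, sorted(owner))

    def spec_for(self, name: str) -> VariableSpec:
        return self.entries[self.resolve(name)]

    def add_alias(self, canonical_name: str, alias: str) -> "VariableDictionary":
        """Register ``alias`` under an existing canonical variable."""
        if canonical_name not in self.entries:
            raise UnknownVariableError(canonical_name, sorted(self.entries))
        if not alias:
            raise PhenotypeError("alias must be non-empty")
        owner = self._name_owner()
        if alias in owner:
            raise AliasCollisionError(
                f"alias {alias!r} already used by variable {owner[alias]!r}")
        self.entries[canonical_name].aliases.add(alias)
        return self

    def to_dict(self) -> dict:
        return {"study_label": self.study_label,
                "entries": [self.entries[k].to_dict() for k in sorted(self.entries)]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "VariableDictionary":
        return cls(d["study_label"], (VariableSpec.from_dict(e) for e in d["entries"]))

    def save(self, path: Path | str) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            atomic_write_text(path, yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            atomic_write_json(path, self.to_dict())

    @classmethod
    def load(cls, path: Path | str) -> "VariableDictionary":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)


@dataclass
class ParticipantPhenoDocument:
    """One participant's hierarchical phenotype record."""

    participant_id: str
    demographics: dict = field(default_factory=dict)
    sessions: dict[str, dict] = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self):
        if not self.participant_id or not str(self.participant_id).isalnum():
            raise PhenotypeError(
                f"participant_id must be a non-empty alphanumeric label, "
                f"got {self.participant_id!r}")
        session_vars = {v for sess in self.sessions.values() for v in sess}
        overlap = session_vars & set(self.demographics)
        if overlap:
            raise PhenotypeError(
                f"variables in both demographics and sessions: {sorted(overlap)}")

    def cell_count(self) -> int:
        return len(self.demographics) + sum(len(s) for s in self.sessions.values())

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "demographics": dict(self.demographics),
            "sessions": {k: dict(v) for k, v in sorted(self.sessions.items())},
            "schema_version": self.schema_version,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParticipantPhenoDocument":
        return cls(
            participant_id=d["participant_id"],
            demographics=dict(d.get("demographics", {})),
            sessions={k: dict(v) for k, v in d.get("sessions", {}).items()},
            schema_version=d.get("schema_version", SCHEMA_VERSION),
        )

    def validate_against(self, dictionary: VariableDictionary) -> None:
        for name in self.demographics:
            if dictionary.spec_for(name).level != "demographic":
                raise PhenotypeError(f"{name!r} is not a demographic variable")
        for sess in self.sessions.values():
            for name in sess:
                if dictionary.spec_for(name).level != "session":
                    raise PhenotypeError(f"{name!r} is not a session variable")


def document_path(bids_root: Path | str, participant_id: str) -> Path:
    return Path(bids_root) / f"sub-{participant_id}" / f"sub-{participant_id}_phenotype.json"


def write_documents(documents: Mapping[str, ParticipantPhenoDocument],
                    bids_root: Path | str) -> list[Path]:
    """Store each document inside its subject folder (created if absent)."""
    paths = []
    for pid in sorted(documents):
        p = document_path(bids_root, pid)
        atomic_write_json(p, documents[pid].to_dict())
        paths.append(p)
    return paths


def read_documents(bids_root: Path | str) -> dict[str, ParticipantPhenoDocument]:
    docs = {}
    for p in sorted(Path(bids_root).glob("sub-*/sub-*_phenotype.json")):
        with open(p, encoding="utf-8") as fh:
            doc = ParticipantPhenoDocument.from_dict(json.load(fh))
        docs[doc.participant_id] = doc
    return docs


def _is_missing(value) -> bool:
    if value is None or (isinstance(value, str) and value in ("", MISSING)):
        return True
    try:
        return bool(pd.isna(value))
    except (TypeError, ValueError):
        return False


def _session_label(raw) -> str:
    """Normalize a visit identifier to a BIDS session label ('01', '02', ...)."""
    if isinstance(raw, float) and raw == int(raw):
        raw = int(raw)
    if isinstance(raw, int):
        return f"{raw:02d}"
    s = str(raw)
    return f"{int(s):02d}" if s.isdigit() else s


def count_table_cells(tables: Iterable[pd.DataFrame], id_column: str,
                      session_column: str | None = None) -> int:
    """Non-missing data cells across wide tables (key columns excluded)."""
    total = 0
    for table in tables:
        cols = [c for c in table.columns if c not in (id_column, session_column)]
        for col in cols:
            total += int(table[col].map(lambda v: not _is_missing(v)).sum())
    return total


def count_document_cells(documents: Mapping[str, ParticipantPhenoDocument]) -> int:
    return sum(doc.cell_count() for doc in documents.values())


def deconstruct_tables(
    tables: Sequence[pd.DataFrame],
    dictionary: VariableDictionary,
    id_column: str,
    session_column: str | None = None,
) -> dict[str, ParticipantPhenoDocument]:
    """Split wide study tables into per-participant documents.

    Every data column must resolve in ``dictionary`` (canonical name,
    alias, or provenance original name).  Demographic values are stored
    once with conflict detection; session values are keyed by visit label.
    The number of non-missing cells is conserved.
    """
    docs: dict[str, ParticipantPhenoDocument] = {}
    for ti, table in enumerate(tables):
        source = table.attrs.get("source_file", f"table[{ti}]")
        if id_column not in table.columns:
            raise PhenotypeError(f"{source}: id column {id_column!r} missing")
        has_session = session_column is not None and session_column in table.columns
        colmap: dict[str, str] = {}
        for col in table.columns:
            if col in (id_column, session_column):
                continue
            colmap[col] = dictionary.resolve_column(col)  # raises UnknownVariableError

        for _, row in table.iterrows():
            pid = str(row[id_column])
            doc = docs.setdefault(pid, ParticipantPhenoDocument(participant_id=pid))
            ses = _session_label(row[session_column]) if has_session else None
            for col, canonical in colmap.items():
                value = row[col]
                if _is_missing(value):
                    continue
                spec = dictionary.entries[canonical]
                value = spec.cast(value)
                if spec.level == "demographic":
                    if canonical in doc.demographics and doc.demographics[canonical] != value:
                        raise ConflictingValueError(
                            f"participant {pid!r}: conflicting values for {canonical!r} "
                            f"({doc.demographics[canonical]!r} vs {value!r} in {source})")
                    doc.demographics[canonical] = value
                else:
                    if ses is None:
                        raise PhenotypeError(
                            f"{source}: session variable {canonical!r} requires a "
                            f"session column")
                    sess = doc.sessions.setdefault(ses, {})
                    if canonical in sess and sess[canonical] != value:
                        raise ConflictingValueError(
                            f"participant {pid!r}, session {ses!r}: conflicting values "
                            f"for {canonical!r}")
                    sess[canonical] = value
    for doc in docs.values():
        doc.sessions = {k: doc.sessions[k] for k in sorted(doc.sessions)}
    return dict(sorted(docs.items()))


def generate_tables(
    documents: Mapping[str, ParticipantPhenoDocument],
    dictionary: VariableDictionary,
    requested_variables: Sequence[str] | None = None,
    domains: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Regenerate phenotype tables from participant documents.

    Returns a ``participants`` table (one row per participant) for
    demographic variables and one table per session domain (default:
    a single ``sessions`` table).  The column header is the name the
    caller requested, so alias requests are honored in the header while
    values come from the canonical variable.  Missing cells are ``NA`` in
    the returned frames and ``n/a`` once written to TSV.
    """
    if requested_variables is None:
        requested = [(name, name) for name in sorted(dictionary.entries)]
    else:
        requested = [(name, dictionary.resolve(name)) for name in requested_variables]

    demo = [(hdr, canon) for hdr, canon in requested
            if dictionary.entries[canon].level == "demographic"]
    sess_vars = [(hdr, canon) for hdr, canon in requested
                 if dictionary.entries[canon].level == "session"]

    def checked(canon, value):
        if value is None:
            return pd.NA
        dictionary.entries[canon].validate_code(value)
        return value

    out: dict[str, pd.DataFrame] = {}
    pids = sorted(documents)
    if demo:
        rows = [
            {"participant_id": pid,
             **{hdr: checked(canon, documents[pid].demographics.get(canon))
                for hdr, canon in demo}}
            for pid in pids
        ]
        out["participants"] = pd.DataFrame(
            rows, columns=["participant_id"] + [h for h, _ in demo])

    if sess_vars:
        canon_by_hdr = dict(sess_vars)
        if domains is None:
            domain_map = {"sessions": [h for h, _ in sess_vars]}
        else:
            domain_map = {dom: [h for h in hdrs if h in canon_by_hdr]
                          for dom, hdrs in domains.items()}
        for dom, headers in domain_map.items():
            if not headers:
                continue
            rows = []
            for pid in pids:
                doc = documents[pid]
                for ses in sorted(doc.sessions):
                    rows.append({
                        "participant_id": pid,
                        "session_id": ses,
                        **{hdr: checked(canon_by_hdr[hdr],
                                        doc.sessions[ses].get(canon_by_hdr[hdr]))
                           for hdr in headers},
                    })
            out[dom] = pd.DataFrame(rows, columns=["participant_id", "session_id"] + list(headers))
    return out


def write_phenotype_tables(
    tables: Mapping[str, pd.DataFrame],
    out_dir: Path | str,
    dictionary: VariableDictionary | None = None,
) -> list[Path]:
    """Write tables as TSV plus a JSON data dictionary with provenance."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        tsv = out_dir / f"{name}.tsv"
        atomic_write_text(tsv, df.to_csv(sep="\t", index=False, na_rep=MISSING))
        written.append(tsv)
        if dictionary is not None:
            sidecar = {}
            for col in df.columns:
                if col in ("participant_id", "session_id"):
                    sidecar[col] = {"Description": "row key"}
                    continue
                spec = dictionary.spec_for(col)
                entry = {
                    "Description": spec.canonical_name,
                    "ValueType": spec.value_type,
                    "Provenance": [p.to_dict() for p in spec.provenance],
                }
                if spec.accepted_codes:
                    entry["Levels"] = spec.accepted_codes
                sidecar[col] = entry
            jpath = out_dir / f"{name}.json"
            atomic_write_json(jpath, sidecar)
            written.append(jpath)
    return written


def harmonize_dictionaries(
    dicts: Sequence[VariableDictionary],
    equivalence_map: Mapping[tuple[str, str], str] | Iterable[tuple[tuple[str, str], str]],
) -> VariableDictionary:
    """Merge study dictionaries, condensing declared-equivalent variables.

    ``equivalence_map`` maps ``(study_label, name)`` — a canonical name or
    a provenance original name within that study — to the canonical name
    the merged entry should carry.  Equivalent entries must share the same
    level; their provenance records are concatenated and superseded
    canonical names are kept as aliases.  Undeclared name clashes between
    studies are rejected rather than silently merged.
    """
    eq = dict(equivalence_map if isinstance(equivalence_map, Mapping)
              else dict(equivalence_map))
    by_study = {d.study_label: d for d in dicts}
    if len(by_study) != len(dicts):
        raise PhenotypeError("study labels must be distinct")
    for (study, name) in eq:
        if study not in by_study:
            raise PhenotypeError(f"equivalence references unknown study {study!r}")
        by_study[study].resolve_column(name, source_study=None)

    groups: dict[str, list[tuple[VariableDictionary, VariableSpec, bool]]] = {}
    for d in dicts:
        for spec in d.entries.values():
            keys = {(d.study_label, spec.canonical_name)}
            keys |= {(p.source_study, p.original_variable_name) for p in spec.provenance}
            targets = {eq[k] for k in keys if k in eq}
            if len(targets) > 1:
                raise PhenotypeError(
                    f"{spec.canonical_name!r} in {d.study_label!r} is declared "
                    f"equivalent to multiple targets {sorted(targets)}")
            declared = bool(targets)
            target = targets.pop() if declared else spec.canonical_name
            groups.setdefault(target, []).append((d, spec, declared))

    merged = VariableDictionary("+".join(d.study_label for d in dicts))
    for target in sorted(groups):
        members = groups[target]
        if len(members) > 1 and not all(declared for _, _, declared in members):
            owners = sorted({d.study_label for d, _, _ in members})
            raise PhenotypeError(
                f"name clash on {target!r} between studies {owners} without a "
                f"declared equivalence")
        levels = {spec.level for _, spec, _ in members}
        if len(levels) > 1:
            raise PhenotypeError(
                f"cannot merge {target!r}: entries differ in level {sorted(levels)}")
        value_types = {spec.value_type for _, spec, _ in members}
        if len(value_types) > 1:
            raise PhenotypeError(
                f"cannot merge {target!r}: entries differ in value_type "
                f"{sorted(value_types)}")
        aliases: set[str] = set()
        codes: dict[str, str] = {}
        provenance: list[SourceRecord] = []
        for d, spec, _ in members:
            aliases |= spec.aliases
            if spec.canonical_name != target:
                aliases.add(spec.canonical_name)
            if spec.accepted_codes:
                for k, v in spec.accepted_codes.items():
                    codes.setdefault(k, v)
            if spec.provenance:
                provenance.extend(spec.provenance)
            else:
                provenance.append(SourceRecord(d.study_label, "unspecified",
                                               spec.canonical_name))
        merged.add(VariableSpec(
            canonical_name=target,
            level=members[0][1].level,
            value_type=members[0][1].value_type,
            aliases=aliases - {target},
            accepted_codes=codes or None,
            provenance=provenance,
        ))
    return merged
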